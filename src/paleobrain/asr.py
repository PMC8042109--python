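"""Ancestral state reconstruction: continuous traits and discrete locomotion.

Continuous traits are reconstructed under Brownian motion by generalized
least squares: the root estimate is the GLS mean ``(1'C^-1 1)^-1 1'C^-1 x``
and every internal node receives its conditional expectation given the tip
data, which coincides with the maximum-likelihood (re-rooting) estimate.

The discrete locomotor character evolves under a continuous-time Markov
model with equal transition rates (Mk-ER): a single rate ``q`` governs all
transitions among the k observed states, so ``P(t)`` has the closed
spectral form ``P_ii = 1/k + (k-1)/k e^{-kqt}``, ``P_ij = (1 - e^{-kqt})/k``.
``q`` is estimated by maximising the Felsenstein pruning likelihood with a
uniform root prior (which for ER is also the stationary distribution).
Stochastic character maps are drawn by sampling joint node states from the
conditional distribution and then filling in each edge's substitution
history conditioned on its endpoints (rejection sampling, with a
uniformization bridge as fallback on difficult edges).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import ValidationError
from .phylo_core import Phylogeny, shared_path_matrix

log = logging.getLogger(__name__)

Q_LOWER = 1e-8


@dataclass
class AsrContinuous:
    """Per-internal-node ML estimates of a continuous trait."""

    estimates: pd.Series      # indexed by internal node id
    variances: pd.Series      # conditional variance scaled by ML sigma^2
    root_estimate: float
    sigma2: float


def asr_continuous(tree: Phylogeny, trait: pd.Series) -> AsrContinuous:
    """Brownian-motion GLS reconstruction at every internal node."""
    missing = set(tree.labels) - set(trait.index)
    if missing:
        raise ValidationError(
            f"trait missing for tips {sorted(missing)}; prune the tree first"
        )
    x = trait.loc[tree.labels].to_numpy(dtype=float)
    if np.any(~np.isfinite(x)):
        bad = [t for t, v in zip(tree.labels, x) if not np.isfinite(v)]
        raise ValidationError(f"non-finite trait values for {bad}; prune the tree first")
    n = tree.n_tips
    C = shared_path_matrix(tree)
    Cinv = np.linalg.inv(C)
    one = np.ones(n)
    denom = one @ Cinv @ one
    mu = float(one @ Cinv @ x / denom)
    resid = x - mu
    sigma2 = float(resid @ Cinv @ resid / n)
    depth = tree.depths()
    est, var = {}, {}
    for node in tree.postorder:
        if node < n:
            continue
        tips_below = set(tree.clade_tips(node))
        t0 = next(iter(tips_below))
        c = np.minimum(depth[node], C[t0])  # shared path of node with each tip
        for i in tips_below:
            c[i] = depth[node]
        w = Cinv @ c
        est[node] = float(mu + w @ resid)
        var[node] = float(sigma2 * max(depth[node] - c @ w + (1 - one @ w) ** 2 / denom, 0.0))
    estimates = pd.Series(est).sort_index()
    return AsrContinuous(
        estimates=estimates,
        variances=pd.Series(var).sort_index(),
        root_estimate=float(estimates.loc[tree.root]),
        sigma2=sigma2,
    )


# -- Mk equal-rates machinery ------------------------------------------------


def er_transition_matrix(k: int, q: float, t: float) -> np.ndarray:
    """Closed-form P(t) for the k-state equal-rates model."""
    decay = np.exp(-k * q * t)
    P = np.full((k, k), (1.0 - decay) / k)
    np.fill_diagonal(P, 1.0 / k + (k - 1) / k * decay)
    return P


def _tip_partials(tree: Phylogeny, states: pd.Series, levels: list[str]) -> np.ndarray:
    n = tree.n_tips
    L = np.zeros((tree.n_nodes, len(levels)))
    index = {s: i for i, s in enumerate(levels)}
    for i, tip in enumerate(tree.labels):
        s = states.loc[tip]
        if s not in index:
            raise ValidationError(f"state {s!r} for tip {tip!r} not in levels {levels}")
        L[i, index[s]] = 1.0
    return L


def _pruning(tree: Phylogeny, tip_partials: np.ndarray, q: float, k: int):
    """Felsenstein pruning; returns per-node partials and total log-likelihood."""
    L = tip_partials.copy()
    logscale = 0.0
    for node in tree.postorder:
        if node < tree.n_tips:
            continue
        part = np.ones(k)
        for c in tree.children[node]:
            P = er_transition_matrix(k, q, tree.edge_length[c])
            part = part * (P @ L[c])
        s = part.sum()
        if s <= 0:
            return L, -np.inf
        L[node] = part / s
        logscale += np.log(s)
    root_like = float(np.mean(L[tree.root]))  # uniform prior 1/k
    return L, logscale + np.log(root_like) + 0.0


@dataclass
class MkErFit:
    q: float
    loglik: float
    levels: list[str]
    partials: np.ndarray = field(repr=False)  # scaled conditional likelihoods
    tree: Phylogeny = field(repr=False, default=None)

    def transition_matrix(self, t: float) -> np.ndarray:
        return er_transition_matrix(len(self.levels), self.q, t)

    @property
    def rate_matrix(self) -> np.ndarray:
        k = len(self.levels)
        Q = np.full((k, k), self.q)
        np.fill_diagonal(Q, -(k - 1) * self.q)
        return Q


def mk_er_loglik(tree: Phylogeny, states: pd.Series, q: float, levels: list[str]) -> float:
    L = _tip_partials(tree, states, levels)
    return _pruning(tree, L, q, len(levels))[1]


def mk_er_fit(
    tree: Phylogeny, states: pd.Series, levels: list[str] | None = None
) -> MkErFit:
    """ML rate of the equal-rates Markov model by bounded scalar search."""
    if levels is None:
        levels = sorted(set(states.loc[tree.labels]))
    k = len(levels)
    observed = set(states.loc[tree.labels])
    tip_L = _tip_partials(tree, states, levels)
    height = float(tree.tip_depths().max())
    if len(observed) < 2:
        warnings.warn("single observed state: rate estimate pinned at its lower bound")
        q = Q_LOWER
    else:
        lo, hi = np.log(Q_LOWER), np.log(100.0 / height)
        grid = np.linspace(lo, hi, 40)
        lls = [_pruning(tree, tip_L, float(np.exp(t)), k)[1] for t in grid]
        best = int(np.argmax(lls))
        a, b = grid[max(best - 1, 0)], grid[min(best + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda t: -_pruning(tree, tip_L, float(np.exp(t)), k)[1],
            bounds=(a, b),
            method="bounded",
            options={"xatol": 1e-8},
        )
        cand = [float(np.exp(grid[best])), float(np.exp(res.x))]
        q = max(cand, key=lambda qq: _pruning(tree, tip_L, qq, k)[1])
    partials, ll = _pruning(tree, tip_L, q, k)
    return MkErFit(q=q, loglik=ll, levels=list(levels), partials=partials, tree=tree)


# -- stochastic character mapping -------------------------------------------


@dataclass
class SimmapSummary:
    node_probs: pd.DataFrame       # internal node id x state frequencies
    state_times: pd.Series         # expected total Myr spent in each state
    q: float
    n_maps: int
    change_counts: np.ndarray      # substitutions per map
    node_states: np.ndarray = field(repr=False, default=None)  # n_maps x n_nodes


def _er_jump(rng: np.random.Generator, k: int, s: int) -> int:
    """Uniform jump to one of the other k-1 states."""
    j = int(rng.integers(k - 1))
    return j if j < s else j + 1


def _sample_path_rejection(
    rng: np.random.Generator, k: int, q: float, a: int, b: int, t: float, budget: int = 100
):
    """Endpoint-conditioned ER path by rejection; None if budget exhausted."""
    rate = (k - 1) * q
    for _ in range(budget):
        s, now, events = a, 0.0, []
        if rate > 0:
            while True:
                dt = rng.exponential(1.0 / rate)
                now += dt
                if now >= t:
                    break
                s = _er_jump(rng, k, s)
                events.append((now, s))
        if s == b:
            return events
    return None


def _sample_path_uniformization(
    rng: np.random.Generator, k: int, q: float, a: int, b: int, t: float
):
    """Endpoint-conditioned path via the uniformization bridge."""
    omega = k * q  # dominating rate > max(-Q_ii), so virtual jumps occur
    if omega <= 0:
        return []
    R = np.eye(k) + np.where(np.eye(k, dtype=bool), -(k - 1) * q, q) / omega
    Pt = er_transition_matrix(k, q, t)[a, b]
    # sample number of uniformized jumps
    u = rng.uniform()
    cum = 0.0
    n_jumps = 0
    powers = [np.eye(k)]
    log_pois = -omega * t
    term = np.exp(log_pois)
    nmax = 10000
    while n_jumps <= nmax:
        prob = term * powers[n_jumps][a, b] / Pt
        cum += prob
        if u <= cum:
            break
        n_jumps += 1
        powers.append(powers[-1] @ R)
        term *= omega * t / n_jumps
    # intermediate states
    states = [a]
    for m in range(1, n_jumps + 1):
        prev = states[-1]
        w = R[prev] * powers[n_jumps - m][:, b]
        w = w / w.sum()
        states.append(int(rng.choice(k, p=w)))
    times = np.sort(rng.uniform(0.0, t, size=n_jumps))
    events = [
        (float(tt), s)
        for tt, prev, s in zip(times, states[:-1], states[1:])
        if s != prev
    ]
    return events


def simmap_sample(
    tree: Phylogeny,
    states: pd.Series,
    q: float | None = None,
    n_maps: int = 1000,
    seed: int = 0,
    levels: list[str] | None = None,
    keep_histories: bool = False,
) -> SimmapSummary:
    """Stochastic character maps under Mk-ER with the empirical rate.

    ``q=None`` refits the ML rate first (the "empirical" convention).  Node
    state probabilities are the frequencies of each state across maps;
    per-state times and change counts come from the sampled histories.
    Deterministic for a fixed seed.
    """
    if q is None:
        fit = mk_er_fit(tree, states, levels)
        q = fit.q
    else:
        lv = levels if levels is not None else sorted(set(states.loc[tree.labels]))
        tip_L = _tip_partials(tree, states, lv)
        partials, ll = _pruning(tree, tip_L, q, len(lv))
        fit = MkErFit(q=q, loglik=ll, levels=list(lv), partials=partials, tree=tree)
    k = len(fit.levels)
    L = fit.partials
    rng = np.random.default_rng(seed)
    n_nodes = tree.n_nodes
    node_states = np.zeros((n_maps, n_nodes), dtype=int)
    state_time = np.zeros(k)
    changes = np.zeros(n_maps, dtype=int)
    histories: list[dict[int, list]] = []
    preorder = list(reversed(tree.postorder))
    root_w = L[tree.root] / L[tree.root].sum()  # uniform prior cancels
    fallbacks = 0
    for m in range(n_maps):
        s = np.zeros(n_nodes, dtype=int)
        s[tree.root] = int(rng.choice(k, p=root_w))
        hist: dict[int, list] = {}
        for node in preorder:
            for c in tree.children[node]:
                P = er_transition_matrix(k, q, tree.edge_length[c])
                w = P[s[node]] * L[c]
                w = w / w.sum()
                s[c] = int(rng.choice(k, p=w))
                ev = _sample_path_rejection(rng, k, q, s[node], s[c], tree.edge_length[c])
                if ev is None:
                    ev = _sample_path_uniformization(
                        rng, k, q, s[node], s[c], tree.edge_length[c]
                    )
                    fallbacks += 1
                changes[m] += len(ev)
                # accumulate state occupancy along the edge
                prev_t, prev_s = 0.0, s[node]
                for tt, ss in ev:
                    state_time[prev_s] += tt - prev_t
                    prev_t, prev_s = tt, ss
                state_time[prev_s] += tree.edge_length[c] - prev_t
                if keep_histories:
                    hist[c] = ev
        node_states[m] = s
        if keep_histories:
            histories.append(hist)
    if fallbacks:
        log.info("uniformization fallback used on %d edges", fallbacks)
    internal = [nd for nd in range(n_nodes) if nd >= tree.n_tips]
    probs = np.zeros((len(internal), k))
    for r, nd in enumerate(internal):
        counts = np.bincount(node_states[:, nd], minlength=k)
        probs[r] = counts / n_maps
    summary = SimmapSummary(
        node_probs=pd.DataFrame(probs, index=internal, columns=fit.levels),
        state_times=pd.Series(state_time / n_maps, index=fit.levels),
        q=q,
        n_maps=n_maps,
        change_counts=changes,
        node_states=node_states,
    )
    if keep_histories:
        summary.histories = histories  # type: ignore[attr-defined]
    return summary
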