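"""Non-phylogenetic ANOVA by residual randomization (RRPP) with post-hoc tests.

Each model term is tested by permuting the residuals of the reduced model
that excludes it, adding them back to the reduced fitted values, refitting,
and recomputing the sequential (Type I) F statistic.  Empirical p-values use
the +1 convention, counting the observed arrangement as one member of the
null distribution.  Post-hoc pairwise comparisons measure the distance
between group least-squares means (covariate held at its grand mean,
slope-adjusted when the interaction is in the model) against the same
residual-randomization distribution, unadjusted for multiplicity by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FitError
from .pgls import Design


@dataclass
class RrppResult:
    anova: pd.DataFrame        # term, df, ss, F, p
    iterations: int
    seed: int
    design: Design
    groups: pd.Series | None = None


def _hat_fit(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    return fitted, resid, float(resid @ resid)


def _term_matrices(design: Design) -> tuple[list[str], list[np.ndarray]]:
    """Nested design sequence: intercept, then cumulative term blocks."""
    X = design.X.to_numpy()
    names = ["intercept"]
    mats = [X[:, :1]]
    for term in ("pred1", "locomotion", "interaction"):
        sl = design.term_slices.get(term)
        if sl is None:
            continue
        names.append(term)
        mats.append(X[:, : sl.stop])
    return names, mats


def rrpp_anova(design: Design, iterations: int = 1000, seed: int = 0) -> RrppResult:
    """Sequential-F ANOVA with residual-randomization p-values."""
    if iterations < 99:
        raise FitError("need at least 99 iterations")
    y = design.y.to_numpy(dtype=float)
    names, mats = _term_matrices(design)
    n = y.size
    X_full = mats[-1]
    p_full = X_full.shape[1]
    if np.linalg.matrix_rank(X_full) < p_full:
        raise FitError("full design is rank deficient")

    def seq_stats(yy: np.ndarray):
        """Per-term (ss, F) given a response vector."""
        rss = [_hat_fit(m, yy)[2] for m in mats]
        ms_full = rss[-1] / (n - p_full)
        out = []
        for j in range(1, len(mats)):
            dfj = mats[j].shape[1] - mats[j - 1].shape[1]
            ss = rss[j - 1] - rss[j]
            out.append((ss, (ss / dfj) / ms_full if ms_full > 0 else 0.0, dfj))
        return rss, out

    rss_obs, obs = seq_stats(y)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(obs))
    for _ in range(iterations):
        for j in range(1, len(mats)):
            fitted, resid, _ = _hat_fit(mats[j - 1], y)
            y_star = fitted + rng.permutation(resid)
            rssr = _hat_fit(mats[j - 1], y_star)[2]
            rssf = _hat_fit(mats[j], y_star)[2]
            rss_full_star = _hat_fit(X_full, y_star)[2]
            dfj = mats[j].shape[1] - mats[j - 1].shape[1]
            ms = rss_full_star / (n - p_full)
            F_star = ((rssr - rssf) / dfj) / ms if ms > 0 else 0.0
            if F_star >= obs[j - 1][1] - 1e-12:
                exceed[j - 1] += 1
    # +1 convention: the observed arrangement is one member of the null set
    pvals = (exceed + 1.0) / (iterations + 1.0)
    table = pd.DataFrame(
        {
            "term": names[1:],
            "df": [o[2] for o in obs],
            "ss": [o[0] for o in obs],
            "F": [o[1] for o in obs],
            "p": pvals,
        }
    )
    table.loc[len(table)] = ["residual", n - p_full, rss_obs[-1], np.nan, np.nan]
    return RrppResult(anova=table, iterations=iterations, seed=seed, design=design)


def _ls_means(design: Design, beta: np.ndarray) -> pd.Series:
    """Group least-squares means at the grand-mean covariate value."""
    X = design.X
    xbar = float(X["pred1"].mean())
    names = list(X.columns)
    levels = [design.reference] + [c[4:-1] for c in names if c.startswith("loc[")]
    means = {}
    for level in levels:
        row = np.zeros(len(names))
        row[names.index("intercept")] = 1.0
        row[names.index("pred1")] = xbar
        loc_col = f"loc[{level}]"
        if loc_col in names:
            row[names.index(loc_col)] = 1.0
        int_col = f"pred1:loc[{level}]"
        if int_col in names:
            row[names.index(int_col)] = xbar
        means[level] = float(row @ beta)
    return pd.Series(means)


def rrpp_pairwise(
    design: Design, iterations: int = 1000, seed: int = 0, adjust: bool = False
) -> pd.DataFrame:
    """Pairwise LS-mean distances with residual-randomization p-values.

    The null model excludes every locomotion term (main effect and
    interaction); its permuted residuals generate the null distribution of
    each pairwise distance.  ``adjust=True`` applies BH over the pairs.
    """
    y = design.y.to_numpy(dtype=float)
    X = design.X.to_numpy()
    sl = design.term_slices["locomotion"]
    reduced = X[:, : sl.start]

    def distances(yy: np.ndarray) -> dict[tuple[str, str], float]:
        beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
        ls = _ls_means(design, beta)
        out = {}
        levels = list(ls.index)
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                out[(levels[i], levels[j])] = abs(ls[levels[i]] - ls[levels[j]])
        return out

    obs = distances(y)
    rng = np.random.default_rng(seed)
    fitted, resid, _ = _hat_fit(reduced, y)
    exceed = {pair: 0.0 for pair in obs}
    for _ in range(iterations):
        y_star = fitted + rng.permutation(resid)
        d_star = distances(y_star)
        for pair in obs:
            if d_star[pair] >= obs[pair] - 1e-12:
                exceed[pair] += 1
    rows = [
        {
            "group1": a,
            "group2": b,
            "distance": obs[(a, b)],
            "p": (exceed[(a, b)] + 1.0) / (iterations + 1.0),
        }
        for (a, b) in obs
    ]
    table = pd.DataFrame(rows)
    if adjust:
        from .group_tests import benjamini_hochberg

        table["p_adjusted"] = benjamini_hochberg(table["p"].to_numpy())
    return table
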