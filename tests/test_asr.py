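"""Continuous ASR, Mk equal-rates likelihood, stochastic character maps."""

import itertools

import numpy as np
import pandas as pd
import pytest

from paleobrain.asr import (
    asr_continuous,
    er_transition_matrix,
    mk_er_fit,
    mk_er_loglik,
    simmap_sample,
)
from paleobrain.errors import ValidationError
from paleobrain.phylo_core import Phylogeny

from conftest import random_tree


def reroot_pic_estimate(tree: Phylogeny, trait: pd.Series) -> dict[int, float]:
    """Independent oracle: BM belief propagation (re-rooting) estimates.

    Each subtree sends a (mean, variance) message along its edge; an
    internal node's ML estimate is the precision-weighted mean of all its
    neighbour messages.  Equivalent to re-rooting at every node.
    """
    x = trait.loc[tree.labels].to_numpy(dtype=float)
    up: dict[int, tuple[float, float]] = {}
    for node in tree.postorder:
        if node < tree.n_tips:
            up[node] = (x[node], 0.0)
        else:
            ms = [(up[c][0], up[c][1] + tree.edge_length[c]) for c in tree.children[node]]
            prec = sum(1.0 / v for _, v in ms)
            mean = sum(m / v for m, v in ms) / prec
            up[node] = (mean, 1.0 / prec)
    down: dict[int, tuple[float, float] | None] = {tree.root: None}
    for node in reversed(tree.postorder):
        for c in tree.children[node]:
            ms = []
            if down[node] is not None:
                m, v = down[node]
                ms.append((m, v))
            for sib in tree.children[node]:
                if sib != c:
                    ms.append((up[sib][0], up[sib][1] + tree.edge_length[sib]))
            prec = sum(1.0 / v for _, v in ms)
            mean = sum(m / v for m, v in ms) / prec
            down[c] = (mean, 1.0 / prec + tree.edge_length[c])
    est = {}
    for node in tree.postorder:
        if node < tree.n_tips:
            continue
        ms = [(up[c][0], up[c][1] + tree.edge_length[c]) for c in tree.children[node]]
        if down[node] is not None:
            ms.append(down[node])
        prec = sum(1.0 / v for _, v in ms)
        est[node] = sum(m / v for m, v in ms) / prec
    return est


class TestContinuousAsr:
    def test_constant_trait_everywhere(self, three_tip_tree):
        rec = asr_continuous(three_tip_tree, pd.Series(2.5, index=["A", "B", "C"]))
        assert np.allclose(rec.estimates, 2.5)

    def test_two_tip_closed_form(self):
        tree = Phylogeny.from_newick("(A:2,B:3);")
        rec = asr_continuous(tree, pd.Series({"A": 1.0, "B": 4.0}))
        expected = (1.0 / 2 + 4.0 / 3) / (1.0 / 2 + 1.0 / 3)
        assert rec.root_estimate == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_rerooting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_tree(rng, 10)
        trait = pd.Series(rng.normal(size=10), index=tree.labels)
        rec = asr_continuous(tree, trait)
        oracle = reroot_pic_estimate(tree, trait)
        for node, val in oracle.items():
            assert rec.estimates.loc[node] == pytest.approx(val, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_estimates_within_tip_range(self, seed):
        rng = np.random.default_rng(100 + seed)
        tree = random_tree(rng, 15)
        trait = pd.Series(rng.normal(size=15), index=tree.labels)
        rec = asr_continuous(tree, trait)
        assert rec.estimates.min() >= trait.min() - 1e-9
        assert rec.estimates.max() <= trait.max() + 1e-9
        assert len(rec.estimates) == tree.n_nodes - tree.n_tips

    def test_missing_tip_instructs_to_prune(self, three_tip_tree):
        with pytest.raises(ValidationError, match="prune"):
            asr_continuous(three_tip_tree, pd.Series({"A": 1.0, "B": 2.0}))


class TestMkEqualRates:
    def test_pruning_matches_enumeration(self):
        """3-tip tree, 2 states: sum over all interior-state assignments."""
        tree = Phylogeny.from_newick("((A:1.2,B:0.7):0.9,C:2.1);")
        states = pd.Series({"A": "x", "B": "y", "C": "x"})
        levels = ["x", "y"]
        tip_idx = {"A": 0, "B": 1, "C": 0}
        rng = np.random.default_rng(0)
        for q in rng.uniform(0.01, 2.0, size=20):
            P = {n: er_transition_matrix(2, q, tree.edge_length[n]) for n in range(4)}
            # interior nodes: 3 (parent of A,B), 4 (root); enumerate states
            brute = 0.0
            for s3, s4 in itertools.product(range(2), repeat=2):
                term = 0.5  # uniform root prior
                term *= P[3][s4, s3] * P[2][s4, tip_idx["C"]]
                term *= P[0][s3, tip_idx["A"]] * P[1][s3, tip_idx["B"]]
                brute += term
            ll = mk_er_loglik(tree, states, q, levels)
            assert np.exp(ll) == pytest.approx(brute, abs=1e-10)

    def test_two_state_closed_form_same_tip_probability(self):
        """P(same endpoints) = (1 + exp(-2qt))/2 on a two-tip tree."""
        tree = Phylogeny.from_newick("(A:1.5,B:2.5);")
        states = pd.Series({"A": "x", "B": "x"})
        for q in (0.05, 0.4, 1.3):
            ll = mk_er_loglik(tree, states, q, ["x", "y"])
            p_same = lambda t: (1 + np.exp(-2 * q * t)) / 2
            p_diff = lambda t: (1 - np.exp(-2 * q * t)) / 2
            brute = 0.5 * (
                p_same(1.5) * p_same(2.5) + p_diff(1.5) * p_diff(2.5)
            )
            assert np.exp(ll) == pytest.approx(brute, abs=1e-12)

    def test_monomorphic_tips_pin_rate_low(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        states = pd.Series({t: "x" for t in "ABCD"})
        with pytest.warns(UserWarning, match="lower bound"):
            fit = mk_er_fit(tree, states, levels=["x", "y"])
        assert fit.q <= 1e-6
        root_prob = fit.partials[tree.root] / fit.partials[tree.root].sum()
        assert root_prob[0] > 0.999

    def test_rate_matrix_shape(self, default_dataset):
        fit = mk_er_fit(default_dataset.tree, default_dataset.traits.column("locomotion"))
        Q = fit.rate_matrix
        assert Q.shape == (5, 5)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
        assert fit.q > 0


class TestSimmap:
    def test_low_rate_monomorphic_maps_are_constant(self):
        tree = Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        states = pd.Series({t: "x" for t in "ABCD"})
        summary = simmap_sample(tree, states, q=1e-8, n_maps=50, seed=1,
                                levels=["x", "y"])
        assert np.all(summary.change_counts == 0)
        assert np.allclose(summary.node_probs["x"], 1.0)

    def test_root_frequencies_match_analytic_conditional(self):
        """Two-tip tree: sampled root states vs exact conditional probabilities."""
        tree = Phylogeny.from_newick("(A:1.0,B:2.0);")
        states = pd.Series({"A": "x", "B": "y"})
        q = 0.3
        n_maps = 10_000
        summary = simmap_sample(tree, states, q=q, n_maps=n_maps, seed=2,
                                levels=["x", "y"])
        Pa = er_transition_matrix(2, q, 1.0)
        Pb = er_transition_matrix(2, q, 2.0)
        w = np.array([Pa[s, 0] * Pb[s, 1] for s in range(2)])  # uniform prior
        p_root = w / w.sum()
        freq = summary.node_probs.loc[tree.root].to_numpy()
        se = np.sqrt(p_root * (1 - p_root) / n_maps)
        assert np.all(np.abs(freq - p_root) <= 3 * se + 1e-12)

    def test_histories_consistent_with_node_states(self, default_dataset):
        tree = default_dataset.tree
        states = default_dataset.traits.column("locomotion")
        summary = simmap_sample(tree, states, n_maps=20, seed=3, keep_histories=True)
        levels = list(summary.node_probs.columns)
        for m, hist in enumerate(summary.histories):
            s = summary.node_states[m]
            for node in tree.postorder:
                for c in tree.children[node]:
                    cur = s[node]
                    for _, new in hist[c]:
                        cur = new
                    assert cur == s[c]

    def test_change_count_monotone_in_rate(self, default_dataset):
        tree = default_dataset.tree
        states = default_dataset.traits.column("locomotion")
        fit = mk_er_fit(tree, states)
        means = []
        for factor in (1.0, 2.0, 4.0):
            summary = simmap_sample(
                tree, states, q=fit.q * factor, n_maps=100, seed=4
            )
            means.append(summary.change_counts.mean())
        assert means[0] < means[1] < means[2]

    def test_node_probabilities_sum_to_one(self, default_dataset):
        summary = simmap_sample(
            default_dataset.tree,
            default_dataset.traits.column("locomotion"),
            n_maps=50,
            seed=5,
        )
        assert np.allclose(summary.node_probs.sum(axis=1), 1.0, atol=1e-9)
        # expected state times cover the whole tree length
        total = default_dataset.tree.edge_length.sum()
        assert summary.state_times.sum() == pytest.approx(total, rel=1e-6)
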