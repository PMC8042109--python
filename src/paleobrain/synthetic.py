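"""Study-shaped synthetic datasets with known ground truth.

The generator emulates the structure of a fossil-inclusive comparative
dataset of sciuroid-grade rodents: a birth-death tree bearing 25 extant
tips and 13 fossil tips with Eocene-Miocene stratigraphic age bins, a
five-state locomotor character evolving under an equal-rates Markov
process, and log-scale brain measurements built as allometry
(E = a * M^b on the log10 scale) plus locomotor-category offsets plus
phylogenetically correlated residual noise (lambda-transformed Brownian
motion scaled to a target residual SD).  Brain-component fractions
(neocortex, petrosal lobules, olfactory bulbs) are generated on the logit
scale around root baselines so the trait-table invariants (component
strictly inside its whole) hold automatically.

Every latent quantity is stored in a truth record that the analysis
pipeline never reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .phylo_core import CovModelSpec, Phylogeny, model_covariance
from .timescale import AgeBinMatrix, prune_tree
from .traits import LOCOMOTOR_CATEGORIES, TraitTable

RESIDUAL_SD_DEFAULT = 0.103  # residual SD of the endocranial-volume regression


@dataclass
class SynthConfig:
    """Generator settings; defaults are the emulated study's conditions."""

    n_extant: int = 25
    n_fossil: int = 13
    birth_rate: float = 0.12          # lineages / Myr
    death_rate: float = 0.06
    origin_age: float = 56.0          # Ma; early Eocene origin
    fossil_window: tuple[float, float] = (10.0, 52.0)  # Ma (Miocene-Eocene)
    q_true: float = 0.01              # ER transition rate / Myr
    root_state: str = "scansorial"
    a_true: float = 0.42              # allometric coefficient (g, mm^3 units)
    b_true: float = 0.57              # allometric exponent
    lambda_true: float = 0.72
    residual_sd: float = RESIDUAL_SD_DEFAULT
    bm_root_log10: float = 2.7        # ~500 g ancestral body mass
    bm_rate: float = 0.007            # BM variance of log10 mass per Myr
    offsets: dict = field(
        default_factory=lambda: {"fossorial": -2.0, "arboreal": 1.0}
    )  # category offsets on log10 E, in units of residual_sd
    neo_base_pct: float = 18.3        # root-level component baselines
    pl_base_pct: float = 1.25
    ob_base_pct: float = 5.8
    component_sd: float = 0.30        # logit-scale residual SD of components
    ob_offsets: dict = field(
        default_factory=lambda: {"fossorial": 1.0, "arboreal": -0.5}
    )  # olfactory bulbs run opposite to neocortex/petrosal lobules
    missing_petrosal: int = 1         # tips lacking petrosal lobules
    require_all_categories: bool = True
    bin_width_range: tuple[float, float] = (2.0, 5.0)  # Myr, NALMA-like
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.b_true < 1):
            raise ValidationError("b_true must lie in (0, 1)")
        if min(self.birth_rate, self.death_rate, self.q_true) <= 0:
            raise ValidationError("rates must be > 0")
        if not 0 <= self.lambda_true <= 1:
            raise ValidationError("lambda_true must lie in [0, 1]")


@dataclass
class SynthDataset:
    tree: Phylogeny            # true calibrated tree (also the analysis topology)
    age_bins: AgeBinMatrix
    traits: TraitTable
    truth: dict                # latent values; never read by the pipeline


# -- birth-death tree --------------------------------------------------------


def _simulate_bd_forward(rng, birth, death, origin, max_nodes=50_000):
    """Forward birth-death simulation from one lineage at ``origin`` Ma.

    Each lineage lives an Exp(birth+death) time independently of the rest;
    at its end it splits with probability birth/(birth+death), otherwise it
    goes extinct.  Lineages reaching the present are truncated at age 0.
    Returns (parent, length, children, birth_time) or None if the tree
    exceeds ``max_nodes``.
    """
    parent = [-1]
    length = [0.0]
    children: list[list[int]] = [[]]
    birth_time = [float(origin)]   # age (Ma) at which the node's branch starts
    stack = [0]
    while stack:
        node = stack.pop()
        start = birth_time[node]
        life = rng.exponential(1.0 / (birth + death))
        end = start - life
        if end <= 0.0:
            length[node] = start  # survives to the present, age 0
            continue
        length[node] = life
        if rng.uniform() < birth / (birth + death):
            if len(parent) + 2 > max_nodes:
                return None
            for _ in range(2):
                parent.append(node)
                length.append(0.0)
                children.append([])
                birth_time.append(end)
                children[node].append(len(parent) - 1)
                stack.append(len(parent) - 1)
        # else: extinction at `end`; the branch simply stops
    return parent, length, children, birth_time


def _bd_phylogeny(rng, cfg: SynthConfig) -> Phylogeny | None:
    sim = _simulate_bd_forward(rng, cfg.birth_rate, cfg.death_rate, cfg.origin_age)
    if sim is None:
        return None
    parent, length, children, birth_time = sim
    tips = [i for i, ch in enumerate(children) if not ch]
    if len(tips) < 2:
        return None
    tip_age = {i: birth_time[i] - length[i] for i in tips}
    extant = [i for i in tips if tip_age[i] <= 1e-9]
    lo, hi = cfg.fossil_window
    fossils = [i for i in tips if lo <= tip_age[i] <= hi]
    if len(extant) < cfg.n_extant or len(fossils) < cfg.n_fossil:
        return None
    keep_ext = list(rng.choice(extant, size=cfg.n_extant, replace=False))
    keep_fos = list(rng.choice(fossils, size=cfg.n_fossil, replace=False))
    keep = set(keep_ext) | set(keep_fos)
    # relabel into a Phylogeny with tips first
    labels = {}
    for r, i in enumerate(sorted(keep_ext)):
        labels[i] = f"extant_{r + 1:02d}"
    for r, i in enumerate(sorted(keep_fos)):
        labels[i] = f"fossil_{r + 1:02d}"
    n_all = len(parent)
    tip_ids = [i for i in range(n_all) if not children[i]]
    internal_ids = [i for i in range(n_all) if children[i]]
    remap = {}
    all_labels = []
    for r, i in enumerate(tip_ids):
        remap[i] = r
        all_labels.append(labels.get(i, f"drop_{i}"))
    for r, i in enumerate(internal_ids):
        remap[i] = len(tip_ids) + r
    par = np.full(n_all, -1, dtype=int)
    elen = np.zeros(n_all)
    for i in range(n_all):
        if parent[i] >= 0:
            par[remap[i]] = remap[parent[i]]
        elen[remap[i]] = length[i]
    # the displayed root is the origin lineage's first branching event, so the
    # stem segment (node 0's own lifetime) does not count toward tip depths
    full = Phylogeny(
        labels=all_labels,
        parent=par,
        edge_length=elen,
        root_height=cfg.origin_age - length[0],
    )
    drop = [lab for lab in all_labels if lab.startswith("drop_")]
    tree = prune_tree(full, drop)
    return tree


# -- character & trait simulation -------------------------------------------


def _simulate_er_character(rng, tree: Phylogeny, q: float, root_state: str):
    """ER history on the tree; returns (node state array, change count)."""
    k = len(LOCOMOTOR_CATEGORIES)
    idx = {s: i for i, s in enumerate(LOCOMOTOR_CATEGORIES)}
    states = np.zeros(tree.n_nodes, dtype=int)
    states[tree.root] = idx[root_state]
    changes = 0
    rate = (k - 1) * q
    for node in reversed(tree.postorder):
        for c in tree.children[node]:
            s = states[node]
            t = tree.edge_length[c]
            now = 0.0
            while True:
                now += rng.exponential(1.0 / rate)
                if now >= t:
                    break
                j = int(rng.integers(k - 1))
                s = j if j < s else j + 1
                changes += 1
            states[c] = s
    return states, changes


def _phylo_noise(rng, tree: Phylogeny, lam: float, sd: float) -> np.ndarray:
    """Zero-mean noise with lambda-transformed BM covariance.

    The covariance is scaled so the mean tip variance equals ``sd**2``; the
    noise law therefore lies inside the lambda-model family the regression
    machinery fits.
    """
    if sd == 0.0:
        return np.zeros(tree.n_tips)
    V = model_covariance(tree, CovModelSpec("lambda", lam))
    cov = sd**2 * V / float(np.mean(np.diag(V)))
    cov += 1e-12 * np.eye(tree.n_tips)
    return rng.multivariate_normal(np.zeros(tree.n_tips), cov, method="cholesky")


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def simulate_dataset(cfg: SynthConfig) -> SynthDataset:
    """One complete synthetic dataset (tree + bins + traits + truth record)."""
    rng = np.random.default_rng(cfg.seed)
    tree = None
    for _ in range(500):
        tree = _bd_phylogeny(rng, cfg)
        if tree is not None:
            break
    if tree is None:
        raise ValidationError(
            "could not realise the requested tip counts; adjust birth/death rates"
        )
    # locomotor character (optionally retried until all categories appear)
    for attempt in range(200):
        node_states, n_changes = _simulate_er_character(
            rng, tree, cfg.q_true, cfg.root_state
        )
        tip_states = [LOCOMOTOR_CATEGORIES[s] for s in node_states[: tree.n_tips]]
        if not cfg.require_all_categories or len(set(tip_states)) == len(
            LOCOMOTOR_CATEGORIES
        ):
            break
    else:
        raise ValidationError(
            "could not realise all locomotor categories; increase q_true or "
            "set require_all_categories=False"
        )
    n = tree.n_tips
    ages = tree.tip_ages()
    extant = ages <= 1e-9

    # body mass: plain BM on log10 grams
    C = model_covariance(tree, CovModelSpec("brownian"))
    log_m = cfg.bm_root_log10 + rng.multivariate_normal(
        np.zeros(n), cfg.bm_rate * C + 1e-12 * np.eye(n), method="cholesky"
    )

    # endocranial volume: allometry + category offsets + correlated noise
    offset = np.array(
        [cfg.offsets.get(s, 0.0) * cfg.residual_sd for s in tip_states]
    )
    noise_e = _phylo_noise(rng, tree, cfg.lambda_true, cfg.residual_sd)
    log_e = np.log10(cfg.a_true) + cfg.b_true * log_m + offset + noise_e

    # component fractions on the logit scale
    def component(base_pct: float, offsets: dict) -> np.ndarray:
        off = np.array(
            [offsets.get(s, 0.0) * cfg.component_sd for s in tip_states]
        )
        z = (
            _logit(base_pct / 100.0)
            + off
            + _phylo_noise(rng, tree, cfg.lambda_true, cfg.component_sd)
        )
        return 100.0 * _expit(z)

    neo_pct = component(cfg.neo_base_pct, cfg.offsets)
    pl_pct = component(cfg.pl_base_pct, cfg.offsets)
    ob_pct = component(cfg.ob_base_pct, cfg.ob_offsets)

    E = 10.0**log_e
    M = 10.0**log_m
    SA_E = 4.84 * E ** (2.0 / 3.0)  # near-spherical endocast surface
    SA_N = neo_pct / 100.0 * SA_E
    V_PL = pl_pct / 100.0 * E
    V_OB = ob_pct / 100.0 * E

    pl_missing = np.zeros(n, dtype=bool)
    if cfg.missing_petrosal > 0:
        gliders = [i for i, s in enumerate(tip_states) if s == "glider" and extant[i]]
        pool = gliders if gliders else list(np.flatnonzero(extant))
        miss = rng.choice(pool, size=min(cfg.missing_petrosal, len(pool)), replace=False)
        pl_missing[np.asarray(miss, dtype=int)] = True

    traits = TraitTable.from_frame(
        pd.DataFrame(
            {
                "species": tree.labels,
                "status": np.where(extant, "extant", "extinct"),
                "locomotion": tip_states,
                "body_mass": M,
                "endocranial_volume": E,
                "endocranial_surface": SA_E,
                "neocortex_surface": SA_N,
                "olfactory_bulb_volume": V_OB,
                "petrosal_lobule_volume": np.where(pl_missing, np.nan, V_PL),
            }
        )
    )

    # stratigraphic bins: NALMA-like intervals around the true fossil age
    rows = []
    for i, tip in enumerate(tree.labels):
        if extant[i]:
            rows.append({"tip": tip, "fad_early": 0.0, "fad_late": 0.0,
                         "lad_early": 0.0, "lad_late": 0.0})
        else:
            w = rng.uniform(*cfg.bin_width_range)
            u = rng.uniform()
            early = ages[i] + u * w
            late = max(early - w, 0.0)
            rows.append({"tip": tip, "fad_early": early, "fad_late": late,
                         "lad_early": early, "lad_late": late})
    age_bins = AgeBinMatrix.from_frame(pd.DataFrame(rows))

    truth = {
        "config": cfg,
        "tip_states": pd.Series(tip_states, index=tree.labels),
        "node_states": node_states,
        "n_state_changes": n_changes,
        "log10_mass": pd.Series(log_m, index=tree.labels),
        "log10_endocranial": pd.Series(log_e, index=tree.labels),
        "allometric_noise": pd.Series(noise_e, index=tree.labels),
        "category_offset": pd.Series(offset, index=tree.labels),
        "node_ages": tree.node_ages(),
        "neo_pct": pd.Series(neo_pct, index=tree.labels),
        "pl_pct": pd.Series(pl_pct, index=tree.labels),
        "ob_pct": pd.Series(ob_pct, index=tree.labels),
    }
    return SynthDataset(tree=tree, age_bins=age_bins, traits=traits, truth=truth)


def truth_frame(ds: SynthDataset) -> pd.DataFrame:
    """Tabular truth record for CSV export (never read by the pipeline)."""
    t = ds.truth
    return pd.DataFrame(
        {
            "locomotion_true": t["tip_states"],
            "log10_mass_true": t["log10_mass"],
            "log10_endocranial_true": t["log10_endocranial"],
            "allometric_noise": t["allometric_noise"],
            "neo_pct_true": t["neo_pct"],
            "pl_pct_true": t["pl_pct"],
            "ob_pct_true": t["ob_pct"],
        }
    ).rename_axis("species")


# -- hand-sized fixture ------------------------------------------------------

FIXTURE_NEWICK = "(((A:10,B:10):10,(C:12,D:12):8):10,(E:15,F:15):15);"

_FIXTURE_ROWS = [
    # species, status, locomotion, M (g), E (mm^3), SA_E, SA_N, V_OB, V_PL
    ("A", "extant", "arboreal", 400.0, 4200.0, 1265.0, 380.0, 210.0, 63.0),
    ("B", "extant", "arboreal", 520.0, 5100.0, 1437.0, 450.0, 240.0, 78.0),
    ("C", "extant", "glider", 150.0, 2300.0, 845.0, 250.0, 130.0, 30.0),
    ("D", "extant", "terrestrial", 600.0, 4400.0, 1305.0, 330.0, 260.0, 55.0),
    ("E", "extinct", "fossorial", 900.0, 4000.0, 1224.0, 240.0, 300.0, 40.0),
    ("F", "extinct", "scansorial", 300.0, 3000.0, 1011.0, 230.0, 180.0, 42.0),
]


def fixture_small() -> SynthDataset:
    """Fixed six-tip dataset for hand-checkable oracle tests.

    Branch lengths and measurements are printed constants; the shared-path
    matrix, GLS estimates and permutation enumerations on this fixture can
    be verified by hand or brute force.
    """
    tree = Phylogeny.from_newick(FIXTURE_NEWICK)
    traits = TraitTable.from_frame(
        pd.DataFrame(
            _FIXTURE_ROWS,
            columns=[
                "species", "status", "locomotion", "body_mass",
                "endocranial_volume", "endocranial_surface",
                "neocortex_surface", "olfactory_bulb_volume",
                "petrosal_lobule_volume",
            ],
        )
    )
    rows = [
        {"tip": s, "fad_early": 0.0, "fad_late": 0.0, "lad_early": 0.0, "lad_late": 0.0}
        if st == "extant"
        else {"tip": s, "fad_early": 4.0, "fad_late": 2.0, "lad_early": 4.0, "lad_late": 2.0}
        for s, st, *_ in _FIXTURE_ROWS
    ]
    age_bins = AgeBinMatrix.from_frame(pd.DataFrame(rows))
    return SynthDataset(tree=tree, age_bins=age_bins, traits=traits, truth={"fixture": True})
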