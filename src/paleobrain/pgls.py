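"""Phylogenetic generalized least squares with evolutionary-model selection.

The regression machinery follows the comparative-methods convention: traits
are log10-transformed, the error covariance is a phylogenetic matrix built
under one of four models (Brownian motion, Pagel's lambda, Early Burst,
Ornstein-Uhlenbeck), the single covariance parameter is estimated by
maximising the profile log-likelihood, and competing formulas/models are
ranked by AIC.  Estimation is by maximum likelihood (not REML) throughout,
because formulas with different fixed effects are compared by AIC.

Six named regressions relate brain measurements to body size, brain size
and a five-level locomotor factor:

====  =============================  ==========================
id    response (log10)               predictor 1 (log10)
====  =============================  ==========================
1.EB  endocranial volume             body mass
1.PB  petrosal lobule volume         body mass
1.OB  olfactory bulb volume          body mass
2.PE  petrosal lobule volume         endocranial volume
2.NE  neocortex surface area         endocranial surface area
2.OE  olfactory bulb volume          endocranial volume
====  =============================  ==========================

Formula "a" is ``response ~ predictor1 + locomotion``; formula "b" adds the
``predictor1 x locomotion`` interaction.  The locomotor factor uses
treatment coding with "arboreal" (alphabetically first) as the reference
level; contrasts affect coefficients but not AIC, log-likelihood or the
sequential F tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import FitError, ParameterError, ValidationError
from .phylo_core import CovModelSpec, Phylogeny, model_covariance
from .traits import LOCOMOTOR_CATEGORIES, TraitTable

log = logging.getLogger(__name__)

REGRESSIONS: dict[str, tuple[str, str]] = {
    "1.EB": ("endocranial_volume", "body_mass"),
    "1.PB": ("petrosal_lobule_volume", "body_mass"),
    "1.OB": ("olfactory_bulb_volume", "body_mass"),
    "2.PE": ("petrosal_lobule_volume", "endocranial_volume"),
    "2.NE": ("neocortex_surface", "endocranial_surface"),
    "2.OE": ("olfactory_bulb_volume", "endocranial_volume"),
}

ALPHA_MAX_SCALE = 50.0   # alpha upper bound = 50 / tree height
EB_RATE_SCALE = 10.0     # early-burst lower bound = -10 / tree height


@dataclass(frozen=True)
class RegressionSpec:
    """One of the six named regressions plus a formula choice."""

    regression_id: str
    formula: str = "a"  # "a": no interaction, "b": with interaction

    def __post_init__(self) -> None:
        if self.regression_id not in REGRESSIONS:
            raise ValidationError(
                f"unknown regression {self.regression_id!r}; expected {sorted(REGRESSIONS)}"
            )
        if self.formula not in ("a", "b"):
            raise ValidationError("formula must be 'a' or 'b'")

    @property
    def response(self) -> str:
        return REGRESSIONS[self.regression_id][0]

    @property
    def predictor1(self) -> str:
        return REGRESSIONS[self.regression_id][1]


@dataclass
class Design:
    """Design matrix, response and bookkeeping for sequential tests."""

    X: pd.DataFrame
    y: pd.Series
    species: list[str]
    term_slices: dict[str, slice]  # column slices in formula order
    reference: str = "arboreal"    # reference level of the factor coding


@dataclass
class GLSFit:
    """A fitted GLS regression under a phylogenetic covariance model."""

    params: pd.Series
    sigma2: float
    loglik: float
    aic: float
    k: int
    rse: float
    df: tuple[int, int]  # (n, n - p_fixed)
    cov_spec: CovModelSpec
    design: Design | None = None
    V: np.ndarray | None = field(default=None, repr=False)
    pvalues: pd.Series | None = None

    @property
    def n(self) -> int:
        return self.df[0]


def build_design(table: TraitTable, spec: RegressionSpec) -> Design:
    """log10 response + design matrix with treatment-coded locomotion.

    Rows with a missing response or predictor are dropped with a logged
    warning (e.g. a species lacking petrosal lobules reduces n by one).
    """
    df = table.table
    used = [spec.response, spec.predictor1]
    keep = df[used].notna().all(axis=1)
    if not keep.all():
        dropped = df.species[~keep].tolist()
        log.warning("dropping %d species with missing %s: %s", len(dropped), used, dropped)
    sub = df[keep]
    observed = sorted(set(sub.locomotion))
    missing_levels = set(LOCOMOTOR_CATEGORIES) - set(observed)
    if missing_levels:
        raise ValidationError(
            f"locomotor levels absent from data: {sorted(missing_levels)}; observed {observed}"
        )
    y = np.log10(sub[spec.response].to_numpy())
    x1 = np.log10(sub[spec.predictor1].to_numpy())
    cols = {"intercept": np.ones(len(sub)), "pred1": x1}
    slices = {"pred1": slice(1, 2)}
    ref = LOCOMOTOR_CATEGORIES[0]  # arboreal
    start = len(cols)
    for level in LOCOMOTOR_CATEGORIES:
        if level == ref:
            continue
        cols[f"loc[{level}]"] = (sub.locomotion == level).astype(float).to_numpy()
    slices["locomotion"] = slice(start, len(cols))
    if spec.formula == "b":
        start = len(cols)
        for level in LOCOMOTOR_CATEGORIES:
            if level == ref:
                continue
            cols[f"pred1:loc[{level}]"] = cols[f"loc[{level}]"] * x1
        slices["interaction"] = slice(start, len(cols))
    X = pd.DataFrame(cols, index=sub.species.tolist())
    return Design(
        X=X,
        y=pd.Series(y, index=sub.species.tolist(), name=spec.response),
        species=sub.species.tolist(),
        term_slices=slices,
    )


def group_design(
    y,
    x,
    groups,
    names: list[str] | None = None,
    reference: str | None = None,
    interaction: bool = False,
) -> Design:
    """Generic covariate + factor design with treatment coding.

    Used for ad-hoc designs (simulations, toy fixtures) that do not come
    from a :class:`~paleobrain.traits.TraitTable`; column naming matches
    :func:`build_design` so downstream code treats both identically.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    g = np.asarray(groups)
    levels = sorted(np.unique(g))
    ref = reference if reference is not None else levels[0]
    if names is None:
        names = [f"s{i}" for i in range(y.size)]
    cols = {"intercept": np.ones(y.size), "pred1": x}
    slices = {"pred1": slice(1, 2)}
    start = len(cols)
    for level in levels:
        if level == ref:
            continue
        cols[f"loc[{level}]"] = (g == level).astype(float)
    slices["locomotion"] = slice(start, len(cols))
    if interaction:
        start = len(cols)
        for level in levels:
            if level == ref:
                continue
            cols[f"pred1:loc[{level}]"] = (g == level).astype(float) * x
        slices["interaction"] = slice(start, len(cols))
    X = pd.DataFrame(cols, index=names)
    return Design(
        X=X,
        y=pd.Series(y, index=names),
        species=list(names),
        term_slices=slices,
        reference=ref,
    )


def _whiten(V: np.ndarray) -> np.ndarray:
    """Cholesky factor of V, with one shot of diagonal jitter if needed."""
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError:
        jitter = 1e-10 * float(np.mean(np.diag(V)))
        try:
            return linalg.cholesky(V + jitter * np.eye(V.shape[0]), lower=True)
        except linalg.LinAlgError as exc:
            raise FitError("covariance matrix not positive definite") from exc


def gls_fit(
    y: np.ndarray | pd.Series,
    X: np.ndarray | pd.DataFrame,
    V: np.ndarray,
    cov_spec: CovModelSpec | None = None,
    design: Design | None = None,
) -> GLSFit:
    """ML generalized least squares under a fixed covariance matrix.

    beta = (X' V^-1 X)^-1 X' V^-1 y; sigma^2 profiled at RSS/n; AIC counts
    the fixed effects, sigma^2, and the covariance parameter if the model
    has one.  With V = I this reduces exactly to OLS.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else None
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    n, p = Xa.shape
    if n <= p:
        raise FitError(f"need n > p, got n={n}, p={p}")
    L = _whiten(V)
    z = linalg.solve_triangular(L, ya, lower=True)
    W = linalg.solve_triangular(L, Xa, lower=True)
    gram = W.T @ W
    rank = np.linalg.matrix_rank(gram)
    if rank < p:
        bad = names[rank] if names else f"column {rank}"
        raise FitError(f"design is rank deficient (collinear from {bad})")
    beta = linalg.solve(gram, W.T @ z, assume_a="pos")
    resid = z - W @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + n + logdetV)
    spec = cov_spec if cov_spec is not None else CovModelSpec("brownian")
    k = p + 1 + (0 if spec.model == "brownian" else 1)
    aic = -2.0 * loglik + 2.0 * k
    params = pd.Series(beta, index=names if names else [f"b{i}" for i in range(p)])
    return GLSFit(
        params=params,
        sigma2=sigma2,
        loglik=loglik,
        aic=aic,
        k=k,
        rse=float(np.sqrt(rss / (n - p))),
        df=(n, n - p),
        cov_spec=spec,
        design=design,
        V=np.asarray(V, dtype=float),
    )


def align_design(design: Design, tree: Phylogeny) -> Design:
    """Reorder design rows to the tree's tip order; sets must match exactly."""
    if set(design.species) != set(tree.labels):
        extra = sorted(set(design.species) ^ set(tree.labels))
        raise ValidationError(f"design species and tree tips differ: {extra}")
    X = design.X.loc[tree.labels]
    y = design.y.loc[tree.labels]
    return Design(X=X, y=y, species=list(tree.labels), term_slices=design.term_slices)


def _param_bounds(model: str, tree_height: float) -> tuple[float, float]:
    if model == "lambda":
        return (0.0, 1.0)
    if model == "ou":
        return (1e-6, ALPHA_MAX_SCALE / tree_height)
    if model == "early_burst":
        return (-EB_RATE_SCALE / tree_height, 0.0)
    raise ParameterError(f"model {model!r} has no free parameter")


def profile_fit(
    y: np.ndarray | pd.Series,
    X: np.ndarray | pd.DataFrame,
    tree: Phylogeny,
    model: str,
    design: Design | None = None,
    grid_points: int = 25,
) -> GLSFit:
    """ML fit with the covariance parameter profiled out by scalar search.

    A coarse grid locates the basin; Brent's bounded method then refines
    inside the bracketing interval.  ``brownian`` has no free parameter.
    """
    if model not in ("brownian", "lambda", "early_burst", "ou"):
        raise ParameterError(f"unknown model {model!r}")
    if design is not None:
        design = align_design(design, tree)
        y, X = design.y, design.X
    if model == "brownian":
        V = model_covariance(tree, CovModelSpec("brownian"))
        return gls_fit(y, X, V, CovModelSpec("brownian"), design)

    height = float(tree.tip_depths().max())

    def fit_at(theta: float) -> GLSFit:
        spec = CovModelSpec(model, float(theta))
        return gls_fit(y, X, model_covariance(tree, spec), spec, design)

    lo, hi = _param_bounds(model, height)
    grid = np.linspace(lo, hi, grid_points)
    lls = np.array([fit_at(t).loglik for t in grid])
    best = int(np.argmax(lls))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, grid_points - 1)]
    try:
        res = optimize.minimize_scalar(
            lambda t: -fit_at(t).loglik, bounds=(a, b), method="bounded",
            options={"xatol": 1e-7},
        )
    except Exception as exc:
        raise FitError(f"profile optimization failed near theta={grid[best]}") from exc
    candidates = [grid[best], float(res.x)]
    fits = [fit_at(t) for t in candidates]
    return max(fits, key=lambda f: f.loglik)


def select_model(
    design_a: Design,
    design_b: Design,
    tree: Phylogeny,
) -> tuple[GLSFit, pd.DataFrame]:
    """The published two-stage AIC selection over formulas and models.

    Fits all four evolutionary models for each formula, takes each
    formula's AIC-minimal model, and returns the overall winner (ties
    resolved toward the simpler formula "a").  The full 8-row AIC table is
    returned as the selection trace; individual fit failures are recorded
    in the trace and skipped.
    """
    rows = []
    fits: dict[tuple[str, str], GLSFit] = {}
    for formula, design in (("a", design_a), ("b", design_b)):
        for model in ("brownian", "lambda", "early_burst", "ou"):
            try:
                fit = profile_fit(design.y, design.X, tree, model, design)
                fits[(formula, model)] = fit
                rows.append(
                    {
                        "formula": formula,
                        "model": model,
                        "parameter": fit.cov_spec.parameter,
                        "loglik": fit.loglik,
                        "aic": fit.aic,
                        "k": fit.k,
                        "error": "",
                    }
                )
            except (FitError, ValidationError) as exc:
                rows.append(
                    {
                        "formula": formula,
                        "model": model,
                        "parameter": np.nan,
                        "loglik": np.nan,
                        "aic": np.nan,
                        "k": np.nan,
                        "error": str(exc),
                    }
                )
    trace = pd.DataFrame(rows)
    if not fits:
        raise FitError("every constituent fit failed; see trace")
    winners = {}
    for formula in ("a", "b"):
        sub = {m: f for (fml, m), f in fits.items() if fml == formula}
        if sub:
            winners[formula] = min(sub.values(), key=lambda f: f.aic)
    # tie broken toward formula a by iteration order + strict inequality
    best_formula = "a" if "a" in winners else "b"
    best = winners[best_formula]
    for formula, fit in winners.items():
        if fit.aic < best.aic - 1e-12:
            best, best_formula = fit, formula
    return best, trace


def sequential_pvalues(fit: GLSFit) -> pd.Series:
    """Sequential (Type I) F tests in formula order under the fitted covariance.

    Terms enter in the order predictor1, locomotion, interaction; each F is
    the drop in generalized residual sum of squares scaled by the full-model
    mean square, with denominator df = n - p_full.
    """
    if fit.design is None or fit.V is None:
        raise FitError("fit carries no design; refit via profile_fit/gls_fit with a Design")
    X = fit.design.X.to_numpy()
    y = fit.design.y.to_numpy()
    L = _whiten(fit.V)
    z = linalg.solve_triangular(L, y, lower=True)
    W = linalg.solve_triangular(L, X, lower=True)
    n, p = W.shape

    def rss(cols: int) -> float:
        beta, res, *_ = np.linalg.lstsq(W[:, :cols], z, rcond=None)
        r = z - W[:, :cols] @ beta
        return float(r @ r)

    rss_full = rss(p)
    denom_df = n - p
    ms_full = rss_full / denom_df
    out = {}
    prev_cols = 1  # intercept
    order = ["pred1", "locomotion", "interaction"]
    for term in order:
        sl = fit.design.term_slices.get(term)
        if sl is None:
            continue
        cols = sl.stop
        num_df = sl.stop - sl.start
        drop = rss(prev_cols) - rss(cols)
        F = (drop / num_df) / ms_full
        out[term] = float(stats.f.sf(max(F, 0.0), num_df, denom_df))
        prev_cols = cols
    return pd.Series(out)


@dataclass
class ResidualDiagnostic:
    """Phylogenetic clustering check on OLS residuals."""

    ordered_residuals: pd.Series  # residuals in post-order tip sequence
    score: float                  # mean |adjacent difference| along the tip order
    p_value: float
    use_pgls: bool


def phylo_residual_diagnostic(
    residuals: pd.Series,
    tree: Phylogeny,
    n_permutations: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> ResidualDiagnostic:
    """Flag phylogenetic signal in OLS residuals.

    Residuals are laid out in the tree's post-order tip sequence, so
    phylogenetic neighbours are adjacent.  The score is the mean absolute
    difference between adjacent residuals; clustering makes it small
    relative to its permutation distribution (orders shuffled uniformly).
    """
    order = [node for node in tree.postorder if node < tree.n_tips]
    names = [tree.labels[i] for i in order]
    r = residuals.loc[names].to_numpy(dtype=float)
    obs = float(np.mean(np.abs(np.diff(r))))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(r)
        if np.mean(np.abs(np.diff(perm))) <= obs:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    if obs == 0.0:
        p = 1.0
    return ResidualDiagnostic(
        ordered_residuals=pd.Series(r, index=names),
        score=obs,
        p_value=p,
        use_pgls=bool(p <= alpha and obs > 0.0),
    )


def table2_row(
    regression_id: str,
    fit: GLSFit,
    lambda_hat: float,
    pvalues: pd.Series,
) -> dict:
    """One exported row in the shape of the published regression table."""
    slopes = fit.params
    inter = slopes.get("intercept", np.nan)
    pred1 = slopes.get("pred1", np.nan)
    loc_cols = [c for c in slopes.index if c.startswith("loc[")]
    int_cols = [c for c in slopes.index if c.startswith("pred1:")]
    return {
        "regression": regression_id,
        "model": fit.cov_spec.model,
        "formula": "b" if int_cols else "a",
        "aic": fit.aic,
        "intercept": inter,
        "slope_pred1": pred1,
        "slope_pred2_mean": float(np.mean(slopes[loc_cols])) if loc_cols else np.nan,
        "slope_interaction_mean": float(np.mean(slopes[int_cols])) if int_cols else np.nan,
        "p_pred1": pvalues.get("pred1", np.nan),
        "p_pred2": pvalues.get("locomotion", np.nan),
        "p_interaction": pvalues.get("interaction", np.nan),
        "lambda": lambda_hat,
        "rse": fit.rse,
        "df_n": fit.df[0],
        "df_resid": fit.df[1],
    }
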