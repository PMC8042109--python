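"""Fisher-Pitman permutation tests across locomotor groups.

The K-sample test uses the asymptotic (moment-based) form: the linear
statistic is the vector of within-group sums; its exact permutation mean
and covariance have closed forms, and the quadratic form of the centred
statistic with a generalized inverse is chi-squared with k-1 df under the
null.  Pairwise comparisons use the standardized two-sample linear
statistic with a normal reference, adjusted across the 10 pairs by the
Benjamini-Hochberg step-up procedure.  An exact-enumeration mode over all
label permutations is provided for small n as a test oracle.

Variance-homogeneity preconditions follow the usual route: Shapiro-Wilk
for normality, then Bartlett (normal) or Brown-Forsythe Levene
(non-normal).  A failed homogeneity check attaches a warning to the result
instead of refusing to compute.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError


@dataclass
class PermTestResult:
    statistic: float          # chi^2 (K-sample) or standardized Z (pairwise)
    df: int
    p_value: float
    groups: dict[str, int]    # group label -> size
    pair: tuple[str, str] | None = None
    p_adjusted: float | None = None
    warnings: list[str] = field(default_factory=list)


def _clean(values, groups) -> tuple[np.ndarray, np.ndarray]:
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    keep = np.isfinite(v)
    return v[keep], g[keep]


def _moments(values: np.ndarray, groups: np.ndarray):
    """Permutation mean vector and covariance of the within-group sums."""
    labels, counts = np.unique(groups, return_counts=True)
    N = values.size
    ybar = values.mean()
    s2 = np.sum((values - ybar) ** 2) / N
    mu = counts * ybar
    cov = (s2 * N / (N - 1)) * (np.diag(counts) - np.outer(counts, counts) / N)
    T = np.array([values[groups == g].sum() for g in labels])
    return labels, counts, T, mu, cov


def fp_ksample(values, groups) -> PermTestResult:
    """Asymptotic K-sample Fisher-Pitman permutation test (chi^2 form)."""
    v, g = _clean(values, groups)
    labels, counts, T, mu, cov = _moments(v, g)
    if labels.size < 2:
        raise ValidationError("need at least 2 non-empty groups")
    if np.allclose(v, v[0]):
        return PermTestResult(0.0, labels.size - 1, 1.0, dict(zip(labels, counts)))
    d = T - mu
    chi2 = float(d @ np.linalg.pinv(cov) @ d)
    dfree = labels.size - 1
    p = float(stats.chi2.sf(chi2, dfree))
    return PermTestResult(chi2, dfree, max(p, np.finfo(float).tiny), dict(zip(labels, counts)))


def _group_assignments(indices: tuple[int, ...], counts: list[int]):
    """Yield all distinct splits of ``indices`` into groups of the given sizes."""
    if len(counts) == 1:
        yield (indices,)
        return
    for first in itertools.combinations(indices, counts[0]):
        rest = tuple(i for i in indices if i not in set(first))
        for tail in _group_assignments(rest, counts[1:]):
            yield (first,) + tail


def fp_ksample_exact(values, groups) -> float:
    """Exact permutation p of the K-sample statistic (n <= 12 oracle).

    Enumerates the distinct assignments of values to groups (the statistic
    is invariant to within-group order), i.e. the full permutation null.
    """
    v, g = _clean(values, groups)
    if v.size > 12:
        raise ValidationError("exact enumeration limited to n <= 12")
    labels, counts, T, mu, cov = _moments(v, g)
    covinv = np.linalg.pinv(cov)
    obs = float((T - mu) @ covinv @ (T - mu))
    count = total = 0
    for split in _group_assignments(tuple(range(v.size)), list(counts)):
        Tp = np.array([v[list(part)].sum() for part in split])
        st = float((Tp - mu) @ covinv @ (Tp - mu))
        count += st >= obs - 1e-12
        total += 1
    return count / total


def _pair_z(v: np.ndarray, g: np.ndarray, a: str, b: str) -> float:
    """Standardized two-sample linear statistic restricted to groups a, b."""
    keep = (g == a) | (g == b)
    vv, gg = v[keep], g[keep]
    N = vv.size
    na = int((gg == a).sum())
    ybar = vv.mean()
    s2 = np.sum((vv - ybar) ** 2) / N
    var = s2 * N / (N - 1) * na * (1 - na / N)
    if var <= 0:
        return 0.0
    return float((vv[gg == a].sum() - na * ybar) / np.sqrt(var))


def fp_pairwise(values, groups) -> list[PermTestResult]:
    """All unordered pairwise two-sample tests with BH-adjusted p-values."""
    v, g = _clean(values, groups)
    labels = sorted(np.unique(g))
    if len(labels) < 2:
        raise ValidationError("need at least 2 groups")
    results = []
    for a, b in itertools.combinations(labels, 2):
        z = _pair_z(v, g, a, b)
        p = float(2.0 * stats.norm.sf(abs(z))) if z != 0.0 else 1.0
        sizes = {a: int((g == a).sum()), b: int((g == b).sum())}
        results.append(PermTestResult(z, 1, min(p, 1.0), sizes, pair=(a, b)))
    raw = [r.p_value for r in results]
    adj = benjamini_hochberg(raw)
    for r, q in zip(results, adj):
        r.p_adjusted = float(q)
    return results


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH step-up adjustment (delegated to statsmodels)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


@dataclass
class VarianceCheck:
    normality_p: float
    homogeneity_p: float
    route: str                # "bartlett" or "levene"
    warnings: list[str] = field(default_factory=list)


def variance_checks(values, groups, alpha: float = 0.05, center: str = "median") -> VarianceCheck:
    """Normality then homogeneity-of-variance preconditions.

    Shapiro-Wilk decides the route: Bartlett for normal-looking data,
    Brown-Forsythe Levene (median centring by default) otherwise.  Groups
    of size < 2 are excluded with a warning.
    """
    v, g = _clean(values, groups)
    warnings: list[str] = []
    samples = []
    for lab in np.unique(g):
        sample = v[g == lab]
        if sample.size < 2:
            warnings.append(f"group {lab!r} has fewer than 2 values; excluded")
        else:
            samples.append(sample)
    if len(samples) < 2:
        raise ValidationError("need at least 2 groups of size >= 2")
    if np.allclose(v, v[0]):
        return VarianceCheck(1.0, 1.0, "levene", warnings + ["constant values"])
    sw_p = float(stats.shapiro(v).pvalue)
    if sw_p >= alpha:
        stat, p = stats.bartlett(*samples)
        route = "bartlett"
    else:
        stat, p = stats.levene(*samples, center=center)
        route = "levene"
    if p < alpha:
        warnings.append(
            f"variance homogeneity violated ({route} p={p:.4g}); "
            "interpret group-mean comparisons with caution"
        )
    return VarianceCheck(sw_p, float(p), route, warnings)


def table1_block(values: pd.Series, groups: pd.Series, response: str) -> pd.DataFrame:
    """K-sample row + 10 pairwise rows in the published table's shape."""
    ks = fp_ksample(values, groups)
    check = variance_checks(values, groups)
    rows = [
        {
            "response": response,
            "comparison": "k-sample",
            "statistic": ks.statistic,
            "df": ks.df,
            "p_value": ks.p_value,
            "p_adjusted": np.nan,
            "warning": "; ".join(check.warnings),
        }
    ]
    for r in fp_pairwise(values, groups):
        rows.append(
            {
                "response": response,
                "comparison": f"{r.pair[0]} - {r.pair[1]}",
                "statistic": r.statistic,
                "df": r.df,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "warning": "",
            }
        )
    return pd.DataFrame(rows)
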