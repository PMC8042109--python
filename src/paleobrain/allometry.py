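"""Brain-body allometry, encephalization quotients, and component percentages.

The encephalization quotient compares observed endocranial volume ``E_i``
with the volume ``E_c = a * M^b`` expected for a species of body mass ``M``.
The classic quotient (EQ) uses Jerison's mammal-wide constants
``E_c = 0.12 * M^0.67``.  The phylogenetic variant (PEQ) instead derives
``a`` and ``b`` from a PGLS regression of log10 endocranial volume on log10
body mass over the study sample itself, so the expectation is corrected for
shared ancestry.  The exponent ``b`` is unit-free; the coefficient ``a``
depends on the measurement units (grams and mm^3 here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .pgls import profile_fit
from .phylo_core import Phylogeny
from .traits import TraitTable

JERISON_A = 0.12
JERISON_B = 0.67


@dataclass(frozen=True)
class AllometricModel:
    """Power law E_c(M) = a * M^b, fitted on log10 scale."""

    a: float
    b: float
    source: str = "pgls"
    units: str = "mass: g, volume: mm^3"

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValidationError(f"allometric coefficient must be > 0, got {self.a}")

    def expected_volume(self, mass) -> np.ndarray:
        return self.a * np.asarray(mass, dtype=float) ** self.b


def fit_allometry(table: TraitTable, tree: Phylogeny) -> tuple[AllometricModel, object]:
    """PGLS allometry of endocranial volume on body mass (intercept + slope only).

    The covariance model is AIC-selected among the four evolutionary models,
    mirroring the regression workflow.  Returns the power-law model together
    with the winning GLS fit (for lambda reporting etc.).
    """
    df = table.aligned_to(tree.labels).table
    if df.endocranial_volume.isna().any() or df.body_mass.isna().any():
        missing = df.species[df[["endocranial_volume", "body_mass"]].isna().any(axis=1)]
        raise ValidationError(f"allometry needs E and M for every species; missing {list(missing)}")
    y = pd.Series(np.log10(df.endocranial_volume.to_numpy()), index=tree.labels)
    X = pd.DataFrame(
        {"intercept": np.ones(len(df)), "pred1": np.log10(df.body_mass.to_numpy())},
        index=tree.labels,
    )
    fits = [profile_fit(y, X, tree, m) for m in ("brownian", "lambda", "early_burst", "ou")]
    best = min(fits, key=lambda f: f.aic)
    model = AllometricModel(
        a=float(10.0 ** best.params["intercept"]),
        b=float(best.params["pred1"]),
        source=f"pgls[{best.cov_spec.model}]",
    )
    return model, best


def compute_peq(table: TraitTable, model: AllometricModel) -> pd.Series:
    """Per-species PEQ = E_i / (a * M^b)."""
    df = table.table
    if (df.body_mass.dropna() <= 0).any() or (df.endocranial_volume.dropna() <= 0).any():
        raise ValidationError("body mass and endocranial volume must be positive")
    peq = df.endocranial_volume.to_numpy() / model.expected_volume(df.body_mass.to_numpy())
    return pd.Series(peq, index=df.species, name="peq")


def compute_eq(table: TraitTable) -> pd.Series:
    """Jerison's EQ with the mammal-wide constants a=0.12, b=0.67."""
    return compute_peq(table, AllometricModel(JERISON_A, JERISON_B, source="jerison")).rename("eq")


def compute_percentages(table: TraitTable) -> pd.DataFrame:
    """OB%, PL% (of endocranial volume) and Neo% (of endocranial surface).

    Missing measurements yield missing percentages, never zeros.
    """
    df = table.table
    out = pd.DataFrame(
        {
            "ob_pct": 100.0 * df.olfactory_bulb_volume / df.endocranial_volume,
            "pl_pct": 100.0 * df.petrosal_lobule_volume / df.endocranial_volume,
            "neo_pct": 100.0 * df.neocortex_surface / df.endocranial_surface,
        }
    )
    out.index = df.species
    return out


def quotient_table(table: TraitTable, model: AllometricModel) -> pd.DataFrame:
    """CSV-shaped export: species, PEQ, EQ, OB%, PL%, Neo%."""
    out = compute_percentages(table)
    out.insert(0, "eq", compute_eq(table))
    out.insert(0, "peq", compute_peq(table, model))
    return out.rename_axis("species")
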