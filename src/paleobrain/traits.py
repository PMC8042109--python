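"""Species-level trait table: endocast measurements plus locomotor category.

One row per species.  Volumes are in mm^3, surfaces in mm^2, body mass in
grams.  Missing measurements are allowed (e.g. a species whose petrosal
lobules are not preserved) and propagate as missing through every derived
quantity rather than being imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

LOCOMOTOR_CATEGORIES = ("arboreal", "fossorial", "glider", "scansorial", "terrestrial")

NUMERIC_COLUMNS = [
    "body_mass",
    "endocranial_volume",
    "endocranial_surface",
    "neocortex_surface",
    "olfactory_bulb_volume",
    "petrosal_lobule_volume",
]
COLUMNS = ["species", "status", "locomotion"] + NUMERIC_COLUMNS


@dataclass
class TraitTable:
    """Validated measurement table keyed by species name."""

    table: pd.DataFrame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TraitTable":
        df = frame.copy()
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"trait table missing columns {missing}")
        df = df[COLUMNS]
        if df.species.duplicated().any():
            dupes = sorted(df.species[df.species.duplicated()].unique())
            raise ValidationError(f"duplicate species: {dupes}")
        bad_status = set(df.status) - {"extant", "extinct"}
        if bad_status:
            raise ValidationError(f"status must be extant|extinct, got {sorted(bad_status)}")
        bad_loc = set(df.locomotion) - set(LOCOMOTOR_CATEGORIES)
        if bad_loc:
            raise ValidationError(
                f"unknown locomotor categories {sorted(bad_loc)}; "
                f"expected {LOCOMOTOR_CATEGORIES}"
            )
        for col in NUMERIC_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="raise")
            vals = df[col]
            if (vals.dropna() <= 0).any():
                bad = df.species[vals <= 0].tolist()
                raise ValidationError(f"non-positive {col} for {bad}")
        both = df.neocortex_surface.notna() & df.endocranial_surface.notna()
        if (df.neocortex_surface[both] > df.endocranial_surface[both] + 1e-9).any():
            bad = df.species[both & (df.neocortex_surface > df.endocranial_surface)].tolist()
            raise ValidationError(f"neocortex surface exceeds endocranial surface for {bad}")
        if (df.neocortex_surface[both] == df.endocranial_surface[both]).any():
            warnings.warn("neocortex surface equals endocranial surface for some species")
        for part in ("olfactory_bulb_volume", "petrosal_lobule_volume"):
            both = df[part].notna() & df.endocranial_volume.notna()
            if (df[part][both] >= df.endocranial_volume[both]).any():
                bad = df.species[both & (df[part] >= df.endocranial_volume)].tolist()
                raise ValidationError(f"{part} not smaller than endocranial volume for {bad}")
        return cls(df.reset_index(drop=True))

    @classmethod
    def read_csv(cls, path) -> "TraitTable":
        return cls.from_frame(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @property
    def species(self) -> list[str]:
        return self.table.species.tolist()

    def aligned_to(self, tip_labels: list[str]) -> "TraitTable":
        """Reorder rows to match a tree's tip order; error on mismatch."""
        missing = set(tip_labels) - set(self.species)
        if missing:
            raise ValidationError(f"tree tips missing from trait table: {sorted(missing)}")
        df = self.table.set_index("species").loc[list(tip_labels)].reset_index()
        return TraitTable(df)

    def column(self, name: str) -> pd.Series:
        return self.table.set_index("species")[name]
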