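"""Species trait table and group-balanced Gower dissimilarity.

The trait set mirrors the standard adult-odonate dispersal/thermoregulation
panel: three body measurements (mm), abdomen colour (RGB), freshwater habitat
flags (lentic / lotic) and flight-season length (months).  Traits are combined
into four groups — (1) body measurements, (2) habitat, (3) flight season,
(4) pigmentation — and the groups contribute *equally* to the final
dissimilarity, so that the three correlated size traits cannot swamp the
single-trait groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["TraitTable", "DEFAULT_GROUPS", "gower_grouped"]

CONTINUOUS = ("body_length_mm", "abdomen_length_mm", "wing_length_mm", "flight_months")
RGB = ("abdomen_r", "abdomen_g", "abdomen_b")
HABITAT = ("lentic", "lotic")

#: trait -> Gower group; every trait appears in exactly one group
DEFAULT_GROUPS: dict[str, int] = {
    "body_length_mm": 1,
    "abdomen_length_mm": 1,
    "wing_length_mm": 1,
    "habitat": 2,
    "flight_months": 3,
    "rgb": 4,
}


@dataclass
class TraitTable:
    """Validated per-species trait table.

    ``data`` is indexed by species id with columns ``body_length_mm``,
    ``abdomen_length_mm``, ``wing_length_mm``, ``abdomen_r/g/b`` (0-255),
    ``lentic``, ``lotic`` (0/1) and ``flight_months`` (1-12).
    """

    data: pd.DataFrame
    groups: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))

    def __post_init__(self) -> None:
        df = self.data
        needed = list(CONTINUOUS[:3]) + list(RGB) + list(HABITAT) + ["flight_months"]
        missing = [c for c in needed if c not in df.columns]
        if missing:
            raise ValueError(f"trait table missing columns: {missing}")
        if df[needed].isna().any().any():
            raise ValueError("trait table has missing values")
        if (df[list(CONTINUOUS[:3])] <= 0).any().any():
            raise ValueError("length traits must be positive")
        if ((df["flight_months"] < 1) | (df["flight_months"] > 12)).any():
            raise ValueError("flight_months must lie in 1..12")
        if ((df[list(HABITAT)].sum(axis=1)) < 1).any():
            raise ValueError("every species needs at least one habitat flag")
        if ((df[list(RGB)] < 0) | (df[list(RGB)] > 255)).any().any():
            raise ValueError("RGB values must lie in 0..255")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @classmethod
    def from_csv(cls, path) -> "TraitTable":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.data.to_csv(path)


def _range_normalized(col: np.ndarray) -> np.ndarray | None:
    """Pairwise |xi - xj| / range; None when the range is zero."""
    rng = np.ptp(col)
    if rng == 0:
        return None
    return np.abs(col[:, None] - col[None, :]) / rng


def gower_grouped(traits: TraitTable) -> tuple[np.ndarray, list[str]]:
    """Group-balanced Gower dissimilarity matrix.

    Per trait: continuous traits use the range-normalised absolute difference;
    the two habitat flags each contribute a 0/1 mismatch and are averaged;
    RGB is a single trait, the Euclidean distance in the unit colour cube
    divided by sqrt(3).  Within a group, member-trait dissimilarities are
    averaged; the final dissimilarity is the unweighted mean over groups, so
    each group contributes equally regardless of how many traits it holds.

    Constant traits (zero range) are dropped with a warning; a group whose
    traits are all dropped is excluded from the across-group mean.

    Returns
    -------
    (n, n) dissimilarity matrix in [0, 1] and the species order.
    """
    df = traits.data
    n = len(df)

    group_mats: dict[int, list[np.ndarray]] = {}

    def add(group: int, mat: np.ndarray | None, name: str) -> None:
        if mat is None:
            logger.warning("gower_grouped: dropping constant trait %r", name)
            return
        group_mats.setdefault(group, []).append(mat)

    groups = traits.groups
    for trait in ("body_length_mm", "abdomen_length_mm", "wing_length_mm", "flight_months"):
        add(groups[trait], _range_normalized(df[trait].to_numpy(dtype=float)), trait)

    # habitat: mean of the per-flag 0/1 mismatches
    hab = df[list(HABITAT)].to_numpy(dtype=float)
    hab_d = np.abs(hab[:, None, :] - hab[None, :, :]).mean(axis=2)
    add(groups["habitat"], hab_d, "habitat")

    # pigmentation: scaled Euclidean distance in the unit RGB cube
    rgb = df[list(RGB)].to_numpy(dtype=float) / 255.0
    diff = rgb[:, None, :] - rgb[None, :, :]
    rgb_d = np.sqrt((diff**2).sum(axis=2)) / np.sqrt(3.0)
    if np.ptp(rgb_d) == 0 and n > 1:
        add(groups["rgb"], None, "rgb")
    else:
        add(groups["rgb"], rgb_d, "rgb")

    if not group_mats:
        raise ValueError("all traits constant: dissimilarity undefined")

    per_group = [np.mean(mats, axis=0) for _, mats in sorted(group_mats.items())]
    d = np.mean(per_group, axis=0)
    np.fill_diagonal(d, 0.0)
    return d, traits.species
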