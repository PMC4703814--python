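"""Calibration of protein-marker OTU thresholds against 16S taxonomy.

Taxonomic thresholds defined on the 16S rRNA gene (species 98.7%, genus
94.5%, family 86.5%, phylum 75%) are transferred to a protein marker by
regressing, over all strain pairs of a cultured reference set, percent
protein identity on percent 16S identity and reading the protein threshold
off the fitted line at each 16S threshold.  For the MasD marker this
procedure yields species/genus/family cutoffs of 96/86/72% amino-acid
identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from ._align import percent_identity

__all__ = [
    "DEFAULT_16S_THRESHOLDS",
    "StrainRecord",
    "PairwiseSimilarity",
    "CalibrationModel",
    "build_pairs",
    "fit_threshold_model",
    "map_threshold",
    "pairwise_identity",
]

#: 16S rRNA thresholds for species, genus, family and phylum (percent).
DEFAULT_16S_THRESHOLDS = (98.7, 94.5, 86.5, 75.0)


@dataclass
class StrainRecord:
    """A cultured strain with paired marker-protein and 16S sequences."""

    strain_id: str
    protein: str
    s16: str
    accessions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.protein or not self.s16:
            raise ValueError(f"strain {self.strain_id}: both sequences required")


@dataclass
class PairwiseSimilarity:
    """Percent identities of one strain pair on both markers."""

    strain_a: str
    strain_b: str
    s16: float
    sprot: float

    def __post_init__(self) -> None:
        if not (0 <= self.s16 <= 100 and 0 <= self.sprot <= 100):
            raise ValueError("identities must be in [0, 100]")


@dataclass
class CalibrationModel:
    """Fitted identity-identity regression plus mapped thresholds."""

    slope: float
    intercept: float
    r_squared: float
    n_pairs: int
    mapped_thresholds: dict[float, int]
    regression: str = "ols"

    def to_json(self) -> str:
        return json.dumps({
            "slope": self.slope, "intercept": self.intercept,
            "r_squared": self.r_squared, "n_pairs": self.n_pairs,
            "regression": self.regression,
            "mapped_thresholds": {str(k): v
                                  for k, v in self.mapped_thresholds.items()},
        }, indent=2)


def pairwise_identity(a: str, b: str, alphabet: str = "protein") -> float:
    """Percent identity from an end-gap-free global alignment.

    Identity = identical columns / aligned columns with terminal gap
    columns excluded and internal gaps counted as mismatches; symmetric.
    """
    return percent_identity(a, b, alphabet)


def build_pairs(strains: list[StrainRecord]) -> list[PairwiseSimilarity]:
    """All unordered strain pairs with identities on both markers."""
    if len(strains) < 3:
        raise ValueError("need at least 3 strains")
    ids = [s.strain_id for s in strains]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain_id in input")
    pairs = []
    for a, b in combinations(sorted(strains, key=lambda s: s.strain_id), 2):
        pairs.append(PairwiseSimilarity(
            strain_a=a.strain_id, strain_b=b.strain_id,
            s16=pairwise_identity(a.s16, b.s16, "nucleotide"),
            sprot=pairwise_identity(a.protein, b.protein, "protein"),
        ))
    return pairs


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    if sxx == 0:
        raise ValueError("zero variance in 16S identities; slope undefined")
    slope = ((x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    ss_res = ((y - (intercept + slope * x)) ** 2).sum()
    ss_tot = ((y - ym) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(intercept), float(r2)


def _orthogonal(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Total least squares (Deming with unit variance ratio) line."""
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    syy = ((y - ym) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    if sxx == 0:
        raise ValueError("zero variance in 16S identities; slope undefined")
    slope = (syy - sxx + np.sqrt((syy - sxx) ** 2 + 4 * sxy ** 2)) / (2 * sxy)
    intercept = ym - slope * xm
    _, _, r2 = _ols(x, y)
    return float(slope), float(intercept), r2


def fit_threshold_model(
    pairs: list[PairwiseSimilarity],
    target_16s_thresholds: tuple[float, ...] = DEFAULT_16S_THRESHOLDS,
    regression: str = "ols",
) -> CalibrationModel:
    """Fit protein% = intercept + slope * 16S% and map the 16S thresholds.

    Mapped thresholds are rounded to integer percent and clamped to
    [0, 100].  ``regression`` is 'ols' (default) or 'orthogonal'.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = np.array([p.s16 for p in pairs], dtype=float)
    y = np.array([p.sprot for p in pairs], dtype=float)
    fit = _ols if regression == "ols" else _orthogonal
    slope, intercept, r2 = fit(x, y)
    model = CalibrationModel(slope=slope, intercept=intercept, r_squared=r2,
                             n_pairs=len(pairs), mapped_thresholds={},
                             regression=regression)
    model.mapped_thresholds = {
        t: map_threshold(model, t) for t in target_16s_thresholds
    }
    return model


def map_threshold(model: CalibrationModel, s16: float) -> int:
    """Protein threshold (integer percent, clamped to [0, 100]) at ``s16``%."""
    value = model.intercept + model.slope * s16
    return int(min(100, max(0, round(value))))
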