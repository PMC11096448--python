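"""CYP2D6 activity-score phenotyping.

Maps a CYP2D6 activity score (AS, 0-3) to a turnover frequency (kcat,
1/min) and a metaboliser class. Tabulated scores return the packaged table
value exactly; scores between rows are linearly interpolated. The AS=1.5
extensive-metaboliser row (kcat 1.6/min) is the 100% reference; the
poor-metaboliser kcat is a small positive value (0.03/min) reflecting
residual morphine formation in PMs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._data import load_packaged_yaml
from .compound import CompoundParameters

__all__ = [
    "PhenotypeTable", "load_phenotype_table",
    "kcat_for_activity_score", "phenotype_for_activity_score", "apply_phenotype",
    "REFERENCE_ACTIVITY_SCORE",
]

REFERENCE_ACTIVITY_SCORE = 1.5


@dataclass(frozen=True)
class PhenotypeRow:
    activity_score: float
    phenotype: str
    kcat_per_min: float
    kcat_rel_percent: float


@dataclass(frozen=True)
class PhenotypeTable:
    """Activity-score -> CYP2D6 turnover table."""

    rows: tuple[PhenotypeRow, ...]

    def __post_init__(self) -> None:
        scores = [r.activity_score for r in self.rows]
        kcats = [r.kcat_per_min for r in self.rows]
        if sorted(scores) != scores:
            raise ValueError("rows must be sorted by activity score")
        if any(k2 <= k1 for k1, k2 in zip(kcats, kcats[1:])):
            raise ValueError("kcat must be strictly increasing in activity score")
        if any(k <= 0 for k in kcats):
            raise ValueError("all kcat values must be positive")
        ref = [r for r in self.rows
               if r.activity_score == REFERENCE_ACTIVITY_SCORE]
        if not ref or ref[0].kcat_rel_percent != 100:
            raise ValueError("AS=1.5 reference row must carry kcat_rel = 100%")

    @property
    def scores(self) -> np.ndarray:
        return np.array([r.activity_score for r in self.rows])

    @property
    def kcats(self) -> np.ndarray:
        return np.array([r.kcat_per_min for r in self.rows])

    def kcat(self, activity_score: float) -> float:
        """kcat (1/min) at an activity score; linear between tabulated rows."""
        _check_as(activity_score)
        return float(np.interp(activity_score, self.scores, self.kcats))


def _check_as(activity_score: float) -> None:
    if not 0.0 <= activity_score <= 3.0:
        raise ValueError(f"activity score {activity_score} outside [0, 3]")


def load_phenotype_table() -> PhenotypeTable:
    """Packaged activity-score table."""
    raw = load_packaged_yaml("cyp2d6_activity_scores.yaml")
    rows = tuple(PhenotypeRow(float(r["activity_score"]), r["phenotype"],
                              float(r["kcat_per_min"]), float(r["kcat_rel_percent"]))
                 for r in raw["rows"])
    return PhenotypeTable(rows)


def kcat_for_activity_score(activity_score: float,
                            table: PhenotypeTable | None = None) -> float:
    """CYP2D6 turnover frequency (1/min) for an activity score in [0, 3]."""
    return (table or load_phenotype_table()).kcat(activity_score)


def phenotype_for_activity_score(activity_score: float) -> str:
    """Metaboliser class for an activity score: PM, IM, EM or UM."""
    _check_as(activity_score)
    if activity_score == 0:
        return "PM"
    if activity_score <= 1:
        return "IM"
    if activity_score <= 2:
        return "EM"
    return "UM"


def apply_phenotype(compound: CompoundParameters, activity_score: float,
                    table: PhenotypeTable | None = None) -> CompoundParameters:
    """Copy of ``compound`` with its CYP2D6 kcat set for the activity score.

    Every other field (all other pathways included) is left untouched.
    Raises ``KeyError`` when the compound has no CYP2D6 pathway.
    """
    kcat = kcat_for_activity_score(activity_score, table)
    return compound.with_pathway("CYP2D6", kcat_per_min=kcat)
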