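"""Per-plate control statistics, HTS-score normalization and Z'-factor QC.

The HTS score rescales each plate onto its own control window:

    score(x) = (Av_neg - x) / (Av_neg - Av_pos)

so the negative-control (vehicle) mean maps to 0 (no cytotoxicity) and the
positive-control (doxorubicin) mean maps to 1. Scores are *not* clipped:
values below 0 indicate apparent growth stimulation, values above 1 a
stronger kill than the positive control.

The screening-window coefficient

    Z' = 1 - 3 (SD_pos + SD_neg) / |Av_pos - Av_neg|

gates each plate; the conventional pass rule is the strict inequality
Z' > 0.5. Sample standard deviations (n - 1 denominator) are used
throughout, appropriate for the 32 control wells per plate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import QCError, UndefinedStatisticError
from .plate_model import (
    PlateLayout,
    PlateRead,
    WellRole,
    format_well_label,
)

__all__ = [
    "ControlStats",
    "PlateQC",
    "ScoredPlate",
    "control_stats",
    "zprime",
    "gate_plate",
    "score_plate",
    "DEFAULT_ZPRIME_THRESHOLD",
]

DEFAULT_ZPRIME_THRESHOLD = 0.5


@dataclass(frozen=True)
class ControlStats:
    """Mean and sample SD of each control population on one plate."""

    av_neg: float
    sd_neg: float
    av_pos: float
    sd_pos: float
    n_neg: int
    n_pos: int


@dataclass(frozen=True)
class PlateQC:
    zprime: float
    passed: bool
    threshold: float = DEFAULT_ZPRIME_THRESHOLD


@dataclass
class ScoredPlate:
    """HTS scores for every non-empty well of one plate (NaN on empty wells)."""

    barcode: str
    scores: np.ndarray
    layout: PlateLayout
    stats: ControlStats

    def to_frame(self, plate_read: PlateRead | None = None) -> pd.DataFrame:
        """Long-format table: barcode, well, role, raw_signal, score."""
        fmt = self.layout.format
        rows = []
        for r in range(fmt.n_rows):
            for c in range(fmt.n_cols):
                role = self.layout.roles[r, c]
                if role is WellRole.EMPTY:
                    continue
                rows.append(
                    {
                        "barcode": self.barcode,
                        "well": format_well_label(r, c),
                        "role": role.value,
                        "raw_signal": float(plate_read.signals[r, c])
                        if plate_read is not None
                        else np.nan,
                        "score": float(self.scores[r, c]),
                    }
                )
        return pd.DataFrame(rows)


def control_stats(plate: PlateRead, layout: PlateLayout) -> ControlStats:
    """Control means and sample SDs over the designated wells of one plate."""
    neg = plate.signals[layout.mask(WellRole.NEGATIVE_CONTROL)]
    pos = plate.signals[layout.mask(WellRole.POSITIVE_CONTROL)]
    if neg.size < 2 or pos.size < 2:
        raise QCError(
            f"plate {plate.barcode!r}: needs >= 2 wells of each control role, "
            f"found {neg.size} negative and {pos.size} positive"
        )
    return ControlStats(
        av_neg=float(np.mean(neg)),
        sd_neg=float(np.std(neg, ddof=1)),
        av_pos=float(np.mean(pos)),
        sd_pos=float(np.std(pos, ddof=1)),
        n_neg=int(neg.size),
        n_pos=int(pos.size),
    )


def zprime(stats: ControlStats) -> float:
    """Screening-window coefficient 1 - 3(SD_pos + SD_neg)/|Av_pos - Av_neg|."""
    sep = abs(stats.av_pos - stats.av_neg)
    if sep == 0:
        raise UndefinedStatisticError(
            "Z' undefined: positive and negative control means coincide"
        )
    return 1.0 - 3.0 * (stats.sd_pos + stats.sd_neg) / sep


def gate_plate(
    stats: ControlStats, threshold: float = DEFAULT_ZPRIME_THRESHOLD
) -> PlateQC:
    """Pass/fail gate on the plate's Z'; strict inequality, never silent."""
    z = zprime(stats)
    return PlateQC(zprime=z, passed=z > threshold, threshold=threshold)


def score_plate(
    plate: PlateRead, layout: PlateLayout, stats: ControlStats
) -> ScoredPlate:
    """Normalize one plate to its own controls.

    ``stats`` must come from the same plate — normalization is strictly
    per plate. Scores are left unclipped; empty wells score NaN.
    """
    sep = stats.av_neg - stats.av_pos
    if sep == 0:
        raise UndefinedStatisticError(
            f"plate {plate.barcode!r}: control means coincide, scores undefined"
        )
    scores = (stats.av_neg - plate.signals) / sep
    scores = np.where(layout.mask(WellRole.EMPTY), np.nan, scores)
    return ScoredPlate(barcode=plate.barcode, scores=scores, layout=layout, stats=stats)
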