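"""Replicate aggregation, 3-SD hit calling and confirmation-screen planning.

Per-compound scores are averaged over all replicate wells of all QC-passed
plates (design target: 3 independent experiments x duplicate = 6 wells).
The hit threshold is derived from the pooled per-well negative-control
scores of the campaign: mean + ``sd_multiplier`` x sample SD (default 3).
Because per-plate normalization pins the negative-control mean of every
plate at 0, the pooled mean is ~0 and the rule reduces to 3 x SD of the
vehicle scores. A compound is a hit when its mean score is *strictly*
greater than the threshold.

Confirmed hits are re-tested in a tiered confirmation screen: strong
primary hits (score strictly above ``tier_threshold``, default 0.65) are
re-tested at a 12x lower concentration (0.83 uM via a 2.5 nl dispense),
the rest again at the screening concentration (10 uM via 30 nl).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError, QCError

__all__ = [
    "ConfirmationTier",
    "aggregate_scores",
    "hit_threshold",
    "call_hits",
    "assign_confirmation",
    "evaluate_confirmation",
    "DEFAULT_TIER_THRESHOLD",
    "LOW_CONC_TIER",
    "SCREEN_CONC_TIER",
]

logger = logging.getLogger(__name__)

DEFAULT_TIER_THRESHOLD = 0.65


@dataclass(frozen=True)
class ConfirmationTier:
    name: str
    target_conc_um: float
    drop_nl: float
    stock_mm: float = 10.0


#: Strong hits: 2.5 nl of 10 mM stock into 30 ul -> 0.83 uM.
LOW_CONC_TIER = ConfirmationTier(name="low_conc", target_conc_um=0.83, drop_nl=2.5)
#: Ordinary hits: re-test at the 10 uM screening concentration.
SCREEN_CONC_TIER = ConfirmationTier(name="screen_conc", target_conc_um=10.0, drop_nl=30.0)


def aggregate_scores(
    scored: pd.DataFrame,
    min_wells: int = 6,
) -> pd.DataFrame:
    """Per-compound summaries from a long table of scored compound wells.

    ``scored`` needs columns ``compound_id``, ``score`` and optionally
    ``cell_line`` and ``experiment``. Only pass wells from QC-passed
    plates. Returns one row per (compound, cell line) with ``n_wells``,
    ``mean_score``, ``sd_score`` (sample SD; NaN when n < 2), a
    ``low_replicate`` flag for compounds below ``min_wells`` wells, and
    ``per_experiment`` mean scores (a dict column, dropped on CSV export).
    """
    if "compound_id" not in scored.columns or "score" not in scored.columns:
        raise InputError("scored wells need 'compound_id' and 'score' columns")
    df = scored.copy()
    if "cell_line" not in df.columns:
        df["cell_line"] = ""
    if "experiment" not in df.columns:
        df["experiment"] = 0
    df = df[df["compound_id"].astype(str) != ""]

    records = []
    for (cid, cell), grp in df.groupby(["compound_id", "cell_line"], sort=True):
        scores = grp["score"].to_numpy(dtype=float)
        scores = scores[np.isfinite(scores)]
        if scores.size == 0:
            logger.warning("compound %s (%s): no finite scores, omitted", cid, cell)
            continue
        per_exp = {
            exp: float(np.mean(g["score"])) for exp, g in grp.groupby("experiment")
        }
        n = int(scores.size)
        if n < min_wells:
            logger.warning(
                "compound %s (%s): only %d wells (target %d)", cid, cell, n, min_wells
            )
        records.append(
            {
                "compound_id": cid,
                "cell_line": cell,
                "n_wells": n,
                "mean_score": float(np.mean(scores)),
                "sd_score": float(np.std(scores, ddof=1)) if n >= 2 else np.nan,
                "low_replicate": n < min_wells,
                "per_experiment": per_exp,
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "compound_id",
            "cell_line",
            "n_wells",
            "mean_score",
            "sd_score",
            "low_replicate",
            "per_experiment",
        ],
    )


def hit_threshold(
    negative_control_scores, sd_multiplier: float = 3.0
) -> float:
    """Hit threshold: mean + ``sd_multiplier`` x sample SD of pooled vehicle scores."""
    scores = np.asarray(negative_control_scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if scores.size < 2:
        raise QCError(
            f"need >= 2 negative-control scores for a threshold, got {scores.size}"
        )
    return float(np.mean(scores) + sd_multiplier * np.std(scores, ddof=1))


def call_hits(summaries: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Strict-greater hit decision per compound, sorted by descending margin."""
    if not np.isfinite(threshold):
        raise InputError(f"hit threshold must be finite, got {threshold}")
    out = summaries.copy()
    out["threshold"] = threshold
    out["margin"] = out["mean_score"] - threshold
    out["is_hit"] = out["mean_score"] > threshold
    return out.sort_values(
        ["margin", "compound_id"], ascending=[False, True]
    ).reset_index(drop=True)


def assign_confirmation(
    hits: pd.DataFrame,
    tier_threshold: float = DEFAULT_TIER_THRESHOLD,
) -> pd.DataFrame:
    """Tier each primary hit for the confirmation screen.

    Primary score strictly above ``tier_threshold`` -> low-concentration
    tier (0.83 uM / 2.5 nl); at or below -> screening-concentration tier
    (10 uM / 30 nl). Non-hits are rejected.
    """
    if "is_hit" in hits.columns and not hits["is_hit"].all():
        bad = hits.loc[~hits["is_hit"], "compound_id"].iloc[0]
        raise InputError(
            f"assign_confirmation accepts primary hits only; {bad!r} is not a hit"
        )
    records = []
    for rec in hits.itertuples(index=False):
        tier = LOW_CONC_TIER if rec.mean_score > tier_threshold else SCREEN_CONC_TIER
        records.append(
            {
                "compound_id": rec.compound_id,
                "cell_line": getattr(rec, "cell_line", ""),
                "primary_score": rec.mean_score,
                "tier": tier.name,
                "target_conc_um": tier.target_conc_um,
                "drop_nl": tier.drop_nl,
                "stock_mm": tier.stock_mm,
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "compound_id",
            "cell_line",
            "primary_score",
            "tier",
            "target_conc_um",
            "drop_nl",
            "stock_mm",
        ],
    )


def evaluate_confirmation(
    assignments: pd.DataFrame,
    confirmation_scored: pd.DataFrame,
    threshold: float,
) -> pd.DataFrame:
    """Confirm each assigned compound against the confirmation run's own threshold.

    ``confirmation_scored`` is a long table of scored compound wells from the
    confirmation plates (QC-passed only); ``threshold`` is derived from that
    run's negative controls via :func:`hit_threshold`. A compound is
    confirmed when its mean confirmation score is strictly greater than the
    threshold. Scored compounds without an assignment, and assignments
    without any wells, are errors.
    """
    assigned = set(assignments["compound_id"])
    seen = set(confirmation_scored["compound_id"].astype(str)) - {""}
    stray = seen - assigned
    if stray:
        raise InputError(
            f"scored confirmation wells for unassigned compound(s): {sorted(stray)[:5]}"
        )
    records = []
    grouped = dict(list(confirmation_scored.groupby("compound_id")))
    for rec in assignments.itertuples(index=False):
        grp = grouped.get(rec.compound_id)
        if grp is None or len(grp) == 0:
            raise InputError(
                f"no confirmation wells for assigned compound {rec.compound_id!r}"
            )
        scores = grp["score"].to_numpy(dtype=float)
        mean = float(np.mean(scores))
        records.append(
            {
                "compound_id": rec.compound_id,
                "tier": rec.tier,
                "conc_um": rec.target_conc_um,
                "n_wells": int(scores.size),
                "confirmation_score": mean,
                "threshold": threshold,
                "confirmed": mean > threshold,
            }
        )
    return pd.DataFrame(
        records,
        columns=[
            "compound_id",
            "tier",
            "conc_um",
            "n_wells",
            "confirmation_score",
            "threshold",
            "confirmed",
        ],
    )
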