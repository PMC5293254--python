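"""Campaign orchestration: primary screen -> confirmation -> dose-response.

These functions tie the per-plate operations into reproducible runs over
in-memory objects; :mod:`platescreen.cli` wraps them with file I/O. Every
step is deterministic given its inputs and configuration, plates failing
the Z' gate are flagged (and excluded from aggregation by default, never
silently dropped), and input tables are never mutated.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InputError, QCError
from .hit_calling import (
    DEFAULT_TIER_THRESHOLD,
    aggregate_scores,
    assign_confirmation,
    call_hits,
    evaluate_confirmation,
    hit_threshold,
)
from .dose_response import (
    FitConstraints,
    classify_fit,
    fit_4pl,
    replicate_spread,
)
from .errors import DegenerateDataError, ScreenError
from .normalization import (
    DEFAULT_ZPRIME_THRESHOLD,
    control_stats,
    gate_plate,
    score_plate,
)
from .plate_model import PlateLayout, PlateRead, WellRole

__all__ = [
    "RunConfig",
    "PrimaryResult",
    "run_primary",
    "run_confirmation",
    "run_dose_response",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Protocol constants for one campaign run.

    Defaults are the screening protocol's printed values: Z' pass above
    0.5, hit rule at 3 sample SDs of the pooled vehicle scores, strong-hit
    tier above a primary score of 0.65.
    """

    cell_line: str = ""
    zprime_threshold: float = DEFAULT_ZPRIME_THRESHOLD
    hit_sd_multiplier: float = 3.0
    tier_threshold: float = DEFAULT_TIER_THRESHOLD
    min_wells: int = 6
    exclude_failed_plates: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))


@dataclass
class PrimaryResult:
    qc_report: pd.DataFrame
    scored_wells: pd.DataFrame
    hit_table: pd.DataFrame
    threshold: float

    @property
    def n_failed_plates(self) -> int:
        return int((~self.qc_report["qc_passed"]).sum())


def _score_campaign(
    plates: list[PlateRead],
    plate_maps: pd.DataFrame,
    layout: PlateLayout,
    config: RunConfig,
    plate_meta: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plate QC + scoring; returns (qc_report, long scored-well table)."""
    meta_by_barcode: dict[str, dict] = {}
    if plate_meta is not None:
        meta_by_barcode = {
            str(rec["barcode"]): dict(rec) for _, rec in plate_meta.iterrows()
        }
    qc_rows = []
    well_frames = []
    for plate in plates:
        stats = control_stats(plate, layout)
        qc = gate_plate(stats, config.zprime_threshold)
        logger.info(
            "plate %s: Z'=%.3f (%s)", plate.barcode, qc.zprime,
            "pass" if qc.passed else "FAIL",
        )
        qc_rows.append(
            {
                "barcode": plate.barcode,
                "n_neg": stats.n_neg,
                "n_pos": stats.n_pos,
                "av_neg": stats.av_neg,
                "sd_neg": stats.sd_neg,
                "av_pos": stats.av_pos,
                "sd_pos": stats.sd_pos,
                "zprime": qc.zprime,
                "qc_passed": qc.passed,
            }
        )
        scored = score_plate(plate, layout, stats)
        frame = scored.to_frame(plate)
        pmap = plate_maps[plate_maps["barcode"] == plate.barcode]
        frame = frame.merge(
            pmap[["well", "compound_id"]], on="well", how="left"
        )
        frame["compound_id"] = frame["compound_id"].fillna("")
        frame["zprime"] = qc.zprime
        frame["qc_passed"] = qc.passed
        meta = meta_by_barcode.get(plate.barcode, {})
        frame["experiment"] = meta.get("experiment", 0)
        frame["cell_line"] = config.cell_line or plate.cell_line
        well_frames.append(frame)
    qc_report = pd.DataFrame(qc_rows)
    scored_wells = pd.concat(well_frames, ignore_index=True)
    return qc_report, scored_wells


def run_primary(
    plates: list[PlateRead],
    plate_maps: pd.DataFrame,
    layout: PlateLayout,
    config: RunConfig = RunConfig(),
    plate_meta: pd.DataFrame | None = None,
) -> PrimaryResult:
    """Primary screen: per-plate QC + scoring, pooled threshold, hit calls.

    The hit threshold is mean + ``hit_sd_multiplier`` x SD of the pooled
    per-well negative-control scores of all QC-passed plates. Compound
    wells from failed plates are excluded from aggregation (configurable)
    but retained, flagged, in ``scored_wells``.
    """
    if not plates:
        raise InputError("no plates supplied")
    qc_report, scored_wells = _score_campaign(
        plates, plate_maps, layout, config, plate_meta
    )
    usable = scored_wells if not config.exclude_failed_plates else scored_wells[
        scored_wells["qc_passed"]
    ]
    if usable.empty:
        raise QCError("no QC-passed plates: cannot derive a hit threshold")
    neg_scores = usable.loc[
        usable["role"] == WellRole.NEGATIVE_CONTROL.value, "score"
    ].to_numpy()
    threshold = hit_threshold(neg_scores, config.hit_sd_multiplier)
    summaries = aggregate_scores(
        usable[usable["role"] == WellRole.COMPOUND.value], min_wells=config.min_wells
    )
    hit_table = call_hits(summaries, threshold)
    return PrimaryResult(
        qc_report=qc_report,
        scored_wells=scored_wells,
        hit_table=hit_table,
        threshold=threshold,
    )


def run_confirmation(
    hit_table: pd.DataFrame,
    plates: list[PlateRead],
    plate_maps: pd.DataFrame,
    layout: PlateLayout,
    config: RunConfig = RunConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confirmation screen: tier assignment + evaluation against its own controls.

    Returns ``(assignments, confirmation_table)``. An empty hit table
    yields empty outputs. The confirmation threshold is re-derived from
    the confirmation plates' negative controls with the same SD rule.
    """
    hits = hit_table[hit_table["is_hit"]] if "is_hit" in hit_table.columns else hit_table
    assignments = assign_confirmation(hits, config.tier_threshold)
    if assignments.empty:
        return assignments, pd.DataFrame(
            columns=[
                "compound_id", "tier", "conc_um", "n_wells",
                "confirmation_score", "threshold", "confirmed",
            ]
        )
    qc_report, scored_wells = _score_campaign(plates, plate_maps, layout, config)
    usable = scored_wells if not config.exclude_failed_plates else scored_wells[
        scored_wells["qc_passed"]
    ]
    if usable.empty:
        raise QCError("no QC-passed confirmation plates")
    neg = usable.loc[
        usable["role"] == WellRole.NEGATIVE_CONTROL.value, "score"
    ].to_numpy()
    threshold = hit_threshold(neg, config.hit_sd_multiplier)
    compound_wells = usable[usable["role"] == WellRole.COMPOUND.value]
    table = evaluate_confirmation(assignments, compound_wells, threshold)
    return assignments, table


def run_dose_response(
    observations: dict[str, pd.DataFrame],
    constraints: FitConstraints = FitConstraints(),
) -> pd.DataFrame:
    """Batch 4PL fitting: one row per compound, failures recorded, batch continues.

    Each observation table needs columns ``conc_um`` and ``viability``.
    """
    rows = []
    for cid, obs in observations.items():
        row: dict = {
            "compound_id": cid,
            "ic50_um": np.nan, "ci_low_um": np.nan, "ci_high_um": np.nan,
            "hill": np.nan, "top": np.nan, "bottom": np.nan,
            "rss": np.nan, "n_obs": 0,
            "fix_bottom_zero": constraints.fix_bottom_zero,
            "fix_top_one": constraints.fix_top_one,
            "converged": False, "flags": "", "error": "",
        }
        try:
            conc = obs["conc_um"].to_numpy(dtype=float)
            viab = obs["viability"].to_numpy(dtype=float)
            fit = fit_4pl(conc, viab, constraints)
            flags = classify_fit(fit, observations=(conc, viab))
            row.update(
                ic50_um=fit.params.ic50,
                ci_low_um=fit.ic50_ci95[0],
                ci_high_um=fit.ic50_ci95[1],
                hill=fit.params.hill,
                top=fit.params.top,
                bottom=fit.params.bottom,
                rss=fit.rss,
                n_obs=fit.n_obs,
                converged=fit.converged,
                flags=";".join(sorted(flags)),
            )
        except (ScreenError, KeyError) as exc:
            logger.warning("compound %s: fit failed (%s)", cid, exc)
            row["error"] = str(exc)
            if isinstance(exc, DegenerateDataError):
                row["flags"] = "degenerate"
        rows.append(row)
    return pd.DataFrame(rows)
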