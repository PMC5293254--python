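"""Synthetic screening campaigns and dose-response data with known truth.

Signal model
------------
A compound well with true effect score ``s`` has expected fluorescence

    mu(s) = mu_neg - s * (mu_neg - mu_pos)

so s = 0 reads like a vehicle well and s = 1 like the positive control.
Each plate gets a multiplicative scale factor (1 + N(0, plate_scale_sd)),
modelling day-to-day reader gain and cell-density drift; it cancels in
per-plate normalization. Optionally, occupied edge wells lose a fixed
fraction of signal (the edge effect that the confirmation layout avoids).
Well noise is Gaussian with a role-specific coefficient of variation —
fluorescence readouts at these intensities are well approximated as
Gaussian. With the default CVs of 5% and a 10x control separation the
expected plate Z' is 1 - 3(0.05*mu_pos + 0.05*mu_neg)/(mu_neg - mu_pos)
~ 0.82, inside the 0.6-0.85 band a validated screen shows.

Reproducibility
---------------
All randomness flows from the campaign seed through named
``numpy.random.SeedSequence`` substreams keyed by (plate, well), so adding
a compound or plate never perturbs the draws of the others, and zero-noise
configurations return the truth exactly.

Ground truth is recorded before any noise is drawn and emitted alongside
every dataset in its own file; no analysis stage reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dose_response import DilutionSeries, FourPLParams, _four_pl_raw
from .errors import CapacityError, ConfigurationError, InputError
from .plate_model import (
    DispenseSpec,
    PlateFormat,
    PlateLayout,
    PlateRead,
    WellRole,
    build_primary_layout,
    confirmation_plate_map,
    build_confirmation_layout,
    parse_well_label,
    plan_plates,
    primary_plate_map,
)

__all__ = [
    "ScreenSimConfig",
    "ScreenTruth",
    "SimulatedScreen",
    "make_screen_truth",
    "simulate_plate_read",
    "simulate_screen",
    "simulate_confirmation",
    "simulate_dose_response",
]


@dataclass(frozen=True)
class ScreenSimConfig:
    """Campaign-level simulation parameters.

    Defaults emulate a validated viability screen: vehicle wells around
    20000 fluorescence units, doxorubicin wells around 2000, 5% CV on all
    roles, three independent experiments each in duplicate, and a 5%
    per-plate multiplicative drift.
    """

    mu_neg: float = 20000.0
    mu_pos: float = 2000.0
    cv_neg: float = 0.05
    cv_pos: float = 0.05
    cv_compound: float = 0.05
    n_experiments: int = 3
    duplicates: int = 2
    plate_scale_sd: float = 0.05
    edge_depression: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.mu_neg > self.mu_pos > 0):
            raise ConfigurationError(
                f"need mu_neg > mu_pos > 0, got {self.mu_neg}, {self.mu_pos}"
            )
        for name in ("cv_neg", "cv_pos", "cv_compound", "plate_scale_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0 <= self.edge_depression < 1:
            raise ConfigurationError("edge_depression must be in [0, 1)")
        if self.n_experiments < 1 or self.duplicates < 1:
            raise ConfigurationError("need >= 1 experiment and >= 1 duplicate")


@dataclass(frozen=True)
class ScreenTruth:
    """Immutable ground truth, recorded before any noise is drawn."""

    scores: dict[str, float]
    dose_response: dict[str, tuple[FourPLParams, float]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"compound_id": list(self.scores), "true_score": list(self.scores.values())}
        )


def make_screen_truth(
    n_compounds: int,
    active_scores: dict[str, float] | None = None,
    n_actives: int = 0,
    active_score: float = 0.8,
    inert_score: float = 0.0,
) -> ScreenTruth:
    """Truth for a campaign of ``CPD0000...`` compounds.

    Either pass explicit ``active_scores`` (compound id -> true score) or
    spike the first ``n_actives`` compounds at ``active_score``; everyone
    else is inert. True scores live on the HTS-score scale in (-0.2, 1.2).
    """
    ids = [f"CPD{i:04d}" for i in range(n_compounds)]
    scores = {cid: float(inert_score) for cid in ids}
    if active_scores is not None:
        unknown = set(active_scores) - set(ids)
        if unknown:
            raise InputError(f"active_scores for unknown compounds: {sorted(unknown)[:5]}")
        scores.update({k: float(v) for k, v in active_scores.items()})
    else:
        for cid in ids[:n_actives]:
            scores[cid] = float(active_score)
    for cid, s in scores.items():
        if not -0.2 < s < 1.2:
            raise InputError(f"true score {s} for {cid} outside (-0.2, 1.2)")
    return ScreenTruth(scores=scores)


def _well_rng(seed: int, plate_index: int, row: int, col: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(plate_index, 1, row, col))
    )


def _plate_rng(seed: int, plate_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(plate_index, 0))
    )


_ROLE_CV = {
    WellRole.NEGATIVE_CONTROL: "cv_neg",
    WellRole.POSITIVE_CONTROL: "cv_pos",
    WellRole.COMPOUND: "cv_compound",
}


def simulate_plate_read(
    truth: ScreenTruth,
    layout: PlateLayout,
    plate_map: pd.DataFrame,
    config: ScreenSimConfig,
    plate_index: int = 0,
    barcode: str | None = None,
    cell_line: str = "SIM",
) -> PlateRead:
    """Simulate one plate read for a layout and its compound map.

    ``plate_map`` rows with role ``compound`` tie wells to compound ids in
    ``truth``; with all CVs, drift and edge depression at zero, scoring the
    plate returns every compound's true score exactly.
    """
    fmt = layout.format
    compound_by_well: dict[tuple[int, int], str] = {}
    for rec in plate_map.itertuples(index=False):
        if rec.role != WellRole.COMPOUND.value or not rec.compound_id:
            continue
        addr = parse_well_label(rec.well, fmt)
        if layout.roles[addr.row, addr.col] is not WellRole.COMPOUND:
            raise InputError(
                f"map assigns compound {rec.compound_id!r} to non-compound well {rec.well}"
            )
        if rec.compound_id not in truth.scores:
            raise InputError(f"compound {rec.compound_id!r} missing from truth")
        compound_by_well[(addr.row, addr.col)] = rec.compound_id

    n_compound_wells = layout.compound_capacity
    mapped = len(compound_by_well)
    if mapped == 0 and n_compound_wells > 0 and truth.scores:
        raise InputError("plate map assigns no truth compound to any compound well")

    scale = 1.0
    if config.plate_scale_sd > 0:
        scale = float(
            1.0 + _plate_rng(config.seed, plate_index).normal(0.0, config.plate_scale_sd)
        )
        scale = max(scale, 0.1)

    window = config.mu_neg - config.mu_pos
    signals = np.zeros((fmt.n_rows, fmt.n_cols), dtype=float)
    for r in range(fmt.n_rows):
        for c in range(fmt.n_cols):
            role = layout.roles[r, c]
            if role is WellRole.EMPTY:
                continue
            if role is WellRole.NEGATIVE_CONTROL:
                mu = config.mu_neg
            elif role is WellRole.POSITIVE_CONTROL:
                mu = config.mu_pos
            else:
                cid = compound_by_well.get((r, c))
                if cid is None:
                    continue  # unoccupied compound well
                mu = config.mu_neg - truth.scores[cid] * window
            mu *= scale
            if config.edge_depression > 0 and fmt.is_edge(r, c):
                mu *= 1.0 - config.edge_depression
            cv = getattr(config, _ROLE_CV[role])
            if cv > 0:
                mu += _well_rng(config.seed, plate_index, r, c).normal(0.0, cv * abs(mu))
            signals[r, c] = max(mu, 0.0)
    return PlateRead(
        barcode=barcode if barcode is not None else f"SIMPLATE{plate_index:03d}",
        signals=signals,
        cell_line=cell_line,
        format=fmt,
    )


@dataclass
class SimulatedScreen:
    """A full simulated campaign: plate reads, maps and acquisition metadata."""

    plates: list[PlateRead]
    plate_maps: pd.DataFrame  # long format, all plates
    plate_meta: pd.DataFrame  # barcode, page, experiment, replicate
    layout: PlateLayout
    truth: ScreenTruth


def simulate_screen(
    truth: ScreenTruth,
    config: ScreenSimConfig,
    fmt: PlateFormat = PlateFormat(),
    cell_line: str = "SIM",
    dispense: DispenseSpec = DispenseSpec(),
) -> SimulatedScreen:
    """Simulate a primary campaign: every layout page is read
    ``n_experiments x duplicates`` times (six wells per compound at the
    defaults). Barcodes encode page/experiment/replicate.
    """
    layout = build_primary_layout(fmt)
    capacity = layout.compound_capacity
    ids = sorted(truth.scores)
    n_pages = plan_plates(len(ids), capacity)
    plates: list[PlateRead] = []
    maps: list[pd.DataFrame] = []
    meta: list[dict] = []
    plate_index = 0
    for page in range(n_pages):
        page_ids = ids[page * capacity : (page + 1) * capacity]
        for exp in range(1, config.n_experiments + 1):
            for rep in range(1, config.duplicates + 1):
                barcode = f"SIM-P{page + 1:02d}-E{exp}-R{rep}"
                pmap = primary_plate_map(layout, page_ids, barcode, dispense)
                plates.append(
                    simulate_plate_read(
                        truth, layout, pmap, config, plate_index, barcode, cell_line
                    )
                )
                maps.append(pmap)
                meta.append(
                    {
                        "barcode": barcode,
                        "page": page + 1,
                        "experiment": exp,
                        "replicate": rep,
                    }
                )
                plate_index += 1
    return SimulatedScreen(
        plates=plates,
        plate_maps=pd.concat(maps, ignore_index=True),
        plate_meta=pd.DataFrame(meta),
        layout=layout,
        truth=truth,
    )


def simulate_confirmation(
    assignments: pd.DataFrame,
    confirmation_truth: dict[str, float],
    config: ScreenSimConfig,
    fmt: PlateFormat = PlateFormat(),
    n_control_wells: int = 28,
    replicates: int = 2,
    cell_line: str = "SIM",
    plate_index_base: int = 10_000,
) -> SimulatedScreen:
    """Simulate the confirmation run for tiered assignments.

    ``confirmation_truth`` maps each assigned compound to its true score at
    its assigned concentration (an all-or-none compound has a high score at
    10 uM but ~0 at 0.83 uM). Uses the edge-free confirmation layout; each
    compound is assayed in ``replicates`` wells per plate.
    """
    missing = set(assignments["compound_id"]) - set(confirmation_truth)
    if missing:
        raise InputError(
            f"confirmation truth missing for compounds: {sorted(missing)[:5]}"
        )
    interior = (fmt.n_rows - 2) * (fmt.n_cols - 2)
    per_plate = (interior - n_control_wells) // replicates
    if per_plate < 1:
        raise CapacityError("no room for compounds on the confirmation layout")
    truth = ScreenTruth(scores={k: float(v) for k, v in confirmation_truth.items()})
    plates: list[PlateRead] = []
    maps: list[pd.DataFrame] = []
    meta: list[dict] = []
    chunks = [
        assignments.iloc[i : i + per_plate]
        for i in range(0, len(assignments), per_plate)
    ] or [assignments]
    for page, chunk in enumerate(chunks):
        layout = build_confirmation_layout(
            fmt, n_compounds=len(chunk), n_control_wells=n_control_wells,
            replicates=replicates,
        )
        barcode = f"CONF-P{page + 1:02d}"
        pmap = confirmation_plate_map(layout, chunk, barcode, replicates=replicates)
        plates.append(
            simulate_plate_read(
                truth, layout, pmap, config, plate_index_base + page, barcode, cell_line
            )
        )
        maps.append(pmap)
        meta.append({"barcode": barcode, "page": page + 1, "experiment": 1, "replicate": 1})
    return SimulatedScreen(
        plates=plates,
        plate_maps=pd.concat(maps, ignore_index=True),
        plate_meta=pd.DataFrame(meta),
        layout=build_confirmation_layout(
            fmt, n_compounds=min(len(assignments), per_plate),
            n_control_wells=n_control_wells, replicates=replicates,
        ),
        truth=truth,
    )


def simulate_dose_response(
    params: FourPLParams,
    series: DilutionSeries,
    noise_sd: float,
    seed: int,
    replicates: int | None = None,
) -> pd.DataFrame:
    """Observations viability = 4PL(c) + N(0, noise_sd), one row per well.

    Zero ``noise_sd`` puts every observation exactly on the curve;
    ``replicates`` defaults to the series' replicates_per_level.
    """
    if noise_sd < 0:
        raise InputError(f"noise sd must be >= 0, got {noise_sd}")
    reps = series.replicates_per_level if replicates is None else replicates
    if reps < 0:
        raise InputError(f"replicates must be >= 0, got {reps}")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    rows = []
    for conc in series.concentrations:
        mu = _four_pl_raw(
            np.asarray(conc), params.top, params.bottom,
            np.log10(params.ic50), params.hill,
        )
        for rep in range(1, reps + 1):
            v = float(mu) + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rows.append({"conc_um": float(conc), "replicate": rep, "viability": v})
    return pd.DataFrame(rows, columns=["conc_um", "replicate", "viability"])
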