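"""Plate geometry, screening layouts, dispense arithmetic and plate-table I/O.

Conventions
-----------
* Wells are addressed 0-based internally (``row=0, col=0`` is the top-left
  well) and 1-based in labels: row letters ``A``–``Z`` then ``AA``, ``AB``…,
  column numbers zero-padded to two digits, e.g. ``"A01"``. Single-digit
  column labels (``"A1"``) are accepted on read and padded on write.
* The default format is the 384-well plate, 16 rows x 24 columns.
* The primary screening layout frames each plate with controls: columns 1-2
  are vehicle-only negative controls, columns 23-24 are positive controls
  (doxorubicin 10 uM), and the 20 middle columns hold one test compound per
  well (320 compounds on a 384-well plate).
* The confirmation layout leaves every edge well (first/last row and column)
  empty to avoid the edge effect; compounds and controls occupy only the
  interior.

Dispense arithmetic follows acoustic droplet ejection into a pre-filled
well: a drop of ``drop_volume`` nl of DMSO stock at ``stock_concentration``
mM lands in ``well_volume`` ul of medium, so the final concentration uses
the total (well + drop) volume in the denominator.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, ConfigurationError, InputError

__all__ = [
    "PlateFormat",
    "WellAddress",
    "WellRole",
    "PlateLayout",
    "PlateRead",
    "DispenseSpec",
    "parse_well_label",
    "format_well_label",
    "build_primary_layout",
    "build_confirmation_layout",
    "plan_plates",
    "final_concentration",
    "vehicle_fraction",
    "drop_volume_for",
    "primary_plate_map",
    "confirmation_plate_map",
    "read_plate_csv",
    "write_plate_csv",
    "read_plate_map",
    "write_plate_map",
    "PLATE_MAP_COLUMNS",
]


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateFormat:
    """Rectangular well grid; defaults to the 384-well (16 x 24) plate."""

    n_rows: int = 16
    n_cols: int = 24

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ConfigurationError(
                f"plate format must have positive dimensions, got "
                f"{self.n_rows} x {self.n_cols}"
            )

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def is_edge(self, row: int, col: int) -> bool:
        """True for wells in the first/last row or column."""
        return (
            row == 0
            or col == 0
            or row == self.n_rows - 1
            or col == self.n_cols - 1
        )


def _row_letters(row: int) -> str:
    """0 -> 'A', 25 -> 'Z', 26 -> 'AA' (spreadsheet-style)."""
    letters = ""
    n = row
    while True:
        letters = chr(ord("A") + n % 26) + letters
        n = n // 26 - 1
        if n < 0:
            return letters


def _letters_to_row(letters: str) -> int:
    n = 0
    for ch in letters:
        n = n * 26 + (ord(ch) - ord("A") + 1)
    return n - 1


@dataclass(frozen=True)
class WellAddress:
    """0-based (row, col) position on a plate."""

    row: int
    col: int

    @property
    def label(self) -> str:
        return format_well_label(self.row, self.col)


def format_well_label(row: int, col: int, pad: int = 2) -> str:
    """Canonical label for a 0-based (row, col), e.g. (0, 0) -> 'A01'."""
    if row < 0 or col < 0:
        raise InputError(f"well coordinates must be non-negative, got ({row}, {col})")
    return f"{_row_letters(row)}{col + 1:0{pad}d}"


_LABEL_RE = re.compile(r"^([A-Za-z]+)0*([0-9]+)$")


def parse_well_label(label: str, fmt: PlateFormat = PlateFormat()) -> WellAddress:
    """Parse a well label like 'A01' / 'p7' into a :class:`WellAddress`.

    Raises
    ------
    InputError
        If the label is malformed or addresses a well outside ``fmt``.
    """
    m = _LABEL_RE.match(str(label).strip())
    if not m:
        raise InputError(f"malformed well label {label!r}")
    row = _letters_to_row(m.group(1).upper())
    col = int(m.group(2)) - 1
    if col < 0 or row >= fmt.n_rows or col >= fmt.n_cols:
        raise InputError(
            f"well label {label!r} outside the {fmt.n_rows} x {fmt.n_cols} plate"
        )
    return WellAddress(row=row, col=col)


# ---------------------------------------------------------------------------
# Layouts
# ---------------------------------------------------------------------------

class WellRole(str, Enum):
    NEGATIVE_CONTROL = "negative_control"
    POSITIVE_CONTROL = "positive_control"
    COMPOUND = "compound"
    EMPTY = "empty"


@dataclass(frozen=True)
class PlateLayout:
    """Role assignment over a well grid."""

    format: PlateFormat
    roles: np.ndarray  # object array of WellRole, shape (n_rows, n_cols)

    def __post_init__(self) -> None:
        if self.roles.shape != (self.format.n_rows, self.format.n_cols):
            raise ConfigurationError(
                f"role grid shape {self.roles.shape} does not match format "
                f"{self.format.n_rows} x {self.format.n_cols}"
            )

    def wells(self, role: WellRole) -> list[WellAddress]:
        rows, cols = np.nonzero(self.mask(role))
        return [WellAddress(int(r), int(c)) for r, c in zip(rows, cols)]

    def mask(self, role: WellRole) -> np.ndarray:
        # identity comparison: enum members are singletons and numpy's ==
        # is unreliable on object arrays of str-enums
        return np.frompyfunc(lambda x: x is role, 1, 1)(self.roles).astype(bool)

    def role_counts(self) -> dict[WellRole, int]:
        return {role: int(self.mask(role).sum()) for role in WellRole}

    @property
    def compound_capacity(self) -> int:
        return int(self.mask(WellRole.COMPOUND).sum())


def build_primary_layout(fmt: PlateFormat = PlateFormat()) -> PlateLayout:
    """Primary screen layout: controls frame the plate, compounds in between.

    First two columns -> negative control, last two -> positive control,
    everything else a compound well. On 16 x 24 this gives 32 + 32 controls
    and 320 compound wells.
    """
    if fmt.n_cols < 5:
        raise ConfigurationError(
            f"primary layout needs at least 5 columns, format has {fmt.n_cols}"
        )
    roles = np.empty((fmt.n_rows, fmt.n_cols), dtype=object)
    roles[...] = WellRole.COMPOUND
    roles[:, :2] = WellRole.NEGATIVE_CONTROL
    roles[:, -2:] = WellRole.POSITIVE_CONTROL
    return PlateLayout(format=fmt, roles=roles)


def build_confirmation_layout(
    fmt: PlateFormat = PlateFormat(),
    n_compounds: int = 0,
    n_control_wells: int = 28,
    replicates: int = 2,
) -> PlateLayout:
    """Confirmation layout: edge wells empty, controls in interior columns.

    Negative-control wells fill the leftmost interior columns top to bottom,
    positive controls the rightmost; compound wells (``replicates`` each, in
    adjacent wells) fill the remaining interior column-major. This control
    placement is a declared convention of this package; only the edge-well
    exclusion itself is part of the protocol.

    Raises
    ------
    CapacityError
        If ``n_compounds * replicates + n_control_wells`` exceeds the
        interior capacity ``(n_rows - 2) * (n_cols - 2)``.
    """
    if fmt.n_rows < 3 or fmt.n_cols < 3:
        raise ConfigurationError("confirmation layout needs an interior, format too small")
    if n_compounds < 0 or n_control_wells < 0 or replicates < 1:
        raise ConfigurationError("counts must be non-negative and replicates >= 1")
    interior_capacity = (fmt.n_rows - 2) * (fmt.n_cols - 2)
    needed = n_compounds * replicates + n_control_wells
    if needed > interior_capacity:
        raise CapacityError(
            f"{n_compounds} compounds x {replicates} wells + {n_control_wells} "
            f"controls = {needed} wells exceed the interior capacity of "
            f"{interior_capacity} ({fmt.n_rows - 2} x {fmt.n_cols - 2} non-edge wells)"
        )
    roles = np.empty((fmt.n_rows, fmt.n_cols), dtype=object)
    roles[...] = WellRole.EMPTY
    # interior wells column-major: natural dispensing order
    interior = [
        (r, c)
        for c in range(1, fmt.n_cols - 1)
        for r in range(1, fmt.n_rows - 1)
    ]
    n_neg = n_control_wells - n_control_wells // 2  # negatives get the odd extra
    n_pos = n_control_wells // 2
    for r, c in interior[:n_neg]:
        roles[r, c] = WellRole.NEGATIVE_CONTROL
    for r, c in interior[::-1][:n_pos]:
        roles[r, c] = WellRole.POSITIVE_CONTROL
    free = [rc for rc in interior if roles[rc] is WellRole.EMPTY]
    for r, c in free[: n_compounds * replicates]:
        roles[r, c] = WellRole.COMPOUND
    return PlateLayout(format=fmt, roles=roles)


def plan_plates(n_compounds: int, capacity_per_plate: int) -> int:
    """Plates required to host ``n_compounds`` at one well per compound."""
    if capacity_per_plate < 1:
        raise ConfigurationError(
            f"capacity per plate must be >= 1, got {capacity_per_plate}"
        )
    if n_compounds < 0:
        raise InputError(f"compound count must be >= 0, got {n_compounds}")
    return math.ceil(n_compounds / capacity_per_plate)


# ---------------------------------------------------------------------------
# Dispense arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DispenseSpec:
    """One acoustic dispense: stock (mM), drop (nl) into a well (ul)."""

    stock_concentration_mm: float = 10.0
    drop_volume_nl: float = 30.0
    well_volume_ul: float = 30.0

    def __post_init__(self) -> None:
        if self.stock_concentration_mm <= 0:
            raise InputError(
                f"stock concentration must be > 0 mM, got {self.stock_concentration_mm}"
            )
        if self.drop_volume_nl < 0:
            raise InputError(f"drop volume must be >= 0 nl, got {self.drop_volume_nl}")
        if self.well_volume_ul <= 0:
            raise InputError(f"well volume must be > 0 ul, got {self.well_volume_ul}")


def final_concentration(spec: DispenseSpec) -> float:
    """Final compound concentration in uM after the drop lands in the well.

    Mass balance on the total volume: ``stock * drop / (well + drop)``,
    with the stock in uM and volumes in nl. The classic screening dispense,
    30 nl of 10 mM stock into 30 ul, gives 9.99 uM (reported as 10 uM).
    """
    stock_um = spec.stock_concentration_mm * 1000.0
    well_nl = spec.well_volume_ul * 1000.0
    return stock_um * spec.drop_volume_nl / (well_nl + spec.drop_volume_nl)


def vehicle_fraction(spec: DispenseSpec) -> float:
    """Vehicle (DMSO) volume percentage contributed by the drop."""
    well_nl = spec.well_volume_ul * 1000.0
    return 100.0 * spec.drop_volume_nl / (well_nl + spec.drop_volume_nl)


def drop_volume_for(
    target_um: float, stock_concentration_mm: float, well_volume_ul: float
) -> float:
    """Drop volume (nl) that yields ``target_um`` — inverse of final_concentration."""
    stock_um = stock_concentration_mm * 1000.0
    if not 0 <= target_um < stock_um:
        raise InputError(
            f"target {target_um} uM not reachable from a {stock_concentration_mm} mM stock"
        )
    well_nl = well_volume_ul * 1000.0
    return target_um * well_nl / (stock_um - target_um)


# ---------------------------------------------------------------------------
# Plate reads
# ---------------------------------------------------------------------------

@dataclass
class PlateRead:
    """One plate's raw fluorescence matrix with acquisition metadata."""

    barcode: str
    signals: np.ndarray
    cell_line: str = ""
    exposure_h: float = float("nan")
    format: PlateFormat = PlateFormat()

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.shape != (self.format.n_rows, self.format.n_cols):
            raise InputError(
                f"plate {self.barcode!r}: signal matrix shape {self.signals.shape} "
                f"does not match format {self.format.n_rows} x {self.format.n_cols}"
            )
        if not np.all(np.isfinite(self.signals)):
            bad = np.argwhere(~np.isfinite(self.signals))[0]
            raise InputError(
                f"plate {self.barcode!r}: non-finite signal at well "
                f"{format_well_label(int(bad[0]), int(bad[1]))}"
            )
        if np.any(self.signals < 0):
            bad = np.argwhere(self.signals < 0)[0]
            raise InputError(
                f"plate {self.barcode!r}: negative signal at well "
                f"{format_well_label(int(bad[0]), int(bad[1]))}"
            )


# ---------------------------------------------------------------------------
# I/O — plate matrix CSV and long-format plate map CSV
# ---------------------------------------------------------------------------

PLATE_MAP_COLUMNS = [
    "barcode",
    "well",
    "compound_id",
    "role",
    "conc_um",
    "stock_mm",
    "drop_nl",
]


def write_plate_csv(read: PlateRead, path: str | Path) -> None:
    """Write a plate matrix CSV: header = column numbers, first column = row letters."""
    fmt = read.format
    df = pd.DataFrame(
        read.signals,
        index=[_row_letters(r) for r in range(fmt.n_rows)],
        columns=[str(c + 1) for c in range(fmt.n_cols)],
    )
    df.to_csv(path, index_label="row")


def read_plate_csv(
    path: str | Path,
    fmt: PlateFormat = PlateFormat(),
    barcode: str | None = None,
    cell_line: str = "",
    exposure_h: float = float("nan"),
) -> PlateRead:
    """Read a plate matrix CSV written by :func:`write_plate_csv`.

    The barcode defaults to the file stem. Shape mismatches and bad values
    raise :class:`InputError` naming the file (and well, where known).
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    if df.shape != (fmt.n_rows, fmt.n_cols):
        raise InputError(
            f"{path.name}: expected {fmt.n_rows} rows x {fmt.n_cols} columns, "
            f"found {df.shape[0]} x {df.shape[1]}"
        )
    expected_rows = [_row_letters(r) for r in range(fmt.n_rows)]
    if list(df.index) != expected_rows:
        raise InputError(f"{path.name}: row letters do not match the plate format")
    signals = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(signals)):
        r, c = np.argwhere(~np.isfinite(signals))[0]
        raise InputError(
            f"{path.name}: non-numeric signal at well {format_well_label(int(r), int(c))}"
        )
    return PlateRead(
        barcode=barcode if barcode is not None else path.stem,
        signals=signals,
        cell_line=cell_line,
        exposure_h=exposure_h,
        format=fmt,
    )


def write_plate_map(plate_map: pd.DataFrame, path: str | Path) -> None:
    _validate_plate_map(plate_map, name=str(path))
    plate_map.to_csv(path, index=False, columns=PLATE_MAP_COLUMNS)


def read_plate_map(path: str | Path, fmt: PlateFormat = PlateFormat()) -> pd.DataFrame:
    """Read a long-format plate map CSV and validate labels against ``fmt``."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"barcode": str, "well": str, "compound_id": str})
    _validate_plate_map(df, name=path.name)
    for well in df["well"]:
        try:
            parse_well_label(well, fmt)
        except InputError as exc:
            raise InputError(f"{path.name}: {exc}") from exc
    return df


def _validate_plate_map(df: pd.DataFrame, name: str = "plate map") -> None:
    missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{name}: missing plate-map columns {missing}")
    compound = df[df["role"] == WellRole.COMPOUND.value]
    if (compound["conc_um"] <= 0).any():
        bad = compound.loc[compound["conc_um"] <= 0].iloc[0]
        raise InputError(
            f"{name}: non-positive concentration for compound well {bad['well']}"
        )
    dup = compound.duplicated(subset=["barcode", "well"])
    if dup.any():
        bad = compound.loc[dup].iloc[0]
        raise InputError(
            f"{name}: duplicate map entry for well {bad['well']} on plate {bad['barcode']}"
        )


def _column_major_wells(layout: PlateLayout, role: WellRole) -> list[WellAddress]:
    fmt = layout.format
    return [
        WellAddress(r, c)
        for c in range(fmt.n_cols)
        for r in range(fmt.n_rows)
        if layout.roles[r, c] is role
    ]


def primary_plate_map(
    layout: PlateLayout,
    compound_ids: Sequence[str],
    barcode: str,
    spec: DispenseSpec = DispenseSpec(),
) -> pd.DataFrame:
    """Long-format map for one primary plate: compounds fill column-major.

    Unused compound wells (when fewer compounds than capacity) are recorded
    with role ``empty``. Every well of the plate gets a row, so the map
    doubles as the audit trail for control wells.
    """
    wells = _column_major_wells(layout, WellRole.COMPOUND)
    if len(compound_ids) > len(wells):
        raise CapacityError(
            f"{len(compound_ids)} compounds exceed the layout capacity of {len(wells)}"
        )
    conc = final_concentration(spec)
    rows: list[dict] = []
    assigned = {w: cid for w, cid in zip(wells, compound_ids)}
    fmt = layout.format
    for r in range(fmt.n_rows):
        for c in range(fmt.n_cols):
            role = layout.roles[r, c]
            addr = WellAddress(r, c)
            if role is WellRole.COMPOUND:
                cid = assigned.get(addr)
                rows.append(
                    {
                        "barcode": barcode,
                        "well": addr.label,
                        "compound_id": cid if cid is not None else "",
                        "role": (role if cid is not None else WellRole.EMPTY).value,
                        "conc_um": conc if cid is not None else 0.0,
                        "stock_mm": spec.stock_concentration_mm,
                        "drop_nl": spec.drop_volume_nl if cid is not None else 0.0,
                    }
                )
            else:
                rows.append(
                    {
                        "barcode": barcode,
                        "well": addr.label,
                        "compound_id": "",
                        "role": role.value,
                        "conc_um": conc if role is WellRole.POSITIVE_CONTROL else 0.0,
                        "stock_mm": spec.stock_concentration_mm,
                        "drop_nl": spec.drop_volume_nl
                        if role is not WellRole.EMPTY
                        else 0.0,
                    }
                )
    return pd.DataFrame(rows, columns=PLATE_MAP_COLUMNS)


def confirmation_plate_map(
    layout: PlateLayout,
    assignments: pd.DataFrame,
    barcode: str,
    replicates: int = 2,
    well_volume_ul: float = 30.0,
) -> pd.DataFrame:
    """Map for one confirmation plate from tier assignments.

    ``assignments`` needs columns compound_id, target_conc_um, drop_nl,
    stock_mm; each compound receives ``replicates`` adjacent compound wells
    in column-major order.
    """
    wells = _column_major_wells(layout, WellRole.COMPOUND)
    if len(assignments) * replicates > len(wells):
        raise CapacityError(
            f"{len(assignments)} compounds x {replicates} wells exceed the "
            f"layout's {len(wells)} compound wells"
        )
    rows: list[dict] = []
    it = iter(wells)
    for rec in assignments.itertuples(index=False):
        for _ in range(replicates):
            addr = next(it)
            rows.append(
                {
                    "barcode": barcode,
                    "well": addr.label,
                    "compound_id": rec.compound_id,
                    "role": WellRole.COMPOUND.value,
                    "conc_um": rec.target_conc_um,
                    "stock_mm": rec.stock_mm,
                    "drop_nl": rec.drop_nl,
                }
            )
    for role in (WellRole.NEGATIVE_CONTROL, WellRole.POSITIVE_CONTROL):
        for addr in _column_major_wells(layout, role):
            rows.append(
                {
                    "barcode": barcode,
                    "well": addr.label,
                    "compound_id": "",
                    "role": role.value,
                    "conc_um": 10.0 if role is WellRole.POSITIVE_CONTROL else 0.0,
                    "stock_mm": 10.0,
                    "drop_nl": 30.0,
                }
            )
    return pd.DataFrame(rows, columns=PLATE_MAP_COLUMNS)
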