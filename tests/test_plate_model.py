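"""Geometry, layout and dispense-arithmetic behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from platescreen.errors import CapacityError, ConfigurationError, InputError
from platescreen.plate_model import (
    DispenseSpec,
    PlateFormat,
    PlateRead,
    WellAddress,
    WellRole,
    build_confirmation_layout,
    build_primary_layout,
    confirmation_plate_map,
    drop_volume_for,
    final_concentration,
    format_well_label,
    parse_well_label,
    plan_plates,
    primary_plate_map,
    read_plate_csv,
    read_plate_map,
    vehicle_fraction,
    write_plate_csv,
    write_plate_map,
)


class TestWellLabels:
    @pytest.mark.parametrize(
        "label,row,col",
        [("A01", 0, 0), ("P24", 15, 23), ("a1", 0, 0), ("H12", 7, 11)],
    )
    def test_parse(self, label, row, col):
        addr = parse_well_label(label)
        assert (addr.row, addr.col) == (row, col)

    @pytest.mark.parametrize("label", ["Q01", "A25", "A0", "1A", "", "A-1"])
    def test_rejects_malformed_or_out_of_bounds(self, label):
        with pytest.raises(InputError):
            parse_well_label(label, PlateFormat(16, 24))

    def test_error_names_the_label(self):
        with pytest.raises(InputError, match="Q01"):
            parse_well_label("Q01")

    @given(st.integers(0, 15), st.integers(0, 23))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip(self, row, col):
        addr = WellAddress(row, col)
        assert parse_well_label(addr.label) == addr

    def test_double_letter_rows(self):
        assert format_well_label(26, 0) == "AA01"
        fmt = PlateFormat(32, 48)
        assert parse_well_label("AA01", fmt) == WellAddress(26, 0)


class TestLayouts:
    def test_primary_384_well_counts(self, primary_layout):
        counts = primary_layout.role_counts()
        assert counts[WellRole.NEGATIVE_CONTROL] == 32
        assert counts[WellRole.POSITIVE_CONTROL] == 32
        assert counts[WellRole.COMPOUND] == 320
        assert counts[WellRole.EMPTY] == 0

    def test_primary_96_well_counts(self):
        # same rule on 8x12: two 8-well columns per control side, 8x8 compounds
        layout = build_primary_layout(PlateFormat(8, 12))
        counts = layout.role_counts()
        assert counts[WellRole.NEGATIVE_CONTROL] == 16
        assert counts[WellRole.POSITIVE_CONTROL] == 16
        assert counts[WellRole.COMPOUND] == 64
        assert sum(counts.values()) == 96

    def test_primary_control_columns(self, primary_layout):
        assert all(
            primary_layout.roles[r, c] is WellRole.NEGATIVE_CONTROL
            for r in range(16)
            for c in (0, 1)
        )
        assert all(
            primary_layout.roles[r, c] is WellRole.POSITIVE_CONTROL
            for r in range(16)
            for c in (22, 23)
        )

    def test_primary_too_narrow(self):
        with pytest.raises(ConfigurationError):
            build_primary_layout(PlateFormat(8, 4))

    def test_layout_conservation(self, primary_layout, fmt384):
        assert sum(primary_layout.role_counts().values()) == fmt384.n_wells

    def test_confirmation_edges_empty(self, fmt384):
        layout = build_confirmation_layout(fmt384, n_compounds=100, n_control_wells=28)
        for r in range(16):
            for c in range(24):
                if fmt384.is_edge(r, c):
                    assert layout.roles[r, c] is WellRole.EMPTY

    def test_confirmation_interior_capacity(self, fmt384):
        assert (fmt384.n_rows - 2) * (fmt384.n_cols - 2) == 308
        # 200 compounds x 2 + 16 controls = 416 > 308
        with pytest.raises(CapacityError, match="308"):
            build_confirmation_layout(fmt384, n_compounds=200, n_control_wells=16)

    def test_confirmation_no_compounds(self, fmt384):
        layout = build_confirmation_layout(fmt384, n_compounds=0, n_control_wells=28)
        counts = layout.role_counts()
        assert counts[WellRole.COMPOUND] == 0
        assert counts[WellRole.NEGATIVE_CONTROL] + counts[WellRole.POSITIVE_CONTROL] == 28

    def test_confirmation_well_counts(self, fmt384):
        layout = build_confirmation_layout(fmt384, n_compounds=50, n_control_wells=28)
        assert layout.compound_capacity == 100


class TestPlanPlates:
    @pytest.mark.parametrize(
        "n,cap,expected", [(1280, 320, 4), (321, 320, 2), (0, 320, 0), (1, 1, 1)]
    )
    def test_examples(self, n, cap, expected):
        assert plan_plates(n, cap) == expected

    @given(st.integers(1, 10_000), st.integers(1, 500))
    @settings(max_examples=200, derandomize=True)
    def test_ceiling_invariant(self, n, cap):
        p = plan_plates(n, cap)
        assert p * cap >= n
        assert (p - 1) * cap < n

    def test_zero_capacity_rejected(self):
        with pytest.raises(ConfigurationError):
            plan_plates(10, 0)


class TestDispenseMath:
    def test_screening_dispense(self):
        spec = DispenseSpec(10, 30, 30)
        assert final_concentration(spec) == pytest.approx(9.990, abs=1e-3)
        assert vehicle_fraction(spec) == pytest.approx(0.0999, abs=1e-4)

    def test_low_tier_dispense(self):
        assert final_concentration(DispenseSpec(10, 2.5, 30)) == pytest.approx(
            0.833, abs=1e-3
        )

    def test_zero_drop(self):
        assert final_concentration(DispenseSpec(10, 0, 30)) == 0.0
        assert vehicle_fraction(DispenseSpec(10, 0, 30)) == 0.0

    def test_equal_volumes_give_half_vehicle(self):
        assert vehicle_fraction(DispenseSpec(10, 30_000, 30)) == pytest.approx(50.0)

    def test_linear_in_stock(self):
        base = final_concentration(DispenseSpec(10, 30, 30))
        assert final_concentration(DispenseSpec(25, 30, 30)) == pytest.approx(2.5 * base)

    @given(st.floats(1, 100), st.floats(0.1, 100), st.floats(1, 100))
    @settings(max_examples=100, derandomize=True)
    def test_monotone_in_drop_volume(self, stock, drop, well):
        lo = final_concentration(DispenseSpec(stock, drop, well))
        hi = final_concentration(DispenseSpec(stock, drop * 1.5, well))
        assert hi > lo

    def test_negative_volume_rejected(self):
        with pytest.raises(InputError):
            DispenseSpec(10, -1, 30)

    def test_drop_volume_inverse(self):
        drop = drop_volume_for(0.83, 10, 30)
        assert final_concentration(DispenseSpec(10, drop, 30)) == pytest.approx(0.83)


class TestPlateIO:
    def test_plate_csv_round_trip(self, tmp_path, toy_plate):
        path = tmp_path / "TOY1.csv"
        write_plate_csv(toy_plate, path)
        back = read_plate_csv(path)
        assert back.barcode == "TOY1"
        np.testing.assert_allclose(back.signals, toy_plate.signals)

    def test_shape_mismatch_names_file(self, tmp_path, toy_plate):
        path = tmp_path / "bad.csv"
        write_plate_csv(toy_plate, path)
        with pytest.raises(InputError, match="bad.csv"):
            read_plate_csv(path, PlateFormat(8, 12))

    def test_negative_signal_names_well(self):
        signals = np.ones((16, 24))
        signals[2, 5] = -1.0
        with pytest.raises(InputError, match="C06"):
            PlateRead(barcode="X", signals=signals)

    def test_plate_map_round_trip(self, tmp_path, primary_layout):
        ids = [f"C{i:03d}" for i in range(320)]
        pmap = primary_plate_map(primary_layout, ids, barcode="B1")
        assert (pmap["role"] == "compound").sum() == 320
        path = tmp_path / "map.csv"
        write_plate_map(pmap, path)
        back = read_plate_map(path)
        compound = back[back["role"] == "compound"]
        assert set(compound["compound_id"]) == set(ids)
        assert (compound["conc_um"] > 0).all()

    def test_map_rejects_duplicate_wells(self, tmp_path):
        df = pd.DataFrame(
            {
                "barcode": ["B", "B"],
                "well": ["C05", "C05"],
                "compound_id": ["x", "y"],
                "role": ["compound", "compound"],
                "conc_um": [10.0, 10.0],
                "stock_mm": [10.0, 10.0],
                "drop_nl": [30.0, 30.0],
            }
        )
        with pytest.raises(InputError, match="C05"):
            write_plate_map(df, tmp_path / "dup.csv")

    def test_confirmation_map_duplicates_each_compound(self, fmt384):
        layout = build_confirmation_layout(fmt384, n_compounds=3, n_control_wells=28)
        assignments = pd.DataFrame(
            {
                "compound_id": ["a", "b", "c"],
                "target_conc_um": [0.83, 10.0, 10.0],
                "drop_nl": [2.5, 30.0, 30.0],
                "stock_mm": [10.0] * 3,
            }
        )
        pmap = confirmation_plate_map(layout, assignments, barcode="CONF")
        compound = pmap[pmap["role"] == "compound"]
        assert compound["compound_id"].value_counts().eq(2).all()
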