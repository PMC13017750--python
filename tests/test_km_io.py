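"""Digitized-curve parsing, normalization and grid interpolation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from idasurv import (
    ExtrapolationError,
    KMCoordinates,
    KMCurve,
    KMValidationError,
    RiskTable,
    common_t_max,
    enforce_monotone,
    interpolate_to_grid,
    read_km_csv,
    read_risk_table_csv,
    write_km_csv,
)


# ---------------------------------------------------------------- CSV parsing

def test_read_km_csv_parses_plain_rows(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text("0,1.0\n6,0.93\n12,0.85\n")
    coords = read_km_csv(p, arm_label="x")
    assert coords.n_points == 3
    np.testing.assert_allclose(coords.times, [0, 6, 12])
    np.testing.assert_allclose(coords.survival, [1.0, 0.93, 0.85])
    assert coords.arm_label == "x"


def test_read_km_csv_accepts_header_and_comments(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text("# digitized curve\ntime_months,survival\n0,1.0\n6,0.9\n")
    coords = read_km_csv(p)
    assert coords.n_points == 2
    np.testing.assert_allclose(coords.survival, [1.0, 0.9])


def test_duplicate_times_collapse_to_minimum(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text("0,1.0\n6,0.93\n6,0.92\n")
    coords = read_km_csv(p)
    assert coords.n_points == 2
    assert coords.survival[coords.times == 6] == pytest.approx(0.92)


@pytest.mark.parametrize(
    "rows",
    ["0,1.0\n6,1.2\n", "0,1.0\n-3,0.9\n", "0,1.0\n6,93\n"],
    ids=["survival_above_one", "negative_time", "percent_scale"],
)
def test_invalid_values_rejected(tmp_path, rows):
    p = tmp_path / "c.csv"
    p.write_text(rows)
    with pytest.raises(KMValidationError):
        read_km_csv(p)


def test_non_numeric_cell_rejected(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text("0,1.0\nsix,0.9\n")
    with pytest.raises(KMValidationError):
        read_km_csv(p)


def test_missing_file_raises():
    with pytest.raises(FileNotFoundError):
        read_km_csv("no/such/file.csv")


def test_survival_just_above_one_clamps(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text(f"0,1.0\n3,{1 + 5e-7}\n6,0.9\n")
    coords = read_km_csv(p)
    assert coords.survival[coords.times == 3] == pytest.approx(1.0)


def test_origin_prepended_when_absent():
    coords = KMCoordinates([2.0, 4.0], [0.9, 0.8])
    assert coords.times[0] == 0.0
    assert coords.survival[0] == 1.0


def test_km_csv_round_trips(tmp_path):
    coords = KMCoordinates([0, 1, 2], [1.0, 0.8, 0.5])
    p = tmp_path / "out.csv"
    write_km_csv(coords, p)
    back = read_km_csv(p)
    np.testing.assert_allclose(back.times, coords.times)
    np.testing.assert_allclose(back.survival, coords.survival)


# ---------------------------------------------------------------- risk tables

def test_risk_table_csv_and_validation(tmp_path):
    p = tmp_path / "rt.csv"
    p.write_text("time_months,n_at_risk\n0,100\n6,80\n12,50\n")
    rt = read_risk_table_csv(p)
    assert rt.n0 == 100
    assert rt.truncate(6.0).times.tolist() == [0, 6]


@pytest.mark.parametrize(
    "times,counts",
    [([0, 6], [80, 100]), ([6, 12], [100, 80]), ([0, 0], [100, 90]), ([0], [-1])],
    ids=["increasing_counts", "missing_t0", "duplicate_times", "negative_count"],
)
def test_risk_table_invariants(times, counts):
    with pytest.raises(KMValidationError):
        RiskTable(times, counts)


# ------------------------------------------------------------- monotone repair

def test_enforce_monotone_running_minimum():
    c = KMCoordinates([0, 1, 2, 3], [1.0, 0.95, 0.97, 0.90])
    np.testing.assert_allclose(enforce_monotone(c).survival, [1.0, 0.95, 0.95, 0.90])


def test_enforce_monotone_keeps_ties_and_sorted_input():
    c = KMCoordinates([0, 1, 2], [1.0, 1.0, 0.99])
    np.testing.assert_allclose(enforce_monotone(c).survival, c.survival)


@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=30)
)
def test_enforce_monotone_idempotent_and_nonincreasing(values):
    c = KMCoordinates(np.arange(1, len(values) + 1, dtype=float), values)
    once = enforce_monotone(c)
    twice = enforce_monotone(once)
    assert np.all(np.diff(once.survival) <= 0)
    np.testing.assert_array_equal(once.survival, twice.survival)
    np.testing.assert_array_equal(once.times, c.times)


# ------------------------------------------------------------- interpolation

def test_interpolation_midpoint_knot_and_flat_segment():
    c = KMCoordinates([0, 1], [1.0, 0.9])
    curve = interpolate_to_grid(c, 0.5)
    assert curve.survival_at(0.5) == pytest.approx(0.95)

    c2 = KMCoordinates([0, 2, 4], [1.0, 0.8, 0.8])
    curve2 = interpolate_to_grid(c2, 0.5)
    assert curve2.survival_at(2.0) == pytest.approx(0.8)  # exact at knot
    assert curve2.survival_at(3.0) == pytest.approx(0.8)  # flat segment


def test_extrapolation_request_rejected():
    c = KMCoordinates([0, 10], [1.0, 0.5])
    with pytest.raises(ExtrapolationError):
        interpolate_to_grid(c, 0.5, t_max=12.0)


def test_grid_round_trip_reproduces_grid_sampled_curve():
    t = np.arange(0, 10.5, 0.5)
    s = np.exp(-0.1 * t)
    curve = interpolate_to_grid(KMCoordinates(t, s), 0.5)
    np.testing.assert_allclose(curve.survival, s, atol=1e-12)


@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=3, max_size=20)
)
def test_interpolation_preserves_monotonicity(values):
    coords = enforce_monotone(
        KMCoordinates(np.arange(1, len(values) + 1, dtype=float), values)
    )
    curve = interpolate_to_grid(coords, 0.25)
    assert np.all(np.diff(curve.survival) <= 1e-12)
    assert curve.survival[0] == 1.0


def test_common_t_max_is_minimum_of_last_times():
    a = KMCoordinates([0, 10], [1.0, 0.5])
    b = KMCoordinates([0, 8], [1.0, 0.6])
    assert common_t_max(a, b) == pytest.approx(8.0)


def test_km_curve_invariant_violations_rejected():
    t = np.arange(0, 5.5, 0.5)
    with pytest.raises(KMValidationError):
        KMCurve(t, np.linspace(1.0, 1.2, t.size), 0.5)  # above one
    with pytest.raises(KMValidationError):
        KMCurve(t, np.linspace(0.5, 0.2, t.size), 0.5)  # does not start at 1
    s = np.linspace(1.0, 0.5, t.size)
    s[4] = 0.99  # local increase
    with pytest.raises(KMValidationError):
        KMCurve(t, s, 0.5)
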