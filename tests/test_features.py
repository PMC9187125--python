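"""24-measure catalogue: hand oracles, degenerate denominators, standardize."""

import numpy as np
import pandas as pd
import pytest

from paintraj.features import (
    DEFAULT_WINSOR_PCT,
    FEATURE_NAMES,
    compute_measures,
    feature_matrix,
    standardize,
)
from tests.conftest import make_series

IDX = {name: i for i, name in enumerate(FEATURE_NAMES)}


def test_linear_series_oracle(linear_series):
    """Exact line (0,2,4,6) at (0,24,48,72): slope 2/24, change 6, R^2 1,
    all second differences 0."""
    f = compute_measures(linear_series)
    m = f.m
    assert m[IDX["slope"]] == pytest.approx(2 / 24)
    assert m[IDX["change"]] == pytest.approx(6.0)
    assert m[IDX["r_squared"]] == pytest.approx(1.0)
    assert m[IDX["mean_second_diff"]] == pytest.approx(0.0, abs=1e-12)
    assert m[IDX["max_abs_second_diff"]] == pytest.approx(0.0, abs=1e-12)
    # y[0] = 0 -> change relative to first score is degenerate: 0 + flag
    assert m[IDX["change_rel_first"]] == 0.0
    assert f.flags[IDX["change_rel_first"]]


# Hand-computed oracle for scores (6, 2, 5, 1) at times (0, 12, 36, 60):
#   dt = (12, 24, 24); d = (-4, 3, -4); w = d/dt = (-1/3, 1/8, -1/6)
#   second differences: diff(w) / ((t[2:] - t[:-2]) / 2) over spans (18, 24)
#   slope = -114/2124; SE(slope) = sqrt((17 - slope^2*2124)/2/2124) = 0.0506
#   |slope| = 0.0537 <= 2 SE -> slope-denominator measures degenerate.
ZIGZAG_ORACLE = {
    "range": 5.0,
    "mean_over_time": 3.5,
    "sd": 2.3804761428476167,
    "coef_variation": 0.6801360408136048,
    "change": -5.0,
    "mean_change_per_h": -5.0 / 60.0,
    "change_rel_first": -5.0 / 6.0,
    "change_rel_mean": -5.0 / 3.5,
    "slope": -114.0 / 2124.0,
    "r_squared": 361.0 / 1003.0,  # slope^2 * Sxx / SST = 114^2 / (2124 * 17)
    "max_first_diff": 3.0,
    "sd_first_diff": 4.041451884327381,
    "sd_first_diff_per_h": 31.0 ** 0.5 / 24.0,  # SD of (-1/3, 1/8, -1/6)
    "mean_abs_first_diff": 11.0 / 3.0,
    "max_abs_first_diff": 4.0,
    "max_abs_fd_over_mean": 4.0 / 3.5,
    "max_abs_fd_over_slope": 0.0,   # degenerate: |slope| within 2 SE of 0
    "sd_fd_over_slope": 0.0,        # degenerate: |slope| within 2 SE of 0
    "mean_second_diff": 0.006655092592592594,
    "mean_abs_second_diff": 0.018807870370370372,
    "max_abs_second_diff": 0.025462962962962965,
    "max_abs_sd_over_mean": 0.025462962962962965 / 3.5,
    "max_abs_sd_over_mean_abs_fd": 1.0 / 144.0,
    "mean_abs_sd_over_mean_abs_fd": 0.005129419191919192,
}


def test_zigzag_hand_oracle(zigzag_series):
    f = compute_measures(zigzag_series)
    for name, expected in ZIGZAG_ORACLE.items():
        assert f.m[IDX[name]] == pytest.approx(expected, rel=1e-9, abs=1e-12), name
    assert f.flags[IDX["max_abs_fd_over_slope"]]
    assert f.flags[IDX["sd_fd_over_slope"]]
    assert not f.flags[IDX["coef_variation"]]


def test_flat_zero_series_fully_degenerate():
    f = compute_measures(make_series("F", (0.0, 8.0, 16.0, 24.0), (0, 0, 0, 0)))
    assert np.all(np.isfinite(f.m))
    assert np.all(f.m == 0.0)
    for name in ("coef_variation", "change_rel_first", "change_rel_mean",
                 "r_squared", "max_abs_fd_over_mean", "max_abs_fd_over_slope",
                 "max_abs_sd_over_mean", "max_abs_sd_over_mean_abs_fd"):
        assert f.flags[IDX[name]], name


def test_scale_equivariance():
    """Scaling scores by c scales the level/spread measures by c and leaves
    the ratio measures and R^2 unchanged (unflagged entries)."""
    t = (0.0, 10.0, 25.0, 50.0, 70.0)
    base = compute_measures(make_series("S1", t, (1, 3, 2, 5, 4)))
    double = compute_measures(make_series("S2", t, (2, 6, 4, 10, 8)))
    equivariant = ("range", "mean_over_time", "sd", "change", "mean_change_per_h",
                   "slope", "max_first_diff", "sd_first_diff",
                   "sd_first_diff_per_h", "mean_abs_first_diff",
                   "max_abs_first_diff", "mean_second_diff",
                   "mean_abs_second_diff", "max_abs_second_diff")
    invariant = ("coef_variation", "change_rel_first", "change_rel_mean",
                 "r_squared", "max_abs_fd_over_mean", "max_abs_sd_over_mean",
                 "max_abs_sd_over_mean_abs_fd", "mean_abs_sd_over_mean_abs_fd")
    for name in equivariant:
        assert double.m[IDX[name]] == pytest.approx(2 * base.m[IDX[name]]), name
    for name in invariant:
        if not base.flags[IDX[name]]:
            assert double.m[IDX[name]] == pytest.approx(base.m[IDX[name]]), name


def test_too_few_or_unordered_observations_rejected():
    with pytest.raises(ValueError, match="at least 4"):
        compute_measures(make_series("X", (0.0, 1.0, 2.0), (1, 2, 3)))


def test_feature_matrix_layout(wellsep_cohort):
    series, _, _ = wellsep_cohort
    df = feature_matrix(series[:10])
    assert df.shape == (10, 48)
    assert list(df.columns[:24]) == list(FEATURE_NAMES)
    assert all(c.startswith("flag_") for c in df.columns[24:])
    assert df.index.name == "patient_id"
    assert np.all(np.isfinite(df[list(FEATURE_NAMES)].to_numpy()))


def test_standardize_mean_zero_sd_one():
    rng = np.random.default_rng(0)
    X = rng.normal(2.0, 3.0, size=(100, 5))
    Z, means, sds = standardize(X)
    assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-12)
    assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-12)


def test_standardize_winsorized_keeps_contract():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(400, 3))
    X[0, 0] = 1e6  # a wild outlier
    Z, _, _ = standardize(X, winsor_pct=DEFAULT_WINSOR_PCT)
    assert np.allclose(Z.mean(axis=0), 0.0, atol=1e-10)
    assert np.allclose(Z.std(axis=0, ddof=1), 1.0, atol=1e-10)
    assert abs(Z[0, 0]) < 10  # the outlier no longer dominates its column
    with pytest.raises(ValueError, match="winsor_pct"):
        standardize(X, winsor_pct=60.0)


def test_standardize_drops_zero_variance_columns():
    X = np.column_stack([np.arange(10.0), np.full(10, 7.0)])
    with pytest.warns(UserWarning, match="zero-variance"):
        Z, means, sds, dropped = standardize(X, return_dropped=True)
    assert Z.shape == (10, 1) and list(dropped) == [1]
    with pytest.raises(ValueError, match="zero variance"):
        standardize(np.full((10, 2), 3.0))
    with pytest.raises(ValueError, match="at least 2"):
        standardize(np.ones((1, 3)))
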