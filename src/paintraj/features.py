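"""The 24 per-patient trajectory change measures that feed clustering.

The catalogue describes linear and non-linear change, abrupt short-term
fluctuation, deviation from monotonicity, and early-versus-late change in a
longitudinal series. Measures 11, 12, 14 and 15 use raw successive
differences d_j = y_{j+1} - y_j; measure 13 and the second-difference
measures use divided differences honoring irregular observation spacing
(w_j = d_j / (t_{j+1} - t_j); second differences are divided differences of
the w_j over half the spanning interval). At unit spacing this reduces to
the established equally-spaced catalogue.

Ratio measures with a degenerate denominator (zero mean, zero first score,
zero mean absolute difference) are set to 0 and flagged, so feature vectors
stay finite on flat trajectories. The slope denominator of measures 17-18
is additionally treated as degenerate when the fitted slope is within two
OLS standard errors of zero: the ratio's sign is then sampling noise and
the unguarded value explodes for flat trajectories.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from paintraj.cohort import PainSeries

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "range",                      # 1
    "mean_over_time",             # 2
    "sd",                         # 3
    "coef_variation",             # 4
    "change",                     # 5 last - first
    "mean_change_per_h",          # 6 change / elapsed time
    "change_rel_first",           # 7
    "change_rel_mean",            # 8
    "slope",                      # 9 OLS slope of score on time
    "r_squared",                  # 10
    "max_first_diff",             # 11
    "sd_first_diff",              # 12
    "sd_first_diff_per_h",        # 13 SD of divided differences
    "mean_abs_first_diff",        # 14
    "max_abs_first_diff",         # 15
    "max_abs_fd_over_mean",       # 16 = 15 / 2
    "max_abs_fd_over_slope",      # 17 = 15 / 9
    "sd_fd_over_slope",           # 18 = 12 / 9
    "mean_second_diff",           # 19
    "mean_abs_second_diff",       # 20
    "max_abs_second_diff",        # 21
    "max_abs_sd_over_mean",       # 22 = 21 / 2
    "max_abs_sd_over_mean_abs_fd",  # 23 = 21 / 14
    "mean_abs_sd_over_mean_abs_fd",  # 24 = 20 / 14
)


@dataclass
class TrajectoryFeatures:
    """The 24-measure change-descriptor vector for one patient."""

    patient_id: str
    m: np.ndarray
    flags: np.ndarray  # True where a degenerate denominator was substituted

    def __post_init__(self):
        if self.m.shape != (24,) or self.flags.shape != (24,):
            raise ValueError("expected exactly 24 measures")
        if not np.all(np.isfinite(self.m)):
            raise ValueError("measures must be finite after substitution")


def _safe_ratio(num: float, den: float, idx: int, flags: np.ndarray) -> float:
    if den == 0.0:
        flags[idx] = True
        return 0.0
    return num / den


def compute_measures(series: PainSeries) -> TrajectoryFeatures:
    """Compute the 24 change measures for one pain series.

    Requires at least 4 observations at strictly increasing times (the
    cohort filters guarantee this).
    """
    t = series.times
    y = series.scores
    if len(y) < 4:
        raise ValueError(
            f"patient {series.patient_id}: at least 4 observations required, got {len(y)}")
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"patient {series.patient_id}: times must be strictly increasing")

    m = np.zeros(24)
    flags = np.zeros(24, dtype=bool)

    dt = np.diff(t)
    d = np.diff(y)            # raw successive differences
    w = d / dt                # divided differences (per hour rates)
    # second differences: divided differences of w over half the spanning interval
    mid_dt = (t[2:] - t[:-2]) / 2.0
    sd2 = np.diff(w) / mid_dt

    mean_y = float(np.mean(y))
    sd_y = float(np.std(y, ddof=1))
    change = float(y[-1] - y[0])
    elapsed = float(t[-1] - t[0])

    # OLS slope and R^2 of score on time
    tc = t - t.mean()
    sxx = float(np.sum(tc**2))
    slope = float(np.sum(tc * y) / sxx)
    sst = float(np.sum((y - mean_y) ** 2))
    if sst == 0.0:
        r2 = 0.0
        flags[9] = True
    else:
        r2 = slope**2 * sxx / sst

    m[0] = float(np.max(y) - np.min(y))
    m[1] = mean_y
    m[2] = sd_y
    m[3] = _safe_ratio(sd_y, mean_y, 3, flags)
    m[4] = change
    m[5] = change / elapsed
    m[6] = _safe_ratio(change, float(y[0]), 6, flags)
    m[7] = _safe_ratio(change, mean_y, 7, flags)
    m[8] = slope
    m[9] = r2
    m[10] = float(np.max(d))
    m[11] = float(np.std(d, ddof=1))
    m[12] = float(np.std(w, ddof=1))
    m[13] = float(np.mean(np.abs(d)))
    m[14] = float(np.max(np.abs(d)))
    # The slope-denominator ratios are sign-unstable when the slope is not
    # distinguishable from zero: treat |slope| <= 2 SE(slope) (the usual 5%
    # two-sided cutoff) as degenerate (same substitution as an exact zero).
    rss = sst - slope**2 * sxx
    slope_se = float(np.sqrt(max(rss, 0.0) / (len(y) - 2) / sxx))
    slope_den = slope if abs(slope) > 2.0 * slope_se else 0.0

    m[15] = _safe_ratio(m[14], m[1], 15, flags)
    m[16] = _safe_ratio(m[14], slope_den, 16, flags)
    m[17] = _safe_ratio(m[11], slope_den, 17, flags)
    m[18] = float(np.mean(sd2))
    m[19] = float(np.mean(np.abs(sd2)))
    m[20] = float(np.max(np.abs(sd2)))
    m[21] = _safe_ratio(m[20], m[1], 21, flags)
    m[22] = _safe_ratio(m[20], m[13], 22, flags)
    m[23] = _safe_ratio(m[19], m[13], 23, flags)

    return TrajectoryFeatures(series.patient_id, m, flags)


def feature_matrix(series_collection) -> "pd.DataFrame":
    """One row per patient, 24 named measure columns plus flag columns."""
    import pandas as pd

    rows = []
    for s in series_collection:
        f = compute_measures(s)
        row = {"patient_id": f.patient_id}
        row.update(dict(zip(FEATURE_NAMES, f.m)))
        row.update({f"flag_{n}": bool(v) for n, v in zip(FEATURE_NAMES, f.flags)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


#: Two-sided winsorization percentage applied to raw columns before
#: z-scoring in the clustering pipeline. Ratio measures (e.g.
#: fluctuation-to-slope) are heavy-tailed when the denominator is near
#: zero; a handful of extreme patients would otherwise dominate the
#: column SD, the correlation PCA and k-means distances.
DEFAULT_WINSOR_PCT = 0.5


def standardize(X, return_dropped: bool = False, winsor_pct: float | None = None):
    """Column z-scoring: (x - mean) / SD, dropping zero-variance columns.

    ``X`` is an (n_patients x 24) array or DataFrame with at least 2 rows.
    Returns ``(Z, means, sds)`` restricted to the kept columns (and the
    dropped column indices if requested). All columns zero-variance is an
    error: there is nothing to cluster on. If ``winsor_pct`` is given,
    each column is first winsorized to its [p, 100-p] percentile range
    (see :data:`DEFAULT_WINSOR_PCT`); the z-scoring then applies to the
    winsorized values, so columns still come out with mean 0 and SD 1.
    """
    import pandas as pd

    is_frame = isinstance(X, pd.DataFrame)
    values = X.to_numpy(dtype=float) if is_frame else np.asarray(X, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("standardization needs at least 2 patients")
    if winsor_pct is not None:
        if not (0.0 < winsor_pct < 50.0):
            raise ValueError("winsor_pct must be in (0, 50)")
        lo = np.percentile(values, winsor_pct, axis=0)
        hi = np.percentile(values, 100.0 - winsor_pct, axis=0)
        values = np.clip(values, lo, hi)
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=1)
    keep = sds > 0
    if not np.any(keep):
        raise ValueError("all feature columns have zero variance")
    if not np.all(keep):
        dropped = np.where(~keep)[0]
        names = list(X.columns[dropped]) if is_frame else list(dropped)
        warnings.warn(f"dropping zero-variance feature columns: {names}")
    Z = (values[:, keep] - means[keep]) / sds[keep]
    if is_frame:
        Z = pd.DataFrame(Z, index=X.index, columns=X.columns[keep])
    if return_dropped:
        return Z, means[keep], sds[keep], np.where(~keep)[0]
    return Z, means[keep], sds[keep]
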