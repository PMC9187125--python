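"""Normalized AUC profiles of fitted pain curves and empirical mean trajectories.

Subject-level areas under the fitted intensity and probability-of-pain
curves are computed by the trapezoid rule on an hourly grid and normalized
by the theoretical maximum over the 96-hour window (a sustained score of 10
for intensity, a sustained probability of 1 for the probability curve), so
values are comparable across cohorts and lie in [0, 1]. Normalized AUCs are
averaged by cluster over 8-hour intervals (a 6-hour variant is also
emitted), with interval contributions summing exactly to the full-window
normalized AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from paintraj.zicmp import ZicmpFit, predict_decomposition, predict_subject_curves

NRS_MAX = 10.0


@dataclass
class AucProfile:
    """Per-cluster normalized interval AUCs for intensity and probability curves."""

    cluster: int
    interval_edges: np.ndarray
    intensity: np.ndarray     # normalized AUC contribution per interval
    probability: np.ndarray
    cumulative_intensity: float = field(init=False)
    cumulative_probability: float = field(init=False)

    def __post_init__(self):
        for arr in (self.intensity, self.probability):
            if np.any(arr < -1e-12) or np.any(arr > 1.0 + 1e-12):
                raise ValueError("normalized AUC values must lie in [0, 1]")
        self.cumulative_intensity = float(np.sum(self.intensity))
        self.cumulative_probability = float(np.sum(self.probability))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cluster": self.cluster,
            "interval_start_h": self.interval_edges[:-1],
            "interval_end_h": self.interval_edges[1:],
            "intensity_auc": self.intensity,
            "probability_auc": self.probability,
        })


def trapezoid_auc(times, values, t0: float, t1: float) -> float:
    """Trapezoidal integral of a piecewise-linear curve over [t0, t1].

    Endpoints inside the curve span are interpolated linearly.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if t0 < times[0] - 1e-12 or t1 > times[-1] + 1e-12 or t0 > t1:
        raise ValueError(f"[{t0}, {t1}] not within the curve span")
    inner = times[(times > t0) & (times < t1)]
    grid = np.concatenate(([t0], inner, [t1]))
    vals = np.interp(grid, times, values)
    return float(np.trapezoid(vals, grid))


def normalize_auc(auc: float, kind: str, window_h: float = 96.0) -> float:
    """Divide an AUC by its theoretical maximum over the window.

    ``kind='intensity'``: maximum is a sustained NRS of 10 (divisor
    10 * window); ``kind='probability'``: a sustained probability of 1
    (divisor window).
    """
    if auc < 0:
        raise ValueError("auc must be non-negative")
    if kind == "intensity":
        return auc / (NRS_MAX * window_h)
    if kind == "probability":
        return auc / window_h
    raise ValueError(f"unknown kind {kind!r}")


def _interval_profile(grid, curve, edges, kind, window_h) -> np.ndarray:
    return np.array([
        normalize_auc(trapezoid_auc(grid, curve, a, b), kind, window_h)
        for a, b in zip(edges[:-1], edges[1:])
    ])


def cluster_auc_profiles(fits: dict, interval_h: float = 8.0,
                         subject_level: bool = True, grid_step_h: float = 1.0,
                         force: bool = False) -> dict:
    """Normalized interval-AUC profiles per cluster.

    ``fits`` maps cluster label -> converged ZicmpFit. With
    ``subject_level=True`` each patient's curve is evaluated at their
    estimated random-intercept mode, the per-subject normalized interval
    AUCs are computed, and the cluster profile is their average; otherwise
    the population (fixed-effects) curve is profiled directly.
    """
    out = {}
    for cluster, fit in fits.items():
        if not fit.converged and not force:
            raise RuntimeError(f"cluster {cluster}: unconverged fit (pass force=True)")
        window = fit.spec.window_h
        edges = np.arange(0.0, window + 1e-9, interval_h)
        if not np.isclose(edges[-1], window):
            edges = np.append(edges, window)
        grid = np.arange(0.0, window + 1e-9, grid_step_h)
        if subject_level and fit.b_modes is not None:
            grid, p_mat, m_mat = predict_subject_curves(fit, grid)
            inten = np.mean([
                _interval_profile(grid, np.minimum(row, NRS_MAX), edges, "intensity", window)
                for row in m_mat], axis=0)
            prob = np.mean([
                _interval_profile(grid, row, edges, "probability", window)
                for row in p_mat], axis=0)
        else:
            dec = predict_decomposition(fit, grid, force=force)
            inten = _interval_profile(grid, np.minimum(dec["mean_pain"].to_numpy(), NRS_MAX),
                                      edges, "intensity", window)
            prob = _interval_profile(grid, dec["p_pain"].to_numpy(), edges,
                                     "probability", window)
        out[cluster] = AucProfile(cluster=cluster, interval_edges=edges,
                                  intensity=inten, probability=prob)
    return out


def profiles_to_frame(profiles: dict) -> pd.DataFrame:
    """Long plot-ready table of interval AUC profiles across clusters."""
    return pd.concat([p.to_frame() for p in profiles.values()], ignore_index=True)


def moving_average(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average for display smoothing only (NaN-aware)."""
    values = np.asarray(values, dtype=float)
    half = window // 2
    out = np.full_like(values, np.nan)
    for i in range(len(values)):
        seg = values[max(0, i - half): i + half + 1]
        if np.any(np.isfinite(seg)):
            out[i] = np.nanmean(seg)
    return out


def empirical_mean_trajectory(series_collection, assignment, bin_h: float = 1.0,
                              smooth_window: int = 5) -> pd.DataFrame:
    """Hourly-bin mean observed pain per cluster, with a display smoother.

    ``assignment`` maps patient_id -> cluster label (a dict or a
    ClusterAssignment). Bins are [i*bin_h, (i+1)*bin_h); the ``smoothed``
    column is a centered moving average for plotting only — no analysis
    depends on it.
    """
    labels = assignment.labels if hasattr(assignment, "labels") else dict(assignment)
    rows = []
    for s in series_collection:
        lab = labels.get(s.patient_id)
        if lab is None:
            continue
        for o in s.observations:
            rows.append((lab, int(o.time_h // bin_h), o.score))
    if not rows:
        raise ValueError("no observations matched the assignment")
    df = pd.DataFrame(rows, columns=["cluster", "bin", "score"])
    agg = (df.groupby(["cluster", "bin"])["score"]
             .agg(["mean", "count"]).reset_index()
             .rename(columns={"mean": "mean_score", "count": "n_obs"}))
    agg["time_h"] = agg["bin"] * bin_h + bin_h / 2.0
    parts = []
    for lab, grp in agg.groupby("cluster"):
        grp = grp.sort_values("bin").copy()
        grp["smoothed"] = moving_average(grp["mean_score"].to_numpy(), smooth_window)
        parts.append(grp)
    return pd.concat(parts, ignore_index=True)[
        ["cluster", "bin", "time_h", "mean_score", "n_obs", "smoothed"]]
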