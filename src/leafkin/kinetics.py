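"""Metric series -> presented kinetics.

Four transforms, applied in this order in the standard pipeline:

1. ``relative_series`` — subtract, per metric, the mean of the first five
   valid frames, so every plant starts at zero and treatment effects read
   as relative change.
2. ``sync_by_transition`` — time-sync replicate plants on the first
   day->night transition visible in their frames, shifting whole series
   (no resampling) onto a common zeitgeber axis.
3. ``angular_speed`` — backward difference over a 60-min window, in
   degrees/hour.
4. ``bin_series`` — per-plant means in left-closed 2-h zeitgeber bins, the
   unit of downstream statistical testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from leafkin.geometry import METRIC_COLUMNS

DEFAULT_N_BASELINE = 5
DEFAULT_LIGHTS_OFF_ZT_H = 9.0
DEFAULT_MAX_SHIFT_MIN = 30.0
DEFAULT_BIN_H = 2.0
DEFAULT_MIN_POINTS = 10

LONG_COLUMNS = ["plant_id", "treatment", "zt_h", "metric", "value"]
BINNED_COLUMNS = ["plant_id", "treatment", "bin_start_zt_h", "metric", "mean", "n"]


def relative_series(metrics: pd.DataFrame, n_baseline: int = DEFAULT_N_BASELINE,
                    columns: list[str] | None = None) -> pd.DataFrame:
    """Baseline-subtracted copy: each metric minus the mean of its first
    ``n_baseline`` valid (non-missing) values.  Missing values stay missing."""
    columns = columns if columns is not None else [c for c in METRIC_COLUMNS
                                                  if c in metrics.columns]
    out = metrics.copy()
    for col in columns:
        vals = metrics[col].to_numpy(float)
        valid = np.flatnonzero(~np.isnan(vals))
        if len(valid) < n_baseline:
            raise ValueError(
                f"metric {col!r} has {len(valid)} valid frames; "
                f"need >= {n_baseline} for the baseline"
            )
        out[col] = vals - vals[valid[:n_baseline]].mean()
    return out


def find_day_night_transition(illumination: pd.Series | np.ndarray) -> int:
    """Index of the first frame labelled night that follows a day frame."""
    lab = np.asarray(illumination)
    is_day = lab == "day"
    for i in range(1, len(lab)):
        if is_day[i - 1] and not is_day[i]:
            return i
    raise ValueError("no day->night transition in sequence")


def sync_by_transition(series: dict[str, pd.DataFrame],
                       lights_off_zt_h: float = DEFAULT_LIGHTS_OFF_ZT_H,
                       max_shift_min: float = DEFAULT_MAX_SHIFT_MIN,
                       ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Align replicate plants on their first day->night transition.

    Each plant's frame at the transition is assigned zt = lights_off; the
    whole series is shifted (pure time translation — within-plant sample
    spacing is untouched).  Requires each series to carry ``illumination``
    and ``t_min``; a ``zt_h`` column, if present, is replaced by the
    aligned axis.  Returns (aligned series, shift report); plants whose
    shift relative to their nominal zt axis exceeds ``max_shift_min`` are
    flagged in the report.
    """
    aligned: dict[str, pd.DataFrame] = {}
    report_rows = []
    for pid, df in series.items():
        try:
            k = find_day_night_transition(df["illumination"])
        except ValueError as e:
            raise ValueError(f"plant {pid!r}: {e}") from e
        t = df["t_min"].to_numpy(float)
        zt_aligned = lights_off_zt_h + (t - t[k]) / 60.0
        if "zt_h" in df.columns and df["zt_h"].notna().all():
            shift_min = float((zt_aligned[0] - float(df["zt_h"].iloc[0])) * 60.0)
        else:
            shift_min = 0.0
        out = df.copy()
        out["zt_h"] = zt_aligned
        aligned[pid] = out
        report_rows.append({
            "plant_id": pid,
            "transition_frame": k,
            "shift_min": shift_min,
            "flagged": abs(shift_min) > max_shift_min,
        })
    return aligned, pd.DataFrame(report_rows)


def angular_speed(series: pd.DataFrame, metric: str, window_min: float = 60.0,
                  method: str = "difference") -> pd.Series:
    """Speed of a metric over a trailing window, in units/hour (degrees/hour
    for angles).

    ``difference`` (default): speed(t) = (v(t) - v(t - window)) / window.
    ``slope``: least-squares slope over the right-open window (t-window, t].
    The first ``window_min`` of the series is undefined (NaN).
    """
    if metric not in series.columns:
        raise KeyError(f"unknown metric {metric!r}; have {list(series.columns)}")
    t = series["t_min"].to_numpy(float)
    v = series[metric].to_numpy(float)
    dt = np.diff(t)
    if len(dt) == 0 or window_min < 2 * dt.min():
        raise ValueError("window must span at least two frame intervals")
    n = len(t)
    out = np.full(n, np.nan)
    if method == "difference":
        # match t - window to an actual sample (tolerates tiny float error)
        for i in range(n):
            target = t[i] - window_min
            j = int(np.searchsorted(t, target - 1e-9))
            if j < n and abs(t[j] - target) < 1e-6:
                out[i] = (v[i] - v[j]) / window_min * 60.0
    elif method == "slope":
        for i in range(n):
            mask = (t > t[i] - window_min - 1e-9) & (t <= t[i] + 1e-9)
            if t[i] - window_min < t[0] - 1e-9:
                continue
            tt, vv = t[mask], v[mask]
            ok = ~np.isnan(vv)
            if ok.sum() >= 2:
                out[i] = np.polyfit(tt[ok], vv[ok], 1)[0] * 60.0
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.Series(out, index=series.index, name=f"{metric}_speed_per_h")


def to_long(metrics: pd.DataFrame, plant_id: str, treatment: str,
            columns: list[str] | None = None) -> pd.DataFrame:
    """Wide per-frame metrics -> long format (plant_id, treatment, zt_h,
    metric, value), the interchange for binning and statistics."""
    columns = columns if columns is not None else [c for c in METRIC_COLUMNS
                                                   if c in metrics.columns]
    long = metrics.melt(id_vars=["zt_h"], value_vars=columns,
                        var_name="metric", value_name="value")
    long.insert(0, "plant_id", plant_id)
    long.insert(1, "treatment", treatment)
    return long[LONG_COLUMNS]


def bin_series(long: pd.DataFrame, bin_h: float = DEFAULT_BIN_H,
               min_points: int = DEFAULT_MIN_POINTS) -> pd.DataFrame:
    """Per-plant per-metric means in left-closed zeitgeber bins
    [k*bin_h, (k+1)*bin_h).  Bin edges are anchored at zt = 0.  Bins with
    fewer than ``min_points`` valid frames are marked unreliable."""
    if len(long) == 0:
        raise ValueError("empty input")
    df = long.copy()
    df["bin_start_zt_h"] = np.floor(df["zt_h"].to_numpy(float) / bin_h) * bin_h
    grouped = (
        df.dropna(subset=["value"])
        .groupby(["plant_id", "treatment", "bin_start_zt_h", "metric"], as_index=False)
        .agg(mean=("value", "mean"), n=("value", "size"))
    )
    grouped["reliable"] = grouped["n"] >= min_points
    return grouped[BINNED_COLUMNS + ["reliable"]]
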