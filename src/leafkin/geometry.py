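"""Pixel trajectories -> leaf metrics in degrees and millimetres.

All angles are measured from horizontal, positive upward (hyponasty reads
as an increasing angle).  Image coordinates have y pointing down, so the
conversion flips the y-difference once, here, and nowhere else:

    angle(origin -> end) = atan2(origin_y - end_y, end_x - origin_x)

Per frame: petiole angle/length from (center, junction), lamina from
(junction, tip), whole leaf from (center, tip).  Derived quantities:
junction angle = lamina - petiole (signed; a downward-kinked lamina is
negative), tip height = vertical tip position above the rosette center,
projected lamina length = horizontal junction->tip extent (x only).
Frames flagged as lost propagate as missing values — interpolation policy
belongs downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

METRIC_COLUMNS = [
    "petiole_angle_deg", "lamina_angle_deg", "leaf_angle_deg", "junction_angle_deg",
    "petiole_len_mm", "lamina_len_mm", "leaf_len_mm", "tip_height_mm",
    "projected_lamina_mm",
]

METRICS_CSV_COLUMNS = ["frame", "t_min", "zt_h", "illumination"] + METRIC_COLUMNS


@dataclass(frozen=True)
class ScaleCalibration:
    mm_per_px: float

    def __post_init__(self) -> None:
        if not (self.mm_per_px > 0 and np.isfinite(self.mm_per_px)):
            raise ValueError(f"mm_per_px must be positive and finite, got {self.mm_per_px}")


def calibrate(p1: tuple[float, float], p2: tuple[float, float], known_mm: float
              ) -> ScaleCalibration:
    """mm-per-pixel from a segment of known physical length."""
    if known_mm <= 0:
        raise ValueError("known_mm must be > 0")
    d = float(np.hypot(p2[0] - p1[0], p2[1] - p1[1]))
    if d == 0.0:
        raise ValueError("calibration points coincide")
    return ScaleCalibration(known_mm / d)


def segment_angle(origin: tuple[float, float], end: tuple[float, float]) -> float:
    """Angle of origin->end in degrees above horizontal, range (-180, 180]."""
    dx = end[0] - origin[0]
    dy = origin[1] - end[1]  # image y points down
    if dx == 0.0 and dy == 0.0:
        raise ValueError("segment endpoints coincide")
    return float(np.degrees(np.arctan2(dy, dx)))


def compute_metrics(track: pd.DataFrame, cal: ScaleCalibration,
                    start_zt_h: float | None = None) -> pd.DataFrame:
    """Per-frame leaf metrics from a trajectory table.

    ``track`` is the canonical trajectory table (frame, t_min, illumination,
    cx..ty, confidences, optional lost flags).  Rows flagged lost become
    missing values for every metric.  ``start_zt_h`` anchors the zeitgeber
    axis (zt_h = start + t_min/60); NaN if not given.
    """
    n = len(track)
    if n == 0:
        raise ValueError("empty trajectory table")
    cx = track["cx"].to_numpy(float)
    cy = track["cy"].to_numpy(float)
    jx = track["jx"].to_numpy(float)
    jy = track["jy"].to_numpy(float)
    tx = track["tx"].to_numpy(float)
    ty = track["ty"].to_numpy(float)

    lost = np.zeros(n, dtype=bool)
    for col in ("lost_j", "lost_t"):
        if col in track.columns:
            lost |= track[col].to_numpy(bool)
    if lost.all():
        raise ValueError("all frames flagged lost; nothing to measure")

    s = cal.mm_per_px
    ang_p = np.degrees(np.arctan2(cy - jy, jx - cx))
    ang_l = np.degrees(np.arctan2(jy - ty, tx - jx))
    ang_leaf = np.degrees(np.arctan2(cy - ty, tx - cx))
    len_p = np.hypot(jx - cx, jy - cy) * s
    len_l = np.hypot(tx - jx, ty - jy) * s
    len_leaf = np.hypot(tx - cx, ty - cy) * s

    out = pd.DataFrame({
        "frame": track["frame"].to_numpy(),
        "t_min": track["t_min"].to_numpy(float),
        "zt_h": (start_zt_h + track["t_min"].to_numpy(float) / 60.0
                 if start_zt_h is not None else np.nan),
        "illumination": track["illumination"].to_numpy(),
        "petiole_angle_deg": ang_p,
        "lamina_angle_deg": ang_l,
        "leaf_angle_deg": ang_leaf,
        "junction_angle_deg": ang_l - ang_p,
        "petiole_len_mm": len_p,
        "lamina_len_mm": len_l,
        "leaf_len_mm": len_leaf,
        "tip_height_mm": (cy - ty) * s,
        "projected_lamina_mm": np.abs(tx - jx) * s,
    })
    out.loc[lost, METRIC_COLUMNS] = np.nan
    return out
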