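"""Appearance-based landmark tracking through a time-lapse sequence.

Each landmark (petiole–lamina junction, leaf tip) is followed with an
adaptive-template localizer: a 40 x 60 px template around the annotated
point is matched by zero-normalised cross-correlation (ZNCC) within a
search window around the previous estimate; the response peak is refined
to sub-pixel precision with a separable quadratic fit, and the template is
blended towards the new appearance with a small learning rate so it adapts
to slow shape change (growth, rotation) and to the day->night illumination
switch.  ZNCC is invariant to affine intensity changes, which is what makes
the switch survivable on a well-chosen channel.

The rosette center is not tracked: it is annotated on the first and last
frame and linearly interpolated in frame index between the two.

On day frames the tracker operates on the single colour channel with the
greatest contrast inside the initial box (chosen once at init); night
frames are channel-identical so the same index applies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from leafkin.frameio import Annotation, FrameSequence, TRACK_TABLE_COLUMNS, classify_illumination

logger = logging.getLogger(__name__)

DEFAULT_BOX = (40, 60)  # (w, h) pixels


@dataclass
class TrackConfig:
    box_w: int = 40
    box_h: int = 60
    search_radius: int = 20
    learning_rate: float = 0.05
    anchor_weight: float = 0.15
    reanchor_interval: int = 240  # frames between anchor refreshes (0 = frozen anchor)
    min_confidence: float = 0.2
    max_jump_px: float = 15.0
    max_lost_fraction: float = 0.1
    gray_tol: float = 8.0


@dataclass
class TrackerState:
    """Current estimate + appearance model for one landmark."""

    point: tuple[float, float]
    template: np.ndarray          # adaptive appearance model, float64 (box_h, box_w)
    template0: np.ndarray         # frozen first-frame template (drift anchor)
    box: tuple[int, int]          # (w, h)
    frac: tuple[float, float] = (0.0, 0.0)  # sub-pixel offset of the landmark
                                            # relative to the template's integer center
    confidence: float = 1.0
    channel: int = 0
    age: int = 0                  # successful updates since init


def _clamped_patch(img: np.ndarray, cx: float, cy: float, w: int, h: int
                   ) -> tuple[np.ndarray, int, int]:
    """Extract a (h, w) patch centred as close to (cx, cy) as the image
    bounds allow; returns (patch, x0, y0) of its top-left corner."""
    H, W = img.shape
    if w > W or h > H:
        raise ValueError(f"box {w}x{h} larger than {W}x{H} image")
    x0 = int(round(cx)) - w // 2
    y0 = int(round(cy)) - h // 2
    x0 = min(max(x0, 0), W - w)
    y0 = min(max(y0, 0), H - h)
    return img[y0:y0 + h, x0:x0 + w].astype(np.float64), x0, y0


def _subpixel_patch(img: np.ndarray, cx: float, cy: float, w: int, h: int
                    ) -> tuple[np.ndarray, float, float]:
    """Bilinearly sampled (h, w) patch whose pixel (h//2, w//2) sits exactly
    at (cx, cy) — so the landmark is always at the template's center pixel,
    keeping the appearance model aligned across sub-pixel motion.

    The center is clamped so every sample stays inside the image; returns
    (patch, frac_x, frac_y) where frac is the (edge-case) residual offset of
    the true point from the clamped center.
    """
    import scipy.ndimage

    H, W = img.shape
    if w > W or h > H:
        raise ValueError(f"box {w}x{h} larger than {W}x{H} image")
    cxc = float(np.clip(cx, w // 2, W - w + w // 2))
    cyc = float(np.clip(cy, h // 2, H - h + h // 2))
    ys = cyc + (np.arange(h) - h // 2)
    xs = cxc + (np.arange(w) - w // 2)
    grid = np.meshgrid(ys, xs, indexing="ij")
    patch = scipy.ndimage.map_coordinates(img.astype(np.float64), grid, order=1,
                                          mode="nearest")
    return patch, float(cx - cxc), float(cy - cyc)


def select_channel(frame: np.ndarray, point: tuple[float, float],
                   box: tuple[int, int] = DEFAULT_BOX) -> int:
    """Channel with the greatest intensity spread inside the box — the one
    where plant and background separate best."""
    w, h = box
    stds = []
    for c in range(frame.shape[2]):
        patch, _, _ = _clamped_patch(frame[:, :, c], point[0], point[1], w, h)
        stds.append(patch.std())
    return int(np.argmax(stds))


def init_tracker(frame: np.ndarray, point: tuple[float, float],
                 box: tuple[int, int] = DEFAULT_BOX,
                 channel: int | None = None) -> TrackerState:
    """Initialise a tracker at an annotated point.

    ``frame`` may be RGB (channel selected by contrast if not given) or a
    single-channel image.  The state's point equals the given point exactly;
    the template box is clamped inside the image when the point is near an
    edge.
    """
    x, y = point
    if frame.ndim == 3:
        H, W = frame.shape[:2]
        if not (0 <= x < W and 0 <= y < H):
            raise ValueError(f"init point ({x}, {y}) outside {W}x{H} image")
        if channel is None:
            channel = select_channel(frame, point, box)
        img = frame[:, :, channel]
    else:
        H, W = frame.shape
        if not (0 <= x < W and 0 <= y < H):
            raise ValueError(f"init point ({x}, {y}) outside {W}x{H} image")
        channel = 0 if channel is None else channel
        img = frame
    w, h = box
    template, fx, fy = _subpixel_patch(img, x, y, w, h)
    # frac is non-zero only when the box had to be clamped at an image edge
    return TrackerState(point=(float(x), float(y)), template=template,
                        template0=template.copy(), box=(w, h), frac=(fx, fy),
                        confidence=1.0, channel=channel)


def zncc_response(search: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Zero-normalised cross-correlation of ``template`` at every placement
    inside ``search``; values in [-1, 1].  Vectorised sliding-window
    computation (no FFT: windows here are small)."""
    h, w = template.shape
    windows = np.lib.stride_tricks.sliding_window_view(search, (h, w))
    n = h * w
    t = template - template.mean()
    t_norm = np.sqrt((t * t).sum())
    wsum = windows.sum(axis=(2, 3))
    wsq = (windows.astype(np.float64) ** 2).sum(axis=(2, 3))
    cross = np.einsum("ijkl,kl->ij", windows, t, optimize=True)
    var = wsq - wsum * wsum / n
    denom = np.sqrt(np.maximum(var, 0.0)) * t_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 1e-12, cross / denom, 0.0)
    return r


def _quadratic_offset(rm1: float, r0: float, rp1: float) -> float:
    denom = rm1 - 2.0 * r0 + rp1
    if denom >= -1e-12:  # not a proper maximum
        return 0.0
    off = 0.5 * (rm1 - rp1) / denom
    return float(np.clip(off, -0.5, 0.5))


def track_next(state: TrackerState, frame: np.ndarray,
               cfg: TrackConfig | None = None) -> tuple[TrackerState, tuple[float, float], float]:
    """Locate the landmark in the next frame.

    Returns (state, point, confidence).  Confidence is the normalised peak
    response clipped to [0, 1].  If it falls below ``min_confidence`` the
    point is held at the last good estimate and the appearance model is
    frozen (the caller flags the row as lost); otherwise the template is
    blended towards the new appearance with the learning rate.
    """
    cfg = cfg or TrackConfig()
    if frame.ndim == 3:
        img = frame[:, :, state.channel]
    else:
        img = frame
    H, W = img.shape
    w, h = state.box
    px, py = state.point
    r = cfg.search_radius

    # search region: previous point +/- radius, plus template half-extent
    x0 = max(int(round(px)) - w // 2 - r, 0)
    y0 = max(int(round(py)) - h // 2 - r, 0)
    x1 = min(int(round(px)) - w // 2 + r + w, W)
    y1 = min(int(round(py)) - h // 2 + r + h, H)
    search = img[y0:y1, x0:x1].astype(np.float64)
    if search.shape[0] < h or search.shape[1] < w:
        return state, state.point, 0.0

    # anchored response: adaptive template follows slow appearance change,
    # the frozen first-frame template pins the estimate against drift
    aw = cfg.anchor_weight
    resp = (1.0 - aw) * zncc_response(search, state.template)
    if aw > 0.0:
        resp += aw * zncc_response(search, state.template0)
    iy, ix = np.unravel_index(int(np.argmax(resp)), resp.shape)
    peak = float(resp[iy, ix])
    conf = float(np.clip(peak, 0.0, 1.0))

    # sub-pixel refinement: separable quadratic fit around the peak
    dx = dy = 0.0
    if 0 < ix < resp.shape[1] - 1:
        dx = _quadratic_offset(resp[iy, ix - 1], peak, resp[iy, ix + 1])
    if 0 < iy < resp.shape[0] - 1:
        dy = _quadratic_offset(resp[iy - 1, ix], peak, resp[iy + 1, ix])

    new_x = x0 + ix + w // 2 + dx + state.frac[0]
    new_y = y0 + iy + h // 2 + dy + state.frac[1]

    if conf < cfg.min_confidence:
        # lost: hold position, freeze the appearance model
        return TrackerState(state.point, state.template, state.template0, state.box,
                            state.frac, conf, state.channel, state.age), state.point, conf

    patch, _, _ = _subpixel_patch(img, new_x, new_y, w, h)
    lr = cfg.learning_rate
    template = (1.0 - lr) * state.template + lr * patch
    age = state.age + 1
    # periodic re-anchoring: a fixed anchor pins against drift but goes
    # stale as the leaf rotates and grows; refreshing it from the adaptive
    # model keeps the rotation mismatch (and its localisation bias) small
    if cfg.reanchor_interval > 0 and age % cfg.reanchor_interval == 0:
        template0 = template.copy()
    else:
        template0 = state.template0
    new_state = TrackerState((float(new_x), float(new_y)), template, template0,
                             state.box, state.frac, conf, state.channel, age)
    return new_state, (float(new_x), float(new_y)), conf


def interpolate_center(ann: Annotation, n_frames: int) -> np.ndarray:
    """Rosette center per frame: linear interpolation in frame index between
    the first- and last-frame annotations.  Shape (n_frames, 2)."""
    c0 = np.asarray(ann.center_first, dtype=float)
    c1 = np.asarray(ann.center_last, dtype=float)
    frac = np.arange(n_frames, dtype=float) / max(n_frames - 1, 1)
    return c0[None, :] + frac[:, None] * (c1 - c0)[None, :]


def track_sequence(seq: FrameSequence, ann: Annotation,
                   cfg: TrackConfig | None = None) -> pd.DataFrame:
    """Track junction and tip through the whole sequence.

    Returns the trajectory table: one row per frame with interpolated
    center, tracked junction/tip (sub-pixel), per-landmark confidence,
    illumination label, and boolean lost flags.  Errors if more than
    ``max_lost_fraction`` of frames are flagged for either landmark.
    """
    cfg = cfg or TrackConfig()
    n = len(seq)
    first = seq.frame(0)
    H, W = first.shape[:2]
    ann.validate_bounds(W, H)
    box = (cfg.box_w, cfg.box_h)

    st_j = init_tracker(first, ann.junction_first, box)
    st_t = init_tracker(first, ann.tip_first, box)
    centers = interpolate_center(ann, n)

    rows = []
    prev = {"j": ann.junction_first, "t": ann.tip_first}
    lost_counts = {"j": 0, "t": 0}
    for i in range(n):
        frame = seq.frame(i)
        illum = classify_illumination(frame, cfg.gray_tol)
        if i == 0:
            pts = {"j": ann.junction_first, "t": ann.tip_first}
            confs = {"j": 1.0, "t": 1.0}
            lost = {"j": False, "t": False}
        else:
            st_j, pj, cj = track_next(st_j, frame, cfg)
            st_t, pt, ct = track_next(st_t, frame, cfg)
            pts = {"j": pj, "t": pt}
            confs = {"j": cj, "t": ct}
            lost = {}
            for key in ("j", "t"):
                jump = float(np.hypot(pts[key][0] - prev[key][0], pts[key][1] - prev[key][1]))
                lost[key] = confs[key] < cfg.min_confidence or jump > cfg.max_jump_px
                if lost[key]:
                    lost_counts[key] += 1
        prev = pts
        rows.append({
            "frame": i,
            "t_min": seq.t_min[i],
            "illumination": illum,
            "cx": centers[i, 0], "cy": centers[i, 1],
            "jx": pts["j"][0], "jy": pts["j"][1],
            "tx": pts["t"][0], "ty": pts["t"][1],
            "confidence_j": confs["j"], "confidence_t": confs["t"],
            "lost_j": lost["j"], "lost_t": lost["t"],
        })

    table = pd.DataFrame(rows, columns=TRACK_TABLE_COLUMNS + ["lost_j", "lost_t"])
    for key, label in (("j", "junction"), ("t", "tip")):
        frac = lost_counts[key] / n
        if frac > cfg.max_lost_fraction:
            raise RuntimeError(
                f"{label} lost on {frac:.0%} of frames for plant {ann.plant_id!r} "
                f"(> {cfg.max_lost_fraction:.0%}); re-annotate and re-run"
            )
        if lost_counts[key]:
            logger.warning("plant %s: %d %s frame(s) flagged lost",
                           ann.plant_id, lost_counts[key], label)
    return table
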