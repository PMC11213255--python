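"""Synthetic leaf time-lapse generator with exact ground truth.

Emulates the imaging regime of a low-cost side-view phenotyping rig:
1 frame/min, short-day photoperiod (9 h light / 15 h dark), plant rendered
green on a uniform blue background by day and as a bright shape on a dark
background by night (near-infrared imaging makes all channels identical).

The leaf is two rigid segments: a petiole from the rosette center to the
petiole–lamina junction, and a lamina (drawn as an ellipse) from the
junction to the leaf tip.  Its pose over time follows a minimal kinematic
model — diurnal sinusoid + logistic treatment ramp + night-gated
oscillation for the angles, linear elongation for the lengths:

    theta_p(t) = theta0 + A_d * sin(2*pi*zt/24)
                 + dose * H * sigma(m)                # treatment ramp
                 + dose * A_osc * sin(...) * gate(t)  # night oscillation

where sigma(m) = 1/(1 + exp(-k*(m - m_onset))) is a logistic in minutes
since treatment start, and gate(t) is a smooth sin^2 envelope spanning each
night (zero at both dusk and dawn, so landmark motion stays continuous).
The lamina angle responds with a configurable fraction of the petiole's
treatment terms; lamina length grows at the untreated rate regardless of
dose (far-red enrichment elongates the petiole, not the lamina).

Ground truth is kept at sub-pixel precision; rounding happens only at
rasterisation, so tests can separate tracker error from quantisation.
"""

from __future__ import annotations

import dataclasses
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image, ImageDraw

TREATMENTS = ("WL", "FRw", "FRt")

# Rendering palette, chosen so the green channel carries the strongest
# plant/background contrast by day with the same polarity (bright plant on
# dark background) as the night frames — an appearance-based tracker can
# then survive the day->night switch on a single channel.
DAY_BACKGROUND = (40, 60, 150)
DAY_PLANT = (30, 200, 40)
NIGHT_BACKGROUND = 18
NIGHT_PLANT = 210
SCALE_BAR_DAY = (235, 235, 235)
SCALE_BAR_NIGHT = 160
_SS = 4  # supersampling factor for anti-aliased rasterisation

GROUND_TRUTH_COLUMNS = [
    "frame", "t_min", "zt_h", "illumination", "cx", "cy", "jx", "jy", "tx", "ty",
    "petiole_angle_deg", "lamina_angle_deg", "petiole_len_mm", "lamina_len_mm",
]

FRAME_PATTERN = "frame_{index:06d}_{t_min:g}.png"


@dataclass
class SimScenario:
    """Parameters of one synthetic experiment.

    Times are minutes unless suffixed otherwise; angles degrees above
    horizontal (positive = upward); zeitgeber time (zt) in hours since
    lights-on.  Defaults describe a 24-h short-day run started at ZT 2
    (treatment onset) on a plant whose focal petiole is 5 mm — the middle
    of the 4.5–5.5 mm selection window used when picking leaves to image.
    """

    duration_min: float = 1440.0
    frame_interval_min: float = 1.0
    lights_on_zt_h: float = 0.0
    lights_off_zt_h: float = 9.0
    start_zt_h: float = 2.0
    treatment_start_zt_h: float = 2.0
    treatment: str = "WL"
    dose: float = 0.0                    # R:FR-derived dose in [0, 1]; 0 for WL
    petiole_len0_mm: float = 5.0
    lamina_len0_mm: float = 8.0
    angle0_petiole_deg: float = 25.0
    angle0_lamina_deg: float = 10.0
    diurnal_amp_deg: float = 4.0
    hyponasty_amp_deg: float = 15.0
    hyponasty_onset_min: float = 180.0   # minutes after treatment start
    hyponasty_rate_per_min: float = 0.04
    osc_amp_deg: float = 2.0
    osc_period_min: float = 90.0
    lamina_response_frac: float = 0.6
    elong_rate_mm_per_h: float = 0.05
    elong_fr_multiplier: float = 2.0
    mm_per_px: float = 0.05
    image_w_px: int = 640
    image_h_px: int = 480
    center_x_px: float = 150.0
    center_y_px: float = 360.0
    center_drift_x_px: float = 0.0       # total linear drift over the sequence
    center_drift_y_px: float = 0.0
    noise_sd: float = 3.0                # gray levels, luminance noise
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("duration_min must be > 0")
        if self.frame_interval_min <= 0:
            raise ValueError("frame_interval_min must be > 0")
        if self.mm_per_px <= 0:
            raise ValueError("mm_per_px must be > 0")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if not 0.0 <= self.dose <= 1.0:
            raise ValueError("dose must be in [0, 1]")
        if self.treatment == "WL" and self.dose != 0.0:
            raise ValueError("dose must be 0 when treatment is WL")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_min / self.frame_interval_min))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimScenario":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**d)


def load_scenario(path: str | Path) -> SimScenario:
    with open(path) as fh:
        return SimScenario.from_dict(yaml.safe_load(fh) or {})


def save_scenario(scenario: SimScenario, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)


def _is_day(zt_h: np.ndarray, on: float, off: float) -> np.ndarray:
    ztm = np.mod(zt_h, 24.0)
    return (ztm >= on) & (ztm < off)


def _night_envelope(t_min: np.ndarray, scenario: SimScenario) -> np.ndarray:
    """Smooth sin^2 gate spanning each night, starting from the first
    lights-off after sequence start.  Zero at dusk and dawn keeps the
    oscillation term continuous, so inter-frame motion stays bounded."""
    zt = scenario.start_zt_h + t_min / 60.0
    on, off = scenario.lights_on_zt_h, scenario.lights_off_zt_h
    night_len_h = 24.0 - (off - on)
    # hours since the most recent lights-off
    since_off = np.mod(zt - off, 24.0)
    env = np.where(
        since_off < night_len_h,
        np.sin(np.pi * since_off / night_len_h) ** 2,
        0.0,
    )
    # gate only engages from the first lights-off after sequence start
    first_off_t = (off - scenario.start_zt_h) % 24.0 * 60.0
    return np.where(t_min >= first_off_t, env, 0.0)


def simulate_pose(scenario: SimScenario) -> pd.DataFrame:
    """Ground-truth pose per frame.

    Returns a DataFrame with columns t_min, zt_h, petiole_angle_deg,
    lamina_angle_deg, petiole_len_mm, lamina_len_mm, illumination.
    Deterministic given the scenario (the pose itself is noise-free; the
    seed only affects rendering noise).
    """
    n = scenario.n_frames
    t = np.arange(n, dtype=float) * scenario.frame_interval_min
    zt = scenario.start_zt_h + t / 60.0
    m = (zt - scenario.treatment_start_zt_h) * 60.0  # minutes since treatment start

    diurnal = scenario.diurnal_amp_deg * np.sin(2.0 * np.pi * zt / 24.0)
    k = scenario.hyponasty_rate_per_min
    sigma = 1.0 / (1.0 + np.exp(-k * (m - scenario.hyponasty_onset_min)))
    ramp = scenario.dose * scenario.hyponasty_amp_deg * sigma
    env = _night_envelope(t, scenario)
    osc = (
        scenario.dose
        * scenario.osc_amp_deg
        * np.sin(2.0 * np.pi * t / scenario.osc_period_min)
        * env
    )

    theta_p = scenario.angle0_petiole_deg + diurnal + ramp + osc
    frac = scenario.lamina_response_frac
    theta_l = scenario.angle0_lamina_deg + diurnal + frac * (ramp + osc)

    hours = t / 60.0
    rate = scenario.elong_rate_mm_per_h
    # FRw elongates the petiole dose-dependently; lamina (and FRt petiole)
    # grow at the untreated rate.
    if scenario.treatment == "FRw":
        petiole_rate = rate * (1.0 + scenario.dose * (scenario.elong_fr_multiplier - 1.0))
    else:
        petiole_rate = rate
    len_p = scenario.petiole_len0_mm + petiole_rate * hours
    len_l = scenario.lamina_len0_mm + rate * hours

    for name, arr in (("petiole", theta_p), ("lamina", theta_l)):
        if np.any(arr <= -90.0) or np.any(arr >= 180.0):
            i = int(np.argmax((arr <= -90.0) | (arr >= 180.0)))
            raise ValueError(
                f"{name} angle leaves the valid range (-90, 180) at frame {i}: {arr[i]:.2f} deg"
            )

    day = _is_day(zt, scenario.lights_on_zt_h, scenario.lights_off_zt_h)
    return pd.DataFrame(
        {
            "t_min": t,
            "zt_h": zt,
            "petiole_angle_deg": theta_p,
            "lamina_angle_deg": theta_l,
            "petiole_len_mm": len_p,
            "lamina_len_mm": len_l,
            "illumination": np.where(day, "day", "night"),
        }
    )


def pose_to_pixels(
    pose: pd.DataFrame,
    scenario: SimScenario,
    center_px: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Landmark pixel coordinates per frame (sub-pixel, image convention:
    origin top-left, y down — hence the sign flip on sines).

    junction = center + (petiole_len/mm_per_px) * (cos th_p, -sin th_p)
    tip      = junction + (lamina_len/mm_per_px) * (cos th_l, -sin th_l)
    """
    n = len(pose)
    if center_px is None:
        cx0, cy0 = scenario.center_x_px, scenario.center_y_px
    else:
        cx0, cy0 = center_px
    frac = np.arange(n, dtype=float) / max(n - 1, 1)
    cx = cx0 + frac * scenario.center_drift_x_px
    cy = cy0 + frac * scenario.center_drift_y_px

    thp = np.deg2rad(pose["petiole_angle_deg"].to_numpy())
    thl = np.deg2rad(pose["lamina_angle_deg"].to_numpy())
    lp = pose["petiole_len_mm"].to_numpy() / scenario.mm_per_px
    ll = pose["lamina_len_mm"].to_numpy() / scenario.mm_per_px

    jx = cx + lp * np.cos(thp)
    jy = cy - lp * np.sin(thp)
    tx = jx + ll * np.cos(thl)
    ty = jy - ll * np.sin(thl)

    w, h = scenario.image_w_px, scenario.image_h_px
    for name, xs, ys in (("center", cx, cy), ("junction", jx, jy), ("tip", tx, ty)):
        out = (xs < 0) | (xs >= w) | (ys < 0) | (ys >= h)
        if np.any(out):
            i = int(np.argmax(out))
            raise ValueError(
                f"{name} landmark leaves the {w}x{h} frame at frame {i}: "
                f"({xs[i]:.1f}, {ys[i]:.1f})"
            )

    return pd.DataFrame(
        {
            "frame": np.arange(n),
            "t_min": pose["t_min"].to_numpy(),
            "zt_h": pose["zt_h"].to_numpy(),
            "illumination": pose["illumination"].to_numpy(),
            "cx": cx, "cy": cy, "jx": jx, "jy": jy, "tx": tx, "ty": ty,
        }
    )


def scale_bar_segment(scenario: SimScenario) -> tuple[tuple[float, float], tuple[float, float], float]:
    """Endpoints (px) and physical length (mm) of the rendered scale bar."""
    p1 = (12.0, 12.0)
    p2 = (112.0, 12.0)
    return p1, p2, 100.0 * scenario.mm_per_px


def _ellipse_polygon(j: tuple[float, float], t: tuple[float, float], width_frac: float = 0.3,
                     n_pts: int = 72) -> list[tuple[float, float]]:
    cx, cy = (j[0] + t[0]) / 2.0, (j[1] + t[1]) / 2.0
    dx, dy = t[0] - j[0], t[1] - j[1]
    a = math.hypot(dx, dy) / 2.0
    b = max(a * width_frac, 1.0)
    phi = math.atan2(dy, dx)
    ang = np.linspace(0.0, 2.0 * np.pi, n_pts, endpoint=False)
    ex = a * np.cos(ang)
    ey = b * np.sin(ang)
    xs = cx + ex * math.cos(phi) - ey * math.sin(phi)
    ys = cy + ex * math.sin(phi) + ey * math.cos(phi)
    return list(zip(xs.tolist(), ys.tolist()))


def _render_frame(row: pd.Series, scenario: SimScenario, rng: np.random.Generator) -> np.ndarray:
    w, h = scenario.image_w_px, scenario.image_h_px
    day = row["illumination"] == "day"
    ss = _SS
    if day:
        bg, plant, bar = DAY_BACKGROUND, DAY_PLANT, SCALE_BAR_DAY
    else:
        g = NIGHT_BACKGROUND
        bg = (g, g, g)
        plant = (NIGHT_PLANT,) * 3
        bar = (SCALE_BAR_NIGHT,) * 3

    img = Image.new("RGB", (w * ss, h * ss), bg)
    draw = ImageDraw.Draw(img)

    def pt(x: float, y: float) -> tuple[float, float]:
        return (x * ss, y * ss)

    c = (row["cx"], row["cy"])
    j = (row["jx"], row["jy"])
    t = (row["tx"], row["ty"])

    # scale bar (physical object, present day and night)
    p1, p2, _ = scale_bar_segment(scenario)
    draw.line([pt(*p1), pt(*p2)], fill=bar, width=2 * ss)

    # rosette disc at the center landmark
    r = 1.5 / scenario.mm_per_px * ss
    draw.ellipse([c[0] * ss - r, c[1] * ss - r, c[0] * ss + r, c[1] * ss + r], fill=plant)
    # petiole: thick line center -> junction
    pw = max(int(round(0.8 / scenario.mm_per_px * ss)), ss)
    draw.line([pt(*c), pt(*j)], fill=plant, width=pw)
    # lamina: filled ellipse along the junction -> tip axis
    poly = [(x * ss, y * ss) for x, y in _ellipse_polygon(j, t)]
    draw.polygon(poly, fill=plant)

    img = img.resize((w, h), Image.BOX)  # exact box average = anti-aliasing
    arr = np.asarray(img, dtype=np.float64)
    if scenario.noise_sd > 0:
        noise = rng.normal(0.0, scenario.noise_sd, size=(h, w))
        arr = arr + noise[:, :, None]  # luminance noise: identical across channels
    return np.clip(np.rint(arr), 0, 255).astype(np.uint8)


def render_sequence(scenario: SimScenario, out_dir: str | Path) -> tuple[list[Path], Path]:
    """Render the full sequence to ``out_dir``.

    Writes one PNG per frame (``frame_{index:06d}_{t_min:g}.png``), the
    ground-truth table ``ground_truth.csv`` and an annotation file
    ``annotation.yaml`` holding the first/last-frame landmark positions and
    the scale-bar segment.  Returns (frame paths, ground-truth path).
    Bit-identical output for identical scenario + seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pose = simulate_pose(scenario)
    pix = pose_to_pixels(pose, scenario)
    rng = np.random.default_rng(scenario.rng_seed)

    paths: list[Path] = []
    for _, row in pix.iterrows():
        arr = _render_frame(row, scenario, rng)
        name = FRAME_PATTERN.format(index=int(row["frame"]), t_min=row["t_min"])
        p = out_dir / name
        Image.fromarray(arr).save(p)
        paths.append(p)

    gt = pix.copy()
    for col in ("petiole_angle_deg", "lamina_angle_deg", "petiole_len_mm", "lamina_len_mm"):
        gt[col] = pose[col].to_numpy()
    gt = gt[GROUND_TRUTH_COLUMNS]
    gt_path = out_dir / "ground_truth.csv"
    gt.to_csv(gt_path, index=False)  # default float repr: exact round-trip

    from leafkin.frameio import Annotation, save_annotation

    p1, p2, bar_mm = scale_bar_segment(scenario)
    first, last = pix.iloc[0], pix.iloc[-1]
    ann = Annotation(
        plant_id=f"sim_{scenario.treatment}_{scenario.rng_seed}",
        center_first=(float(first["cx"]), float(first["cy"])),
        center_last=(float(last["cx"]), float(last["cy"])),
        junction_first=(float(first["jx"]), float(first["jy"])),
        tip_first=(float(first["tx"]), float(first["ty"])),
        scale_p1=p1,
        scale_p2=p2,
        scale_len_mm=bar_mm,
    )
    save_annotation(ann, out_dir / "annotation.yaml")
    return paths, gt_path


def parse_frame_filename(name: str) -> tuple[int, float]:
    m = re.fullmatch(r"frame_(\d+)_([-+0-9.eE]+)\.(png|jpe?g)", name)
    if m is None:
        raise ValueError(f"cannot parse frame filename: {name!r}")
    return int(m.group(1)), float(m.group(2))


# --- scenario presets -------------------------------------------------------

def default_scenario(treatment: str = "WL", seed: int = 0, **overrides) -> SimScenario:
    """Standard 24-h scenario at the stated dose for the treatment."""
    dose = 0.0 if treatment == "WL" else 1.0
    kw = dict(treatment=treatment, dose=dose, rng_seed=seed)
    kw.update(overrides)
    return SimScenario(**kw)


def day_night_scenario(treatment: str = "WL", seed: int = 0, **overrides) -> SimScenario:
    """240-frame scenario spanning the ZT 9 lights-off transition (ZT 7–11),
    with treatment onset still anchored at ZT 2 — the standard short fixture
    for testing tracking across the day->night appearance switch."""
    kw = dict(duration_min=240.0, start_zt_h=7.0)
    kw.update(overrides)
    return default_scenario(treatment, seed, **kw)
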