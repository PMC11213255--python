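"""Image-sequence loading, cropping, annotation I/O and day/night classification.

Frame timestamps are parsed from filenames rather than file mtimes so that
sequences survive being copied between the acquisition machine and the
analysis machine.  Night frames are detected from the per-pixel channel
spread: near-infrared imaging writes the same value to R, G and B, so the
mean of (max channel - min channel) collapses to ~0 at night and is large
by day against a coloured background.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from leafkin.leafsim import parse_frame_filename

logger = logging.getLogger(__name__)

DEFAULT_GRAY_TOL = 8.0
MAX_GAP_FRACTION = 0.05

TRACK_TABLE_COLUMNS = [
    "frame", "t_min", "illumination", "cx", "cy", "jx", "jy", "tx", "ty",
    "confidence_j", "confidence_t",
]


@dataclass
class Annotation:
    """User-supplied landmark pixel coordinates plus scale segment.

    ``center_first``/``center_last`` anchor the rosette center on the first
    and last frame (it drifts slowly as the plant grows); junction and tip
    are given on the first frame only and tracked from there.  The scale
    segment is two pixel points bracketing a region of known physical
    length, used for the pixel->mm conversion.
    """

    plant_id: str
    center_first: tuple[float, float]
    center_last: tuple[float, float]
    junction_first: tuple[float, float]
    tip_first: tuple[float, float]
    scale_p1: tuple[float, float]
    scale_p2: tuple[float, float]
    scale_len_mm: float
    crop_rect: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        if tuple(self.scale_p1) == tuple(self.scale_p2):
            raise ValueError("scale_p1 and scale_p2 must differ")
        if self.scale_len_mm <= 0:
            raise ValueError("scale_len_mm must be > 0")

    def validate_bounds(self, width: int, height: int) -> None:
        for name in ("center_first", "center_last", "junction_first", "tip_first",
                     "scale_p1", "scale_p2"):
            x, y = getattr(self, name)
            if not (0 <= x < width and 0 <= y < height):
                raise ValueError(
                    f"annotation point {name} = ({x}, {y}) outside {width}x{height} image"
                )


def save_annotation(ann: Annotation, path: str | Path) -> None:
    d = dataclasses.asdict(ann)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def load_annotation(path: str | Path) -> Annotation:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    known = {f.name for f in dataclasses.fields(Annotation)}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown annotation keys in {path}: {sorted(unknown)}")
    for k, v in list(d.items()):
        if isinstance(v, list):
            d[k] = tuple(v)
    return Annotation(**d)


class FrameSequence:
    """Ordered time-lapse frames, loaded lazily from disk.

    Frames may also be supplied in memory (``from_arrays``) for tests.
    """

    def __init__(self, paths: list[Path], indices: list[int], t_min: list[float],
                 crop_rect: tuple[int, int, int, int] | None = None):
        self.paths = paths
        self.indices = indices
        self.t_min = t_min
        self.crop_rect = crop_rect
        self._arrays: list[np.ndarray] | None = None

    @classmethod
    def from_arrays(cls, arrays: list[np.ndarray], t_min: list[float] | None = None
                    ) -> "FrameSequence":
        seq = cls([], list(range(len(arrays))),
                  t_min if t_min is not None else [float(i) for i in range(len(arrays))])
        seq._arrays = arrays
        return seq

    def __len__(self) -> int:
        return len(self.indices)

    def frame(self, i: int) -> np.ndarray:
        """Frame i as uint8 RGB (H, W, 3), cropped if a crop rect is set."""
        if self._arrays is not None:
            arr = self._arrays[i]
        else:
            arr = np.asarray(Image.open(self.paths[i]).convert("RGB"))
        if self.crop_rect is not None:
            arr = crop_frame(arr, self.crop_rect)
        return arr

    @property
    def frame_shape(self) -> tuple[int, int]:
        arr = self.frame(0)
        return arr.shape[0], arr.shape[1]


def load_sequence(directory: str | Path, pattern: str = "frame_*.png",
                  crop_rect: tuple[int, int, int, int] | None = None) -> FrameSequence:
    """Load and order a frame directory by the timestamps in the filenames.

    Warns about gaps in the expected cadence (inferred from the median
    inter-frame interval); errors if more than 5% of expected frames are
    missing or if frame dimensions are inconsistent.
    """
    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    if len(files) < 2:
        raise ValueError(f"need >= 2 frames matching {pattern!r} in {directory}")

    parsed = []
    for p in files:
        try:
            idx, t = parse_frame_filename(p.name)
        except ValueError as e:
            raise ValueError(f"unparseable frame filename {p.name!r} in {directory}") from e
        parsed.append((t, idx, p))
    parsed.sort()
    t_min = [t for t, _, _ in parsed]
    indices = [i for _, i, _ in parsed]
    paths = [p for _, _, p in parsed]

    sizes = {Image.open(p).size for p in paths}
    if len(sizes) != 1:
        raise ValueError(f"inconsistent frame dimensions in {directory}: {sorted(sizes)}")

    dt = np.diff(t_min)
    if np.any(dt <= 0):
        raise ValueError(f"non-increasing timestamps in {directory}")
    interval = float(np.median(dt))
    missing = int(np.round((dt / interval)).sum()) - len(dt)
    if missing > 0:
        expected = len(paths) + missing
        if missing / expected > MAX_GAP_FRACTION:
            raise ValueError(
                f"{missing} of {expected} expected frames missing in {directory} "
                f"(> {MAX_GAP_FRACTION:.0%}); re-acquire or relax the gap policy"
            )
        logger.warning("sequence %s has %d missing frame interval(s)", directory, missing)

    return FrameSequence(paths, indices, t_min, crop_rect)


def crop_frame(frame: np.ndarray, rect: tuple[int, int, int, int]) -> np.ndarray:
    """Crop (x, y, w, h); output pixel (0,0) equals input pixel (y, x)."""
    x, y, w, h = rect
    H, W = frame.shape[:2]
    if not (0 <= x and 0 <= y and w > 0 and h > 0 and x + w <= W and y + h <= H):
        raise ValueError(f"crop rect {rect} out of bounds for {W}x{H} frame")
    return frame[y:y + h, x:x + w]


def classify_illumination(frame: np.ndarray, gray_tol: float = DEFAULT_GRAY_TOL) -> str:
    """'night' iff the mean per-pixel channel spread (max - min over R,G,B)
    is <= gray_tol gray levels, else 'day'."""
    arr = frame.astype(np.float64)
    spread = arr.max(axis=2) - arr.min(axis=2)
    return "night" if float(spread.mean()) <= gray_tol else "day"


def write_track_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the canonical trajectory CSV (interchange with geometry)."""
    table[TRACK_TABLE_COLUMNS].to_csv(path, index=False, float_format="%.6f")


def read_track_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table {path} missing columns {sorted(missing)}")
    return df
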