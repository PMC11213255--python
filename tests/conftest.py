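"""Shared fixtures: small rendered sequences with ground truth.

The "small" scenario uses a coarser pixel scale (0.08 mm/px) and a 320x240
frame so unit tests render and track in seconds; it spans a day->night
transition (start ZT 8.5, 60 min) so illumination handling is exercised
everywhere.
"""

from __future__ import annotations

import pandas as pd
import pytest

from leafkin import frameio, leafsim

SMALL_KWARGS = dict(
    duration_min=60.0,
    start_zt_h=8.5,
    mm_per_px=0.08,
    image_w_px=320,
    image_h_px=240,
    center_x_px=80.0,
    center_y_px=190.0,
)


def small_scenario(treatment: str = "FRw", seed: int = 7, **overrides) -> leafsim.SimScenario:
    kw = dict(SMALL_KWARGS)
    kw.update(overrides)
    return leafsim.default_scenario(treatment, seed=seed, **kw)


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory) -> dict:
    """Rendered small FRw run (60 frames, day->night at t=30) + ground truth."""
    out = tmp_path_factory.mktemp("sim_frw")
    scen = small_scenario()
    paths, gt_path = leafsim.render_sequence(scen, out)
    return {
        "dir": out,
        "scenario": scen,
        "frame_paths": paths,
        "gt": pd.read_csv(gt_path, float_precision="round_trip"),
        "annotation": frameio.load_annotation(out / "annotation.yaml"),
    }


@pytest.fixture(scope="session")
def sim_seq(sim_run) -> frameio.FrameSequence:
    return frameio.load_sequence(sim_run["dir"])
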