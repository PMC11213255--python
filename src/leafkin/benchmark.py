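"""Validation benchmarks: every stage of the pipeline measured against the
simulator's ground truth.

These routines generate their own synthetic inputs, run the ordinary user
path (render -> load -> track -> calibrate -> quantify) and return the
measured errors, so the package's accuracy claims can be recomputed from
scratch on any machine.  All randomness flows from explicit seeds.
"""

from __future__ import annotations

import itertools
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from leafkin import frameio, geometry, kinetics, leafsim, stats, tracker


def pose_roundtrip_errors(n_poses: int = 1000, seed: int = 0) -> dict:
    """Project random noise-free poses to pixels and re-measure them.

    Returns the maximum absolute angle error (degrees) and length error (mm)
    over ``n_poses`` random single-frame poses.
    """
    rng = np.random.default_rng(seed)
    # projection is purely mathematical here — a large virtual canvas keeps
    # every random pose inside bounds
    scen = leafsim.SimScenario(image_w_px=2000, image_h_px=2000)
    max_angle = 0.0
    max_len = 0.0
    for _ in range(n_poses):
        pose = pd.DataFrame({
            "t_min": [0.0], "zt_h": [2.0],
            "petiole_angle_deg": [rng.uniform(-60.0, 120.0)],
            "lamina_angle_deg": [rng.uniform(-60.0, 120.0)],
            "petiole_len_mm": [rng.uniform(2.0, 8.0)],
            "lamina_len_mm": [rng.uniform(4.0, 12.0)],
            "illumination": ["day"],
        })
        pix = leafsim.pose_to_pixels(pose, scen, center_px=(1000.0, 1000.0))
        pix["confidence_j"] = 1.0
        pix["confidence_t"] = 1.0
        m = geometry.compute_metrics(pix, geometry.ScaleCalibration(scen.mm_per_px))
        max_angle = max(
            max_angle,
            abs(m["petiole_angle_deg"][0] - pose["petiole_angle_deg"][0]),
            abs(m["lamina_angle_deg"][0] - pose["lamina_angle_deg"][0]),
        )
        max_len = max(
            max_len,
            abs(m["petiole_len_mm"][0] - pose["petiole_len_mm"][0]),
            abs(m["lamina_len_mm"][0] - pose["lamina_len_mm"][0]),
        )
    return {"max_angle_err_deg": float(max_angle), "max_len_err_mm": float(max_len),
            "n": n_poses}


def _run_scenario(scen: leafsim.SimScenario, workdir: Path | None = None):
    """Render, load and track one scenario; returns (gt, track table, annotation)."""
    d = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="leafkin_bench_"))
    _, gt_path = leafsim.render_sequence(scen, d)
    gt = pd.read_csv(gt_path, float_precision="round_trip")
    ann = frameio.load_annotation(d / "annotation.yaml")
    table = tracker.track_sequence(frameio.load_sequence(d), ann)
    return gt, table, ann


def tracking_benchmark(seeds=(0, 1, 2), treatments=("WL", "FRw"),
                       scratch_dir: str | Path | None = None) -> pd.DataFrame:
    """Landmark accuracy on the standard day+night scenario suite.

    One row per (treatment, seed): junction/tip RMSE vs ground truth (px),
    lost-frame count and illumination agreement.
    """
    rows = []
    for treatment, seed in itertools.product(treatments, seeds):
        scen = leafsim.day_night_scenario(treatment, seed=seed)
        sub = Path(scratch_dir) / f"{treatment}_{seed}" if scratch_dir else None
        gt, table, _ = _run_scenario(scen, sub)
        ej = np.hypot(table["jx"] - gt["jx"], table["jy"] - gt["jy"])
        et = np.hypot(table["tx"] - gt["tx"], table["ty"] - gt["ty"])
        day = (gt["illumination"] == "day").to_numpy()
        night5 = gt.index[gt["illumination"] == "night"][:5]
        row = {
            "treatment": treatment, "seed": seed, "n_frames": len(gt),
            "rmse_junction_px": float(np.sqrt((ej ** 2).mean())),
            "rmse_tip_px": float(np.sqrt((et ** 2).mean())),
            "n_lost": int(table["lost_j"].sum() + table["lost_t"].sum()),
            "illumination_agreement": float(
                (table["illumination"].to_numpy() == gt["illumination"].to_numpy()).mean()),
        }
        # appearance-switch robustness: error just after lights-off vs by day
        for lm, e in (("junction", ej), ("tip", et)):
            day_rmse = float(np.sqrt((e[day] ** 2).mean()))
            n5 = float(np.sqrt((e[night5] ** 2).mean())) if len(night5) else np.nan
            row[f"transition_ratio_{lm}"] = n5 / day_rmse if day_rmse > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _exhaustive_ncc_peak(img: np.ndarray, template: np.ndarray,
                         x0: int, y0: int, x1: int, y1: int) -> tuple[int, int]:
    """Brute-force normalized cross-correlation argmax (independent of the
    tracker's vectorised implementation): plain loop over placements."""
    h, w = template.shape
    t = (template - template.mean()).ravel()
    tn = np.sqrt((t * t).sum())
    best, best_pos = -2.0, (x0, y0)
    for yy in range(y0, y1 - h + 1):
        for xx in range(x0, x1 - w + 1):
            patch = img[yy:yy + h, xx:xx + w].astype(np.float64).ravel()
            p = patch - patch.mean()
            pn = np.sqrt((p * p).sum())
            if pn < 1e-12 or tn < 1e-12:
                continue
            r = float(p @ t) / (pn * tn)
            if r > best:
                best, best_pos = r, (xx + w // 2, yy + h // 2)
    return best_pos


def tracker_oracle_deviation(n_frames: int = 15, seed: int = 0) -> dict:
    """Max distance (px) between the tracker's per-step localisation and a
    brute-force exhaustive NCC search, on noise-free frames."""
    scen = leafsim.day_night_scenario("FRw", seed=seed, duration_min=float(n_frames),
                                      noise_sd=0.0)
    d = Path(tempfile.mkdtemp(prefix="leafkin_oracle_"))
    leafsim.render_sequence(scen, d)
    seq = frameio.load_sequence(d)
    ann = frameio.load_annotation(d / "annotation.yaml")
    cfg = tracker.TrackConfig(anchor_weight=0.0)  # single template: oracle-comparable
    st = tracker.init_tracker(seq.frame(0), ann.junction_first)
    worst = 0.0
    for i in range(1, len(seq)):
        img = seq.frame(i)[:, :, st.channel]
        w, h = st.box
        px, py = st.point
        r = cfg.search_radius
        x0 = max(int(round(px)) - w // 2 - r, 0)
        y0 = max(int(round(py)) - h // 2 - r, 0)
        x1 = min(int(round(px)) - w // 2 + r + w, img.shape[1])
        y1 = min(int(round(py)) - h // 2 + r + h, img.shape[0])
        ox, oy = _exhaustive_ncc_peak(img, st.template, x0, y0, x1, y1)
        st, pt, _ = tracker.track_next(st, seq.frame(i), cfg)
        dev = float(np.hypot(pt[0] - st.frac[0] - ox, pt[1] - st.frac[1] - oy))
        worst = max(worst, dev)
    return {"max_deviation_px": worst, "n": n_frames - 1}


def parameter_recovery(seed: int = 0) -> dict:
    """Recover treatment kinetics from a rendered far-red scenario.

    Runs the full simulate -> track -> calibrate -> quantify pipeline on a
    600-min whole-plant far-red scenario with the diurnal and oscillation
    terms disabled, so the relative petiole angle saturates at exactly the
    programmed hyponasty amplitude.  Returns the recovered amplitude
    (degrees), the recovered petiole elongation rate (mm/h, least-squares
    slope) and the programmed truths.
    """
    scen = leafsim.default_scenario("FRw", seed=seed, duration_min=600.0,
                                    diurnal_amp_deg=0.0, osc_amp_deg=0.0)
    gt, table, ann = _run_scenario(scen)
    cal = geometry.calibrate(ann.scale_p1, ann.scale_p2, ann.scale_len_mm)
    m = geometry.compute_metrics(table, cal, start_zt_h=scen.start_zt_h)
    rel = kinetics.relative_series(m)
    amp_est = float(rel["petiole_angle_deg"].iloc[-60:].mean())  # last hour = plateau
    slope = float(np.polyfit(m["t_min"] / 60.0, m["petiole_len_mm"], 1)[0])
    true_rate = scen.elong_rate_mm_per_h * scen.elong_fr_multiplier
    return {
        "hyponasty_amp_est_deg": amp_est,
        "hyponasty_amp_true_deg": scen.dose * scen.hyponasty_amp_deg,
        "elong_rate_est_mm_per_h": slope,
        "elong_rate_true_mm_per_h": true_rate,
        "elong_rate_rel_err": abs(slope / true_rate - 1.0),
        "n": len(gt),
    }


def illumination_benchmark(noise_sd: float = 5.0, seed: int = 0,
                           treatments=("WL", "FRw")) -> dict:
    """Day/night classification agreement with ground truth over full
    default 24-h scenarios at the stated sensor noise."""
    total, correct = 0, 0
    for treatment in treatments:
        scen = leafsim.default_scenario(treatment, seed=seed, noise_sd=noise_sd)
        d = Path(tempfile.mkdtemp(prefix="leafkin_illum_"))
        _, gt_path = leafsim.render_sequence(scen, d)
        gt = pd.read_csv(gt_path)
        seq = frameio.load_sequence(d)
        labels = np.array([frameio.classify_illumination(seq.frame(i))
                           for i in range(len(seq))])
        total += len(gt)
        correct += int((labels == gt["illumination"].to_numpy()).sum())
    return {"agreement": correct / total, "n": total}


def anova_type1_error(n_reps: int = 1000, k: int = 3, n_per_group: int = 10,
                      alpha: float = 0.05, seed: int = 0) -> dict:
    """Rejection rate of the one-way ANOVA under the null (all groups drawn
    from the same normal distribution)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        df = pd.DataFrame({
            "treatment": np.repeat([f"g{i}" for i in range(k)], n_per_group),
            "value": rng.normal(0.0, 1.0, k * n_per_group),
        })
        if stats.anova(df)["p"].iloc[0] < alpha:
            rejections += 1
    return {"type1_rate": rejections / n_reps, "n": n_reps}


def tukey_t_equivalence(n_cases: int = 20, seed: int = 0) -> dict:
    """Max |Tukey p - pooled t-test p| over random two-group data sets
    (with k = 2 the studentized range reduces to the t distribution)."""
    import scipy.stats

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_cases):
        na, nb = rng.integers(5, 15, 2)
        a = rng.normal(0.0, 1.0, na)
        b = rng.normal(rng.uniform(0, 1.5), rng.uniform(0.5, 2.0), nb)
        df = pd.DataFrame({"treatment": ["a"] * na + ["b"] * nb,
                           "value": np.concatenate([a, b])})
        _, p = stats.tukey_hsd(df)
        _, p_t = scipy.stats.ttest_ind(a, b)
        worst = max(worst, abs(p[0, 1] - p_t))
    return {"max_abs_diff": float(worst), "n": n_cases}


def cld_oracle_agreement(n_structures: int = 200, k: int = 6, seed: int = 0) -> dict:
    """Fraction of random significance structures for which the letter
    display reproduces the pairwise significance relation exactly."""
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_structures):
        p = np.ones((k, k))
        for i, j in itertools.combinations(range(k), 2):
            p[i, j] = p[j, i] = rng.choice([0.001, 0.5])
        groups = [f"g{i}" for i in range(k)]
        means = {g: float(rng.normal()) for g in groups}
        letters = stats.compact_letter_display(p, groups, means=means)
        good = all(
            (bool(set(letters[groups[i]]) & set(letters[groups[j]]))
             == (p[i, j] >= 0.05))
            for i, j in itertools.combinations(range(k), 2)
        )
        ok += int(good)
    return {"agreement": ok / n_structures, "n": n_structures}


def determinism_check(seed: int = 0) -> dict:
    """Render and track the same short scenario twice; outputs must be
    byte-identical (images, ground truth, trajectory CSV)."""
    scen = leafsim.day_night_scenario("FRw", seed=seed, duration_min=20.0)
    results = []
    for _ in range(2):
        d = Path(tempfile.mkdtemp(prefix="leafkin_det_"))
        paths, gt_path = leafsim.render_sequence(scen, d)
        ann = frameio.load_annotation(d / "annotation.yaml")
        table = tracker.track_sequence(frameio.load_sequence(d), ann)
        traj = d / "trajectory.csv"
        frameio.write_track_table(table, traj)
        results.append((
            [p.read_bytes() for p in paths], gt_path.read_bytes(), traj.read_bytes(),
        ))
    identical = (results[0][0] == results[1][0]
                 and results[0][1] == results[1][1]
                 and results[0][2] == results[1][2])
    return {"identical": bool(identical), "n": 20}
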