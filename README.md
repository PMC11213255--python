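# leafkin

Quantifying leaf movement and growth from low-cost side-view time-lapse
imagery.

Rosette plants such as *Arabidopsis thaliana* reposition their leaves in
response to neighbour cues: supplemental far-red light (a low red:far-red
ratio) triggers hyponasty — upward movement of the petiole and lamina —
together with petiole elongation. Resolving these kinetics requires
minute-scale imaging of a single leaf from the side: visible light by day,
near-infrared by night, one frame per minute across the light/dark cycle.

`leafkin` turns such image sequences into quantitative leaf kinematics.
Three landmarks are annotated once — rosette center, petiole–lamina
junction, leaf tip — plus a scale segment of known length. The package then

1. **tracks** the junction and tip through every frame with an
   adaptive-template correlation localizer (40 × 60 px appearance model,
   zero-normalised cross-correlation, sub-pixel refinement), interpolating
   the rosette center between its first- and last-frame annotations;
2. **converts** pixel trajectories to metrics by triangulation: petiole,
   lamina, leaf and junction angles (degrees above horizontal), petiole /
   lamina / leaf lengths (mm via the scale calibration), leaf-tip elevation
   and projected lamina length;
3. **normalises** kinetic series to a relative baseline (mean of the first
   five frames), time-syncs replicate plants on the day→night transition
   detected in the images, and computes angular speed over 60-min windows;
4. **compares** treatment groups per 2-h bin with one- or two-way ANOVA,
   Tukey HSD post-hoc tests and compact-letter displays (groups sharing a
   letter are not significantly different at α = 0.05).

A built-in simulator (`leafkin.leafsim`) renders synthetic leaf movies with
exact sub-pixel ground truth under the same imaging regime (blue day
background, grayscale nights, 9 h light / 15 h dark), so every stage of the
pipeline is testable without real data.

## Worked example

Simulate a 4-h far-red run spanning the dusk transition, track it, and
quantify the kinetics:

```sh
leafkin simulate --treatment FRw --seed 7 --out run/
leafkin track --frames run/ --annotation run/annotation.yaml --out run/trajectory.csv
leafkin quantify --trajectory run/trajectory.csv --annotation run/annotation.yaml \
                 --start-zt 2 --out-dir run/q
```

or in Python:

```python
import leafkin
from leafkin import leafsim, frameio, tracker, geometry, kinetics

scen = leafsim.day_night_scenario("FRw", seed=7)       # 240 frames, ZT 7-11
paths, gt = leafsim.render_sequence(scen, "run/")
ann = frameio.load_annotation("run/annotation.yaml")
table = tracker.track_sequence(frameio.load_sequence("run/"), ann)
cal = geometry.calibrate(ann.scale_p1, ann.scale_p2, ann.scale_len_mm)
metrics = geometry.compute_metrics(table, cal, start_zt_h=scen.start_zt_h)
rel = kinetics.relative_series(metrics)
print(f"relative petiole angle at end: {rel['petiole_angle_deg'].iloc[-1]:.2f} deg")
print(f"petiole length at end:        {metrics['petiole_len_mm'].iloc[-1]:.2f} mm")
```

which prints

```
relative petiole angle at end: -2.64 deg
petiole length at end:        5.34 mm
```

— the relative petiole angle falls by ~2.6° across this window because the
far-red ramp is already saturated before ZT 7 and the diurnal rhythm is
past its ZT 6 peak, while the petiole elongates from 5.0 mm to 5.34 mm at
the far-red-doubled rate of 0.1 mm/h (tracked, hence the small deviation
from the programmed 5.4 mm). Comparing the trajectory against the
simulator's ground-truth table gives landmark RMSEs well under 2 px.

For group statistics, feed two or more sets of kinetics CSVs to
`leafkin stats --kinetics WL:... --kinetics FRw:... --out-dir stats/`;
the output tables carry per-2-h-bin means ± SEM, ANOVA p-values and Tukey
significance letters.

## Layout

- `leafkin.leafsim` — synthetic experiment generator + ground truth
- `leafkin.frameio` — sequence loading, cropping, annotation I/O, day/night classification
- `leafkin.tracker` — landmark tracking (adaptive anchored NCC templates)
- `leafkin.geometry` — pixel→metric conversion (angles, lengths, calibration)
- `leafkin.kinetics` — baselines, time sync, angular speed, binning
- `leafkin.stats` — ANOVA, Tukey HSD, compact letter displays, mean ± SEM
- `leafkin.benchmark` — ground-truth validation routines used by the tests
  and the acceptance script
- `leafkin.cli` — `leafkin simulate|track|quantify|stats|all`

See `docs/methods.md` for the models, parameter choices and limitations.
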