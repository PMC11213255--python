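# Methods

This note documents the models, conventions and numerical choices behind
`leafkin`, and what the synthetic validation does and does not demonstrate.

## Coordinate and angle conventions

Raster images put the origin top-left with y increasing downward. All
geometry converts to the "plant" convention (y up, angles in degrees above
horizontal, positive = upward movement) at exactly one place — the
`geometry` module's `segment_angle` / `compute_metrics`
(`atan2(origin_y − end_y, end_x − origin_x)`); everything upstream works in
raw image coordinates. A single flip point avoids sign errors.

Angles are signed and unclamped: a petiole drooping below horizontal is
negative, and the junction angle (lamina − petiole) is negative for a
downward-kinked lamina. Published panels that clamp at zero will differ for
leaves below horizontal.

Metric definitions per frame, from the three landmarks (rosette center C,
petiole–lamina junction J, leaf tip T):

- petiole angle/length from C→J; lamina from J→T; whole leaf from C→T
- junction angle = lamina angle − petiole angle (exact identity)
- tip height = (C_y − T_y) · mm/px — vertical tip elevation above the center
- projected lamina length = |T_x − J_x| · mm/px — horizontal extent only

The mm/px scale comes from a user-annotated segment of known physical
length; `calibrate` divides the known length by the segment's Euclidean
pixel length.

## Landmark tracking

The junction and tip are localised per frame with an adaptive-template
correlation tracker; the rosette center is not tracked but linearly
interpolated in frame index between its first- and last-frame annotations
(it moves by at most a few pixels as the rosette grows, and it has no
texture gradient to lock onto).

Per landmark the tracker holds a 40 × 60 px template (w × h, the default
box) and, per new frame:

1. searches a ±20 px window around the previous estimate, scoring every
   placement by zero-normalised cross-correlation (ZNCC) — invariant to
   affine intensity changes, which is what lets one appearance model
   survive the day→night illumination switch;
2. blends two response maps: the *adaptive* template (updated each frame
   with learning rate 0.05) and an *anchor* template (weight 0.15) that is
   refreshed only every 240 frames. The adaptive model follows slow shape
   change (growth, rotation); the anchor pins the estimate against the
   slow drift that pure adaptive templates accumulate; periodic refreshing
   keeps the anchor from going stale as the leaf rotates, which would
   otherwise bias the peak tangentially;
3. refines the peak to sub-pixel precision with a separable quadratic fit
   over the 3 × 3 response neighbourhood;
4. updates the adaptive template from a *bilinearly resampled* patch
   centred exactly on the sub-pixel estimate. Grid-aligned extraction
   would let the landmark's sub-pixel position inside the template wander
   by up to half a pixel per update, a systematic bias we measured at
   ~1° on a 5-mm petiole before switching to sub-pixel resampling.

Confidence is the normalised peak response clipped to [0, 1]; below 0.2
the row is flagged lost, the position held, and the appearance model
frozen so a transient occlusion cannot corrupt it. A frame-to-frame jump
above 15 px also flags the row. More than 10% flagged rows aborts with a
re-annotation error. On day frames the tracker runs on the single colour
channel with the largest intensity spread inside the initial box (green,
for a green plant on a blue background); night frames are channel-identical
so the same index applies.

Measured on the default day+night scenario suite (240 frames, 3 seeds ×
{white light, far-red}): junction/tip RMSE 0.42–1.17 px, zero lost frames,
error in the five frames after lights-off within 2× the day RMSE, and the
per-step peak within 1 px of an exhaustive NCC search.

## Kinetics

- *Relative series*: each metric minus the mean of its first five valid
  frames — flagged frames are skipped, not counted. Missing values stay
  missing; interpolation is deliberately left out of the pipeline.
- *Time sync*: replicate plants are aligned on the first day→night
  transition found in their illumination labels; that frame is assigned
  zt = lights-off (default 9 h) and the whole series shifts rigidly (no
  resampling). The day→night transition (not dawn) is used because
  treatments start in the light phase, making dusk the nearest shared
  anchor. Shifts beyond 30 min from the plant's nominal clock are flagged.
- *Angular speed*: backward difference over a 60-min window, reported in
  degrees/hour; the first window is undefined. A least-squares-slope
  variant is available via `method="slope"`. The difference form is the
  default because it is the simplest reading of "change over a period" and
  is exactly linear-exact.
- *Binning*: left-closed 2-h bins anchored at zt 0, per-plant means; bins
  with fewer than 10 valid frames are marked unreliable.

## Statistics

Plants are the experimental unit (per-plant bin means enter the tests).
One-way fixed-effects ANOVA for a lone treatment factor; two-way with
interaction when a genotype factor is present, using Type II sums of
squares — the conventional default for unbalanced factorials when the
interaction is not the primary target. Tukey HSD (studentized range)
provides pairwise adjusted p-values; at k = 2 it reduces exactly to the
pooled t-test, which the tests verify numerically.

Letters are assigned by insert-and-absorb: start with one letter covering
all groups; for each significant pair split every letter containing both;
absorb letters that become subsets. Groups are ordered by descending mean
(ties by input order), so the first letter lands on the largest group and
the output is deterministic. The letter-sharing relation provably equals
the non-significance relation; a brute-force clique-cover oracle checks
both the relation and that the letter count is achievable on random
6-group structures.

Statistics are computed per 2-h bin independently with no multiplicity
correction across bins — this mirrors how such kinetic panels are
conventionally presented and is a known caveat, not an oversight. Under a
seeded null simulation (k = 3, n = 10, 1000 reps) the measured type-I
error is within 5% ± 1.5%.

## The simulator

`leafsim` exists to give every downstream stage exact ground truth. It is
a kinematic stand-in, not a biophysical model: the petiole angle follows

    θp(t) = θ0 + A_d·sin(2π·zt/24) + dose·H·σ(m) + dose·A_osc·sin(·)·gate(t)

with σ a logistic ramp in minutes since treatment start
(σ(m) = 1/(1+exp(−k(m − m_onset)))) and gate a sin² envelope spanning each
night from the first lights-off — smooth at dusk and dawn so inter-frame
landmark motion stays bounded (≤ 3 px/frame for default scenarios, which
is what makes tracking well-posed at a ±20 px search radius). The lamina
angle responds with a configurable fraction (default 0.6) of the petiole's
treatment terms — the model exposes one amplitude parameter and scales it,
since organ-specific response amplitudes are scenario knobs, not claims.
Petiole length grows linearly, with the rate multiplied by
1 + dose·(multiplier − 1) under whole-plant far-red; lamina length always
grows at the untreated rate (far-red elongates the petiole, not the
lamina). Local tip-only far-red (FRt) drives the same angular response but
leaves elongation at the untreated rate.

Default conditions: 1 frame/min, 9 h light / 15 h dark, sequence and
treatment start at ZT 2, initial petiole 5.0 mm (the middle of the
4.5–5.5 mm selection window used when choosing leaves to image), initial
lamina 8.0 mm, hyponasty amplitude 15°, onset 180 min after treatment,
logistic rate 0.04/min, diurnal amplitude 4°, night oscillation 2° with a
90-min period (the oscillations' period and amplitude are placeholders —
real night-time oscillations have not been characterised numerically),
elongation 0.05 mm/h doubled by far-red, 0.05 mm/px, 640 × 480 frames,
sensor noise sd 3 gray levels. The 240-frame day+night test preset starts
at ZT 7 so that a short sequence still spans the ZT 9 dusk transition
(treatment anchoring stays at ZT 2). The parameter-recovery benchmark
disables the diurnal and oscillation terms so the relative petiole angle
saturates at exactly dose·H, making the ±1° recovery check a test of the
measurement pipeline alone.

Rendering: day frames are a blue background with the petiole as a thick
anti-aliased line and the lamina as a filled ellipse, both green; night
frames are single-channel (bright plant on dark ground, replicated to
R=G=B) emulating near-infrared imaging. The palette keeps the green
channel's plant/background polarity identical day and night, as a real
IR-lit night image of a bright leaf would. Anti-aliasing comes from 4×
supersampled drawing followed by exact box-average reduction; noise is
luminance-only (identical across channels), which preserves the
channel-spread day/night signature. Ground truth is written at full float
precision; sub-pixel coordinates are rounded only at rasterisation.

Day/night classification of real or rendered frames uses the mean
per-pixel channel spread (max − min over R,G,B) with an 8-gray-level
threshold: IR night frames collapse to ~0 spread; any coloured day scene
scores far above it.

## What the synthetic validation does not show

The simulator renders rigid, straight segments on clean backgrounds. Real
leaves curve (neither petiole nor lamina curvature is modelled — a known
limitation of three-point triangulation), overlap with neighbours, go out
of the focal plane, and live on cluttered backgrounds with shadows and
specularities. Passing the synthetic suite demonstrates the pipeline's
correctness and its accuracy under the stated imaging regime; it bounds,
but does not measure, performance on real imagery. The tracker contract is
behavioural (any appearance-based localizer meeting the accuracy
invariants), so swapping in a more robust localizer for hard field data
would not change any interface.

## Problem sizes used in validation

Geometry round-trip: 1000 random poses. Tracking: six 240-frame scenarios
(3 seeds × 2 treatments) plus a 15-frame noise-free sequence for the
exhaustive-oracle comparison. Parameter recovery: one 600-min scenario
(the logistic is saturated well before the end). Illumination: two full
1440-frame scenarios at noise sd 5. Statistics: 1000 null ANOVA
replicates, 20 Tukey/t comparisons, 200 random letter-display structures.
Determinism: a 20-frame scenario rendered and tracked twice, compared
byte-for-byte.
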