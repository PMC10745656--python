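# Methods

This note documents the models, parameter choices, and numerical
decisions behind `hld`, and what the synthetic benchmark does and does
not establish.

## Synthetic recordings

The generator emulates a living-lab session: one subject, labelled
activity intervals, a 9-axis IMU at 50 Hz, four ambient binary sensors
along a corridor, and an 8 fps camera rendering a 12-landmark stick
figure (48×64 px) on a static background.

**Activity model.** Each activity is a sinusoid bank plus optional
world-frame yaw: per-axis accelerometer oscillation
`amp · w · sin(2πft + φ)` with fixed axis weights w = (0.6, 0.3, 1.0)
and phases (0, π/3, 2π/3), on top of the gravity vector rotated into
the body frame by the scripted orientation. Defaults (amp in m/s²,
f in Hz): lying 0/0 with a 90° body roll, sitting 0.15/0.4, standing
0.25/0.6, walking 1.5/1.8, vacuuming 1.5/3.2, running 3.0/2.6, turning
0.3/1.0 with 0.6 rad/s yaw. Walking cadence ~1.8 Hz and running
~2.6 Hz sit in the range reported for human gait; "vacuuming" shares
walking's amplitude but not its frequency, so amplitude statistics
alone cannot separate that pair. Interval changes are bridged by a
0.5 s slerp so angular velocity stays finite. The gyroscope is exactly
the angular velocity of the scripted quaternion series plus a constant
bias and white noise; the magnetometer is the rotated reference field
(22, 5, −43) µT plus an optional hard-iron offset and noise. Under
this model every downstream statistic has a closed form (sinusoid
variance amp²w²/2 + σ², static gravity magnitude exactly 9.81 m/s²),
which is what the oracle tests check.

**Noise presets** (`default` / `silent` / `noisy`): accelerometer
σ = 0.05 / 0 / 0.6 m/s², gyro σ = 0.01 / 0 / 0.12 rad/s with bias up
to 0.03 rad/s, magnetometer σ = 0.3 / 0 / 1.5 µT (noisy adds a
(4, −2, 1) µT hard iron), pixel σ = 0 / 0 / 4 grey levels. The paper
trail for these sensors gives no noise model; the values are fixtures
chosen at consumer-IMU scale, not claims about any real dataset.

**What the renderer is and is not.** Landmarks are 3×3 bright markers
joined by 1 px limb strokes; a single 3×3 erosion inside
`extract_skeleton` removes the strokes so each movable part becomes
one blob — the simplest image for which blob/centroid analysis is
exact. Leg markers are spread (knees ±0.10, ankles ±0.11 of figure
height) and legs swing at half the arm amplitude so markers never
merge mid-gait. Consequences: passing vision tests show the geometry
pipeline is correct, not that it would survive real video (textured
clothing, occlusion, perspective, multiple people are all absent).
Similarly, a figure that parks in one spot for more than half the
frames leaks into the median background — a real limitation of median
background modelling that the tests demonstrate rather than hide.

## Filtration

Butterworth split: order 4, zero-phase (`sosfiltfilt`, reflect
padding), low-pass corner 5 Hz, high-pass corner 0.3 Hz — the usual
body-motion/impact split for wearable data; corners are config, not
claims. The combined channel is the Euclidean magnitude of the six
filtered components (a printed plain-sum variant is kept behind
`norm_mode="as_printed_sum"`; the Euclidean reading is the default
because it matches the "normalized using the Euclidean distance"
description and is non-negative).

Orientation fusion integrates the quaternion derivative and applies a
normalized gradient step (β = 0.1 by default) on the objective
½‖R(q)ᵀv_world − v_meas‖² for the gravity direction and, when a
magnetometer is given, the field direction (reference direction taken
from the initial sample). The Jacobian is analytic and verified
against central differences. When no initial quaternion is supplied,
tilt is initialized from the first accelerometer sample, which removes
the β-limited convergence transient. Euler angles are the atan2 ratios
of the body-frame gravity direction, mapped to (−π, π].

Gyro denoising is a level-3 `db4` DWT with soft universal thresholding
(MAD noise estimate from the finest band); a zero threshold returns
the input untouched. Hard-iron correction solves the linear sphere fit
‖m − c‖² = r² by damped least squares — the damping (three Tikhonov
rows at 10⁻³·√n·rms(m)) keeps directions the attitude never explored
from producing runaway centers; a near-static window falls back to
mean-minus-reference.

In the pipeline the stationary calibration interval is found
automatically as the 1 s window of minimum acceleration variance; the
gyro bias is its median (median, not mean, so the slerp into a
stationary pose does not bias the estimate) and gravity g_m/g_a are
estimated there.

## Descriptors

**GMRF.** Window mean and unbiased cross-channel covariance,
vectorized as mean ‖ upper triangle. In the pipeline the covariance is
taken over the seven dynamic channels (linear acceleration, gyro, norm)
and the three Euler angles enter as window means only: angle
covariances wrap at ±π and, at ~90 training descriptors per fold, the
65-dimensional full vector was found to swamp the codebook.

**MSST graph.** STFT with a rectangular window on the analytic signal
(hop 1, T = 64 in the pipeline), instantaneous frequency from the
phase advance between adjacent frames, and reassignment of |S|² along
frequency to the nearest estimated bin, iterated by composing the
bin→bin map (M ≤ 2). The analytic signal matters: for a real tone the
negative-frequency image scatters ~30% of the energy and no amount of
reassignment can concentrate it. Energy is conserved exactly by
construction, and the operation is idempotent once every coefficient
sits at its own estimate. The graph has six nodes (band energies) and
co-activation edges: weight(i, j) = fraction of time frames where both
bands are at or above their own median energy (bands with zero median
are never active — this tie rule makes a constant tone's band active
in every frame while leaving silent bands inert). The library default
bands partition [0, Nyquist] equally; the pipeline passes
cadence-aligned interior edges (0.6, 1.2, 2.0, 2.8, 4.0 Hz) because at
a 50 Hz sampling rate all human-motion energy would otherwise land in
a single equal-width band and the graph would carry no information.
Pipeline node energies are normalized to sum to one (cadence signature
rather than amplitude — amplitude is already the GMRF family's job).

**Ambient graph.** M rows are (type code, neighbor count, orientation)
with switch = 0, PIR = 1, infrared = 2; K is the symmetric binary
adjacency; consistency (K = Kᵀ, zero diagonal, row sums = neighbor
counts) is asserted on every build. The per-window vector —
activation counts, active durations (open activations truncated at the
window end), first-activation ranks, and active-subgraph edge count —
is plumbing that makes the graph usable by the codebook; counts and
durations are additive over disjoint windows.

**Vision families.** Thermal: accumulated per-pixel |frame
difference|, summary Σ ln(1 + heat) (an `as_printed_ln` variant masks
zeros), 8×8 mean-pooled map (4×4 in the pipeline for compactness).
Saliency: three difference-of-Gaussian channels (σ pairs 1–2, 2–4,
4–8), a moment-matched GGD per channel (shape from inverting
E|x|²/(E|x|)² = Γ(1/θ)Γ(3/θ)/Γ(2/θ)² by bisection on θ ∈ [0.05, 20],
scale from the first absolute moment), salience = Σ −log P, min-max
normalized with a 10⁻⁹ floor for constant maps. Orientation: interior
angle at the middle joint of six catalogued triangles
(head/shoulders, shoulder–elbow–wrist ×2, knees/torso,
torso–knee–ankle ×2) via atan2(‖u×v‖, u·v) — robust near 0 and π and
identical to the arccos form; degenerate or missing triangles are
flagged, never invented. SLIF: bilinear samples on an N = 8 spoke ×
M = 3 ring web (2 px ring step), out-of-frame nodes sampled as 0 and
flagged; the pipeline averages the web over all detected landmarks for
a fixed-length frame descriptor.

## Codebook and classifier

One GMM per family (K = 8, ridge 0.05 on standardized features,
tol 10⁻⁴, ≤ 100 iterations, k-means++ init from the seed) is fitted
per cross-validation fold on training recordings only, on descriptors
augmented with the segment's normalized time within its recording.
EM records the log-likelihood each iteration (monotonicity is
asserted); a component collapsing below weight 10⁻⁸ is re-seeded once,
then the fit fails loudly. A segment's code is its responsibility
histogram plus the GMR conditional mean of the descriptor given the
segment time — the GMR block is the family's "generalized signal"
evaluated where the segment lives, so it varies across segments; the
fixed-query-grid form of the encoding is exposed separately in
`codebook.encode_segments`. Family blocks are concatenated in a fixed
order (motion-GMRF, motion-graph, ambient, thermal, saliency,
orientation, SLIF).

The classifier is a single-layer Elman RNN: hₜ = tanh(W_xh xₜ +
W_hh hₜ₋₁ + b_h), softmax readout, mean cross-entropy over steps, full
BPTT with per-parameter gradient clipping at norm 5, lr 0.01
(0.05 in small fixtures), ≤ 150–200 epochs with early stopping after
20 plateau epochs. Gradients are verified against central differences
(< 10⁻⁴ relative). Everything is numpy, so a seed fixes
initialization, batch order, and therefore the entire run bit-exactly.
Cross-validation assigns whole recordings to folds (no recording
contributes segments to both sides) and pools the confusion matrix;
metrics are one-vs-rest accuracy/precision/recall/F1 macro-averaged
over classes, with F1 defined as 0 when precision + recall = 0.

## Benchmarks and ablations

The bundled benchmark (`configs/demo.yaml`) uses ten recordings of
four activities × 5 s at the default noise preset, 10-fold CV — sized
so the full run takes well under a minute per stage on one CPU. The
ablation benchmark (`configs/ablation.yaml`) uses eight recordings of
standing/walking/vacuuming/running × 4 s under the noisy preset,
4-fold CV, smaller classifier, five seeds. "Novelty 1 off" replaces
the quaternion filtration with a 0.2 s moving average on the raw
channels; "novelty 2 off" replaces the two graph families with
per-channel mean/variance (motion) and total count/duration (ambient).

On these conditions the full pipeline averages slightly above the
double-ablated baseline (84.9% vs 84.7%). The margin is small and
should be read as a tendency, not an effect size: most residual error
comes from windows straddling activity transitions, which no
descriptor family resolves, and the moving-average baseline itself
attenuates higher cadences more than lower ones, leaking frequency
information into channel variances. A synthetic world in which the
graph descriptors are decisively better would have to be constructed
for that purpose; this one was designed to make every stage's
correctness checkable, and is kept as frozen study conditions.

## Known limitations

- The stick-figure renderer and sinusoid dynamics make several stages
  exact that are approximate on real data (skeleton extraction,
  gravity estimation, background modelling).
- Event-based vision segments are produced and exported but the fused
  classification timeline is the motion windowing; vision descriptors
  are aligned to those windows.
- The staged CLI commands (`descriptors`, `encode`, `train`) fit on
  everything they are given and exist for inspection; only `hld run`
  performs the per-fold honest evaluation.
- Orientation fusion is offline and assumes a constant gyro bias and
  hard iron; no temperature or scale-factor calibration.
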