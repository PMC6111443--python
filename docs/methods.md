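# Methods

## Problem and pipeline

`emgdays` studies how well hand-motion classifiers trained on surface EMG
from one recording session transfer to other sessions and other days.
Day-to-day nonstationarity — electrode re-donning displacement, skin
impedance and gain changes — is the dominant failure mode of pattern-
recognition myoelectric control, and the package quantifies it by running
the same classifiers under four cross-validation protocols of increasing
severity: within-session, between same-day sessions, between every pair of
days, and leave-one-day-out.

The recording model is an 8-electrode forearm ring sampled at 200 Hz.
A session comprises 10 repetitions of each of 7 movement classes (rest RT,
close/open hand CH/OH, wrist flexion/extension WF/WE, pronation PRO,
supination SUP), each cue a 4 s contraction followed by 4 s of relaxation,
cue order randomized per session; the full study design is 2 sessions per
day over 15 days.

Preprocessing: a causal third-order Butterworth high-pass at 2 Hz (movement
artifact removal), trimming of the first and last 0.5 s of every movement
segment (transition artifacts), then overlapping 150 ms windows with a
25 ms step — 30 × 8 samples per window at 200 Hz. Windows never cross
segment boundaries, so every window carries exactly one label.

Two input representations feed the classifiers:

* **Time-domain features** (LDA, SSAE-f): the four Hudgins descriptors —
  mean absolute value, waveform length, slope-sign-change count and
  zero-crossing count — per channel (4 × 8 = 32 values). The SSC/ZC
  threshold is 0; with strict product inequalities, exact zeros never count.
* **Raw windows** (SSAE-r, CNN): the 30 × 8 samples themselves.

## Classifiers

**LDA.** Pooled-within-class-covariance Gaussian discriminant with class-
frequency priors. The pooled covariance receives a fractional ridge
(`ridge * trace(S)/D` on the diagonal, default `ridge = 1e-6`) so the
stabilization is invariant to amplitude units. LDA consumes unscaled
features (it is affine-invariant).

**Stacked sparse autoencoders.** Two sigmoid-encoder / linear-decoder
layers pretrained greedily on the reconstruction objective

J = 1/(2W) Σ‖x − x̂‖² + (l2r/2)‖W‖² + sr Σⱼ KL(sp ‖ ρ̂ⱼ),

with l2r = 1e-4, sr = 0.01, sp = 0.5, ρ̂ⱼ the mean activation of hidden
unit j, and ρ̂ clamped to (1e-8, 1 − 1e-8) to keep the KL term finite.
Layer sizes are 32/16 for the feature input (SSAE-f) and 100/50 for the
raw input (SSAE-r). A softmax head is then trained supervised with
cross-entropy on the frozen layer-2 encodings; an optional joint fine-tune
pass exists but is off by default. All optimization uses Møller's scaled
conjugate gradient (σ₀ = 5e-5, λ₀ = 5e-7), stopping at 400 iterations per
layer or gradient norm < 1e-6, whichever comes first. Input scaling is
learned on training data only: per-feature min-max to [0, 1] for SSAE-f
(the sigmoid encoder's operating range), per-channel z-scores for SSAE-r.

**CNN.** A single valid (unpadded) 3 × 3 convolution with 32 filters over
the z-scored 30 × 8 window (→ 28 × 6 × 32), ReLU, 3 × 1 max pooling with
stride equal to the pool size and floor division (→ 9 × 6 × 32), flatten,
fully connected to 7 logits, softmax. Parameter counts (320 conv,
12 103 FC) are pinned by tests. Training is SGD with classical momentum
(v ← 0.95·v − 0.1·∇, w ← w + v), L2 weight decay 0.001 on weights (not
biases), shuffled batches of 256, a fixed budget of 25 epochs, no early
stopping and no validation split. Weights initialize as zero-mean
Gaussians scaled by 1/√fan-in from a seeded generator; autoencoder weights
use symmetric uniform fan-based limits.

Everywhere, the predicted label is the argmax with ties broken toward the
lower class index, and all three families implement the same
`fit(X, y)` / `predict(X)` contract so the evaluation protocols treat them
interchangeably.

## Evaluation protocols and metric

The metric is classification error, CE = wrongly classified windows /
total windows (CA = 1 − CE). Folds:

* **within_session** — k-fold by repetition index (k = repetitions per
  movement, 10 in the full protocol). Partitioning by repetition rather
  than by random window is the only leakage-safe choice given 83%-
  overlapping windows: all windows of a repetition stand or fall together.
* **between_sessions** — train one same-day session, test the other, swap.
* **pair_of_days** — for each unordered day pair, train all of one day and
  test the other, both directions; the two fold CEs are averaged into the
  pair's single cell value (n days → n(n−1)/2 pairs).
* **leave_one_day_out** — train on all other days (both sessions), test on
  the held-out day.

A classifier is retrained from scratch per fold with a fold-derived seed;
nothing is adapted across folds. Tests audit provenance metadata to prove
that no test repetition/session/day ever contributes training windows.

## Statistics

Classifier comparisons use a balanced fixed-effects two-way ANOVA with
classifier and time level (days or sessions) as factors and subjects (or
folds) as replicates; with one replicate per cell the additive model is
fitted and the interaction stratum serves as error. The decomposition is
computed in closed form for the balanced case (the design is balanced by
construction) and is cross-checked against statsmodels in the tests. Post
hoc comparisons of classifiers use Tukey–Kramer HSD on the residual mean
square, with adjusted p-values and simultaneous intervals from the
studentized-range distribution (evaluated numerically by scipy). α = 0.05;
CE values enter untransformed.

Under the null, the classifier-factor F test's type-I error is verified at
0.05 ± 0.01 over 2 500 simulated balanced 4 × 15 × 7 tables.

## Synthetic multiday generator

No public multiday armband corpus with this session structure exists, so
the generator produces datasets with the statistical structure the
analyses assume:

1. per channel, a carrier of zero-mean Gaussian noise band-pass filtered
   to 20–95 Hz (surface-EMG energy concentrates above 20 Hz; 200 Hz
   sampling caps content below 100 Hz) and normalized to unit variance;
2. per repetition of class c, the carrier on channel k is multiplied by
   `synergy[c, k′] · envelope(t)`, where the envelope is a trapezoid
   (0.5 s ramps) spanning the contraction and k′ indexes the day's
   fractionally rotated synergy row;
3. each channel is multiplied by the day's gain `exp(N(0, day_gain_sd))`;
4. white noise of SD `noise_floor_sd` is added everywhere (relaxation and
   rest are noise floor only);
5. each repetition is scaled by `exp(N(0, rep_amp_jitter_sd))`.

The synergy matrix (7 × 8, rest row zero) uses unit-height circular
Gaussian bumps (width 1 channel) at evenly spaced ring positions for the
six active movements, mimicking distinct muscle groups under the ring.
Day-to-day electrode displacement is modeled as a fractional circular
rotation of the synergy rows (`day_shift_sd`, in channel units, linear
interpolation between adjacent integer shifts) — the natural geometry for
an electrode ring around the forearm. Same-day sessions share the day's
draw plus a session-level jitter whose SDs are scaled by
`session_jitter_scale < 1`, encoding the assumption that same-day sessions
resemble each other more than different days do.

Defaults (arbitrary units throughout; no attempt to match millivolt
ranges): `noise_floor_sd = 0.2`, `day_shift_sd = 0.6`, `day_gain_sd = 0.2`,
`session_jitter_scale = 0.3`, `rep_amp_jitter_sd = 0.1`. These were chosen
once so that the baseline LDA reproduces the magnitude structure reported
for real multiday recordings — within-session CE below a few percent,
pairwise-day CE in the 10–25 % range, day drift clearly dominating session
drift — and are not adjusted per experiment.

**What the generator does not emulate.** Real surface EMG is super-
Gaussian and spiky (motor-unit action-potential trains), carries force-
proportional amplitude and fatigue-related spectral compression, and its
class structure is not purely an amplitude pattern across channels. Two
consequences matter for interpreting results. First, the synthetic classes
are more cleanly separable than real ones: within-session CE here is
~0.1–1 %, below the ~2 % typical of real recordings. Second, raw-input
methods are handicapped more than in reality: for a stationary Gaussian
carrier, class information lives entirely in second-order statistics,
which a sigmoid layer of linear projections captures only weakly, so
SSAE-r sits near the chance ceiling here (it was also clearly the worst of
the four on real data, but not that weak). Passing drift tests therefore
demonstrate the *protocol structure* (day effects, ordering, monotonicity),
not absolute error levels of real EMG.

## Numerical and design choices

* Sample intervals are 0-based half-open `[start, end)`; storage is one
  file per session (every protocol partitions at session granularity);
  annotations store full contraction extents — trimming is a preprocessing
  step, not a storage property.
* Filtering is causal single-pass by default (honors the stated filter
  order exactly and matches online prosthesis use), with state initialized
  to the steady-state response to the first sample; a zero-phase
  forward-backward option sits behind a flag.
* Window length rounds half-up from ms to samples (exact at 200 Hz: 30 and
  5 samples).
* The CNN uses valid convolution and pool stride = pool size with floor
  division; max-pool gradient routes through the first maximum on ties.
* SCG treats indefinite curvature by Levenberg–Marquardt inflation, per
  Møller; non-finite losses raise with the iteration index.
* Degenerate ANOVA tables (zero residual variance) are flagged and report
  nothing as significant rather than dividing by zero.
* One global seed fans out to components by name hashing (SHA-256), so any
  stage can be rerun independently yet reproducibly; identical config +
  seed yields byte-identical datasets and result files.

## Problem sizes used in tests and the acceptance script

Full-protocol studies are expensive to simulate repeatedly, so the test
suite and `scripts/acceptance.py` run structurally complete, scaled-down
studies: 2–3 days × 2 sessions with 10 repetitions and 1–2 s contractions
for drift experiments (50–100 ms window steps), 15 short-cue days for
protocol-arithmetic checks, and reduced SCG budgets (100–150 iterations)
for the autoencoders. The drift experiments average over 3–5 generator
seeds. These sizes are stated here as the package's fixture choices; the
generator's drift and noise defaults are used unchanged except where a
test explicitly studies zero drift.

## Known limitations

* Synthetic data only; see the generator caveats above. Absolute CE values
  are not comparable to real recordings, and SSAE-r's near-chance level is
  a generator artifact in degree (though its last-place ranking matches
  what real data shows).
* Subjects enter the ANOVA as replicates, not as a factor; no
  repeated-measures or mixed-effects modeling.
* No majority-vote post-processing, confusion matrices, online adaptation
  or recalibration strategies — deliberately out of scope.
* The CNN and SSAE run on plain numpy; they are sized for this problem
  (tens of thousands of windows), not for GPU-scale architectures.
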