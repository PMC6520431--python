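# Methods

## Task and cohort model

The paradigm is a continuous performance task with three difficulty levels.
A session is 60 contiguous rounds of 30 s in the fixed order
easy-medium-hard repeated 20 times, giving 20 rounds (600 s) per condition
per subject and a balanced label design by construction. The default cohort
has 14 subjects.

Because no recordings of this paradigm are publicly available, the package
ships a generative model of the cohort. It is a *statistical emulator*, not
a biophysical simulation: its purpose is to give every downstream stage a
signal with the structure the analysis assumes, with known ground truth.

Each channel of the 16-electrode 10–20 montage (Fp1, Fp2, F7, F3, F4, F8,
C3, C4, CP5, CP1, CP2, CP6, P3, P4, O1, O2) is generated as

```
x(t) = b · n_1/f(t) + Σ_band sqrt(P_band · g_cond(ch,band) · s_subj(ch,band)) · u_band(t)
```

where `n_1/f` is Gaussian noise with a 1/f^α amplitude spectrum (α = 1,
shaping flattened below 0.1 Hz to avoid unbounded drift; rms b = 5 µV),
`u_band` is unit-variance white noise band-passed into each analysis band
(4th-order Butterworth, forward–backward), `P_band` are base powers in µV²
(δ 10, θ 6, α 8, β− 3, β+ 2, γ− 1, γ+ 0.6 — a plausible resting profile
decreasing with frequency), `g_cond` is the planted condition gain and
`s_subj` a per-subject, per-channel-band log-normal gain (σ = 0.25) drawn
once per subject. Per-sample gain envelopes follow the round labels, so
condition effects switch at round boundaries.

### Planted effects

The default effect specification plants the spectral correlates of
attentional load this kind of analysis is expected to find, with gains
relative to the easy condition (easy/medium/hard):

| effect | channels | band | gains |
|---|---|---|---|
| prefrontal theta ↑ | Fp1, Fp2, F3, F4 | θ | 1.0 / 1.3 / 1.6 |
| broad gamma ↑ | all 16 | γ−, γ+ | 1.0 / 1.15 / 1.3 |
| central high beta ↑ | C3, C4 | β+ | 1.0 / 1.2 / 1.4 |
| fronto-central alpha ↓ | C3, C4, CP1, CP2 | α | 1.0 / 0.85 / 0.7 |

Only the *directions* of these correlates are established findings; the
magnitudes are this package's choices, set once so that pairwise LOSO
accuracy on default cohorts lands in the 70–90 % range reported for this
kind of paradigm at 5 s epochs. The medium condition is placed between easy
and hard on every effect, which is why easy-vs-hard is the easiest
discrimination and medium-vs-hard the hardest — the ordering the tests
assert.

### Blinks

Blinks are smooth unipolar bumps (squared Hann, 300 ms, 120 µV peak)
projected through a fixed frontal-dominant mixing vector (Fp1 = Fp2 = 1,
frontal neighbors 0.12–0.15, elsewhere ≤ 0.04; ≥ 60 % of the L1 mass on
Fp1/Fp2 by construction). Blink times are Poisson within rounds at
18/14/10 blinks/min for easy/medium/hard — the decrease with difficulty
emulates the reduced blink rate of visually engaged subjects and makes
blink count a *confound* of the label, which is exactly why the removal
stage exists and is tested against the injected ground truth.

### What the generator does not model

No volume conduction or head geometry (channels are statistically
independent up to their shared condition structure), no EMG or movement
artifacts, no arousal/fatigue drift across the session, no inter-channel
correlation of the background. Passing tests therefore demonstrate that the
*pipeline* recovers planted structure under realistic noise levels — not
that real EEG carries that structure.

## Signal processing

Band-pass 0.5–90 Hz and band-stop 48–52 Hz, both 3rd-order Butterworth
applied forward–backward (`sosfiltfilt`): exactly zero phase, effective
magnitude order 6. The notch width is a package choice; only "around
50 Hz" is specified by the method this implements. Filtering precedes
segmentation so filter transients never sit at epoch boundaries.

## SOBI and blink removal

Standard SOBI: center, whiten by eigendecomposition of the sample
covariance (components dropped below a 1e-10 relative eigenvalue
threshold), symmetrized lagged covariances at lags 1…50 samples, and
orthogonal approximate joint diagonalization by Jacobi rotations
(rotation-angle tolerance 1e-8, max 200 sweeps; non-convergence is flagged
on the model, not raised). Lags 1–50 at the working rate are common SOBI
practice; separation quality is validated with the Amari index on AR
mixtures rather than assumed.

Blink components are flagged automatically: mixing-column L1 fraction on
{Fp1, Fp2} ≥ 0.60 **and** source power fraction below 5 Hz ≥ 0.70. The
reference method implies manual component selection; an automated criterion
was chosen so runs are reproducible, and both thresholds are configurable.
Reconstruction zeroes flagged sources and remixes; with nothing flagged it
is the identity to numerical tolerance.

## Features

Epochs are cut from each round start, non-overlapping, remainder discarded;
supported lengths 1/3/5/10/30 s. Band power uses a Hann window and the
one-sided periodogram normalized by the window's sum of squares; absolute
power sums bins whose center frequency lies in the half-open band
[lo, hi), and relative power divides by the total over [1, 45). The
half-open convention makes the seven bands an exact partition of [1, 45),
so relative powers sum to 1 per channel — an invariant the tests assert at
1e-9. Any consistent periodogram scaling cancels in relative power.
Epochs with zero total power on any channel are excluded with a warning.

## Selection: OFR with random probes

Features are standardized (training-fold statistics only) and ranked by
orthogonal forward regression: select the candidate with maximal squared
cosine to the residual target, orthogonalize remaining candidates and the
target against it, repeat. For the three-class target two Helmert contrast
columns are used and relevance is the squared cosine to the subspace they
span, which keeps relevance in [0, 1]. Ties break to the lowest column
index; candidates whose residual norm falls below 1e-12 are dropped.

Retention is the random-probe rule: 100 iid standard-normal probes join the
ranking, and a true feature is kept only if fewer than
(1 − 0.95) · 100 = 5 probes were selected before it; the first violation
stops retention, so kept features are a prefix of the ranking. 100 probes
resolve the 95 % quantile with integer granularity. Under an all-noise
null this calibrates the expected false-selection fraction near 5 %
(asserted ≤ 7 % over 200 runs).

## Classification and evaluation

LDA with pooled within-class covariance, equal priors, and a diagonal load
of ridge · trace(S)/d with ridge = 1e-6 — plain LDA in effect, but immune
to singular folds when k approaches the fold sample count. "Best
threshold" sensitivity/specificity maximizes balanced accuracy over all
score midpoints, computed on held-out scores pooled across folds; balanced
accuracy was chosen because the class design is balanced and it makes the
perfect-separation and null cases exact.

LOSO: for each held-out subject, standardization, probe-guarded selection
and LDA fitting use the remaining subjects only; accuracy-vs-k curves are
averaged over folds and the headline accuracy is the best point of the mean
curve. If a fold retains no feature, the single top-ranked feature is used
so the classifier is always defined (on null data this is still
chance-level by construction). Null (chance-level) calibrations report the
mean of the whole fold × k accuracy matrix instead of the best-k point,
since maximizing over k on null data would bias the estimate upward.

## Problem sizes

Desk-scale defaults used by the test suite and the acceptance script, as
the package's own choices: synthesis at 250–500 Hz (all features live
below 45 Hz; the hardware rate of such studies, 2 kHz, is available by
config), cohorts of 14 subjects with 4–20 cycles, null calibrations with
14 subjects × 120 epochs × 20 features over 20 master seeds, probe-null
calibration over 200 runs, SOBI validation over 50 seeded recordings, and
planted-effect recovery over 10 full-pipeline cohorts.

## Known limitations

* The generator's independence across channels makes SOBI's job easier
  than on real EEG, where volume conduction mixes every source into every
  channel; the blink source is the only genuinely mixed component.
* Single-feature accuracy maps are computed per fold with no selection
  step, so they are directly comparable across features but not identical
  to a map built from features pre-selected on all data.
* The CPT "player" is a delayed proportional controller; it reproduces the
  monotone containment-vs-speed relationship the calibration needs, but no
  aspect of human motor learning or fatigue.
* EDF export quantizes to 16 bits over a per-channel symmetric range
  (error ≤ one digital step, verified against an independent reader).
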