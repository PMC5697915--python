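# Methods

`replaykit` re-implements, as a tested pipeline with simulated ground truth,
the standard analysis chain for awake hippocampal replay on a linearized
Z-track: directional place-field estimation, Bayesian position decoding,
multi-unit burst detection at reward-site stops, constant-velocity line
fitting of decoded trajectories with a ratemap-rotation null, engaged versus
disengaged behavioral-state comparisons, grid–place replay coherence, LFP
ripple/theta analysis, and decision-tree prediction of upcoming choice
accuracy from reactivation content.

## Track model and coordinates

The Z-track is linearized to 600 cm: arm 1 `[0, 190)`, the diagonal arm 2
`[190, 410)`, arm 3 `[410, 600]`, corners at 190 and 410 cm.  Positions are
binned at 2 cm (300 bins per running direction; bin *b* covers `[2b, 2b+2)`
cm).  The final 10 cm at each track end and ±5 cm around each corner are
excluded from ratemaps and decoding (animals eat and groom there).  A bin is
excluded iff its *center* falls in an excluded zone; with the half-open
corner zones `[corner−5, corner+5)` this yields exactly 20 excluded bins per
direction.  Corner 1 is adjacent to arms 1 and 2, corner 2 to arms 2 and 3;
the diagonal arm is adjacent to both corners.

## Ratemaps and place cells

Dwell time and spike counts are accumulated per direction over samples with
running speed ≥ 10 cm/s (speed: central difference of the 50 Hz positions,
boxcar-smoothed over 0.4 s — the same estimate gates the 3 cm/s immobility
criterion).  Both histograms are smoothed with a Gaussian kernel (σ = 5 bins,
truncated at ±4σ, no wrap across the track ends) before division.  The
kernel is renormalized per *source* bin over unmasked bins, so smoothing
conserves total spikes and total dwell exactly and no mass leaks into masked
bins; a flat field stays flat.  Bins without smoothed dwell are masked.  A
cell is a place cell if, in either direction, it fires strictly above its
dwell-weighted mean rate for ≥ 20 contiguous unmasked bins (masked bins break
contiguity) and its peak exceeds 1 Hz (strict).  Session validity is checked
by decoding running position in 500 ms windows (maximum posterior, direction
taken from the majority of samples in the window); a session whose median
absolute error exceeds 30 cm (5% of the track) is flagged for exclusion.

## Bayesian decoder

Memoryless Poisson likelihood with uniform prior:
`P(x|n) ∝ Π_i f_i(x)^{n_i} · exp(−W Σ_i f_i(x))`, computed in log space with
a 0.01 Hz rate floor inside the logarithms (configurable).  Three modes:

- **Event-summed** (arm-level classification): one window per event, both
  directions decoded and normalized *jointly* over the concatenated 600-bin
  space so the six (arm × direction) sums are commensurable.  Winner ties
  are broken lexicographically (arm index, outbound first) and flagged.
- **Trajectory**: 10 ms bins spanning the event (a final partial bin is
  retained); each non-empty row normalized to one, zero-spike rows zeroed so
  they contribute nothing to line fitting or coherence.
- **Running decode**: 500 ms windows for the validity check.

## Event detection and stop segmentation

Multi-unit activity of the place-cell ensemble is binned at 1 ms, smoothed
with a Gaussian (σ = 5 ms), and converted to a rate.  Candidates are periods
above the session mean + 3 SD (baseline over the whole session, running and
stops), extended outward to the mean-crossings.  Events shorter than 40 ms,
with mean speed ≥ 3 cm/s, or with midpoint outside a corner stop are
rejected.  Trajectory analysis additionally requires
`max(ceil(0.15 · ensemble), 6)` distinct active cells.  Corner stops shorter
than 10 s are wholly "engaged"; otherwise the first and last 5 s are engaged
and the interior disengaged; sections under 2 s are dropped.  Events take
the section containing their midpoint.

## Line fitting and the spatial shuffle

A trajectory event's posterior is scored against lines `x(t) = V·t·T + c`
(T = 10 ms, t indexing bins from 0 at the event start) on the exhaustive
grid V ∈ ±[2, 50] m/s step 0.5 (open interval (−2, 2) excluded, ±2 kept) and
c ∈ [−15, 21] m step 0.01 — 194 × 3601 candidates.  The score is the
posterior mass within 30 cm of the line (inclusive), divided by the total
mass.  Every grid line lands on exact multiples of 5 mm per time step, so
band membership is decided in integer arithmetic: the search is exact, and
the implementation (prefix sums + strided accumulation) is verified
bit-for-bit against a nested-loop oracle.  The direction whose normalized
score is higher wins; exact ties are broken at random (seeded) and flagged.

Significance: each cell's chosen-direction ratemap is rotated independently
by a uniform shift in [1, L−1] bins with wraparound, the event re-decoded
and re-fit; 100 shuffles, add-one p-value `p = (1 + #{shuffle ≥ obs})/101`,
replay iff p < 0.025.  Shuffles re-fit only the chosen direction.  Labels:
congruent iff the chosen direction matches travel; local iff the posterior
mean position is within 60 cm (inclusive) of the animal; forward iff V > 0;
prospective iff the mean position is ahead along the current heading.
Trajectory-level chance comes from reassigning events to engaged/disengaged
periods (100 permutations preserving group sizes); arm-level chance from the
cell-identity shuffle (active cells' spikes reassigned without replacement
to maps of cells inactive in the event, 100 repeats).

## Statistics

Proportions and means are bootstrapped (10,000 resamples with replacement);
95% CI from the 2.5/97.5 percentiles; one-sided tests (the hypotheses are
directional): significant against chance when > 97.5% of the bootstrap
distribution exceeds it, and between sections when > 97.5% of paired
bootstrap differences exceed zero.  The engagement × accuracy interaction
bootstraps the four cells independently, forms (correct − error)
difference distributions per section, and asks whether the engaged
differences exceed the disengaged ones.  Distribution comparisons use the
two-sample Kolmogorov–Smirnov test.  No multiple-testing correction is
applied; raw p-values are reported.

## LFP

The 1.2 kHz LFP is band-pass filtered (theta 6–12, delta 2–4, ripple
150–250 Hz) with a symmetric FIR filter applied once with centered output
(zero phase by symmetry; Hamming design, transition width capped at half the
low edge and a third of the bandwidth, ≈ 53 dB stop-band).  Instantaneous
power is the squared modulus of the Hilbert analytic signal — an in-band
sinusoid of amplitude A yields A².  Ripples: power > mean + 2.5 SD
(whole-session baseline), boundaries at mean-crossings, gaps < 40 ms merged,
duration filtered to [40, 500] ms.  The oscillatory state is indexed by
log(theta/delta) power (floored at 1e−12); the immobility control keeps
events at least 1 SD below the running mean.  Coherence uses Welch-averaged
magnitude-squared coherence up to 200 Hz; the alternative analysis
correlates spectrogram power between all frequency pairs.  Event-level
"ripple power" is the mean ripple-band power over the event (the
log(ripple/theta) variant is available behind a config switch).

## Grid–place coherence

For significant replay events containing at least one grid spike (whole
event), a posterior is decoded from grid spikes alone and scored against the
*place-cell* best-fit line with band half-width x/2, where x is the mean
grid-field extent on the track (ground truth in simulation; an estimator
from linear-track grid maps is provided).  Chance: 100 random pairings with
non-concurrent place-cell lines from the same session (with replacement,
flagged, if fewer than 100 exist); coherent iff the observed score beats the
97.5% rank of the shuffle distribution under the add-one rule — the
interpolated percentile of a finite shuffle sample is anticonservative
(~3% type-I at 100 shuffles), whereas the rank rule stays at or below the
nominal 2.5%.  The interpolated percentile is still reported, and the
population chance line is the mean of all shuffle scores.

## Prediction

Per event: congruence `(Pc − Pi)/(Pc + Pi)` (posterior mass on the congruent
vs incongruent running direction), locality `(Pl − Pr)/(Pl + Pr)` (mass on
arms adjacent vs remote to the animal, both directions pooled, computed
regardless of congruence), and mean ripple-band power.  A CART decision tree
(Gini, scikit-learn defaults) predicts correct vs error.  Correct events are
subsampled to the error count; 10 subsample iterations × 10-fold
cross-validation (stratified, avoiding one-class folds at small n — a
deliberate deviation from plain random folds), accuracy pooled over folds.
Null: 100 outcome-label permutations per iteration (1,000 accuracies; the
predictor columns are never permuted against each other); add-one p-value.
Events with undefined measures are dropped and counted.

## Synthetic sessions

The generator emulates the task: alternating outbound/inbound traversals at
40 cm/s (speed noise SD 4 cm/s), corner stops with exponential durations
(mean 10.71 s, truncated below at 3 s — reproducing the heavy tail of long
disengaged stops), 3 s end stops, 22 traversals by default, and 50 Hz
tracking with 0.5 mm jitter during immobility.  Ensembles default to 40
place cells (field centers uniform, σ 7.5–15 cm, peaks 2–20 Hz, inbound and
outbound fields drawn independently) and 8 grid cells (Gaussian field trains,
period 80–120 cm, field size 40 cm).  Running spikes are inhomogeneous
Poisson from the direction-appropriate tuning; stops carry a low baseline
(default 0.4 Hz/cell, exposed as a parameter since no empirical value is
fixed).

Replay injections realize exact ground-truth lines: per corner stop, events
arrive at 0.25 Hz (non-overlapping, ≥ 0.3 s apart), are congruent with the
current run with probability 0.62 (engaged) / 0.52 (disengaged), local given
congruent with 0.81 / 0.71, forward with 0.76 / 0.53 — the study's observed
content biases, fixed as generator conditions.  Trajectories use |V| ∈
[5, 12] m/s on the 0.5 m/s grid, durations of 20–30 decoding bins, span ≥
1.2 m (twice the scoring band, so velocity is identifiable), intercepts on
the 1 cm grid, confined to one arm and kept 10 cm clear of masked zones
(where the decoder carries no mass).  Cells whose field center lies within
5 cm of the path fire two spikes snapped to the decoding bin nearest their
line-crossing time — this makes the fitted intercept unbiased under the
bin-left-edge time convention of the line score.  Grid cells are yoked to
the place line during disengaged events only (configurable), firing where
the line crosses their fields.  The LFP is a sum of band-limited sinusoids
(theta 8 Hz, attenuated ×0.5 during immobility; delta 3 Hz; white noise) —
no 1/f background, so band powers have analytic targets — plus 100 ms
Hann-windowed 200 Hz ripple bursts coincident with 80% of injected events.
Turn outcomes are Bernoulli with base error rate 0.1, scaled by
(1 ∓ congruence_effect) according to whether the stop contained engaged
congruent content.

What the generator does *not* emulate: multimodal or skewed place fields,
theta phase precession and theta sequences, spike-sorting noise, 1/f LFP
background, camera artifacts, and behavioral variability beyond speed noise.
Passing tests therefore demonstrate correctness of the analysis chain on
data satisfying its assumptions, not robustness to every pathology of real
recordings.

## Numerical choices and problem sizes

- Rate floor 0.01 Hz in decoder logs; power floor 1e−12 before log ratios.
- "Within 30 cm" / "within 60 cm" are inclusive; place-cell and significance
  thresholds strict.
- The test-mode configuration coarsens the intercept grid to 0.05 m and the
  bootstrap to 2,000 resamples for continuous-integration speed; all rules
  are unchanged.  Full-resolution grids are the default.
- Test and acceptance runs use sessions of 10–16 traversals, 40–60 cells,
  ~150–300 injected or null events per check, 1,000 simulations for CI
  coverage, and the full 1,000-accuracy permutation null for prediction —
  sizes at which every binomial tolerance is computed at the simulated n.
- Shuffle p-values use the add-one estimator, so p ≥ 1/(n_shuffles + 1) and
  a result can never be "p = 0".

## Known limitations

- The arm-sum winner is not strictly invariant to joint scaling of spike
  counts and window (sharpening the posterior can flip marginal winners);
  the cell-ID chance level is stable to within a few events.
- Short events (span comparable to the 60 cm band) admit whole families of
  perfect-score lines; (V, c) are then identified only up to that family.
  The generator's injections are constructed above this degeneracy.
- With very few behavioral errors the prediction stage balances classes at
  the error count; below two errors per section it reports nothing.
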