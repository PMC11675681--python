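# Methods

## Problem and data model

The package analyses the relation between the beat-to-beat heart rhythm and
expert-scored sleep. Its inputs are, per subject, an RR-interval series
(milliseconds per beat, with per-beat normal/artifact annotations) and a
hypnogram (contiguous bouts of W, N1, N2, N3, R starting at 0 s). RR values
must lie in (0, 5000) ms; values outside the (200, 3000) ms plausibility
window are retained but auto-flagged as artifacts. The default artifact
policy is `split`: the series is broken at every flagged beat so that no
successive-difference pair, Poincaré pair or monotone run ever spans an
edited beat (runs are defined on consecutive sinus beats). A `drop` policy
(concatenate neighbours) is available; real studies differ on this point and
neither choice is canonical.

## Windowing and labels

Recordings are cut into consecutive half-open 5-min windows
[k·300, (k+1)·300); a beat belongs to the window containing its onset and a
trailing partial window is dropped. Per window, each stage receives the
fraction of the window it occupies, rounded half-up to one decimal (so the
rounded fractions sit on a 0.1 grid and may sum to 0.9–1.1).

* *Certain stage*: indicator 1 iff the stage's fraction is ≥ 0.7 (inclusive;
  at most one stage can be certain).
* *Transitions* (seven modeled pairs: N1–N2, N2–N3, N2–R, N3–N2, N3–R,
  R–N2, W–N1): for pair (S, E) at segment t,
  * rule A: frac_S[t] > 0 and 0 < frac_E[t] ≤ 0.6 and
    frac_E[t] ≥ frac_E[t−1], with frac_E[−1] := 0 so the rule can fire at
    the first segment;
  * rule B: frac_S[t] > 0, frac_E[t] = 0, and the next segment has
    0 < frac_E[t+1] ≤ 0.6 (the last segment cannot fire rule B).

  The rules are applied literally; both directions of a pair may fire in
  adjacent segments, and a segment may carry a certain-stage and a
  transition label simultaneously — filtering, if desired, belongs to the
  modeling layer.

## Descriptors

All descriptors are computed per 5-min segment.

**Poincaré geometry.** For consecutive pairs (x_i, x_{i+1}) define
d_i = (x_{i+1} − x_i)/√2 (signed distance from the identity line) and
s_i = (x_i + x_{i+1} − 2·x̄)/√2 (position along it; x̄ is the mean over all
plot coordinates). SD1² and SD2² are the *raw second moments* (divisor N,
no re-centering) of d and s. This convention is deliberate: it is the one
under which the asymmetry partitions below hold exactly, and for stationary
series it differs from the centered versions only by O(1/N). SDNN is the
ordinary standard deviation of the intervals (sample divisor n−1 by
default, population divisor configurable); the *plot-based* total variance
(SD1² + SD2²)/2 is the quantity that partitions exactly.

**Asymmetry (deceleration = RR lengthening).** With dec/acc/neutral defined
by the sign of d_i:

* SD1d² = (1/N) Σ_{d>0} d², SD1a² = (1/N) Σ_{d<0} d² — so
  SD1² = SD1d² + SD1a² to machine precision;
* SD2d² = (1/N)[Σ_{d>0} s² + ½ Σ_{d=0} s²] and symmetrically SD2a²; points
  on the identity line contribute half to each side, which closes
  SD2² = SD2d² + SD2a² exactly (any other split of the neutral term breaks
  it);
* SDNNd² = (SD1d² + SD2d²)/2 and likewise SDNNa², closing
  SDNN_plot² = SDNNd² + SDNNa².

**Runs.** Maximal blocks of same-sign successive differences; a run's
length is its number of difference terms, so lengths sum to n−1. DRi/ARi
count deceleration/acceleration runs of length i (DR4/AR4 enter the
models), DRMAX/ARMAX are the longest runs in the segment. The Shannon
entropy of the run-(type, length) distribution, with probabilities
count/R over all runs, splits by summing −p·log p over deceleration bins
(HDR) and acceleration bins (HAR). Neutral runs are included in R by
default (configurable); entropies are in bits (base configurable; the
partition structure is base-invariant).

**Threshold counts.** pNN30dec / pNN30acc are the percentages of successive
differences strictly above +30 ms / strictly below −30 ms; pNN30 is
computed as their sum, which makes the partition exact in floating point.
Strict inequality mirrors the standard pNN50 convention.

**Sample entropy.** SampEn(m, r) = −ln(A/B), with B the ordered pairs of
m-length templates within Chebyshev tolerance r, A the same at m+1,
self-matches excluded, and the same n−m template positions used at both
lengths. Defaults m = 2, r = 0.2×SD of the segment — the field-standard
convention; these are recorded in outputs since absolute SampEn levels
depend on them. The vectorized quadratic-time matcher is exact (it is
tested bit-for-bit against a naive double loop); at ~300–400 beats per
segment nothing faster is needed. A/B = 0 yields a missing value.

**Spectra.** The tachogram (RR at beat onset) is resampled at 4 Hz by cubic
spline, mean-removed, and Welch-averaged (Hann window, 120-s windows, 50%
overlap). LF = [0.04, 0.15) Hz and HF = [0.15, 0.4) Hz powers are
trapezoidal integrals (half-open bands avoid double-counting 0.15 Hz);
LF/HF is missing when HF = 0. A variance-normalized Lomb–Scargle estimator
on the raw beat times is provided as an alternative; band *ratios* agree
across estimators, absolute powers do not, so LF/HF levels should not be
compared across estimator choices.

## Models

Each response (5 certain stages + 7 transitions) is modeled one-vs-all:
negatives are all other labeled segments. The marginal model is binomial
GEE with logit link (statsmodels), subjects as clusters, and an
exchangeable working correlation R(α) by default — independence and AR(1)
(indexed by segment number) are selectable; inference always uses the
robust sandwich covariance, which is consistent under correlation
misspecification. Rows with missing features are dropped and counted;
covariates that are constant after filtering are excluded from the design.

Backward selection drops, at each step, the covariate whose removal most
lowers the criterion, stopping when no removal improves it; the intercept
is never dropped and the accepted-criterion sequence is non-increasing by
construction. "AIC" is ambiguous for GEE, so the default criterion is the
AIC of the corresponding independence (ordinary logistic) fit — cheap, and
what most practitioners mean by AIC-selection in this setting — with QIC
as the statistically conventional alternative. With the default criterion,
candidate models are scored by GLM fits and only accepted models are refit
as GEE.

Train/test splitting is by whole subject: subjects are grouped by k-means
on their mean stage-fraction vectors (default 4 strata) and ~70% of each
stratum is randomly assigned to training. Hard labels use probability ≥
threshold (default 0.5, ties positive). When a response has a single class
on the test subjects, evaluation falls back to the training set (flagged in
the report) rather than silently skipping the response. AUC is the
rank-based Mann–Whitney estimator with ties worth one half; undefined
metrics are reported missing, never coerced to 0.

## Synthetic cohorts

The generator exists to make every pipeline stage testable with known
ground truth; it aims at statistical plausibility, not physiological
fidelity.

* **Hypnograms**: a first-order Markov chain over 30-s epochs. The
  transition matrix is built reversibly — P_ij ∝ π_j·A_ij with symmetric
  adjacency weights A over plausible stage changes — so its stationary
  distribution equals the configured occupancy targets exactly; the scale
  of the off-diagonal terms sets bout durations (default: largest
  per-epoch leave probability 0.12, i.e. minimum mean bout ≈ 4 min).
  Default occupancy {W 0.28, N1 0.16, N2 0.29, N3 0.14, R 0.13} reflects a
  sleep-lab cohort with frequent wake/N1 alternation.
* **RR series**: per beat, RR = stage mean + noise + LF tone (0.10 Hz) +
  HF tone (0.25 Hz) + event offset. The noise is a mix of an AR(1) process
  (smoothness ρ per stage) and white noise; the white-noise share is the
  stage's complexity dial (higher → higher SampEn). The event process
  fires with a small per-beat probability: one abrupt lengthening
  (60–120 ms) followed by a 4–7-beat linear recovery ramp during which
  noise is damped, producing the longer and more numerous acceleration
  runs characteristic of real heart rhythms. Defaults encode the
  recoverable ground-truth effects: N2 has the largest LF/HF tone ratio,
  N1 the lowest white-noise share, N3 is HF-dominated with the smallest
  variability, W is fast, noisy and maximally irregular.
* **Cluster structure**: per subject, a shared normal shift of the mean RR
  (SD 30 ms) and lognormal scalings of the noise/tone amplitudes (σ 0.12)
  induce the exchangeable within-subject correlation; setting both to 0
  removes it (and the estimated α collapses to ≈ 0).

What the generator does *not* emulate: respiratory sinus arrhythmia as an
actual coupled oscillator (the two tones are fixed-frequency), apnea
events, ectopy/artifacts, circadian drift, and EEG-side scoring noise.
Passing tests therefore demonstrate that the pipeline recovers effects that
are present and correctly propagates stage structure into features and
models — not that real nights would yield the same coefficients.

## Numerical conventions and problem sizes

Rounding of reported fractions/percentages/metrics is decimal half-up (0.35
→ 0.4), not banker's. Windows are half-open; band edges half-open; ties at
the classification threshold predict positive. Test-suite simulations use
reduced cohorts (e.g. 8 subjects × 2.5 h, 20 seeds for effect-recovery
checks) — the package's chosen balance between statistical resolution and
suite runtime; the acceptance script runs the study-sized 31-subject × 8-h
cohort. Random state is always an explicit seed; cohort subjects draw from
spawned, independent seed sequences so per-subject streams are stable.

## Known limitations

* The independence-AIC selection criterion ignores the working correlation
  when scoring candidates (QIC is available but slower).
* Absolute LF/HF and SampEn levels are estimator- and parameter-dependent;
  only within-pipeline comparisons are meaningful.
* The transition rules are applied literally; they can mark both directions
  of a pair in adjacent segments.
* With ~250 segments per short synthetic cohort, rare responses (e.g. N3–R)
  often lack positive test-set cases; reports then fall back to training
  data or record a degenerate-response failure.
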