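# Methods

## The estimator

MF-DFA is implemented exactly as chained in `mfgait.mfdfa.run_mfdfa`:
profile, windowed polynomial detrending, q-order fluctuation functions,
log-log regression for `h(q)`, Legendre transform, spectrum summary.
Numerical choices that were genuinely open:

* **Profile.**  The cumulative sum of the mean-centred series.  The last
  profile value is 0 up to floating error; validation reports the index of
  any non-finite input sample.
* **Segmentation.**  Default `forward_only`: `⌊N/s⌋` windows from the
  head, remainder discarded.  `bidirectional` (add the same count from the
  tail, standard practice when the remainder matters) is available but not
  the default, so that the window count matches the `L = ⌊N/S⌋` convention
  the rest of the analysis assumes.
* **Detrending order.**  Default 1 (MF-DFA1).  Higher orders are
  configurable; the minimum usable scale is `order + 2`.
* **q grid.**  −5 … 5 in steps of 0.5, symmetric and containing 0.  The
  `q = 0` fluctuation function is the logarithmic average
  `F_0(s) = exp{(1/2M) Σ_v ln F²(s,v)}`, the analytic `q → 0` limit of the
  general power mean.
* **Scale grid.**  ~20 geometrically spaced integer scales from
  `max(16, order+2)` to `⌊N/4⌋`.  For 60 s at 60 Hz that is 16 … 900
  samples.
* **Zero-residual windows.**  Exactly-zero `F²` makes `q ≤ 0` moments
  undefined.  Policy: `exclude` (default; the count is recorded per scale),
  `floor` at 1e−15, or `error`.
* **Derivative.**  `α = dτ/dq` by central finite differences (one-sided at
  the grid ends), so `α_min = α(q_max)` and `α_max = α(q_min)` are
  finite-q truncations of the asymptotic spectrum.  Every summary carries
  the full grid configuration in its provenance block for this reason.
* **Stability index.**  `D(α) = |α_max − α_0| − |α_min − α_0|`, the
  right-minus-left arm-length difference.  This is the only reading of the
  index consistent with "lower is more stable" and with observed values of
  both signs; the alternative literal reading
  `|α_max − α_0| − α_min − α_0` is available behind
  `d_alpha_formula="literal"` for comparison.
* **Degenerate spectra.**  All-equal `α` (within 1e−12) is flagged
  monofractal and returns `Δα = Δf = D(α) = 0`.

The estimator is validated against closed forms: for the deterministic
binomial cascade with weight `a`,
`h(q) = 1/q − log₂(a^q + (1−a)^q)/q`, and for fractional Gaussian noise
`h(2) ≈ H`.  With the default grids the cascade exponents are recovered to
better than 0.05 for `|q| ≤ 4` and fGn `h(2)` to better than 0.1 for
`H ∈ {0.3, 0.5, 0.7}` at n = 4096 — both checked in the test suite and
recomputed by `scripts/acceptance.py`.

## The synthetic cohort

No public motion-capture recordings exist for the cohort this analysis
design targets, so the generator's contract is to realise the statistical
structure the pipeline assumes — quasi-periodicity, tunable
multifractality, and group separation — not biomechanical realism.  Each
channel is

```
x(t) = base(t) + noise_sd · u(t)
```

* `base(t)`: a stride sinusoid (~1 Hz) whose frequency and amplitude are
  jittered per cycle (relative sd 0.1) — the quasi-periodic rhythm.
* `u(t)`: zero-mean unit-variance Gaussian noise modulated by a randomized
  binomial-cascade envelope **clipped at its mean**:
  `env = min(c, c̄)/c̄`.  Clipping removes the cascade's large-deviation
  bursts (which would lengthen the spectrum's *left* arm) and preserves
  the scale-invariant heterogeneity of its quiescent phases, so the
  resulting spectra are right-arm dominant and `D(α)` is positive and
  *increases* with the cascade weight `a`.  The group knob is therefore
  `a`: 0.75 for fallers, 0.62 for non-fallers by default — intermittent,
  less stable motion versus steadier motion.

Defaults: 60 s per recording at 60 Hz, base amplitude 0.5, `noise_sd` 3.0
(units are arbitrary marker-coordinate lengths; only the ratio matters,
and it is chosen so the intermittent component dominates the detrended
fluctuations at the analysis scales, which is what a strongly
right-asymmetric spectrum of real unstable gait implies).  Ages and BMIs
are truncated normals from the published per-cell baselines; the single
male faller keeps his printed values (73 y, 24.3 kg/m²).  Every channel is
seeded independently from the cohort seed via spawned seed sequences, so
any recording is reproducible in isolation.

What the generator does **not** emulate: joint kinematic coupling between
markers (channels are statistically independent given the group), marker
dropout/occlusion, gait events, or the absolute scale of the clinical
index.  On the synthetic cohort the group means of `D(α)` come out near
0.21 (fallers) versus 0.15 (non-fallers) — the ordering and the
decisiveness of the separation (t-test p ≪ 0.005) reproduce the clinical
finding, but the absolute values sit below the clinical cohort's reported
means, because a binomial-cascade envelope with weight ≤ 0.75 bounds the
attainable arm asymmetry.  Passing tests therefore demonstrate that the
pipeline detects the constructed group difference at the study's sample
sizes, not that real cohorts behave like the generator.

A deliberate consequence of sampling baselines from the published
per-cell values: the BMI gap between groups (≈23.3 vs ≈25.7 kg/m²) is
real in the generator, so a rank-sum test on BMI rejects in a fair share
of cohorts even though the corresponding age test is null in the large
majority.  The balance property is asserted for age across seeds, not for
BMI.

MF-DFA caveat recorded here because it shapes the tests: a *pure*
periodic signal is a known pathological input — scale crossovers at the
stride period produce a spuriously wide spectrum — so "remove the
multifractal component and the spectrum narrows" is tested via the
cascade's monofractal limit (`a = 0.5`, uniform envelope), not via the
bare sinusoid.

## Group statistics

Per-channel two-sided independent-samples t-tests (pooled variance by
default, Welch optional), significance threshold 0.005, rows in the serial
order of the 42 × 3 channel table.  No multiple-testing correction is
applied in the headline column, matching the uncorrected per-channel
convention of the original table; a Benjamini–Hochberg column is appended
as a clearly labelled extension.  Degenerate channels: both groups
constant and equal gives `t = 0, p = 1`; constant but unequal with zero
variance is an error.  Posture stability averages each joint's three
planes first, then joints (identical to the grand mean at equal plane
counts; both modes exposed).  Rank-sum baseline checks use the exact null
for small tie-free groups and the tie-corrected normal approximation
otherwise.

## Classifier benchmark

Hyperparameters follow the published parameter table; the evaluation
protocol is *not* published, so it is explicit here: stratified 5-fold
cross-validation (seeded) is the default, resubstitution and holdout are
available, and every report names its protocol.  Resubstitution is
documented because perfect scores on a 46-subject / 126-feature problem
are consistent with training-set evaluation.

* **L1/2 sparse kernel iteration** (authored here): polynomial-kernel
  (degree 2) expansion fitted to ±1 targets by proximal gradient descent
  with the closed-form half-thresholding operator; the printed "sparsity
  3" is read as a hard top-3 support constraint applied each iteration;
  step 0.1 normalized by the kernel's spectral scale; max 100 iterations,
  non-convergence is a warning flag, not an error.  With zero penalty and
  no pruning the method reduces to exact kernel least squares.
* **SVM**: polynomial kernel degree 1, `C = 1/regularization`.
* **GBDT**: "square error" taken literally — regression trees on ±1
  targets (depth 5, 20 trees, step 0.1), sign-thresholded.
* **RF**: 20 trees, depth 5, after per-feature uniform discretization
  into 32 bins (the reading of "binning 32").
* **DNN**: one hidden layer of 4 rectified units, Glorot init, SGD
  (lr 0.01, batch 16, 30 epochs), L2 0.01.
* **RNN**: a minimal recurrent cell of 4 rectified units consuming the
  126 features as a length-126 scalar sequence in serial order (the only
  sequence structure a static feature vector offers), logistic readout,
  full backpropagation through time with gradient-norm clipping at 5.

Metrics treat "faller" as the positive class; 0/0 precision or recall is
defined as 0; RMSE is computed on hard 0/1 predicted labels, so a perfect
classifier has RMSE exactly 0.  Constant-predictor rows (all-faller,
all-nofaller, majority) are appended to every benchmark as references.

## Problem sizes

Repeated-seed experiments (parameter recovery, classifier ranking) run on
a reduced 12-channel marker set — both anterior superior iliac spines, the
sacrum, and one foot marker — because the group effect is homogeneous
across markers by default and averaging over more channels only tightens
the subject-level mean.  Single-run analyses (the numbered scripts, the
structural checks) use the full 126 channels at 60 s × 60 Hz.
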