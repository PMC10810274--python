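# Methods

This note documents the models and conventions implemented in `odorid`: the
generative model of the synthetic cohort, the exact definitions of the
classifiers and validation designs, the significance machinery, and the
numerical and design choices that were genuinely open.

## The measurement model

A sample is one simultaneous run of two 10-sensor metal-oxide eNoses. Each
sensor reports a conductivity ratio G0/G that starts at 1 in clean air and
relaxes toward a compound-dependent endpoint during the 50 s measurement
phase. The analysis uses only the endpoint — the final sample of the
measurement phase — so each fused sample is a strictly positive vector in
R²⁰ (device 1 sensors 1–10, then device 2 sensors 1–10). An
`endpoint_window` option averages the last *w* samples instead (default
w = 1) for robustness experiments; it is not used by the main pipeline.

When raw series are simulated, each channel follows

    G(t) = 1 + (E − 1)(1 − exp(−t/τ)),

a first-order relaxation toward the endpoint E with a single time constant
τ (default 8 s, giving ~99.8% of the step at 50 s). One sensor of the
default array responds below 1 (a negative-signal channel), so code paths
never assume endpoints ≥ 1. Extraction of the endpoint from a 50 s series
therefore recovers E to within |E − 1|·exp(−50/τ), the closed-form residual
of the curve, and the tests assert exactly that bound.

## The synthetic cohort

The generator emulates a 12-participant × 5-day study: each participant-day
has 3 body regions × 3 replicate samples plus exactly one fresh
control-odorant measurement; two devices with independent drift processes
measure simultaneously and are fused. All latent factors are multiplicative
and log-normal, which keeps endpoints positive and makes control division
well defined. For participant p, day d, region r, device v, sensor s:

    control = B_s · g_{v,s} · D_{d,v,s} · ε
    body    = B_s · g_{v,s} · D_{d,v,s}^κ · e^{I_{p,d,v,s}}
              · S_{p,r,s} · J_{p,r,d,s} · ε

| term | meaning | default scale (log-sd) |
|------|---------|------------------------|
| B_s | nominal per-sensor endpoint | fixed vector, one sensor < 1 |
| g_{v,s} | per-device gain (device 1 is reference) | 0.10 |
| D_{d,v,s} | day × device drift, shared with the control | 0.30 |
| κ | drift coupling body↔control | 1.0 |
| I | idiosyncratic body drift, scale (1 − min(κ,1))·drift_scale | 0 at κ = 1 |
| S_{p,r,s} | participant's region signature | 0.25 |
| J_{p,r,d,s} | day-to-day signature jitter | ear 0.05, armpit 0.10, back 0.12 |
| ε | per-measurement replicate noise | 0.05 |

Defaults were chosen once as a realistic regime for weak body-odor
headspace on this class of instrument: replicate noise of a few percent,
day-level drift large enough to dominate the across-day signal, signatures
strong enough that within-day identification is nearly saturated, and
region-specific jitter ordered ear < armpit < back so that the ear is the
most day-stable source. A `strong_signal_config()` preset (signature 0.40,
jitter 0.02, noise 0.03, κ = 1) defines the well-separated regime used for
recovery tests, and `null_config()` (signature and jitter 0) the
information-free regime.

The coupling exponent κ spans the two drift regimes a real study can
encounter: at κ = 1 the body samples drift exactly like the control, so
control division removes drift perfectly and across-day accuracy is limited
only by signature jitter; at κ < 1 an idiosyncratic drift term appears that
division cannot remove, so correction helps only partially and can even
hurt. No physical drift model is claimed — κ is a single knob that
reproduces both observed behaviors.

Randomness is one global seed with per-record `SeedSequence` streams keyed
by record identity, so a cohort generated with fewer days is bit-identical
to the prefix of a longer one, and identical (config, seed) pairs give
byte-identical CSV output.

**What the generator does not emulate.** Drift is day-level: within a day
all participants share the same instrument state, whereas a real
instrument also drifts between the first and last participant of a session.
Consequently uncorrected *within-day* accuracy is not degraded by drift
here, and the within-day benefit of control division seen on real data is
not reproduced — on synthetic data the correction's within-day effect is
approximately neutral (tests assert corrected ≥ uncorrected, which holds).
Temperature, humidity, sensor aging, carry-over between samples, and the
chemistry of the control odorant are all out of scope. Passing tests
therefore demonstrate that the *pipeline* is correct under its stated
model, not that any particular accuracy is attainable on real data.

**A property of fresh-control division worth knowing.** All samples of a
participant-day are divided by the *same* noisy control measurement, so the
control's replicate noise becomes a common factor of that participant-day.
Within a day this factor is participant-specific: on signature-free data,
corrected within-day accuracy sits far above chance (~0.74 observed at the
default noise scale) purely through this leak, while uncorrected data stays
at chance. The leak is inherent to the correction design, not a bug: any
study that normalizes by a per-subject-per-session reference measurement
and then validates within the session partially classifies the reference
noise. Across days the leaked factor changes with the control, so across-day
holdout on null data stays at chance (0.083 measured) with or without
correction. Null-behavior tests accordingly use uncorrected data for
within-day schemes.

## Drift correction

`drift_correct` divides each body vector element-wise by the fresh-control
vector with the same (participant, day) key, device-aligned (each device's
endpoints divided by that device's control endpoints — the only physically
sensible alignment), and drops control rows from the output. A missing or
duplicated control, or a non-positive control endpoint, is a hard error in
corrected runs; `mode="none"` passes body rows through untouched. The
operation is scale-equivariant: multiplying a participant-day's body and
control rows by the same positive per-sensor gains leaves the output
unchanged, which is precisely why shared drift cancels.

## Classifiers

Both models are deterministic and randomness-free; stochasticity lives only
in the validation schemes.

**Fine KNN** (default k = 2): majority vote among the k nearest training
samples by Euclidean distance on raw features. Vote ties — frequent at
k = 2 — fall back to the nearer neighbour's label; exact distance ties
break by smallest training-row index, making predictions invariant to
training-row order. Features are not standardized by default; a
`standardize` flag (train-set z-scoring) exists because toolbox defaults in
the wild vary.

**LDA**: pooled within-class covariance with divisor N − C, plus a ridge of
γ × (mean diagonal) on the diagonal (default γ = 10⁻⁶, 0 disables).
Prediction maximises δ_c(x) = x′Σ⁻¹μ_c − ½μ_c′Σ⁻¹μ_c + log π_c with
empirical priors (balanced by design here). With γ = 0 the rule is
invariant to invertible affine feature maps, which the tests check with
well-conditioned random maps.

Both are verified prediction-for-prediction against brute-force oracles
(direct distance enumeration; direct evaluation of the discriminant) on
1000+ random small instances, and cross-checked against scikit-learn on
tie-free, well-separated instances.

## Validation designs

* **Leave-one-out** over the N samples of the evaluation table (36 for one
  region-day of the default design): deterministic, one accuracy.
* **Repeated one-sample-per-participant-out**: each iteration draws, per
  participant, a random permutation of their m samples into m folds; fold j
  trains on m − 1 samples per participant and tests on the held-out one, so
  folds partition the data and every sample is tested exactly once per
  iteration. With 3 replicates this is the 3-fold train-2/test-1-per-person
  design. The default 500 iterations give an accuracy distribution; its
  mean is reported as the model's true accuracy, its median feeds the
  permutation test. Fold randomization is redrawn independently each
  iteration — the natural reading of "repeat the CV 500 times" — with
  per-iteration substreams derived from one seed.
* **Accumulated days**: the same scheme on day windows 1–2, …, 1–5; with r
  replicates/day and k days there are r·k folds (train 5/test 1 per person
  at 2 days; train 11/test 1 at 4 days), holding stringency constant as
  data accumulate.
* **Across-day holdout**: fit once on all body samples of the training days
  and score the unseen day; deterministic. The model is refit on the full
  training set (any inner CV is validation, not model selection).

Accuracy is micro-averaged over test samples; with balanced classes this
equals the macro average. One description in the source literature of this
design family calls the per-participant scheme "3-fold cross validation
(test on 66.7%, train on 33.3%)" while its own worked description trains on
2 of 3 samples per person; the worked description (train 66.7%) is
implemented, the parenthetical treated as a transcription slip.

## Significance

**Permutation test**: per iteration, participant labels are permuted
uniformly over all samples of the evaluation table *before* fold
construction and fitting (the stricter of the two possible conventions,
and unstratified — the per-participant fold constraint is applied to the
shuffled labels). The observed summary is the median of the real accuracy
distribution and p = (1 + #{null ≥ median}) / (1 + N): the add-one
estimator never returns 0 and floors at 1/501 ≈ 0.002 for 500 iterations.
The ≥ exceedance rule is conservative. Null accuracy means sit at 1/C
within Monte-Carlo error for balanced classes; a small finite-sample quirk
is that the *leave-one-out* null runs slightly below 1/C, because removing
the test sample leaves its own class with one fewer training vote — a
well-known pessimistic bias of LOO under label permutation.

**Binomial identification test**: an accuracy a over a roster of n
participants corresponds to r = ⌊a·n + 0.5⌋ correct identifications
(half-up), with exact point probability P(r) = C(n,r) p^r (1−p)^(n−r),
p = 1/n (0.0833 at n = 12), evaluated through log-gamma arithmetic
(`scipy.stats.binom`) and verified against full outcome-vector enumeration.

## Numerical and I/O conventions

* Endpoints are serialized with 17 significant digits and parsed with a
  correctly-rounded strtod, so CSV round-trips are bit-exact (the tests
  assert byte-identity of re-written tables).
* Wide dialect (canonical): one row per fused sample, metadata columns
  `participant, day, kind, region, replicate` then `d1_s1 … d2_s10`. Long
  dialect: one row per device × sensor; fusion is order-invariant and
  rejects device-incomplete or duplicated samples. Non-body rows carry
  empty region/replicate cells.
* Day numbering is 1-based; region labels are a lower-case controlled
  vocabulary (`ear`, `armpit`, `back` by default).
* Empty subset selections, unequal replicate counts, train/test day
  overlap, missing controls, and non-positive endpoints are all hard errors
  with the offending key in the message.

## Problem sizes used in the test suite

Self-contained tests run on the default 12 × 5 × 3 × 3 cohort (600 rows) or
smaller; accuracy-distribution tests use tens of iterations, the
permutation-floor check uses the full 500 null iterations on one region-day,
and null-behavior checks pool 20 seeds (720 Bernoulli trials per scheme
against the 99% binomial interval around 1/12). The acceptance script uses
500 iterations throughout and completes in seconds.

## Known limitations

* The generator's drift is day × device level; intra-day instrument drift
  and sampling-order effects are not modelled (see above).
* Only the two classifiers that this analysis rests on are implemented; no
  model selection or hyperparameter search is provided.
* ANOVA/Tukey comparisons between accuracy distributions of different
  regions are deliberately omitted: CV-iteration accuracies are not
  independent observations, and such comparisons are descriptive at best.
* The real-data reproduction test requires the source study's raw endpoint
  table adapted to the canonical schema; it is not shipped with the
  package.
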