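# Methods

`hrvc` implements a complete heart-rhythm-complexity analysis chain for
beat-to-beat (RR) interval recordings: preprocessing, linear
heart-rate-variability (HRV) metrics, detrended fluctuation analysis
(DFA), multiscale entropy (MSE), and a case-control diagnostic layer.
Because clinical Holter recordings are rarely shareable, the package also
ships a synthetic cohort generator that reproduces the statistical
contrast the analysis is meant to detect; every stage is tested against
it and against exact or closed-form oracles.

## Preprocessing

**Input.** An `RRSeries`: intervals in milliseconds, one per beat, with a
per-beat quality label (`normal | ectopic | artifact | excluded`).  Files
may be a bare interval list, a cumulative-time list, or a CSV with
`time_s, rr_ms, ann` where `ann` carries AAMI-style letters (N = normal,
V/A = ectopic, X = artifact).

**Normal-to-normal (NN) filtering.** Clinical practice reviews
annotations manually; the automated stand-in accepts a beat when its
label is `normal`, its interval lies in [300, 2000] ms, and it differs
from the *previous accepted* interval by at most 20%.  The first accepted
beat is exempt from the jump test.  All three thresholds are config keys
(`min_ms`, `max_ms`, `max_rel_jump`).  Rejected beats are deleted —
adjacent intervals are never merged across the gap — so downstream inputs
are exactly reproducible from the accepted set.  Note that the sequential
anchor makes the filter non-monotone in its threshold (loosening the jump
bound can shift the anchor and reject a beat a stricter run kept); the
guaranteed post-condition is that consecutive accepted intervals always
satisfy the jump bound, and that is what the tests assert.

**Stable-segment selection.** Analyses use a contiguous 4-h daytime
window (clock window 09:00–17:00, both configurable).  Candidate windows
slide in 5-min steps; each is scored by the fraction of its beats flagged
by a *static* artifact rule (non-normal label, out-of-bounds interval, or
a >20% jump from the raw predecessor), computed once with prefix sums.
The lowest-scoring window wins; ties go to the earliest start.  The
static score differs slightly from the sequential NN rule but makes the
search O(1) per window and deterministic.  When a recording cannot cover
the window, the pipeline falls back to the whole recording and sets a QC
flag rather than discarding the subject.

## Linear HRV metrics

*Time domain* (per NN series): mean RR (ms), SDRR (sample SD, ddof = 1;
population variant by flag), and pNN20/pNN50 — the proportion (0–1) of
successive NN differences whose absolute value *strictly exceeds* 20/50
ms.

*Frequency domain*: the NN tachogram (interval against cumulative NN
time) is cubic-spline resampled at 4 Hz, and band powers are integrated
(trapezoid) from a Welch periodogram: Hann windows of 300 s, 50% overlap,
per-segment mean removal (linear detrend by flag).  Bands: VLF
0.003–0.04 Hz, LF 0.04–0.15 Hz, HF 0.15–0.4 Hz, all in absolute ms²; the
LF/HF ratio is NaN when HF power is zero.  The 4 Hz / 300 s choices are
the long-standing tachogram-analysis convention: 4 Hz comfortably exceeds
twice the highest band edge, and 300-s segments resolve the VLF edge on a
4-h recording while still averaging ~95 segments.  A recording shorter
than twice the lowest band period (~11 min) flags its VLF estimate; less
than 60 s is an error.

## Detrended fluctuation analysis

The mean-centred series is integrated; for every box size n = 4…64 the
profile is split into non-overlapping boxes of n beats — taken both
forward and from the reversed profile, so trailing samples contribute —
each box is least-squares detrended with a line, and F(n) is the RMS of
the pooled residuals.  Two slopes of log₁₀F against log₁₀n are reported:
α1 over boxes 4–11 and α2 over 11–64, endpoints inclusive (n = 11 enters
both fits).  α ≈ 0.5 marks uncorrelated noise, ≈ 1.0 1/f-like fractal
correlation, ≈ 1.5 Brownian smoothness.

**Finite-size bias.** Over boxes as small as 4–11 the DFA1 slope of
weakly correlated noise is biased upward: the exact expectation for white
noise is E[F²(n)] = σ²(n² − 4)/(15n), giving a 4–11 slope of 0.6174
rather than the asymptotic 0.5 (the implementation reproduces the exact
values to <1%).  The bias fades with correlation strength (≈ +0.04 at
α = 1) and with box size (white noise over 11–64 gives 0.51).  Tests
therefore validate α1 against the exact closed-form expectation —
computed from the trace of the residual projector over the process
covariance, an oracle independent of the box-wise code — and check
asymptotic exponent recovery on the larger-box range.  Clinical α1
values are unaffected: they sit near 1.0–1.3 where the bias is small,
and the estimator is the field's standard one.

## Multiscale entropy

Sample entropy SampEn(m, r) = −ln(A/B), where B is the number of
template pairs of length m within Chebyshev distance r (self-matches
excluded, both template sets of size N − m) and A the analogous count at
length m + 1.  Matching uses ≤ r.  Counting is exact: a numba-compiled
sweep over templates sorted by first coordinate returns the same integer
counts as naive O(N²) enumeration (asserted to 1e-10 in tests against an
independent brute-force oracle).  Zero A or B yields NaN — "undefined",
never a fabricated 0 or ∞ — and NaN propagates to any summary feature
whose scale range touches it; downstream models drop such subjects
listwise and report the count.

The MSE curve evaluates SampEn on coarse-grained series: scale τ replaces
each block of τ consecutive beats by its mean (length ⌊N/τ⌋).  Defaults
m = 2 and r = 0.15 × SD of the original series, with r *fixed across
scales*, follow the standard multiscale-entropy convention; both are
config keys.  Scales run 1–20 and four features summarise the curve: the
entropy at scale 5, the least-squares slope over scales 1–5, and the
plain sums over scales 1–5 and 6–20.

## Diagnostic layer

Group comparisons dispatch automatically: continuous variables use the
independent t-test when Shapiro–Wilk accepts normality in both groups
(α = 0.05) and the Mann–Whitney U test otherwise; binary variables use
the chi-square test, switching to Fisher's exact test when any expected
cell is below 5 *or* any observed cell is zero (the odds ratio is then
unbounded and the χ² approximation unsafe).  Summaries mirror the
clinical convention (mean ± SD, median (25th–75th), count (%)).

Logistic regression is fitted by maximum likelihood (Newton, BFGS
fallback) with Wald 95% CIs on the odds-ratio scale.  Complete or
quasi-complete separation is detected (degenerate fitted probabilities or
runaway coefficients) and returned as a flagged fit with no finite odds
ratios.  Exactly duplicated terms raise a collinearity error naming the
pair.  Model building mirrors the two-stage clinical convention: terms
univariably significant at p < 0.05 enter a backward elimination that
repeatedly drops the largest-p term ≥ 0.05 (ties: lexicographic) until
all survivors are significant — deterministic and invariant to candidate
order.  Each retained HRV term is then re-estimated in five pre-specified
adjustment models: (1) crude; (2) + age, sex; (3) + age, sex and the
three drug classes (beta blocker, CCB, ACEI/ARB); (4) + age, sex,
creatinine, fasting glucose; (5) + age, sex, creatinine, fasting glucose,
CAD, hypertension, diabetes, dyslipidemia.

ROC analysis is empirical over all observed thresholds.  The trapezoidal
area equals the Mann–Whitney identity U/(n₁n₂) with half-credit ties —
the implementation computes both and refuses to return if they disagree.
Markers *reduced* in cases would score below 0.5 raw; the result
therefore carries the raw AUC, the oriented AUC (≥ 0.5) and the
orientation used, so direction is explicit rather than hidden.  No
multiplicity correction is applied across the 14 parameters, matching the
single-study reporting convention; the ranking is descriptive.

## Synthetic cohorts

The generator emulates ~4-h daytime tachograms (≈ 15,000–20,000 beats)
with the case-control structure the analysis targets:

| parameter | control | heart failure |
|---|---|---|
| mean RR (ms) | 841 ± 110 | 741 ± 100 |
| base SD (ms) | 38 ± 9 | 15 ± 4 |
| spectral exponent β | 1.5 ± 0.12 | 0.95 ± 0.10 |
| LF / HF modulation (ms) | 12 / 8 | 5 / 6 |
| envelope log-SD | 0.15 | 1.3 ± 0.15 |
| ectopic rate | 1% | 2% |

Base noise is spectrally synthesised (power ∝ f^−β, random phases,
inverse FFT), scaled to the subject's mean/SD, with sinusoidal LF
(0.1 Hz) and HF (0.25 Hz) modulations; intervals are clipped to
[300, 2000] ms (>5% clipping warns).  Subject-level parameters are drawn
from the per-group normals above (clipped to physiological ranges), and
ectopy is injected as short–long couplets (0.6×/1.4× the local interval)
labelled `V`, so the NN filter has realistic work to do.

**Why an amplitude envelope.** The clinical signature of heart failure is
*joint*: lower α1 (~1.0 vs ~1.25) *and* lower entropy at every scale.  No
stationary Gaussian process can produce that pair — pushing α1 down
toward 1.0 adds white-like content, which raises entropy, and simulation
confirmed that both an added white component and an added slow sinusoid
move the entropy contrast the wrong way.  The heart-failure profile
therefore modulates its fractal base with a slowly wandering mean-one
lognormal envelope (`env_strength` = log-amplitude SD, envelope spectrum
∝ f^−1.5): quiet low-variability stretches broken by surges.  The surges
inflate the overall SD — and with it the entropy tolerance r = 0.15 SD —
while most templates live in the quiet core, depressing sample entropy at
all scales without moving the DFA slope off its β-programmed value.
Physiologically this mimics the intermittent autonomic surges and
periodic-breathing epochs of heart failure, though it is a statistical
emulation, not a cardiorespiratory model.

**What the generator does not emulate**, and hence what passing tests do
not show about real data: circadian structure beyond the fixed daytime
window; respiratory-frequency drift (HF modulation is a pure tone, so
control pNN20/pNN50 run lower than clinical values and the pNN direction
between groups is not matched); correlated covariates (clinical flags are
independent marginals per group, so confounding structure is absent);
measurement quantisation of real Holter R-peak timestamps.  Separation
measured on these cohorts (scale-5 entropy AUC ≈ 0.85–0.95) demonstrates
pipeline correctness and recovery of a programmed effect, not expected
clinical effect sizes.

## Reproducibility and problem sizes

Every random draw flows from an explicit integer seed through
`numpy.random.SeedSequence`; cohort generation and the full study run are
byte-identical across reruns (fixed float formats, no timestamps in
outputs).  Test and validation runs use 10,000-point series for DFA
benchmarks, 20,000-point series (20 replicates) for MSE structure, 10
seeds of the default 55/97 cohort plus three 100/100 profile-identical
null cohorts for end-to-end recovery — sizes at which the estimator
variances are comfortably below the tested effect sizes.  Per-model
listwise-deletion counts, per-subject QC fields and a JSON run manifest
(config, seed, version) are emitted with every study.

## Known limitations

- The segment-stability score is a proxy (static rule) for the
  sequential NN filter; a window can in principle be chosen whose
  sequential rejection fraction is not strictly minimal.
- Wald CIs are first-order; near-separation they widen dramatically
  before the separation flag trips.  Profile-likelihood CIs are not
  implemented.
- Backward elimination inherits the usual instabilities of stepwise
  selection under collinearity (the 14 HRV parameters are strongly
  inter-correlated); the retained set varies across cohort draws, which
  the end-to-end tests treat as expected behaviour (they require *a*
  complexity term, not a fixed set).
- DFA α1 carries the small-box finite-size bias discussed above; values
  are comparable across subjects and to the literature (which uses the
  same estimator), but are not unbiased estimates of the asymptotic
  scaling exponent for weakly correlated series.
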