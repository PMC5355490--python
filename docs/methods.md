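# Methods

This note records the statistical model, the parameter choices, and the
numerical conventions implemented in `vitalcentiles`, including decisions
the package had to fix where more than one convention is defensible.

## Data model

An observation stream is a table with columns `patient_id`, `time`
(timestamped to the second), `variable` (one of `HR`, `SBP`, `MBP`, `DBP`)
and integer `value`, sampled nominally every 5 seconds. Patient metadata
carries a date of birth; age at each observation is computed exactly as
elapsed seconds divided by 86 400, so no observation is quantized to whole
days before group assignment.

## Age partition

Ages are partitioned into 43 groups:

- 30 day-level groups: Day *d* covers the interval (*d* − 1, *d*] days,
  with Day 1 additionally including age 0.
- 13 coarse groups: 0–3, 3–6, 6–9, 9–12, 12–18, 18–24 months, then 2–3,
  3–4, 4–6, 6–8, 8–12, 12–15, 15–18 years.

One month is 365.25/12 days and one year 365.25 days. Intervals are lower-
open and upper-closed, so an age of exactly 2 years falls in "18–24 months"
and 2 years + 1 day in "2–3 years". Ages above 18 years are out of range.
During the first 30 days a patient contributes to both a day-level and a
coarse group; afterwards only to a coarse group.

## Quality filters

Filters are applied in order: plausibility, pacing, minimum record.

**Plausibility.** Integer values v are kept iff 0 < v < 300. Both bounds
are exclusive; 1 and 299 are the extreme retained values.

**Pacing detection.** Heart-rate streams are cut into non-overlapping
windows of 24 samples (2 minutes). Each window is summarized by four
features: mean, standard deviation, mean absolute successive difference,
and modal-value fraction — paced rhythm is near-constant, so the last three
features separate it sharply from intrinsic rhythm. A single-hidden-layer
perceptron (scikit-learn `MLPClassifier`, 8 logistic hidden units, fixed
random state) is trained on labelled windows; 75 % is used for fitting, the
held-out 25 % reports accuracy, and the model is refit on all windows.

The decision threshold is calibrated on the non-paced training windows: with
inclusion target t (default 0.98) and N non-paced windows, the threshold is
the k-th smallest non-paced score with k = ⌈tN⌉, and a window is flagged
paced iff its score strictly exceeds the threshold. By construction at
least a fraction t of non-paced calibration windows is retained; on fresh
data the retention rate fluctuates binomially around t. Flagged windows are
removed whole; a partial window at the end of a stream is never scored and
is kept.

**Minimum record.** A patient must contribute at least 10 000 samples to an
age group — at 5-second sampling, 13.9 hours of monitoring — or all of that
patient's samples in the group are excluded.

## Distributions and equal weighting

Within an age group, each patient's retained values are binned on the
integer support 1…299 and normalized to a probability mass function (pmf).
Patients with fewer than 10 000 observations raise
`InsufficientObservationsError` rather than silently contributing a noisy
pmf. The group distribution is the unweighted arithmetic mean of the
per-patient pmfs (renormalized against floating-point drift), so record
length does not weight the estimate: multiplying one patient's counts by
100 leaves the group pmf unchanged to ≤ 1e-12.

Shape statistics are computed from the pmf directly: skewness μ₃/σ³ and
excess kurtosis μ₄/σ⁴ − 3 with central moments taken over the support.
A two-point 50/50 pmf gives skewness 0 and excess kurtosis −2 exactly;
degenerate (single-bin) pmfs report NaN.

## Percentiles

The empirical CDF F is the cumulative sum of the pmf over the support. For
level p ∈ {1, …, 99} and q = p/100:

- if q ≤ F at the first occupied support value, that value is returned;
- otherwise the two support values bracketing q are found
  (`searchsorted`, left side) and the percentile is linearly interpolated
  between them in CDF space.

This convention returns the smallest bracketing value on flat CDF segments
and the point mass itself for degenerate distributions. On a discretized
gaussian it sits systematically about 0.5 below the continuous quantile
(e.g. p95 of N(100, 10²) discretized: 115.95 vs 116.45), an unavoidable
half-bin effect of integer support.

## Smoothing

Both pmf smoothing (over the occupied support range, span 0.05) and
centile-over-age smoothing (span 0.3) use LOWESS from statsmodels with
**zero robustness iterations** (`it=0`). The robustness reweighting is
scaled by the median absolute residual; on low-noise inputs that median is
≈ 0, every weight degenerates, and the "smoothed" output equals the input.
With `it=0` the smoother behaves as documented on clean and noisy data
alike. Age smoothing uses log-midpoint abscissae for the coarse groups
(which span three orders of magnitude in age) and linear abscissae for the
day-level groups. Smoothing can locally break the ordering p1 ≤ … ≤ p99
within an age group; each row is re-monotonized by isotonic regression
(scipy), which is the L2-closest monotone sequence. The effective LOWESS
fraction is never allowed below 3/n points.

## Parametric fits

Fits are computed from the group pmf treated as weighted data on the
integer support.

- **Gaussian**: closed-form pmf mean and standard deviation.
- **Logistic**: maximum likelihood by Nelder–Mead, initialized at the
  gaussian moments (scale σ√3/π).
- **LMS (Box-Cox normal)**: parameters L (power), M (median), S
  (coefficient of variation). For fixed L, M and S have closed forms from
  the mean and SD of y = xᴸ: M = m_y^{1/L}, S = s_y/(|L| m_y). The profile
  log-likelihood over L — including the Jacobian term ln|L| + (L−1)ln x −
  ln s_y of the transform, without which the profile degenerates toward
  L = 0 — is maximized by bounded scalar search on L ∈ [−3, 3] with
  tolerance 1e-8. L = 1 reduces to a gaussian in x; on synthetic
  Box-Cox-normal data (L = 0.5, M = 100, S = 0.1) all three parameters are
  recovered within 5 % relative error at n = 2 × 10⁶ (the L estimate
  carries a small positive bias from integer rounding of the data).

**Fit discrepancy** is the sup-norm distance between the fitted continuous
CDF and the empirical CDF, both evaluated at the integer support values, no
continuity correction. Under this convention a distribution concentrated
on one value has discrepancy > 0.4 against any well-spread fit, and
leptokurtic, right-skewed groups (mean arterial pressure-like) show
markedly larger gaussian discrepancy than mesokurtic groups (heart
rate-like) at equal n — the diagnostic used to decide when a gaussian
summary is inadequate.

## Quantile regression

Linear quantile regression minimizes the pinball loss
Σ ρ_p(y − Xβ) exactly, as a linear program (positive/negative parts of β
and of the residuals; equality constraints Xβ + u − v = y; objective
p·Σu + (1−p)·Σv) solved with scipy's HiGHS backend. On small datasets the
attained loss matches brute-force search over all lines through two data
points to 1e-9. A `per_group` covariate mode returns per-age-group sample
quantiles instead of a linear trend. Degenerate designs (a single distinct
age) are rejected.

## Synthetic cohort generator

Ground-truth families: gaussian; logistic; sinh–arcsinh
(x = loc + scale·sinh((asinh(z) + skew)/tail), right-skewed for skew > 0,
heavy-tailed for tail < 1); and Box-Cox normal. Parameters are interpolated
linearly in age between anchor points (`AgeInterpolatedTruth`), so the truth
quantile at any age is available in closed form for validation. The default
truth uses gaussian HR and systolic pressure and sinh–arcsinh mean/diastolic
pressure (the latter leptokurtic and right-skewed), with anchors from birth
to 18 years following broadly physiological trajectories. Values are
rounded half-away-from-zero to integers.

Cohorts draw admission ages log-uniformly over (0.25 days, 18 years) and
stay lengths log-normally (median 48 h, σ = 1 on the log scale); both
samplers are injectable. Artefact injection adds (i) contiguous paced
episodes on HR only, near-constant around a paced rate, and (ii) isolated
implausible values drawn from {−20…0} ∪ {300…330}; every sample carries an
exhaustive, mutually exclusive label in {clean, implausible_artifact,
paced}, so filter performance can be scored against truth. A terminal-digit
preference transform is available to mimic human charting bias. Everything
is deterministic given the seed.

**Realism and limits.** The generator reproduces the statistical features
the pipeline is sensitive to — age-dependent location/scale/shape, heavy
tails, pacing-like constancy, out-of-range artefacts, digit preference —
but each patient's distribution is stationary over the stay: no circadian
rhythm, no autocorrelation beyond the pacing episodes, no drift with
illness severity, no missing-data gaps. Conclusions about filter behaviour
under those phenomena cannot be drawn from it.

## Numerical choices

- Integer support fixed at 1…299; all pmfs are vectors of length 299.
- Equal-weight aggregation renormalizes after averaging to absorb
  floating-point drift.
- LOWESS `it=0` everywhere (see Smoothing).
- LMS profile search: bounded Brent on [−3, 3], `xatol` 1e-8.
- Quantile regression: HiGHS LP, default tolerances; exactness is verified
  against a combinatorial oracle in the test suite.
- Isotonic regression for row monotonization (L2 projection).
- Reference-range comparison counts strict inequalities only (a value equal
  to a cutoff is inside); summary differences report mean ± SD with ddof=1.

## Limitations

Centile tables describe monitored, critically ill populations under the
filters above; they are not healthy-reference ranges. The half-bin
percentile bias (≈ 0.5 units) is inherent to integer-valued support. The
pacing classifier is trained per cohort and its out-of-sample retention is
only approximately the calibration target. Day-level and coarse tables are
smoothed separately; no continuity constraint ties Day 30 to the 0–3-month
group.
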