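# Methods

## The problem

Published oncology trials usually report survival only as Kaplan–Meier (KM)
figures with number-at-risk tables. Comparing many regimens therefore
requires (i) inverting those figures back into pseudo individual patient
data (IPD), (ii) pooling the pseudo-IPD across trials under a common model,
and (iii) summarizing relative effects in a way that does not presuppose
proportional hazards. survpool implements that pipeline and a synthetic
trial-network generator that makes every stage testable against known
ground truth.

## Reconstruction (Guyot inversion)

Inputs per arm: digitized KM coordinates (time in months, survival), the
at-risk table starting at time 0, and optionally the published event total.
Digitization jitter is removed first by replacing survival values with
their running minimum.

Within each consecutive at-risk interval the algorithm (a) guesses the
interval's censoring count from the survival ratio and the next published
at-risk count, (b) spreads those censorings at equal quantiles of the
interval (avoiding pile-ups at drop locations), (c) allocates integer
events at each digitized drop so the rebuilt product-limit curve matches
the digitized value relative to the running KM level, and (d) iterates the
censoring count until the implied at-risk count at the next table time
matches the published one. Two refinements matter in practice:

* **Boundary repair.** Integer rounding can leave a residual mismatch of a
  few patients that censoring cannot absorb (the count is already zero). A
  repair pass then reconciles event counts with the published boundary
  exactly, adjusting the latest drops of the interval first. Without it we
  observed at-risk errors of up to 3; with it, boundary counts match the
  published table exactly on the synthetic study.
* **Event-total matching.** When the published event total is supplied, the
  final pass converts censorings to events (or back) until the total
  matches exactly. Swapping the label of a record at a fixed time leaves
  every at-risk count unchanged, and swapping where the risk set is largest
  (the earliest eligible points) perturbs the curve least, so conversions
  run earliest-first. Matching the total costs a little curve fidelity
  (worst-case max deviation roughly 0.01–0.03 on the synthetic study vs
  below 0.01 without the constraint): when the digitized coordinates are
  exact, the total adds no information, but with real, imperfect
  digitizations it anchors the tail.

Beyond the last at-risk entry the algorithm assumes zero censoring (flagged
in the fidelity report); patients still at risk at the last digitized time
are emitted as censored there. Ties between a drop and a table time follow
the convention that the published count means "at risk just before that
time". Each arm gets a fidelity report (max/mean absolute deviation at the
digitized times, threshold flag at 0.03 by default).

## Survival model

All five families — exponential, Weibull, gamma, log-logistic, log-normal —
are parameterized through one AFT location on the log-time scale plus a
shared positive ancillary parameter (none for the exponential):

| family      | location ↦          | ancillary | S(t) |
|-------------|---------------------|-----------|------|
| exponential | rate λ = e^(−loc)   | —         | e^(−λt) |
| weibull     | scale λ = e^(loc)   | shape k   | exp(−(t/λ)^k) |
| gamma       | rate b = e^(−loc)   | shape a   | 1 − P(a, bt) (regularized) |
| loglogistic | scale λ = e^(loc)   | shape k   | 1/(1 + (t/λ)^k) |
| lognormal   | meanlog μ = loc     | sdlog σ   | 1 − Φ((ln t − μ)/σ) |

Treatment indicators act additively on the location; a positive coefficient
always means longer survival. The ancillary parameter is shared across
treatments. This single-ancillary location-shift structure is an
assumption, not a consequence of the inputs: it is what makes hazard ratios
time-varying for every family except the Weibull/exponential, and it is the
conventional one-parameter-per-treatment model when arm-level information
is too thin to support treatment-specific shapes. Times are in months
throughout and are clamped below at 10⁻⁶ month so log-time likelihoods stay
finite.

Pooling is one-stage and fixed-effect: a single right-censored likelihood
over all reconstructed patients with treatment indicators only, no trial
strata. Arms sharing a regimen label across trials are pooled under one
level. This mirrors a single pooled DIC per family; it ignores between-trial
heterogeneity by design (see Limitations).

## Bayesian fitting

Priors are effectively flat: normal(0, sd 100) on every location
coefficient and flat on the log of the ancillary over [10⁻⁴, 100]. At the
data sizes involved (hundreds to thousands of records) these are
numerically indistinguishable from improper flat priors; the prior
specification is recorded in every fit's metadata.

Sampling uses the emcee affine-invariant ensemble sampler in a
chains-of-ensembles layout: each of the (default 3) chains is an
independent seeded ensemble of 2·ndim+2 walkers initialized with small
jitter around a Nelder–Mead maximum-likelihood point; each chain runs the
configured 4,000 iterations, discards 2,000 as warmup, and contributes one
draw per post-warmup step (rotating through walkers), so the retained draw
count is exactly chains × (iterations − warmup). Split-R̂ (arviz) is
reported per parameter; R̂ > 1.01 attaches a warning rather than failing
the fit. Given a seed, draws are bit-reproducible.

DIC uses the classical plug-in form: D(θ) = −2 log L, DIC = mean D + p_D,
p_D = mean D − D(θ̄), with θ̄ the posterior mean of the *sampled*
parameters — locations on their natural scale, the ancillary averaged on
the log scale. The averaging scale is part of the definition because it
changes p_D. Ties in model selection break to the canonical family order
(exponential, weibull, gamma, loglogistic, lognormal) and are flagged.

## Effect summaries

Per posterior draw, HR(t) = h(t; treatment)/h(t; reference) and plug-in
S(t) are evaluated on a grid (default 0.1-month steps from 0.1, never at
t = 0 where log-time hazards are singular, up to a 60-month horizon). Point
estimates are posterior means of the per-draw curves — parameter
uncertainty propagates into the summaries — with pointwise 2.5/97.5%
quantile bands; a plug-in variant at the posterior-mean parameters is
available behind a flag. Grid points beyond the last observed time are
flagged as extrapolated. Rankings sort treatments by posterior-mean
predicted survival at each fixed time point (12/24/36/60 months by
default); exact ties break lexicographically and are flagged.

## Synthetic data generator

Each simulated arm draws event times by inverse-CDF through the family's
quantile function (one code path for all five families), applies a
censoring time equal to the administrative cutoff minus a uniform accrual
offset (default accrual 18 months, cutoff 30–36 months), and optionally an
independent exponential dropout hazard (off by default). The default
network has four trials (one with three arms) with log-normal ground truth
calibrated to the field's magnitudes: reference median OS ≈ 13.5 months
(μ = 2.6, σ = 0.9), median PFS ≈ 4.5 months, and combination-regimen
effects of 0.10–0.45 on the log-time scale. KM curves are computed with
lifelines, sampled on a 100-point equally spaced digitization grid, and
at-risk counts tabulated every 6 months — the same three CSV schemas the
pipeline reads.

What this emulates: sample sizes, censoring patterns and effect magnitudes
of first-line advanced-HCC trials, and the information loss of reading
coordinates off a figure (grid coarsening). What it does not emulate:
operator digitization error beyond coarsening, image-extraction noise,
between-trial heterogeneity in baseline risk, correlated OS/PFS within
patients (endpoints are simulated independently), informative censoring,
or cure fractions. Passing tests therefore demonstrate correctness of the
algorithms under the stated model, not robustness to violations real data
may carry.

## Validation studies and problem sizes

The studies in `survpool.validation` (shared by the test suite and
`scripts/acceptance.py`) use: 20 round-trip arms of 200–500 patients across
all five families; 50 replicated two-arm log-normal trials (δ = 0.4,
σ = 0.9, 500 patients/arm, cutoff 30 months) fitted with 3 chains ×
1,500 iterations (750 warmup); and a four-trial network at half the default
sample sizes fitted with 3 × 500 (250 warmup) for the determinism check.
The reduced chain lengths are ample for these low-dimensional posteriors
(R̂ ≤ 1.01 throughout) and keep the full validation run to a few minutes.

## Numerical details

* Rounding in the reconstruction is half-away-from-zero.
* The gamma survival function uses the regularized upper incomplete gamma;
  its log can underflow to −inf deep in the tail, which the samplers treat
  as a rejected proposal.
* Quantile functions invert closed forms (and `gammaincinv` for the
  gamma); `survival(quantile(p)) = 1 − p` holds to 10⁻⁸ across families.
* CSV reruns are byte-identical under a fixed seed; reading tables back
  exactly requires pandas' `float_precision="round_trip"`.

## Limitations

Fixed-effect pooling treats all arms of a regimen as one population —
between-trial heterogeneity inflates apparent precision. Pseudo-IPD carry
digitization-grid granularity, not true event times. The shared-ancillary
assumption forces all treatments to share a shape; regimens with genuinely
different hazard shapes (e.g. delayed immunotherapy effects) are only
captured through the location shift. Placebo arms enter as an ordinary
treatment level. No WAIC/LOO, no spline or cure models, no random-effects
network meta-analysis.
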