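# Methods

## The forward model

The state of a homeostatic cell population is a density over genomic
Δ¹⁴C; because new cells copy the current (food-chain-lagged)
atmospheric concentration and die independently of their label under
homeostasis (birth rate = death rate), the population mean c̄(t) obeys
the relaxation equation

    dc̄/dt = β(t)·(c_a(b + t) − c̄),    c̄(0) = c_a(b),

with b the subject's birth year and t the subject's age.  The full
density never needs to be represented at runtime: the mean is the only
quantity entering the likelihood.  The density-level description is
retained in the test suite as a Monte-Carlo oracle (20 000 simulated
cells, replacement at hazard β(t)·dt, each new cell stamped with the
current lagged atmospheric value), which must agree with the ODE
solution within three standard errors for every scenario.

Assumptions worth stating explicitly: the population is homeostatic
(no net growth or loss over life); a renewed cell's DNA fully reflects
the atmosphere of its birth year; the quiescent 2POP fraction never
exchanges with the renewing pool; and both the ODE source term and the
initial condition use the lagged atmospheric value.  On the last
point the two natural conventions (lag the initial condition or not)
differ only by the atmospheric slope over one year at birth; we lag
both for internal consistency and expose `lag_initial_condition=False`
to switch.

## Numerical scheme

The atmospheric record is a piecewise-linear interpolant over decimal
calendar years.  Lookups outside the covered span are errors, never
extrapolations — silently extrapolating a bomb curve is the classic
failure mode of this analysis — so data generators must cover
(earliest birth − lag) through the latest collection.

The ODE is integrated by an exponential (integrating-factor) stepper
on a grid aligned with the record's knots: within a step the source is
exactly linear, so for a constant rate the update

    c̄(t+h) = c̄(t)·e^{−βh} + [s(t+h) − m/β − (s(t) − m/β)·e^{−βh}]

is exact (s = source, m = its slope; expm1-based forms keep it stable
as β → 0).  Scenarios A and 2POP therefore use the knot grid alone and
are exact to rounding; the test suite checks agreement with the
closed form K + (c₀ − K)e^{−βt} at 10⁻⁶ relative tolerance.  For LIN
the clamped rate varies within a step; the grid is refined to ≤ 0.25
years and the rate held at its step midpoint, which integrates ∫β dt
exactly on clamp-free steps (β is linear there) and leaves a
discretisation error orders of magnitude below the measurement noise
(halving the step moves predictions by < 0.05 ‰).  We chose this over
adaptive Runge–Kutta because the stepper vectorises across the whole
cohort and across MCMC walkers — the likelihood of a 13-measurement
cohort is ~20 array operations — which is what makes the full
sampling protocol run in seconds.

The 2POP prediction is assembled exactly as the mixture
(1−f)·c̄(0) + f·c̄_renew(t), and the tests assert this identity.

Mean cell age uses closed forms where they exist — (1 − e^{−βt})/β for
a constant rate, (1−f)·t + f·(1 − e^{−βt})/β for 2POP — and composite
Simpson quadrature on a 0.05-year grid over the renewal-age density
for LIN.  The quadrature result is normalised by the numerically
integrated total mass (analytically 1) to remove residual quadrature
error.

## Inference

The likelihood is Gaussian with a single noise SD σ shared by all
measurements; σ absorbs both biological between-subject variability
and AMS measurement error, so the per-sample AMS uncertainties are
carried as metadata only.  Sampling coordinates are (log-rates, f, σ),
in which every prior is uniform: log β, log β₀, log β₁₀ ~
U(log 10⁻⁶, log 0.5) (rates per year), f ~ U(0, 1), σ ~ U(0, 100) ‰.
Working in the uniform coordinates removes all Jacobian bookkeeping;
σ = 0 is treated as a zero-likelihood state rather than an error.
The parameter classes themselves accept any physically sane values
(finite, non-negative), so β = 0 forward models are expressible even
though the prior excludes them.

The sampler is the affine-invariant ensemble ("stretch move", a = 2)
as implemented in emcee, with 50 walkers per parameter initialised
from the prior, 1000 burn-in steps discarded and 2000 retained.  Point
estimates are marginal posterior medians; "1 σ" bounds are the
16th/84th percentiles.  Two diagnostics are attached to every run: the
mean acceptance fraction (below 0.05 flags a stuck ensemble) and the
maximum rank-normalised split-R̂ across parameters (above 1.05 logs a
warning).  Prior-spread initialisation can leave straggler walkers on
flat likelihood plateaus for a long time when the data are nearly
degenerate (e.g. all samples sharing one collection date); the R̂
warning is the intended detector, and longer burn-in resolves it.

Per-subject fits (scenario A per subject, bilateral measurements
averaged first) co-estimate σ even at n = 1 — weakly identified, but
the posterior median of β remains defined; fixing σ to the AMS
uncertainty is available as an option.  The age/turnover association
is the Pearson correlation of age at collection with the per-subject
posterior median rate, with the two-sided t-test p-value.

## Model comparison

The expected log pointwise predictive density of exact leave-one-out
cross-validation is estimated by Pareto-smoothed importance sampling:
per observation, the importance log-ratios −ℓᵢ(θₛ) have their
M = ⌈min(0.2·S, 3·√S)⌉ largest values replaced by expected order
statistics of a generalized Pareto distribution fitted to the
exceedances by probability-weighted moments, truncated at the raw
maximum; the fitted shape k is reported per observation and k > 0.7
triggers a warning.  The estimator is validated against brute-force
exact LOO (grid refits of every leave-one-out posterior on a dense
2-parameter grid) within two standard errors, and cross-checked
against ArviZ's implementation, which differs only in the GPD fit
method (empirical-Bayes rather than moments) — the elpd difference is
far below one standard error in the reliable-k regime.

Scenario weights are stacking weights: the simplex point maximising
the summed log score of the mixture of LOO predictive densities,
solved by SLSQP (deterministic given inputs).  Pseudo-BMA+ weights
(Bayesian-bootstrap-regularised exponential elpd weights) are
available behind a flag, since "probability of being the best
scenario" admits either reading.

## Lipofuscin statistics

Per-neuron granule counts are trichotomised into exactly {0}, {1–3}
and {>3}; per-subject bin proportions (which sum to 1 by construction)
are summarised as mean ± SEM across subjects together with a normal
95 % interval, since published bracket notations do not always say
which of the two they are.  The omnibus test is the tie-corrected
Kruskal–Wallis H on the three groups of per-subject proportions
(three groups of n subjects — the only configuration consistent with
2 degrees of freedom), with a chi-square p-value.  The post hoc is
Tukey-q on rank sums (the Nemenyi procedure), gatekept on omnibus
significance at α = 0.05 and flagged at α = 0.05 and 0.001.  Note
that the rank-based post hoc depends on group sizes, not raw
separations: with 3 observations per group, adjacent groups can never
reach significance however far apart they are.

## Synthetic data

The generator emulates the study design rather than any particular
dataset.  The atmospheric stand-in is a stylised bomb pulse: baseline
−5 ‰, logistic rise from 1955 to a 800 ‰ peak at 1963.5, exponential
relaxation with a 16-year time constant, knots every 0.5 years from
1920 to 2025.  The default cohort has 12 subjects with births evenly
spaced over 1930–1980 (so it straddles the peak), one neuronal
measurement each collected post mortem in 2015, plus one mid-cohort
subject measured bilaterally with independent noise.  The default
generating truth is the two-population scenario with renewing fraction
f = 0.29, renewal rate β = 0.1 /year and noise σ = 10 ‰ — a renewing
fraction matching the study-scale estimate, a rate in the
weakly-identified regime the real data occupy, and a noise level
between the large- and small-sample AMS uncertainties.  Noise is added
once per measurement; ground truth is always written to a JSON sidecar.
Lipofuscin counts are multinomial over the three bins with per-bin
count distributions 0 / uniform{1..3} / uniform{4..12}; the default
bin probabilities (0.034, 0.077, 0.889) reproduce the reported mean
proportions.

What the generator does not emulate: measurement-specific AMS error
models, hemisphere-specific atmospheric curves, non-homeostatic
(growing or shrinking) populations, and any spatial structure within
the region.  Passing tests therefore demonstrate the correctness and
calibration of the machinery under the stated generative model, not
the biological conclusions, which require the real measurements and a
real atmospheric record.

## Problem sizes and calibration checks

The test suite validates posterior calibration by simulation: for each
scenario, 20 replicate cohorts (n = 12, σ = 10 ‰) are fitted with a
reduced ensemble (10 walkers per parameter, 400 + 400 steps) and the
pooled 16–84 % interval coverage of the true parameters must lie in a
wide binomial band around the nominal 68 %.  Scenario recovery is
checked the same way: five cohorts generated under a strong 2POP
signal (f = 0.3, β = 0.1, σ = 5 ‰) must hand 2POP the top stacking
weight at least four times.  The acceptance script instead runs the
full 50-walkers-per-parameter, 1000 + 2000-step protocol on the single
default cohort.  Reduced-protocol fits are used wherever many
replicate fits are needed; the reduction was chosen once (it keeps
split-R̂ typically below ~1.1 on the well-conditioned cohort designs)
and applies only to replicate studies, never to the headline fits.

## Known limitations

* PSIS with a probability-weighted-moments GPD fit underestimates very
  large tail shapes (k ≳ 1) relative to the empirical-Bayes fit; both
  regimes are unreliable anyway and flagged by the k > 0.7 warning.
* The LIN scenario's likelihood is invariant to the unclamped rate
  line outside [0, 0.5], so β₀/β₁₀ posteriors can be multimodal in
  strongly-clamped regions; the annual-change summary is computed on
  the raw line.
* With a single measurement per subject, per-subject σ is informed
  almost entirely by the prior; per-subject rate medians are usable
  for rank/correlation statements, not as calibrated estimates.
* Exact stepping assumes the atmospheric record is piecewise linear
  between knots; records with very coarse knots should be refined
  before use.
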