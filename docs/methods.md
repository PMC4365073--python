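# Methods

## The model

A count response `Y` with covariate vector `x` is modeled as negative
binomial (NB) with log-linear mean, `log(mu) = offset + x'beta`, and
variance `mu + phi * mu^alpha`.  The family is parameterized by the NB2
dispersion `phi` (size `theta = 1/phi`) with the variance exponent
`alpha` absorbed into a per-observation NB2 dispersion: a model with
`Var = mu + phi* mu^alpha` is identically the NB2 model with
`phi_j = phi* mu_j^(alpha-2)`, i.e. `log(phi_j)` linear in `log(mu_j)`.
All dispersion models in the package are therefore log-polynomials in
the log relative frequency `pi` (for single-response data, `pi = mu`):

| kind    | form                                              | free parameters |
|---------|---------------------------------------------------|-----------------|
| nb2     | `log phi = a0`                                    | 1               |
| nbp     | `log phi = a0 + a1 log pi`                        | 2               |
| nbq     | `log phi = a0 + a1 log pi + a2 (log pi)^2`        | 3               |
| plugin  | per-observation `phi` supplied, treated as known  | 0               |

For RNA-Seq count matrices the mean model is
`log(mu_ij) = log(s_j) + log(R_j) + log(pi_ij)` with library sizes `s_j`
(column totals by default) and known normalization factors `R_j`
(default 1; no normalization method is implemented here — factors are
accepted from file).  Global dispersion models additionally include
`common` (one `phi` for all genes), `genewise` (one per gene),
`trended` (a lowess smooth of log moment-dispersions on log mean
relative frequency, then treated as known), and `plugin` per-gene
tables, which is also the entry point for externally computed
empirical-Bayes (tagwise) dispersions.

## Estimation

Single-response fits maximize the joint likelihood by block coordinate
ascent: iteratively reweighted least squares (Fisher scoring) for `beta`
given the dispersions, then golden-section maximization of each free
dispersion coefficient given the fitted means, iterated until the
relative log-likelihood change falls below 1e-8 (at most 100 outer
iterations).  Dispersion coefficients are optimized in `log pi` centered
at its mean, which decorrelates the intercept and slope directions; the
intercept is searched on `log phi` in [log 1e-8, log 1e4] and slope
terms in [-4, 4].  A solution at the upper intercept boundary is flagged
as non-converged; the lower boundary is the legitimate Poisson limit.
Because the block steps are themselves iterative, the likelihood can
dither by ~1e-5 around a stationary point; a run whose likelihood has
improved by less than 1e-4 over the last five outer iterations is
accepted as converged.  `beta` starts from a Poisson fit and `phi` from
the method-of-moments value `max(sum[(y-mu)^2 - mu]/sum[mu^2], 1e-4)`.
Everything is vectorized over a batch of response vectors sharing one
design matrix; that batch path is what makes the Monte Carlo test
(hundreds of refits per test) and the simulation study (tens of
thousands) affordable.

Global dispersion models profile the per-gene coefficients out by batch
IRLS inside a Nelder-Mead (NBP/NBQ) or bounded scalar (common) search
over the dispersion coefficients.  Joint ML dispersions are biased low
by a factor of about `(n-p)/n` because every gene contributes `p`
estimated mean parameters (the count analogue of the ML variance bias;
measured almost exactly `5/6` at `n=6, p=1`).  The reported dispersion
curve is therefore rescaled by `n/(n-p)` (first order; `dof_correction`
flag, on by default).  The residual at `n = 6` is a few percent.  The
single-gene GOF test needs no such correction: its parametric bootstrap
refits the same estimator in every replicate, so the null distribution
carries the same bias as the observed statistic.

## The goodness-of-fit test

1. Fit the NB regression; compute Pearson residuals
   `r_j = (y_j - mu_j)/sqrt(mu_j + phi_j mu_j^2)` and sort them.
2. Simulate `R` (default 999) datasets from the fitted parameters and
   refit the same model to each, re-estimating all free parameters
   (plug-in dispersions are re-supplied, not re-estimated).
3. Per rank, take the median and the 2.5th/97.5th percentiles of the
   simulated ordered residuals (Hyndman-Fan type-7 quantiles — the
   convention is a recorded constant).
4. Two statistics: the Pearson statistic `sum r_j^2` and the squared
   vertical distance `sum_j (r_(j) - median_(j))^2`.  One-sided Monte
   Carlo p-value: `(#{sim >= obs} + 1)/(R + 1)`; the added 1 makes the
   estimate slightly biased but gives the correct Type-I error rate.

Replicates whose refit fails are retried with two fallback
initializations, then dropped; the p-value denominator uses the achieved
number of replicates (no topping up, to avoid conditioning on
convergence), and results with more than 5% drops are flagged
unreliable.

The empirical probability plot draws observed ordered residuals against
the rank medians with the 95% pointwise envelope (dashed), a
simultaneous band (solid), and a `y = x` reference.  The simultaneous
band calibrates a common per-rank tail probability `gamma` by bisection
so that at least 95% of the simulated replicate vectors lie entirely
inside the band; a max-deviation variant (scaling the pointwise
half-widths until 95% of replicates' maximum standardized deviations
are covered) is available behind a switch.  Bands require `R >= 39`;
with fewer replicates the test still runs and the bands are reported
as absent.

## Multi-gene diagnostics

A random subsample of `m*` genes (default 1000, without replacement,
seeded) is tested gene by gene with the gene's dispersions fixed at the
global-model values while the gene's regression coefficients are
re-estimated per Monte Carlo replicate.  Global dispersion parameters
are *not* refit inside replicates: they are informed by all m genes, so
their sampling error is negligible relative to a single gene's, and a
genome-wide refit 999 times per gene would be computationally absurd.
Only squared-vertical-distance p-values are collected (the Pearson
statistic can cancel under- against over-dispersion across ranks, a
problem amplified across genes).  The per-gene p-values are combined as
`X2 = -2 sum log p_i` against chi-square with `2m*` degrees of freedom
and displayed in a uniform QQ plot; an excess of small p-values
indicates lack of fit, while a deficit signals the conservatism expected
when many dispersion parameters are estimated from tiny samples.

`trend_exploration` provides the quick informal analysis of the
mean-dispersion trend: gamma GLMs (log link) of the per-gene moment
dispersions on polynomials of log mean relative frequency, reporting
deviance-based percent of variability explained per degree and the Wald
p-value of the highest-order term.

## Synthetic data

Two generators define the study conditions.

Single-response scenarios share the log-linear structure `beta = (15,
-1.5)` with the covariate equally spaced on [4, 8], giving means from
about 20 to 8100.  Response laws: NB2 (`phi = 0.1`, or 0.05 in the
NBP-test conditions), NB1 (`phi = 0.5/mu`), NB2 + outliers (a uniformly
chosen 20% of responses doubled), and NB2 + noise (`phi = 0.1 exp(G)`,
`G ~ N(0,1)` per observation).  A second, "illustration" profile (NB1
with variance `2 mu`; noise `G ~ N(0, 2^2)`) exists because both
parameterizations are in common use; they are distinct named scenarios.

`generate_multigene_noise` emulates an RNA-Seq matrix: per-gene relative
frequencies on a log-uniform grid (default 1e-6..1e-3), library sizes
uniform within ±20% of 1e6, and NB2 dispersions
`exp(a0 + a1 log pi [+ a2 (log pi)^2] + eps)`, `eps ~ N(0, sigma^2)`.
The default trend `(-3.5, -0.25)` spans `phi` from roughly 1 (rare
transcripts) to 0.2 (abundant), the shape commonly seen in bulk
RNA-Seq; `sigma = 0` generates data exactly on an NBP/NBQ trend.  What
the generator does not emulate: differential expression, correlated
genes, zero inflation, library-composition artifacts, or empirical-Bayes
shrinkage of dispersions — so passing tests demonstrate correctness of
the diagnostics under the assumed NB mixture law, not robustness to
every feature of real data.  Parameter-recovery and model-comparison
tests restrict to `pi` in (1e-5, 3e-3) (mean counts 10..3000): genes
with mean counts near 1 carry almost no dispersion information, and the
diagnostics target adequately expressed genes.

## Simulation study and problem sizes

`run_study` estimates rejection rates of the 0.05-level NB2 and NBP
tests for both statistics.  Outer replicates consume independent child
seeds spawned from one seed sequence, so results are identical for any
worker count.  The package's standard profile is 250 outer replicates
with 199 inner Monte Carlo replicates (binomial SE ≈ 0.014 at rate 0.05,
≈ 0.032 at rate 0.5); tolerances in the acceptance tests are three
binomial standard errors at that replication.  The full-precision
profile (1000 x 999) is a command-line flag away but takes roughly
sixteen times longer.

## Known limitations

- Joint-ML global dispersions rely on the first-order `n/(n-p)`
  rescaling; at `n <= 4` samples the residual bias is no longer
  negligible and genewise estimates are essentially unusable (they are
  reported raw, as the per-gene MLE).
- The Fisher combination is extremely sensitive to tiny systematic
  miscalibrations of the plug-in dispersions when `m*` is large; with
  biased (uncorrected) global fits even the generating model can be
  rejected.
- Monte Carlo p-values are discrete on a grid of `1/(R+1)`; at `R = 199`
  this matters for thresholds below ~0.01.
- Dispersion estimation uses ML only; quasi-likelihood and adjusted
  profile likelihood are out of scope, as are zero-inflated models and
  normalization-factor estimation.
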