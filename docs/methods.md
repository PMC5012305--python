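# Methods

This note records the statistical model behind each module, the defaults and
why, and the choices made where the design was genuinely open.

## Ratio-estimator abundance (estimation)

For sample-count strata the density, abundance, and variance equations are
the classical ratio estimator for strip transects of unequal length (Jolly's
unequal-sized-unit method): d̂ = Σyᵢ/Σaᵢ, Ŷ = A·d̂, and
var(Ŷ) = N(N−n)/n · (s²_y − 2d̂·s_ay + d̂²·s²_a), N = A/ā.  Conventions the
equations do not pin down:

- Sample statistics use n−1 denominators (standard survey-sampling
  practice).
- N is kept as a real number, never rounded.
- z = 1.959964 (the exact normal 97.5th percentile), not 1.96, for all 95%
  intervals.
- A single-transect sample stratum has no defined variance; it is reported
  as 0 with a logged warning so the degeneracy is auditable.
- The variance bracket can go negative in finite samples when count–area
  covariance is strong; it is floored at 0 with a warning.
- Total-count strata carry their observed count with variance 0.
- Rounding happens only at report time; all internal arithmetic is at full
  precision.

Block counts are treated as transects with their sampled areas; no
small-sample corrections beyond the printed equations are applied.

## Carcass ratios (carcass_stats)

Carcass abundance is estimated with the same ratio estimator as live
animals.  The ratio p = Ĉ/(Ŷ+Ĉ) gets the binomial variance p(1−p)/m times a
finite population correction (1−f).  Two quantities had to be defined:

- m is the raw observed count of live + dead individuals in the region (the
  binomial sample operates on observed individuals, not on the expanded
  estimate);
- f is sampled area / region area, the standard fpc form.

Pooling across scopes always sums carcass and live estimates
(Σcarcass/Σ(live+carcass)), never averages ratios.  Strata whose transects
lack carcass counts are excluded from ratio scopes with a logged notice.
The 8% classification threshold assigns the boundary to the declining side.

## Protection comparison (protection_test)

Weighted t components use reliability weights: weighted mean Σwx/Σw,
unbiased weighted variance Σw(x−m)²/(Σw − Σw²/Σw), and effective sample
size n_eff = (Σw)²/Σw².  For complete ecosystems the pair weight is the
ecosystem's total estimated elephants; the paired t is the weighted
one-sample t of the protected-minus-unprotected differences.  Incomplete
ecosystems enter a weighted pooled-variance two-group t (the classical
two-group t, which lets a protection class with a single ecosystem still
contribute).  A component with too few contributing values for a variance
is set to 0.  The combined statistic is T = t_paired·√a + t_unpaired·√(1−a)
with a = 2n_paired/(n_paired + n), counting estimates (two per complete
ecosystem).

The permutation scheme preserves the pairing structure: complete ecosystems
get within-ecosystem label swaps (a sign flip of the difference; the pair
weight is unchanged), incomplete ecosystems get their labels shuffled
jointly with each observation keeping its own weight.  The test is
two-sided via |T| and the p-value uses the add-one correction
(1 + #{|T*| ≥ |T|})/(R+1) so it is never exactly zero.  Whether weights
should travel with labels and whether the original analysis was one- or
two-sided is not documented anywhere authoritative; the choices above are
the package's defaults and are exercised by the exact-enumeration oracle.
Default 1,000 permutations, seeded generator mandatory.

## Trend inference (trend)

Two-stage Monte Carlo: (1) resample every observation from
Normal(estimate, SE); (2) fit each replicate and resample the aggregated
annual predictions from Normal(prediction, prediction SE).  Final intervals
are empirical percentiles over replicates and therefore carry both
estimate error and fit error.

- Missing SEs are imputed from an OLS regression of log variance on log
  estimate (count-survey variance is approximately a power law of
  population size); imputed SE = √exp(fit).
- Stage-1 and stage-2 negative draws are truncated at 0 (populations cannot
  be negative); truncation counts are logged so any bias is auditable.
- The per-replicate model is a GAM on the log link: B-spline smooth of year
  plus additive unit (stratum/ecosystem) fixed effects, fitted with
  statsmodels.  Draws are continuous by construction, so fits use
  continuous responses on the log link rather than forcing integers.
- Smoothness: the penalized path picks the penalty weight by generalized
  cross-validation, GCV = n·deviance/(n−edf)², over a log-spaced grid.
  Data-driven smoothness selection needs more distinct survey years than
  the df it would otherwise fix, so datasets with fewer than fixed_df + 3
  distinct years fall back to an unpenalized regression spline with
  fixed df = 6 (the small-sample fallback).  Datasets with exactly two
  observations get a log-linear Poisson GLM, which reproduces the two-point
  exponential interpolant exactly.
- The basis is a B-spline (cubic where the df allows); a thin-plate basis
  would differ only in basis functions, not in effective df, and the basis
  used is recorded in the result metadata.
- Family: Poisson vs negative binomial by per-replicate AIC, majority
  across replicates; ties go to the negative binomial as the more
  conservative (wider-interval) family.  The negative-binomial dispersion
  is profiled over a grid by likelihood and costs one extra effective df in
  the AIC.  AIC uses the effective degrees of freedom of the penalized
  smooth so the comparison is well defined.
- Observation weights are m_i/m̄ (unit mean population over the mean of
  unit means) so units contribute in proportion to their size.
- End year defaults to 2014; growth rates are reported for start years
  1995/2005/2010 by default, with per-replicate OLS slopes of log
  population on year.  Replicates with a zero population inside the window
  are excluded from r (log undefined) with a logged count.
- Stage-2 draws are independent across years within a replicate; any
  year-to-year correlation of fit errors is not modeled (documented
  limitation).
- Default R = 1,000 replicates.  The test suite and acceptance script run
  R = 200 with 100 simulated datasets for the recovery study and R = 30–100
  elsewhere, which keeps the full suite under a minute of trend fitting
  while leaving Monte Carlo error well inside the asserted tolerances.

## Synthetic data (synthetic_data)

The survey generator emulates strip-transect sampling of a clustered
population: a square stratum, herd sizes lognormal (mean 8 animals, log-SD
0.75) summing exactly to the configured abundance, herd centers uniform,
and parallel equal-width strips of unequal lengths scaled to a target
sampled fraction (default 15%, within the typical 5–20% range of sample
counts).  Expected transect counts equal density × strip area, so the ratio
estimator is unbiased by construction, while herd clustering produces the
overdispersion that makes the negative binomial win AIC on count fits.  At
sampling fraction 1 the strips tile the stratum and the census limit is
exact.  Carcasses are placed independently at carcass_fraction of abundance
(default 10%, 1% fresh, fresh ⊆ all).  Default stratum area is 2,000 km²
and default abundance 800 (≈0.4 animals km⁻²), matching typical stratum
scale and density.

The history generator draws observed estimates around a (piecewise)
exponential latent trend with variance = coeff·N^exp (defaults 0.09 and
1.8, ≈15% CV at N = 1,000); subsets of records can have SEs withheld (to
exercise imputation) or be marked as total counts with SE 0.

What the generators do *not* emulate — and hence what passing tests do not
establish about real surveys: observer detection bias (all observers miss
some animals), animal movement between strata, double counting, spatially
structured habitat preference, and herd-size measurement error.  Estimator
"unbiasedness" shown here is conditional on every animal inside a strip
being counted.

A calibration caveat: with the default sparse stratum (800 animals, ~3
animals per transect arriving in herds of ~8) the normal-theory 95% CI of
the ratio estimator undercovers (≈89% in simulation), the familiar
small-sample behavior of normal intervals on skewed counts.  The coverage
checks therefore run at the denser simulation condition (abundance 5,000,
fraction 0.15, 40 transects), where counts are near-normal and coverage is
nominal (93–97%).

## Numerical details

- All randomness flows through numpy Generator objects seeded explicitly;
  the pipeline is bit-reproducible for a fixed seed and config.
- Seeds for pipeline sub-stages are derived with numpy SeedSequence.spawn,
  keeping derived seeds below 2³¹.
- Permutation-test internals are vectorized across permutations; exact
  enumeration is available for small problems (all sign flips × all label
  placements) and is the oracle for the sampled test.
- A perfectly interpolating penalized fit (possible on noiseless data)
  falls back to the unpenalized GLM on the same design, its limiting
  solution.

## Known limitations

- Carcass-ratio SEs depend on the fpc and binomial-denominator definitions
  above; alternative readings would scale SEs, not ratios.
- Two-point datasets have no model-error estimate beyond the Poisson GLM's
  Fisher information.
- The trend model assumes survey areas are constant over time within a
  unit; area changes alias into population change.
- Growth-rate CIs are empirical percentiles; with few replicates they are
  noisy (use R ≥ 200 for stable intervals).
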