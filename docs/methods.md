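# Methods

## Model and criteria

The package works with the classical common-factor measurement model.
Dimension X has K_x standardized indicators with loadings λ_x.i, unique
variances 1 − λ²_x.i, and the latent correlation between two dimensions is
φ_xy. Distinctiveness (discriminant validity) of a pair is judged by
comparing each dimension's average variance extracted, AVE = Σλ²/K, against
the shared variance φ². The *manifest* criterion replaces both sides with
quantities derivable from summary statistics:

* AVE from standardized Cronbach's alpha: AVE = α / (α(1 − K) + K). This is
  exact under essential tau-equivalence (equal loadings), where α equals
  reliability and the mean inter-item correlation equals the squared common
  loading. For congeneric indicators α understates reliability, so this AVE
  estimate is biased low.
* φ² from the manifest composite correlation via correction for
  attenuation: r² / (α_x·α_y) ("double") or r² / α_min ("single"). With
  understated reliabilities the double correction overstates φ² and the
  single correction — dividing by only the larger of the two quantities
  √α_min ≥ √(α_x α_y) — understates it.

Both corrected shared variances bracket the truth, so the pair verdict is
certain whenever the two agree and `uncertain` otherwise. The squared form
of the comparison is used throughout (AVE vs r̂², exactly parallel to AVE vs
φ²): only this form makes the double-corrected manifest criterion
algebraically identical to the original criterion under tau-equivalence
(there r = αφ, so r²/α² = φ² exactly), which the simulation confirms. The
single correction divides the correlation by √α_min (shared variance
r²/α_min), the classical one-sided attenuation correction, consistent with
its role as the under-correcting lower bound.

Composite scores are unweighted means of items (equivalent to sums for
correlation purposes). Negative manifest correlations are handled by the
squaring itself; verdicts are sign-symmetric in r. Corrected correlations
with |r̂| > 1 are never clamped — they enter the comparison as-is and set
`overcorrected_flag`, since clamping would silently change decisions.

### Numerical tie policy

A violation requires the shared variance to exceed the AVE by more than a
relative 1e-12 band; differences inside the band count as met. The band
exists because the analytic decision curves are evaluated exactly at the
population threshold: for the equal-0.70 pattern at φ = 0.70, AVE and φ²
are the same real number (0.49) and different float evaluation orders land
one ulp apart, which would otherwise let the oFL and mFL-double curves
disagree at that single grid point. With the band, both curves flip from
met to violated between φ = 0.70 and φ = 0.72 on the 0.02 grid,
deterministically. The band is far below any sampling noise, so it never
affects decisions on estimated quantities.

## CFA fitter

The simulation scores the original criterion per replicate, which needs
loading and φ estimates. The built-in fitter minimizes the normal-theory ML
discrepancy F = log|Σ(θ)| + tr(S Σ(θ)⁻¹) − log|S| − p over loadings, φ and
unique variances, with factor variances fixed at 1 (all loadings free — the
standardized-solution convention the AVE formulas assume, rather than
marker-variable identification). Estimates are computed from the sample
*correlation* matrix; data are generated standardized, so this is the
natural scale. AVE is taken from the completely standardized solution,
λ_i/√(λ_i² + θ_i).

Optimization: L-BFGS-B with an analytic gradient
(dF = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹) dΣ/dθ]), start values loadings 0.7 / φ 0.3 /
uniquenesses 0.5, convergence tolerance 1e-8 on the gradient and 1e-14
relative on F, at most 500 iterations, and up to 5 jittered restarts
(uniform ±0.15, fixed jitter stream) after a failed attempt. Unique
variances are bounded below at 1e-6; a solution on that bound is a Heywood
case, flagged (`heywood`) but retained, mirroring common SEM-package
behavior. φ is bounded to ±(1 − 1e-6). Factor sign indeterminacy is resolved
by flipping each factor so its loading sum is positive, negating φ
accordingly. On the population-implied matrices of all six study patterns
the fitter recovers every parameter to ~1e-8 with discrepancy < 1e-13.

## Synthetic data and the simulation design

`sample_dataset` draws i.i.d. multivariate-normal observations with zero
mean and the model-implied correlation matrix — exactly the population the
validation study assumes. The default `SimulationConfig` *is* that study:
six loading patterns applied to both factors, from the essentially
tau-equivalent (0.70, 0.70, 0.70) to the strongly congeneric
(0.45, 0.70, 0.95); φ from 0.00 to 1.00 in 51 steps of 0.02 (stored as
integer hundredths so cell labels never drift); sample sizes 250 and 1,000;
1,000 replicates per cell. Per replicate, mFL uses *standardized* alphas
computed from the sample inter-item correlation blocks (raw-covariance
alpha would differ only by sampling noise on standardized data) and the
sample composite correlation; oFL uses the CFA estimates.

Seeding: each replicate's generator is spawned from
`SeedSequence([base_seed, pattern_id, phi_hundredths, n, rep])`, so any cell
is reproducible in isolation and the full grid is reproducible from
`base_seed` alone. Non-convergent CFA replicates are excluded from the oFL
denominator only (mFL needs no fitting); convergence counts are reported
per cell. In practice non-convergence is absent at the study's sample
sizes.

What the generator does *not* emulate: ordinal/Likert item scales,
non-normality, missing data, correlated uniquenesses, or more than two
factors. Passing tests therefore shows the criteria behave as derived under
the ideal measurement model, not that real questionnaire data meet those
assumptions.

## Review statistics

`chisq_independence` is the Pearson chi-square without continuity
correction (df = (r−1)(c−1)); on the bundled met/not-met-by-journal counts
(5/4, 4/5, 8/15) it gives χ²(2, N = 41) = 1.19, p = 0.55.
`compare_structure_by_verdict` is the pooled-variance Student t
(df = n₁ + n₂ − 2); Welch's correction is deliberately not applied, matching
the degrees of freedom the review reports. When both groups have zero
variance the t statistic is defined as 0 for equal means (±∞ otherwise)
rather than NaN. An instrument "meets mFL" only when *every* pair is
`distinct_certain`; `uncertain` pairs count as not-met in the binary
summary but are tallied separately.

## Problem sizes in the bundled checks

The acceptance script and test suite run the study at desk scale: the
bounding property over all six patterns at φ ∈ {0.50, 0.60, 0.70, 0.80,
0.90}, n = 1,000, 200 replicates per cell (6,000 CFA fits), and the
no-violation region at φ = 0.48 with 100 replicates per pattern. Bounding
assertions allow two binomial standard errors of the cell's rates. The full
612,000-replicate grid is available through the same `run_grid` call with
the default configuration and produces the identical long-format output,
just slower.

## Known limitations

* The manifest criterion is an auxiliary screen, not a replacement for a
  properly reported factor analysis; with strongly congeneric items the
  `uncertain` band can be wide.
* Alphas and composite correlations are treated as exact inputs; sampling
  error in the *published* summaries themselves is not propagated.
* The CFA fitter is special-cased to two factors with simple structure — no
  cross-loadings, structural paths, mean structures, or categorical
  estimators.
* Verdict ties at exactly the numerical boundary are resolved as met (see
  the tie policy above); this is a measure-zero choice that only matters on
  analytic grids.
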