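# Methods

This note documents the statistical machinery, the choices that were
genuinely open, and what the synthetic experiments do and do not show.

## Spatial weights

Weights are binary Rook contiguity read from a printed adjacency list
(region number, name, neighbour codes), validated for symmetry and
absence of self-loops. Row standardization divides each row by its
degree, making spatial lags neighbour averages; it is the default for
both Moran's *I* and the regressions (a binary-style flag is
available). Islands are errors everywhere except the packaged China
fixture, where the island patch (Hainan–Guangdong) is part of the data:
silently connecting islands would hide bad input, while the fixture's
patch is a documented data decision. All China-derived matrices use
numeric region order 1..31 so results are comparable across runs.

The row-standardized matrix is similar to a symmetric matrix (its
binary base is symmetric), so its spectrum is real, lies in [−1, 1],
and has maximum eigenvalue exactly 1. The interval (1/ω_min, 1) is the
admissible range for the spatial parameters; on the China graph it is
about (−1.612, 1).

## Moran's I inference

Two null distributions are offered:

- `normal_randomization` (default): z = (I − E[I]) / sd(I) against the
  standard normal, where the variance is the *exact* variance of I over
  the n! relabelings of the data (the randomization assumption),
  including the sample-kurtosis term. The test suite checks this
  formula against the exhaustively enumerated permutation distribution
  at n = 5, where they agree to machine precision.
- `permutation`: two-sided pseudo p-value
  (#{|I_perm − E[I]| ≥ |I_obs − E[I]|} + 1) / (n_perm + 1), seeded.

The normal approximation is the default because it is the conventional
choice and is well calibrated here even at n = 31 (type-I error within
binomial tolerance of 5% over 1000 null replicates); the permutation
test is the robust alternative for small n. P-values are two-sided.
Quadrant classification standardizes with the population (1/n)
standard deviation, consistent with S² in the Moran formula; a value or
lag of exactly 0 is classified "low" (deterministic tie-break on a
measure-zero event).

## Spatial panel likelihoods

Fixed effects are removed by demeaning ("within" transform): region
means for individual effects; region and period means (plus the grand
mean) for two-way effects, the default since the model includes both
μ_i and γ_t. Random-effects ML is out of scope.

For each candidate spatial parameter the slopes are profiled out by
least squares, leaving a smooth scalar objective

    l(rho) = const + T · Σ_i ln(1 − rho·ω_i) − (n*/2) · ln(SSR(rho)/n*),

maximized by bounded scalar search on (1/ω_min + 1e−6, 1 − 1e−6) with
parameter tolerance 1e−8; an optimum within 1e−5 of a boundary raises a
convergence error. A 2001-point grid search over the admissible
interval serves as the oracle for unimodality in the tests. For the
SEM the same objective is built from spatially filtered outcome and
regressors, with the slopes re-profiled at every candidate λ.

**Two-way effects and the projected operator.** Subtracting period
means maps each cross-section into the zero-mean subspace. On that
subspace the spatial operator of the transformed model is Q_N·W (Q_N
the cross-sectional centering matrix), not W: Q_N·W's spectrum is
exactly W's spectrum with one unit (Perron) eigenvalue removed, and the
Gaussian dimension is n* = (N−1)·T. The two-way likelihood therefore
uses the projected lag, the reduced spectrum, and the (N−1)·T
dimension. This is exact algebra of the demeaned model; without it the
error-model λ is attenuated by ~20% *persistently* (i.e. even as
T grows). For pooled and individual effects, n* = N·T and the full
spectrum apply unchanged.

**What is deliberately not corrected.** The incidental-parameter
(small-T) bias of within-ML is left in place: no Lee–Yu-style
correction or orthogonal-deviations transformation is applied. At the
study scale (N = 31, T = 5) the measured consequences are a residual
attenuation of about −0.003 in ρ̂ (SLM), −0.027 in λ̂ (SEM), and a
downward-scaled σ̂² (factor ≈ (T−1)/T from time demeaning). σ² uses the
ML dimension divisor, consistent with the reported likelihood.

Standard errors come from the numerical Hessian of the full
log-likelihood at the optimum (central differences, relative step
1e−5), with the variance log-parameterized for stability and
delta-mapped back. The pseudo-R² is the squared correlation between
the observed outcome and the reduced-form fitted values
((I − ρ̂W)⁻¹Xβ̂ for the lag families, Xβ̂ for SEM) on the estimation
(demeaned) scale — ordinary R² is undefined for ML fits, so the
definition is recorded in the pipeline's run metadata. The SDM offers
one δ per covariate (`per_covariate`) or a single δ on the row-sum of
the lagged covariates (`common_scalar`, the default, matching reports
that print a single δ). Impact (direct/indirect) decompositions are a
non-goal; coefficients are reported raw.

## Synthetic data

The generator adopts the estimated model equations themselves as the
data-generating process, with the published regression estimates as
default ground truth, so that the generator and the estimators are
mutually consistent and parameter recovery is a meaningful test
surface. Per period, ψ_t ~ N(0, σ²I); the SEM solves
ε_t = (I − λW)⁻¹ψ_t; the lag families solve
y_t = (I − ρW)⁻¹(α + X_tβ + WX_tδ + μ + γ_t + ψ_t).

Covariates are spatial moving-average Gaussian fields (base field plus
`covariate_mix` times its spatial lag, default 0.9 — chosen so the
fixture's PM\_2.5 Moran's *I* averages inside [0.4, 0.7], the range of
the published per-year values), split into a persistent region
component and per-period innovations (`covariate_time_frac` = 0.3 of
the sd redrawn each period — provinces' covariates move slowly), then
affinely rescaled to the published mean/sd targets and truncated at
the published minima. Region effects default to sd 0.5 and period
effects to sd 0.1 on the outcome scale; both are absorbed by the
two-way transform, so recovery results are insensitive to them.

The China-like fixture (31 regions × 2004–2008, 155 rows) additionally
imposes an east/west offset on PM\_2.5 and solves for region effects so
the reduced-form region means reproduce the published mortality profile
(ten anchored provinces, e.g. Shanghai 2.86 high and Tibet 0.05 low;
the remaining regions split east/central vs. west so the grand mean is
0.61 per 10,000). The fixture floors the outcome at zero for realism;
since flooring raises the mean of low-mortality regions, the profile is
shifted by a scalar solved from the closed-form mean of a floored
Gaussian so the *expected floored* grand mean still hits the target.
Recovery experiments leave flooring off to preserve the exact DGP.

Determinism: one master seed drives everything; the recovery experiment
derives a child seed per replicate through `numpy` seed sequences (all
below 2³¹), so individual replicates are reproducible.

## What the experiments show — and what they don't

Simulate-and-refit experiments (200 replicates, N = 31, T = 5, two-way
effects) recover the DGP values to within a few Monte-Carlo standard
errors for all three models, and nominal 95% intervals for ρ cover a
true ρ = 0 at the expected rate. This validates the estimation
machinery under the model's own assumptions. It does *not* validate
the model against real data: the synthetic covariates are Gaussian
fields with matched first and second moments, not actual
socio-economic series (no heavy tails, no common trends, no
measurement error), the outcome truly follows the fitted equations,
and the weight matrix is assumed correct. Observed-data issues —
omitted variables, endogenous pollution, raster-extraction error in
satellite PM\_2.5 — are untouched by these tests.

## Problem sizes

Defaults were chosen at the study scale: recovery experiments use 200
replicates of the 31 × 5 panel; fixture calibration checks average 100
seeds; the null-calibration suite uses 1000 Moran replicates and 200
coverage replicates. The full test suite and the acceptance script
each run in a couple of minutes on one CPU.

## Known limitations

- Within-ML only: no random-effects ML, GMM/2SLS, dynamic panels, or
  specification-test battery (LM/LR).
- No small-T bias correction (see above); at T = 5 the SEM λ̂ retains
  a bias of roughly −0.03.
- Quadrant output is tabular; no scatterplot rendering, no LISA
  significance testing.
- The adjacency ingest is list-based; polygon/shapefile processing and
  non-contiguity weights (k-NN, distance bands, Queen) are non-goals.
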