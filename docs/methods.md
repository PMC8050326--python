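# Methods

This note documents the models, conventions and design choices behind
`soilgeo`, and what the synthetic generators do and do not emulate.

## Variography

The empirical semivariogram uses the classical Matheron estimator under
the intrinsic hypothesis, binned into half-open distance classes
`[k·w, (k+1)·w)`. Defaults: bin width `w` equal to the survey's minimum
grid spacing (10 m for the reference design) and maximum lag equal to
half the maximum pairwise distance; a pair at exactly the maximum lag is
excluded. Empty bins are omitted and NaN values raise rather than being
dropped. The lag reported per bin is the **mean pair separation within
the bin**, not the geometric bin centre: on a regular grid the attainable
distances (10, 14.1, 20, 22.4 … m) cluster near the lower bin edges, and
centring lags on the bins biases fitted ranges upward.

Permissible models are spherical, exponential and gaussian with nugget
C₀ ≥ 0, partial sill C₁ ≥ 0 and range a > 0, and γ(0) = 0 regardless of
the nugget. The exponential and gaussian kinds are parameterised by the
**practical range**: γ(a) = C₀ + 0.95·C₁ exactly, i.e. decay rate
ln 20 ≈ 2.9957 rather than the common "3" approximation. This makes
fitted ranges exactly comparable across kinds and makes the 95% closed
form exact; the numerical difference from the rate-3 convention is below
0.15% of C₁ at any lag.

Fitting is bounded weighted least squares (`scipy.optimize.least_squares`,
trust-region reflective). Weighting options: pair counts N(h) (default),
equal, and Cressie's N(h)/γ²_model. Initial values: nugget from the first
bin, sill from the sample variance when supplied (otherwise the mean of
the upper half of the bins), range from the smallest lag reaching 95% of
the sill guess. SSR is reported with the fit weighting; R² is unweighted
against the bin-mean baseline; cross-validation RMSE comes from
leave-one-out kriging in raw attribute units. Model selection ranks by
ascending SSR, then descending R², then ascending RMSE — deterministic,
with the full ranking returned.

Heavily right-skewed attributes (in the reference table: Ms, P, Ca, Mg,
Al, SB, CEC) are natural-log transformed before variography; the flag is
recorded on the model, and such attributes are kriged and cross-validated
on the log scale (a naive exponential back-transform would be biased, so
maps stay on the log scale by default).

### Spatial dependence index

SDI% = MF(kind) · [C₁/(C₀+C₁)] · [min(a, MD/2)/(MD/2)] · 100, where MD
is the maximum distance between sampling points (127.28 m for the 90 m
grid diagonal) and the model factors are MF = 0.375 (spherical), 0.317
(exponential), 0.504 (gaussian). Classes: weak ≤ 7 < moderate ≤ 15 <
strong. Factors and thresholds are configuration, not hard-coded; the
defaults reproduce all 24 reference class labels, including the
borderline rows (V at 6.95%, Ca at 7.26%, K at 7.51%, AFPS at 14.73%,
P at 15.17%). A zero-sill model is defined to have SDI = 0 (weak).

## Ordinary kriging

The solver uses the semivariance form of the OK system: the pairwise
γ matrix with a zero diagonal, bordered by the unbiasedness row of ones
and solved with one LU factorisation for all targets. The zero diagonal
makes the predictor an exact interpolator (data are honoured and the
kriging variance is 0 at sample locations) even with a nonzero nugget.
Kriging variance is Σλᵢγᵢ₀ + μ, with values above −10⁻⁹ clamped to zero
and anything lower treated as an error. The default neighbourhood is
global (all samples), appropriate for n = 100; a k-nearest option exists
for larger inputs. Duplicate sample coordinates make the system singular
and are reported by row pair before solving.

Raster maps place cell centres on the data lattice (origin shifted half
a cell below the data minimum), so map cells at sample locations
reproduce the samples exactly. Default export is the ESRI ASCII grid
dialect (6-line header, rows north to south).

## Derived soil-carbon quantities

TOC = SOM/1.724 (van Bemmelen factor). Cstock = OC·Ds·E/10 in Mg ha⁻¹
with OC in g kg⁻¹, Ds in g cm⁻³ and layer depth E in cm (default 20).
SOM measured in g dm⁻³ is treated as g kg⁻¹-equivalent here, matching
the arithmetic of the reference survey's own tabulated means. Daily
emitted carbon converts FCO₂ on a carbon basis:
C–CO₂ = FCO₂ · 10⁻⁶ mol · 12 g mol⁻¹ · 86400 s · 0.01 (Mg ha⁻¹ per
g m⁻²); carbon (12 g mol⁻¹), not CO₂ (44), because the decay constant's
numerator is the labile carbon emitted as CO₂. k = C–CO₂/Cstock is
computed per sample (ratio per point, not ratio of means); zero flux
gives k = 0 and zero stock with nonzero flux is an error.

Pore space: macroporosity = TPV − microporosity and AFPS = TPV − Ms,
with negative differences rejected. Descriptive statistics report
bias-corrected skewness and excess kurtosis (normal = 0); CV classes
follow Warrick–Nielsen with boundary values (exactly 12 or 24%) assigned
to the moderate class.

## Synthetic generators

`simulate_grf` draws exact multivariate-normal fields on the grid: the
covariance implied by the variogram, C(h) = sill − γ(h) off the diagonal
and the full sill on it (the nugget contributes white noise), is
Cholesky-factorised — exact for the 100-point grids used, no spectral
truncation. A failed factorisation (beyond rounding-level jitter of
10⁻¹⁰·sill) raises an error naming the offending parameters.

`simulate_survey` draws one latent zero-mean field per attribute from
its reference variogram, then forms correlated attributes as the linear
mixture ρ·(σₐ/σ_d)·f_driver + √(1−ρ²)·f_own, which preserves each
attribute's marginal variance and gives latent correlation ρ with the
driver (FCO₂ drives SOM, macroporosity, silt, K, Ca and Mg at ρ = 0.5-0.6,
mirroring the observed map similarity; the joint model is a package
choice — only map similarity, not a joint distribution, is observed).
Log-normal attributes exponentiate the latent field with the mean
moment-matched to the target arithmetic mean. TPV is composed as
macro + micro and AFPS as TPV − Ms so the pore-space identities hold
exactly; the carbon columns are then derived, which automatically gives
k the same spatial pattern as FCO₂. Two attributes with non-negligible
probability mass below zero (macroporosity, K) are floored at the
reference minima. The temporal dimension of the reference campaign
(10 measurement days) is collapsed: the generator produces per-point
aggregates.

`simulate_microbiology` draws n = 9 composite samples per region and
variable, normal for enzyme activities, MBC and C/N, log-normal
(moment-matched from the arithmetic mean and SE) for qPCR copy numbers.
Group SEs are generator calibration: the reference figures print group
means but the error bars are not available as numbers, so the SEs were
chosen once to match each assay's typical dispersion and the reported
contrast pattern (pooled-t power ≈ 0.95 at α = 0.01 for the contrasting
variables; rejection well below test level tolerance for the stable
ones). Cellulase means are synthetic stand-ins (24.5 vs 23.0 µg glucose
g⁻¹ 24 h⁻¹) consistent with its no-difference outcome; the reference
table marks them as such.

What the generators do **not** emulate: space-time dynamics
(rainfall-driven changes in efflux), measurement-day structure,
non-Gaussian marginals beyond the log-normal family, cross-correlations
among the microbiological variables (drawn independently), and
small-scale nested structure below the 10 m spacing. Passing tests
therefore demonstrate correctness of the estimators and the internal
consistency of the pipeline under the assumed stationary model, not
fidelity to every feature of field data.

## Two-group battery

Student's t defaults to the pooled (equal-variance) two-sided form with
df = n₁+n₂−2; Welch is available. The degenerate zero-spread case is
defined: equal means → t = 0, p = 1; unequal → p = 0. No
multiple-testing correction is applied across the assay variables by
default (each contrast is reported at its own α, as is conventional for
these assay panels); a Holm adjustment is available.

Hotelling's T² uses the pooled covariance with
F = T²(n₁+n₂−p−1)/((n₁+n₂−2)p) on (p, n₁+n₂−p−1) df; a singular pooled
covariance raises with a suggestion to reduce the variable set.

Clustering is classic Ward on Euclidean distances (scipy linkage),
heights on the distance scale — two singletons merge at their Euclidean
distance; the linkage variant is configurable. The cophenetic
correlation is reported (undefined, NaN, for n = 2).

PCA is computed on the **correlation matrix** even though covariance-PCA
is sometimes quoted in this context: the Kaiser eigenvalue-1 retention
rule and the |loading| ≥ 0.70 interpretation cutoff both presuppose
standardised variables, and the assay variables span nine orders of
magnitude. Loadings are variable-component correlations
(eigenvector·√eigenvalue); each component's sign is fixed so its
largest-magnitude loading is positive. For covariance-PCA
(`standardize=False`) retention uses the mean-eigenvalue analogue.

Region delineation labels kriged-map cells by inclusive value bands,
defaults R1 = 2.9-4.2 and R2 = 1.9-2.7 µmol m⁻² s⁻¹; cells between or
outside the bands stay unassigned, and overlapping bands are rejected.

## Problem sizes and determinism

Monte-Carlo checks in the tests and the acceptance script use 50-200
replicates of the 100-point grid (parameter recovery: 50 fields;
significance pattern: 200 assay tables; type-I calibration: 1000 tables),
sizes at which the binomial/MC tolerances asserted are comfortably
resolved. Every generator accepts either a seed or a shared
`numpy.random.Generator`; a pipeline run draws everything from the
single config seed, and rerunning a config byte-identically reproduces
all outputs. Output provenance (config hash, package version, stage) is
recorded in the run manifest inside `report.json`.
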