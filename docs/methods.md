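# Methods

This note documents the models, numerical choices and limitations of the
`poleward` pipeline, in the order the stages run.

## Synthetic transects (`poleward.simulate`)

The generator emulates a pole-to-pole surface-ocean transect sampled at the
chlorophyll maximum. Its defaults are the package's study conditions and are
used unchanged by the test suite.

**Environment.** Stations are equally spaced in latitude over
`lat_range = (−75°, 75°)` (a single hemisphere can be requested by narrowing
the range). Temperature declines linearly with distance from the equator from
`T_equator = 28 °C` to `T_pole = −1.5 °C`, with 0.1 °C measurement jitter.
Salinity co-varies positively with temperature (33–35.5 PSU); nitrate+nitrite
(0–16), phosphate (0–1.5) and silicate (0–30 µmol L⁻¹) co-vary negatively —
cold upper water is nutrient rich. Gaussian scatter on each covariate
(≈ 15 % of its range) keeps the nutrients imperfect proxies of temperature,
so temperature remains the identifiable structuring gradient; the covariance
signs still hold on every transect with ≥ 20 stations.

**Community.** Two latent regimes switch at the planted threshold ψ\*
(default 14 °C). Each cold/warm feature's expected abundance is
`base × logistic(∓(T − ψ*)/s)` with scale `s = 1.5 °C` and a per-feature peak
abundance `base` log-uniform within one decade around 100. Observed counts
multiply the expectation by 10^N(0, `noise_sd`) (`noise_sd = 0.2` by default;
multiplicative lognormal noise preserves positivity and is all that matters
after hits-per-million rescaling). Values below the detection limit (10
counts) read as absent, so each feature's presence boundary falls where its
own expected abundance crosses the limit — spreading presence–absence
turnover over a few degrees around ψ\* and giving the per-station beta
profile a V-shaped minimum at the regime boundary that the broken-stick
search can localize. A 3 % per-cell dropout adds the false absences real
amplicon data shows; it is disabled in the noiseless regime so that
`noise_sd = 0` yields fully deterministic tables. Shared ("ubiquitous")
taxa are present everywhere at constant expectation. Default richness is
asymmetric (16 warm vs 12 cold taxa per marker), matching the higher
diversity of warm oligotrophic water, which makes Shannon H′ rise with
temperature.

**Reference tables.** 18S species carry genome sizes (log-uniform, 10–1000
Mbp) and copy numbers obeying `log₁₀ copies = 0.66·log₁₀ Mbp + 0.75` plus
N(0, 0.35) noise; that noise level leaves the refit law with R² ≈ 0.55. A
configurable 30 % of species is masked in the emitted reference table to
exercise imputation. 16S genera carry strain-level copy-number records (1–3
species × 1–3 strains per genus) for the strain → species → lineage
averaging route. The taxonomy is a balanced four-level tree
(root/domain/class/genus/species).

**What the generator does not emulate:** ocean circulation, seasonality,
sequence-level artifacts (reads, chimeras), compositional coupling between
markers, and spatial autocorrelation beyond the temperature gradient. Tests
passing on these transects therefore validate the statistical machinery —
estimator correctness, recoverability of a planted boundary under realistic
noise — not the ecological claims on any real transect.

## Normalization (`poleward.normalize`, `poleward.taxonomy`)

Copy-number division runs first, then hits-per-million; means are arithmetic
throughout. The 18S law is fit by OLS on log₁₀ scales with genome size in
Mbp — the unit convention that makes the default coefficients yield
biologically plausible copy numbers (10²–10³ for 10–1000 Mbp genomes); the
unit only shifts the intercept. 18S normalization divides by the predicted
copy number 10^f(log₁₀ G), mirroring the explicit 16S division rule.
Missing attributes are imputed from the nearest ancestor whose subtree
contains a value (values propagate bottom-up as means of child means, so
every imputed value stays inside the range of the supplied ones).

Rank aggregation follows the "Nc."/"U." convention: features whose lineage
lacks the target rank pool under `Nc. <nearest ancestor above the rank>`;
abundance sitting directly on internal nodes between the target rank and the
root keeps its name prefixed `U.`; abundance on the root is dropped and the
dropped fraction reported, so total abundance is conserved up to that
fraction. Normalize-then-aggregate is the default order; both orders are
possible by composing the functions.

## Diversity (`poleward.diversity`)

Shannon H′ = −Σ pᵢ ln pᵢ (nats). The per-feature dispersion index is
Pielou's J′ of the feature's abundances across occupied stations,
H′/ln(occupancy), defined as 1 at occupancy 1 (the ln 1 guard); its exact
[0,1] range follows from H′ ≤ ln S. Bray–Curtis uses the standard
ratio-of-sums form Σ|n₁ₖ−n₂ₖ| / Σ(n₁ₖ+n₂ₖ); it is a semimetric (triangle
inequality not guaranteed), so only bounds and symmetry are asserted.
Covariate selection fits a Gaussian identity-link linear model (the response
is a continuous index) and drops the single least-significant covariate per
iteration (largest p ≥ 0.05, ties broken by column order) — deterministic
given input order. The CCA is the textbook single-constraint form:
chi-square standardization Q = (P − rcᵀ)/√(rcᵀ), row-weighted projection of
Q onto the standardized constraint, constrained inertia over total inertia;
it is cross-checked against an independent ordination implementation in the
tests.

## Networks (`poleward.network`)

Correlations are computed on log₁₀(hits-per-million + 1) profiles; the +1
pseudocount handles the pervasive zeros. The default adjacency is the
unsigned |r|^β (the formula stated with the published method, despite being
called "signed" there — the terminology clash is noted); a true signed
option ((1+r)/2)^β is available and is what the pipeline uses for module
detection, because two regimes that mirror each other along the gradient are
perfectly anti-correlated and indistinguishable under |r|. TOM follows
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(kᵢ,kⱼ) + 1 − a_ij). Module detection is
a fixed-height cut (default 0.99 on 1 − TOM) of average-linkage clustering
with a minimum module size, not the dynamic hybrid tree cut — simpler and
deterministic, sufficient for two planted modules; clusters below the size
floor are grey (unassigned). Modules are named by decreasing size with the
conventional palette (turquoise, blue, …). Eigengenes are the first
principal component of the standardized member block, scaled to unit sample
variance and oriented so the mean member correlation is positive.
Module–trait p-values use the exact t transform with n − 2 df. Latitude
enters trait correlation as altered latitude.

## Breakpoints (`poleward.breakpoints`)

Presence is strict (> 0, or a user threshold). The per-station reduction of
the pairwise Sørensen matrix defaults to the mean dissimilarity to all other
stations; nearest-neighbour and adjacent-by-latitude reductions are exposed
because the choice is genuinely open. The bagplot rule computes exact
bivariate Tukey halfspace depth (per-point angular scan of connecting-segment
normals, with ±ε nudges against boundary ties), takes the convex hull of the
≥ 50 % deepest points as the bag, inflates it by 3 about the depth median,
and flags points outside; degenerate inputs (< 10 points or collinear) flag
nothing and warn. The broken stick is continuous (shared value at ψ — a
well-posed 3-parameter model) with candidate ψ at midpoints of consecutive
sorted unique x (avoiding degenerate segment assignment) and at least 3
points per side; the search is exhaustive, so it equals a brute-force
candidate loop by construction. The reported p-value is the F-test of the
broken stick against the straight line with 2 numerator df; because ψ is
unidentified under the null (the Davies problem) this p-value is
approximate, and the result object carries that caveat. The 16S/18S preset
restricts the temperature axis to [7, 29.02] °C — restriction first, then
outlier flagging. Gap-fill scenarios donate the beta value of the nearest
donor by |latitude| (ties to the northern donor), with donors drawn from all
stations or from named regions.

## Climate projection (`poleward.climate`)

Delta bias correction is exact on the calibration period by construction
(corrected historical ≡ observations to machine precision). Band thresholds
default to the three breakpoint temperatures 9.49 < 13.96 < 18.06 °C and are
assigned half-open upward (a cell exactly at a threshold takes the warmer
band — the published strict inequalities leave boundary cells undefined, so
a convention is required). The ice mask comes from the observed climatology
only. Multi-decade averaging of supplied per-period fields is a plain
arithmetic mean; there is no internal time-series handling. NetCDF I/O uses
the NetCDF3 backend; long-form CSV (lat, lon, value, ice) is the text
fallback.

## Problem sizes and determinism

Default analyses run on 40-station transects with 38–200 taxa and 80 Pfams,
and 60 × 72 grids; the parameter-recovery suite uses 100 such transects.
All randomness flows through `numpy.random.default_rng` seeded from a single
integer, so identical configuration and seed reproduce byte-identical
artifacts.

## Known limitations

* The reference compilation of 185 eukaryote genome sizes and 18S copy
  numbers is not redistributable here; the copy-number law's published
  coefficients can only be re-derived when a user supplies that table
  (`data/reference/copy_number_genome_size_185_species.tsv`).
* The breakpoint p-value is anti-conservative near the null (Davies).
* Single-breakpoint models only; no multiple-changepoint search.
* The bagplot fence is a scalar inflation of the bag hull; the classical
  construction interpolates depth contours and can differ slightly on small
  samples.
* Unsigned adjacency cannot separate anti-correlated modules; use the signed
  option when regimes may mirror each other.
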