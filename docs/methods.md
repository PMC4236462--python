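# Methods

This note documents the models, conventions and numerical choices behind
`medrefugia`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Molecular arm

### Haplotypes and missing data

Bases other than A/C/G/T (IUPAC ambiguity codes, N, gaps) are treated as
unresolved. Haplotype collapsing is strict by default: fully resolved
sequences seed the haplotype classes; a partially resolved sequence joins
a class only when it is compatible (equal at all mutually resolved sites)
with exactly one class. A sequence compatible with several classes is set
aside as unassignable with a warning rather than merged by an arbitrary
rule — partial sequences are fragile and the ambiguity should be visible,
not silently resolved. An `exact` mode (byte equality) is available.

Nucleotide diversity uses complete deletion by default (only sites
resolved in every sequence), while p-distance matrices use pairwise
deletion; the two families of statistics are conventionally computed by
different programs with these respective defaults, and both modes are
switchable. Consequently "analyzed sites" (L_eff) can differ between the
two outputs for the same alignment.

### Neutrality statistics

Fu's Fs uses the Ewens sampling formula with θ̂ = k̄ (mean pairwise
differences). The unsigned Stirling numbers of the first kind are built by
the row recurrence in log space (`logaddexp`), so sample sizes of several
hundred pose no overflow problem. S′ = Pr(K ≥ H_obs) and
Fs = ln(S′/(1 − S′)); S′ numerically equal to 0 or 1 yields signed
infinity rather than an exception, because a boundary value is still
interpretable (H = 1 ⇒ S′ = 1 ⇒ +∞). Fs is undefined at S = 0 and raises.

R2 = sqrt((1/n) Σ (Uᵢ − k̄/2)²)/S with folded singleton counts: a site
contributes to Uᵢ when its minority base occurs exactly once, attributed
to the carrier. Without an outgroup the folded convention is the one an
observed alignment supports; the simulated null uses the same convention
so observed and simulated statistics are comparable.

Significance is by fixed-S coalescent simulation: standard Kingman
genealogies (interval with k lineages ~ Exponential(k(k−1)/2)), exactly S
mutations placed multinomially proportional to branch length, statistic
recomputed per replicate, p = (1 + #{sim ≤ obs})/(n_sims + 1). Both tail
probabilities are exposed because the conventional "significant at 5%"
call for Fs uses the 2% left tail. Calibration: with n = 30, S = 20 and
1000 outer replicates the 5% left-tail rejection rate of both statistics
falls inside the 99% binomial envelope (measured ≈ 0.045 for Fs, ≈ 0.052
for R2).

### Mantel / isolation by distance

Pearson correlation of the upper triangles, geographic distances
log-transformed with zeros replaced by half the smallest positive
distance (the transform needs a zero rule; this one is scale-consistent).
Simultaneous row/column permutation, one-tailed (r ≥ observed),
p = (1 + hits)/(n_perm + 1). Datasets with fewer than five localities are
refused outright — sparse matrices make the permutation distribution
meaningless. Default 999 permutations, configurable (the conventional
counts in the literature vary between 999 and 10000).

### Gridded diversity and rarity

Grid points are laid every `spacing` km in latitude and longitude over
the sampled extent; the neighborhood radius defaults to the spacing and
is configurable over 50–450 km. At each point with at least m (default 5)
samples in radius, B (default 1000) subsamples of size m are drawn
without replacement; per draw: H_T is the bias-corrected haplotype
diversity, H_R the number of distinct haplotypes, and R the mean over
drawn individuals of haplotype rarity, defined as the inverse of the
number of distinct localities occupied by that haplotype dataset-wide.
The rarity definition is an interpretation (the index family is cited in
the literature without a formula); it is monotone in geographic
restrictedness and bounded in (0, 1]. On pools small enough to enumerate,
the bootstrap means match exhaustive-draw expectations within Monte-Carlo
error.

### Statistical-parsimony connection limit

The probability that a j-step connection between haplotypes is
parsimonious (no multiple substitutions behind any single observed
difference) is operationalized as the finite-sites collision estimate

    P(j; L) = (3/4)^(j² / L),

read as: j substitutions scattered uniformly over L sites offer on the
order of j²/L opportunities for a superimposed change, each of which
escapes detection with the Jukes–Cantor factor 3/4. The limit is the
largest j with P(j; L) ≥ the confidence level. For a 1016-site alignment
this gives 13 steps at 95% and 5 at 99% — the limits the TCS program
computes for alignments of that length — and it is monotone in L and in
confidence. Alternative operationalizations examined during development
(plug-in Poisson/Jukes–Cantor single-hit probability; a Bayesian
integral over the pairwise coalescent time) agree at the 99% level but
give 12 rather than 13 steps at 95%; the collision form is the one
consistent with the program's published behavior.

Networks connect haplotype pairs at 1, 2, … up to the limit using raw
mutational differences with pairwise deletion; all edges within the limit
are kept, so alternative equal-length connections (loops) are retained —
delimitation uses connectivity only, never frequency-based loop breaking.

### GMYC, single threshold

Candidate thresholds are the branching ages plus a threshold at the
present. For a threshold T, events older than T belong to the
between-species (Yule-type) process and younger events to within-cluster
coalescent processes; each inter-event interval contributes
ln bᵢ − bᵢ xᵢ with the combined hazard
bᵢ = λ₁ n_Y^p₁ + λ₂ Σ_c [n_c(n_c − 1)]^p₂. The null is a single
generalized branching process b = λ n^p, which is exactly the
alternative's configuration with the threshold at the present — so the
likelihood ratio is non-negative by construction. For fixed p the null
rate has a closed form, leaving a bounded 1-D search; the alternative is
maximized by bounded L-BFGS-B on log-rates (and the exponents unless
fixed) from a deterministic multi-start grid, exponents bounded in
[0.05, 3]. The LRT uses χ² with 3 df (1 when exponents are fixed) — a
stated convention, configurable. Ties between equally good thresholds
break toward the older one; the entity confidence interval collects all
candidates within 2 log-likelihood units. Trees must be binary and
ultrametric (tip-age deviation ≤ 10⁻⁶ of root age); a zero-age internal
node is rejected as the signature of un-collapsed duplicate haplotypes.

## Synthetic data: what it emulates

`SimConfig` defaults describe the study conditions: a ~1 kb
mitochondrial fragment (1016 sites), 60 samples in 4 lineages across 15
localities, θ = 6 per lineage locus, an isolation-by-distance kernel of
300 km, a 60×60 grid of 0.5° cells over a Mediterranean-scale lon/lat
box, 4 pseudo-GCMs over LGM / mid-Holocene / present with 0.5 °C
coherent perturbation fields, and 150 occurrence records.

Lineages get independent Kingman genealogies and infinite-sites
mutations on a shared ancestral background, plus a 25-site
lineage-diagnostic block emulating deep divergence; between-lineage
p-distances land at a realistic few percent and exceed the 95%
connection limit, so lineages form separate networks. Structured
placement draws each sample's locality with weight exp(−d/ibd_scale)
around a lineage center; `mixing_fraction` then reassigns that fraction
of samples uniformly over localities (the human-transport emulation).
With no mixing, locality-level Mantel tests are significant in ≥90% of
runs; with full mixing the rejection rate is nominal. The uniform
reassignment is one stated choice of transport model, not the only
possible one.

The climate truth is a logistic bell in annual mean temperature (BIO1)
and annual precipitation (BIO12), steep enough (logistic factor 8) that
the species has a well-defined envelope: suitability is near 0 or 1
outside a sub-cell-width edge zone. Past slices cool the temperature
field uniformly (−1 °C mid-Holocene, −5 °C LGM) and the moisture
gradient shifts south in concert — glacial storm tracks follow the
cooling — so past climates are southward translations of the present
envelope rather than no-analogue states. Seasonal amplitude and diurnal
spread vary with longitude, not latitude, for the same reason: a uniform
cooling then translates the whole climate vector field instead of
manufacturing conditions that never exist in the calibration region
(which MOP would rightly delete). Truth rasters record per-slice
suitability and the refugium mask (cells ≥ 0.5 in every slice).

What passing the synthetic tests does **not** show: the generator has no
recombination, selection, rate heterogeneity, sequencing error, spatial
sampling bias, or disagreement between GCM physics beyond smooth additive
perturbations — real-data behavior of all downstream methods can be
worse in each of those directions.

## Niche arm

### Bioclim and downscaling

The 19 standard bioclim layers are computed with 3-month wrap-around
quarters (ties toward the earliest window) and sample standard deviations
in BIO4/BIO15; the four quarter-interaction layers known for spatial
artifacts (BIO8, BIO9, BIO18, BIO19) are computed but excluded, leaving
15 for modeling. Change-factor downscaling interpolates coarse anomalies
(bilinear by default, inverse-distance optional) and applies them to the
fine current climatology: additively for temperatures, multiplicatively
for precipitation with an ε = 0.01 mm guard against arid-cell division;
the identity holds exactly under zero anomaly and precipitation never
goes negative. The interpolation choice replaces an unspecified kriging
step; the downstream consensus maps do not depend on the interpolator at
the simulated smoothness.

### Environmental PCA

PCA is on the correlation matrix of the 15 retained layers over the
calibration region (the variables mix °C, mm and indices);
zero-variance variables are dropped with a warning; the retained k is
the smallest with cumulative explained variance ≥ 0.99; component signs
follow a deterministic convention (largest-magnitude loading positive).
Projection to other slices centers and scales with the calibration
means/SDs and multiplies by the stored loadings — never refit.

### Maxent

Features are polynomial terms of the PCA scores — linear, squares,
pairwise products, cubes, fourth powers — standardized over the
background. Products are required because an envelope elliptical in the
original variables is a rotated ellipse in score space, which an
axis-aligned quadratic cannot represent; the even quartic terms let the
exponential-family density take flat-topped, sharp-edged (super-Gaussian)
profiles instead of being forced Gaussian. Hinge/threshold features
remain an extension point. The L1-penalized concave objective is solved
exactly by bounded L-BFGS-B on the positive/negative split η = a − b,
gradient tolerance 10⁻⁶; constant features are dropped; non-convergence
raises with diagnostics. βⱼ = r·sⱼ/√m with multiplier r = 1 by default.
Bootstrap replicates resample presences with replacement, background
fixed.

### Aggregation, thresholding, masking, evaluation

Replicate maps are placed on a common density-ratio scale (raw output ×
background cell count, i.e. suitability relative to uniform), then
median over bootstrap replicates → ×1000 → integer floor → median over
occurrence subsets. A common scale matters: the raw output alone is of
order 1/n_cells and floors to zero, and normalizing each map by its own
maximum would give every time slice its own unit, breaking threshold
transfer. The minimum-training-presence threshold τ is the lowest
aggregated suitability at any occurrence on the *training* (present-day)
surface and is applied unchanged to that model's paleo projections —
training omission is zero by construction. MOP flags strict
extrapolation (any score dimension outside the calibration min–max) and
scores similarity as 1 − (mean distance to the nearest ⌈αn⌉ calibration
points)/(max over projection cells), α = 0.1 by default; suitable cells
under strict extrapolation are removed. Partial ROC restricts the
sensitivity-vs-proportional-area curve to omission ≤ E (default 1%),
divides by the chance-diagonal area over the same range, and bootstraps
test points (50% with replacement, 1000 iterations); a zero-width
restriction degenerates to the sensitivity/area ratio at the single
operating point.

### Refugia

M1 applies the agreement threshold per slice against the models
*available* for that slice (thresholds given as fractions are rounded up,
so {1/G, 1/2, 3/4, 1} of 8 models give counts {1, 4, 6, 8}, and slices
missing some models use ⌈fraction × available⌉); M2 intersects each
model's slices first and applies the threshold to the full model list.
Cells where fewer than k models have data are nodata. The strictest M2
level can legitimately be empty and is reported as such, never as an
error. Components use queen adjacency by default (coastal diagonals) with
latitude-corrected cell areas; rook is available and recorded.

### End-to-end recovery

The pipeline default replication is 3 occurrence subsets × 10 bootstrap
replicates per GCM (the full-study convention of 10 × 100 is a
configuration away; at the simulated smoothness extra replication
changes the maps marginally while multiplying runtime). Against the
synthetic truth, per-slice binary maps reach Jaccard ≈ 0.75–0.95 and
intermediate-stringency refugia typically ≈ 0.7–0.9. The residual, and
its seed-to-seed spread, is dominated by the minimum-training-presence
rule: τ is a minimum statistic of 150 suitability values, and a single
occurrence drawn in the envelope's thin fringe (occurrences are drawn
with probability proportional to suitability, so this happens regularly)
halves the threshold for every model at once. That permissiveness is a
property of the method being reproduced, not of the implementation.

## Determinism

Every stochastic operation takes a seed; the pipeline derives named
substream seeds (FNV-style hash below 2³¹) from one root seed, so stages
can be rerun independently and whole runs are bit-reproducible.
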