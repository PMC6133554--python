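# Methods

## Compartment geometry

A slide is described by a tumor boundary polygon (µm coordinates,
taken from the input as-is) and an optional tissue outline. Three
compartments are derived by Euclidean buffering with round joins:
the tumor core is the tumor eroded by the margin width (default
500 µm), the inner invasive margin is the remainder of the tumor, and
the outer invasive margin is the band of the same width outside the
tumor. Multi-part tumors are buffered jointly, so overlapping outer
margins merge — the reading a pathologist gives a contiguous invasion
front. When a tissue outline is supplied all three compartments are
clipped to it; clipping is optional because annotation practice at
tissue edges varies between labs. Areas convert to mm² via
1 mm² = 10⁶ µm².

Degenerate cases are explicit rather than silent: if the margin width
exceeds the tumor's maximum inscribed radius the core is empty with
area 0 (logged), and densities over zero-area compartments are missing
values — never 0 and never infinite. Slides with a missing needed
compartment are excluded from classification, not imputed.

Cell assignment uses covering (boundary-inclusive) point-in-polygon
tests ordered core → inner margin → outer margin, so a cell exactly on
a shared boundary deterministically joins the inner-most compartment.
Only `cell_class == "positive"` records are counted; negative records
are tolerated and tallied in the log, since many cell-detection exports
interleave both.

The geometry is validated two ways in the test suite: against closed
forms (disk and square tumors) and against an independent raster
oracle that fills the polygon by scanline and measures band membership
with Euclidean distance transforms at 1 µm resolution.

## Classification

The *inside* density defaults to pooling the core with the inner
margin — (count_core + count_inner)/(area_core + area_inner) — because
those two compartments are strongly correlated across slides and
markers while neither tracks the outer margin; a `core_only` mode is
provided for analyses that contrast the core directly with the outer
margin. The *outside* density is the outer-margin density.

Each marker's cutoff is the median of all non-missing slide ×
compartment densities pooled across entities and all three
compartments. Whether that pooled median should instead be taken over
entity-level summaries is ambiguous in principle; pooling slide-level
observations is the simpler estimator and is what this package does
(the choice is recorded in output metadata). "High" means strictly
greater than the cutoff, so ties at the median are "low" — a
deterministic tie-break on a median split. The rule is then: inside
high → hot (whatever the outside); outside high alone → excluded;
otherwise cold. Classification always uses absolute densities.
Percentile normalization — 100·(rank − 0.5)/n with average ranks for
ties, computed per marker across all entities — is reserved for
visualization (target plots) and for the cross-entity similarity
analysis, where markers with different dynamic ranges must be
comparable.

Compartment correlations default to Pearson on raw densities
(Spearman by flag), pairwise-complete with a minimum of three pairs
per matrix entry.

## Cluster-number protocol

Feature matrices are slides × (marker, compartment) absolute
densities; missing entries are mean-imputed per feature with a logged
count. Three algorithms (Gaussian mixture with full covariance and
k-means initialization; k-means with k-means++ and 10 restarts; Ward
hierarchical) are scored by three internal criteria (Davies-Bouldin,
minimized; Calinski-Harabasz and silhouette, maximized) for k = 1..12
with 10 technical replicates. All three criteria are mathematically
undefined at k = 1, so k = 1 is recorded as not-evaluable rather than
silently dropped; consequently "no clustering" can never win, which
the summary metadata states. Ties in the mode resolve to the smaller k
and are flagged. Replicate seeds derive from a master seed through
`SeedSequence`, so runs are reproducible and independent of row order
up to the seed stream.

Cross-entity similarity averages percentile-normalized feature vectors
over the patients of each entity (patients missing any feature are
dropped — the analysis presumes the full marker panel), then
agglomerates entity means with Euclidean distance and average linkage
(both configurable; no linkage choice is canonical for this analysis).
The dendrogram exports to Newick with ultrametric depths equal to
merge heights.

## Survival model

The generative and the fitted model match deliberately. The simulator
draws event times from an exponential baseline hazard multiplied by
exp(linear predictor), where the predictor carries the bivariate
phenotype's log hazard ratio plus stage, age and sex effects;
censoring is an independent exponential. Proportional hazards
therefore hold exactly, and recovery tests measure estimator bias, not
model misspecification.

The Cox partial likelihood uses the Efron tie correction (the
lower-bias standard; with continuous simulated times it coincides with
Breslow) and is maximized by Newton-Raphson with step-halving.
Covariate columns are centered inside the likelihood evaluation —
an exact invariance of the partial likelihood that removes the
floating-point cancellation which otherwise floors the attainable
gradient norm — and iteration stops when the gradient's infinity norm
falls below 1e-9 (well inside the documented 1e-8 contract); failure
to reach it raises with the last gradient norm. The step-halving
acceptance slack scales with |log-likelihood| so numerical noise near
the optimum cannot reject full Newton steps. Binary terms whose
carriers (or non-carriers) have no events are complete-separation
hazards: they are flagged non-estimable and excluded before fitting
instead of drifting to infinite coefficients.

The phenotype enters as eight indicators against the
CD8-cold/CD163-cold reference; stage as three indicators against
stage I; age continuous per year; sex as one indicator. Wald
confidence intervals and p-values are reported. The 3×3 hazard-ratio
table carries HR = 1 at the reference by definition, no HR for empty
cells, and estimability flags. A univariate analogue (one
compartment's density as a continuous covariate with the same
confounders) is provided as the negative control: raw densities alone
are typically not prognostic where the bivariate grid is.

Kaplan-Meier estimates carry Greenwood variance and log-log confidence
intervals; with no censoring the curve equals the empirical survival
function exactly. The k-sample log-rank test uses the hypergeometric
covariance and, for two groups on untied data, equals the Cox score
test — an identity the tests verify to 1e-6. The in-package
implementations are cross-checked against lifelines and against a
grid-search maximizer of the partial likelihood.

## Synthetic data: what it emulates, what it does not

Slides are radially perturbed circles (smooth low-order Fourier noise,
star-shaped hence simple by construction) with piecewise-constant
Poisson intensity per compartment and uniform placement by
bounding-box rejection sampling (bound 10⁶ proposals). The
piecewise-constant choice matches the per-compartment density readout
and keeps every expectation analytic (count ~ Poisson(λ·area)), at the
price of realism: no density gradients across the margin, no clustered
structures such as tertiary lymphoid aggregates, no staining artifacts
and no pixel-level imagery. Passing recovery tests therefore show that
the pipeline measures what the point process encodes — not that real
IHC noise is harmless.

Archetype intensities anchor to the classification cutoff with a
separation factor (default 4×): hot = all compartments at 4× the
cutoff, cold = all at cutoff/4, excluded = outer margin 4× with a low
interior. Cohorts draw the nine bivariate phenotypes from an explicit
joint distribution; an optional concordance parameter instead makes
the myeloid label copy the lymphoid one with a given probability
(a single-parameter simplification — real inter-marker concordance
varies by entity and is not modeled mechanistically). Covariates are
stage ~ multinomial(0.2, 0.3, 0.3, 0.2) over I-IV, age ~ N(65, 10)
truncated to [30, 95], sex ~ Bernoulli(0.5); defaults are arbitrary
but fixed, and configurable. Default hazards (baseline 0.05 events per
time unit, censoring 0.02, stage log-HRs 0/0.3/0.7/1.2, age 0.02 per
year, sex 0.1) give realistic event fractions (~75-85%) in abstract
time units. One master seed spawns per-patient substreams keyed by
patient index, so extending a cohort preserves existing patients, and
exports are byte-identical across reruns of the same seed.

## Problem sizes and numerical choices

The validation suite uses sizes chosen for statistical resolution:
200 slides per archetype for label recovery (binomial SE ≈ 1.5% at
95%), 50 replicate cohorts of n = 1000 for Cox bias (SE of the mean
≈ 0.012 on the log-HR, against a 0.1 bound), 400 replicates for
log-rank type-I error (SE ≈ 1.1% around 5%), and n = 6000 with a
colorectal-like phenotype mix for the hazard-table re-derivation
(SE ≈ 5% per recovered HR). Geometry oracles run at 1 µm raster
resolution; blob fixtures use a 1000 µm mean radius so no compartment
is near-degenerate and relative area comparisons stay well-posed.

## Known limitations

Coordinates must already be in µm — pixel-space annotations without
calibration are rejected by design. No spatial statistics beyond
compartment densities (no nearest-neighbor distances, Ripley's K or
gradients), no consensus clustering or bootstrap stability, no
proportional-hazards diagnostics or competing risks, and no multiple-
testing correction across the eight phenotype terms (the hazard table
reports raw Wald p-values). The cluster-number protocol's verdict on
real cohorts depends on the marker subset supplied; the protocol
accepts arbitrary subsets for that reason.
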