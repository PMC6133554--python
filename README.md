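# immunotopo

Spatial immune topography of solid tumors, from cell centroids and a
tumor boundary to prognosis.

Immunohistochemistry slides of solid tumors are routinely summarized by
where immune cells sit relative to the tumor invasion front. This
package quantifies that *topography*: it splits a slide into three
compartments — the tumor core (`TU_CORE`), the inner 500 µm invasive
margin (`MARG_500_IN`) and the outer 500 µm invasive margin
(`MARG_500_OUT`) — measures per-marker cell densities in cells/mm², and
classifies each slide per marker as

* **hot** — inside density (core pooled with inner margin) strictly
  above the marker's cutoff, regardless of the outside density;
* **immune-excluded** — inside at or below the cutoff, outer margin
  above it;
* **cold** — low on both sides.

The cutoff is the median density for that marker pooled over every
slide, tumor entity and compartment. Pairing a lymphoid marker (CD8)
with a myeloid marker (CD163) gives a 3×3 *bivariate phenotype* grid,
which a multivariable Cox proportional-hazards model (Efron ties; UICC
stage, age and sex as confounders) turns into a hazard-ratio table per
phenotype against the CD8-cold/CD163-cold reference.

For whom: computational pathology and tumor-immunology groups who have
cell-detection exports (CSV/TSV centroid tables) and region annotations
(GeoJSON), and who want compartment densities, hot/cold/excluded calls,
cluster-number diagnostics and phenotype-stratified survival in one
tested pipeline. A synthetic-cohort generator (piecewise-constant
inhomogeneous Poisson point patterns with known archetypes, plus an
exponential proportional-hazards outcome model) makes every stage
testable without any slide data.

## Worked example

`examples/01_simulate_and_classify.py` simulates one hot, one cold and
one immune-excluded slide at 4× intensity separation from a 50 cells/mm²
cutoff, then runs geometry → densities → classification:

```
      slide_id marker  inside_density  outside_density    label
    cold_slide    CD8             9.9             12.8     cold
excluded_slide    CD8            16.1            201.7 excluded
     hot_slide    CD8           199.3            198.2      hot
```

Each slide recovers its generating archetype: the excluded slide has a
dense outer margin (202 cells/mm²) but an empty interior, while the hot
slide is dense everywhere inside.

`examples/03_survival_stratification.py` simulates 2000 patients with
known hazards (HR 1.75 for CD8-excluded/CD163-excluded, HR 2.71 for
CD8-excluded/CD163-hot, double-cold reference) and refits them:

```
hazard ratios vs CD8-cold/CD163-cold (rows: CD8, cols: CD163)
CD163     cold  excluded   hot
CD8
cold      1.00      1.08  1.01
excluded  0.99      1.68  2.55
hot       0.87      0.98  1.04

log-rank across the three CD8-excluded groups: chi2 = 53.50, df = 2, p = 0.0000
```

Only the two phenotype cells simulated with a true effect show elevated
hazard ratios (1.68 and 2.55, against true values 1.75 and 2.71 at this
sample size); all other cells sit near 1. The other examples cover the
cluster-number protocol (`02`, modal optimum k = 2 on a hot-vs-cold
density mixture) and target-plot ring values (`04`).

## Command line

A thin CLI wraps the library for shell use:

```bash
immunotopo simulate --out demo --seed 1 --n-patients 20
immunotopo densities --cells demo/cells.csv --regions demo/regions --out demo/densities.csv
immunotopo classify --densities demo/densities.csv --out demo/labels.csv
immunotopo survive --labels demo/labels.csv --clinical demo/clinical.csv --out demo/surv
immunotopo run --config pipeline.yaml   # full pipeline with manifest
```

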