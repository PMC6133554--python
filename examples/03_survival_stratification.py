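"""Bivariate phenotype survival stratification on a simulated cohort.

Simulates colorectal-like patients whose bivariate CD8 x CD163 phenotype
carries a known hazard: HR 1.75 for CD8-excluded/CD163-excluded and
HR 2.71 for CD8-excluded/CD163-hot versus the double-cold reference,
with UICC stage, age and sex as genuine confounders. A multivariable
Cox model should recover both effects, and the log-rank test should
separate the three CD8-excluded groups.
"""

import math

import numpy as np

from immunotopo import SurvivalSpec, simulate_cohort
from immunotopo.survival import (
    all_phenotypes,
    logrank_by_group,
    phenotype_hazard_table,
    phenotype_name,
)

true_hr = {
    phenotype_name("excluded", "excluded"): 1.75,
    phenotype_name("excluded", "hot"): 2.71,
}
spec = SurvivalSpec(log_hr={ph: math.log(h) for ph, h in true_hr.items()})
probs = {ph: 0.4 / 6 for ph in all_phenotypes()}
probs[phenotype_name("cold", "cold")] = 0.25
probs[phenotype_name("excluded", "excluded")] = 0.20
probs[phenotype_name("excluded", "hot")] = 0.15

cohort = simulate_cohort(2000, probs, survival=spec, seed=1)
tab = phenotype_hazard_table(cohort.patients)

print("hazard ratios vs CD8-cold/CD163-cold (rows: CD8, cols: CD163)")
print(tab["hr"].round(2).to_string())
print()
print("Wald p-values")
print(tab["p"].round(4).to_string())
print()
print("patients per phenotype cell")
print(tab["n"].to_string())

excl = cohort.patients[cohort.patients["label_CD8"] == "excluded"]
lr = logrank_by_group(excl)
print()
print(f"log-rank across the three CD8-excluded groups: chi2 = {lr.statistic:.2f}, "
      f"df = {lr.df}, p = {lr.p:.4f}")
print("HRs near 1.75 and 2.71 with small p confirm that the bivariate grid,")
print("not either marker alone, carries the prognostic signal.")
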