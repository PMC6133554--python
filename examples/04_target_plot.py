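"""Target-plot ring values for an excluded versus an inflamed slide.

Each compartment density is percentile-normalized against a reference
cohort for the marker; the three values color the rings of a 'target
plot' (outer margin -> inner margin -> core). An immune-excluded slide
shows a high outer ring and low center; an inflamed slide is high
everywhere.
"""

import numpy as np

from immunotopo import target_plot_data
from immunotopo.geometry import MARG_IN, MARG_OUT, TU_CORE

rng = np.random.default_rng(2)
reference = rng.exponential(100.0, 300)  # pooled cohort densities, cells/mm2

excluded = {MARG_OUT: 420.0, MARG_IN: 35.0, TU_CORE: 20.0}
inflamed = {MARG_OUT: 380.0, MARG_IN: 300.0, TU_CORE: 260.0}

for name, slide in (("immune-excluded", excluded), ("inflamed", inflamed)):
    rings = target_plot_data(slide, reference)
    print(f"{name} slide, ring percentiles (outer -> inner -> core):")
    print("  " + "  ".join(f"{c}: {v:5.1f}" for c, v in rings.items()))

print()
print("values are percentiles (0-100) of each ring's density within the")
print("reference cohort; use immunotopo.topography.plot_target to render.")
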