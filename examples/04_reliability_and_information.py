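"""Reliability and item functioning before vs after adjustment.

McDonald's omega (one-factor saturation with a percentile-bootstrap CI) and
graded-response-model test information are compared for raw 5-point items
and their 7-point vignette-adjusted versions.
"""

import numpy as np

from avadjust import (SimConfig, apply_keying, compare_omegas, fit_grm,
                      information_curves, mcdonald_omega, recode_survey,
                      simulate)

res = simulate(SimConfig(group_sizes=(300, 150)), seed=3)
table, _ = recode_survey(apply_keying(res.table, res.codebook), res.codebook)

construct = "conscientiousness"
cols = [it.item_id for it in res.codebook.items_for(construct)]

before = mcdonald_omega(table.data[cols], n_bootstrap=300, seed=0)
after = mcdonald_omega(table.data[[c + "_adj" for c in cols]], n_bootstrap=300, seed=0)
print(f"omega({construct}) original: {before}")
print(f"omega({construct}) adjusted: {after}")
print("CI-overlap comparison:", compare_omegas(before, after))

f_o = fit_grm(table.data[cols], compute_se=False)
f_a = fit_grm(table.data[[c + "_adj" for c in cols]], compute_se=False)
band = np.linspace(2, 4, 21)
io = information_curves(f_o, band).test_information.mean()
ia = information_curves(f_a, band).test_information.mean()
print(f"\nmean test information for theta in (2, 4): "
      f"original {io:.2f}, adjusted {ia:.2f}")
print("The adjusted 7-point items keep measuring in the high-trait range "
      "where the original scale has ceiling problems.")
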