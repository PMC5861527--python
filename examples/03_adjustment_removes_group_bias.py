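"""The core claim: vignette adjustment removes group-level threshold DIF.

Both groups have identical latent trait distributions, but group 2 uses the
response scale more conservatively (all thresholds shifted by +0.8).  Raw
scale scores therefore show a spurious between-group difference; scores
recoded against each respondent's own vignette ratings largely do not.
"""

from avadjust import (SimConfig, apply_keying, recode_survey, recovery_report,
                      simulate)
from avadjust.validity import scale_scores

cfg = SimConfig(group_sizes=(1000, 1000), delta=(0.0, 0.8))
res = simulate(cfg, seed=10)
adjusted, _ = recode_survey(apply_keying(res.table, res.codebook), res.codebook)

raw = scale_scores(adjusted, res.codebook, adjusted=False, apply_score_reversal=False)
adj = scale_scores(adjusted, res.codebook, adjusted=True, apply_score_reversal=False)
rep = recovery_report(raw, adj, res.truth.loc[adjusted.data.index])

print(rep[["d_latent", "d_raw", "d_adjusted", "bias_raw", "bias_adjusted"]].round(3))
print("\nd_* are standardized between-group differences; bias_* subtract the")
print("latent-truth difference. The adjusted bias is a fraction of the raw")
print("bias for every construct: the recoding removed the threshold artifact.")
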