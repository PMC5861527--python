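"""Recode single self-ratings against vignette ratings.

A respondent rates three vignettes of known intended order (low < medium <
high) on the same 5-point scale as their self-report.  The self-rating is
then re-expressed on a 7-point scale by its position relative to the
respondent's own vignette ratings: odd categories are gaps, even categories
exact ties.  Ties and misorderings give an interval; the lower bound is the
default scalar value.
"""

from avadjust import chance_baselines, recode_item

cases = [
    ("self below all vignettes", 1, (2, 3, 4)),
    ("self equals the middle vignette", 3, (2, 3, 4)),
    ("self above all vignettes", 5, (2, 3, 4)),
    ("self ties two equally-rated vignettes", 3, (3, 3, 4)),
    ("misordered vignettes, treated as ties", 2, (4, 2, 3)),
]
print("self  vignettes   ->  interval  scalar")
for label, y, z in cases:
    s = recode_item(y, z)
    print(f"  {y}   {z}  ->  [{s.lo}, {s.hi}]     {s.scalar}    ({label})")

pc, pt, pv = chance_baselines(m=5, k=3)
print(f"\nUnder random rating (5-point scale, 3 vignettes): "
      f"{100*pc:.0f}% correct order, {100*pt:.0f}% ties, {100*pv:.0f}% violations.")
print("Observed correct-order rates far above 8% indicate respondents "
      "perceive the vignettes as intended.")
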