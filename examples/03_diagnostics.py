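"""Carrier genotype as a myelotoxicity screen.

Aggregates carriers (TT or CT) across the case-control studies: sensitivity
is the fraction of myelotoxicity cases who carry the variant, specificity
the fraction of unaffected patients who do not.  Also prints pooled
per-genotype adverse-event rates and the spread of per-study CT rates.
"""

from thiometa import carrier_diagnostics, genotype_event_rates, table1_fixture

studies = table1_fixture()
d = carrier_diagnostics(studies)
print(f"sensitivity: {d.sensitivity:.2%} ({d.tp}/{d.tp + d.fn})")
print(f"specificity: {d.specificity:.2%} ({d.tn}/{d.tn + d.fp})")

r = genotype_event_rates(studies)
for g in ("TT", "CT", "CC"):
    print(f"{g} event rate: {r.pooled[g]:.2%}")
print(f"per-study CT rate: min {r.ct_min:.2%}, median {r.ct_median:.2%}, "
      f"max {r.ct_max:.2%}")
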