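"""Combine P values across cohorts and test driver overrepresentation.

Two cohorts of the same anatomical site each give a gene p = 0.05; Fisher's
method turns them into one site-level P ~ 0.0175.  The overrepresentation
example asks: are likely drivers enriched among the 183 curated chromatin
regulatory factors?  34 of 183 CRFs are drivers versus 382 of 22,696 genes
overall — an upper-tail hypergeometric P of ~1.26e-25.
"""

from crfdrivers import bh_adjust, combine_pvalues, combine_site, driver_enrichment_test

p_site = combine_pvalues([0.05, 0.05], method="fisher")
print(f"Fisher combination of [0.05, 0.05]: {p_site:.5f}  (chi^2_4 survival)")

print("BH of [0.01, 0.02, 0.03, 0.04]:",
      [round(float(q), 4) for q in bh_adjust([0.01, 0.02, 0.03, 0.04])])

results = combine_site(
    {"cohortA": {"KMT2D": (0.05, None), "EP300": (0.40, None)},
     "cohortB": {"KMT2D": (0.05, None)}},
    site="bladder",
)
for r in results:
    print(f"{r.gene}: site p_fm={r.p_fm:.4f}, q_fm={r.q_fm:.4f}, from {r.datasets}")

p = driver_enrichment_test(34, 183, 382, 22696)
print(f"\ndriver overrepresentation among CRFs: P = {p:.2e}")
print("(34/183 CRFs are drivers vs 382/22,696 genes overall)")
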