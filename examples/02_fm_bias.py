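"""Detect FM-biased genes: accumulation of high-impact mutations.

Generates a cohort with two impact-shifted driver genes, runs the empirical
FM-bias test on every gene and prints the top of the ranking.  A small p_fm
means the gene's protein-affecting mutations carry systematically higher
functional impact scores than same-size draws from the cohort background —
the positive-selection signal that marks candidate drivers.
"""

from crfdrivers import DriverSpec, SimulationConfig, dataset_fm_bias, generate_catalog, group_fm_bias

config = SimulationConfig(
    n_samples=150, n_genes=200, predictors=("ma",), seed=7,
    driver_specs=(DriverSpec("G0010", "fis_shift"), DriverSpec("G0020", "fis_shift")),
)
catalog = generate_catalog(config)

results = dataset_fm_bias(catalog, n_samplings=10_000, seed=8)
print("gene      n_pam   p_fm       q_fm")
for r in results[:5]:
    print(f"{r.gene_or_group:8s} {r.n_pam:5d}   {r.p_fm:.2e}  {r.q_fm:.2e}")
print("(the two injected genes should lead the ranking with q << 0.05)")

# Gene groups (multiprotein complexes) are tested by pooling member PAMs:
group = group_fm_bias(catalog, {"G0010", "G0020"}, "demo-complex",
                      n_samplings=10_000, seed=9)
print(f"\npooled complex: n_pam={group.n_pam}, "
      f"samples with a PAM={group.n_samples_with_pam}, p_fm={group.p_fm:.2e}")
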