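"""Per-sample CF ratios and mutual exclusivity of complex members.

The CF ratio of a sample is the fraction of its mutated driver genes that
are chromatin regulatory factors; the exclusivity test asks whether two
genes are mutated in fewer common samples than their margins predict
(hypergeometric lower tail), the pattern expected when mutating either
member of a complex suffices.
"""

import numpy as np

from crfdrivers import (
    SimulationConfig,
    alteration_matrix,
    exclusivity_sort,
    generate_catalog,
    generate_gene_universe,
    pairwise_exclusivity_test,
    sample_profiles,
    site_mutated_fraction,
)

config = SimulationConfig(n_samples=120, n_genes=150, predictors=("ma",), seed=11)
catalog = generate_catalog(config)
universe = generate_gene_universe(config)

# pretend genes 6-25 were flagged as drivers; the synthetic universe makes
# its first 15 genes CRFs, so 10 of these 20 drivers are CRFs
genes = sorted(universe.genes)
drivers = set(genes[5:25])
crf_drivers = drivers & universe.crf_genes
profiles = sample_profiles(catalog, drivers, crf_drivers)
ratios = [p.cf_ratio for p in profiles if p.cf_ratio is not None]
print(f"samples with >=1 mutated driver CRF: {site_mutated_fraction(profiles):.0%}")
print(f"median CF ratio over {len(ratios)} samples with mutated drivers: "
      f"{np.median(ratios):.2f}")

# perfectly exclusive toy pair
a = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
b = [0, 0, 0, 0, 1, 1, 1, 1, 0, 0]
print(f"\nexclusivity P for margins (4,4)/10 with no overlap: "
      f"{pairwise_exclusivity_test(a, b):.4f}  (= 15/210)")

matrix = alteration_matrix(catalog, genes[:6])
rows, cols = exclusivity_sort(matrix)
print("memo-sorted alteration matrix (first 12 samples):")
print(matrix.loc[rows, cols].iloc[:, :12].to_string())
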