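"""Detect CLUST-biased genes: mutation hotspots along the protein.

Injects positional hotspots into two genes and calibrates the clustering
score against synonymous mutations of the same cohort.  A gene score of 1
means every positioned PAM sits on a single residue; the one-sided P comes
from a normal fit to the synonymous background scores.
"""

from crfdrivers import DriverSpec, SimulationConfig, dataset_clust_bias, generate_catalog
from crfdrivers.clust import find_clusters

# the detector itself, on a hand-made position multiset:
clusters = find_clusters([50, 50, 50, 53, 53, 200], protein_length=300, gap=5)
print("clusters of {50x3, 53x2, 200x1}:",
      [(c.start, c.end, c.count) for c in clusters],
      "(the singleton at 200 is never a seed)")

config = SimulationConfig(
    n_samples=150, n_genes=200, mutations_per_sample=8.0, predictors=("ma",),
    seed=3,
    driver_specs=(DriverSpec("G0005", "hotspot"), DriverSpec("G0015", "hotspot")),
)
catalog = generate_catalog(config)
calls = dataset_clust_bias(catalog)
print("\ngene      n_pos  score  clusters          q_clust")
for c in calls[:5]:
    spans = ";".join(f"{cl.start}-{cl.end}:{cl.count}" for cl in c.clusters)
    print(f"{c.gene:8s} {c.n_pam_positioned:5d}  {c.gene_score:.3f}  {spans:16s}  {c.q_clust:.2e}")
print("(the two injected genes concentrate all PAMs on one residue, score 1;"
      "\n any other flagged gene carries a genuine chance residue coincidence,"
      "\n which the synonymous-calibrated null treats as clustering evidence)")
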