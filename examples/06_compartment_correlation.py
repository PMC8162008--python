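"""Correlation of expression-class density with an A/B compartment track.

Constitutive genes cluster in gene-dense (A-compartment-like) territory and
repressed genes in pericentromeric (B-compartment-like) territory, so their
fixed-bin densities correlate with the eigenvector with opposite signs.
"""

from expherit import SimulationSpec, compartment_correlation, gene_truth
from expherit.sim import simulate_gene_catalog, simulate_tracks

spec = SimulationSpec(seed=6)
truth = gene_truth(spec)
catalog = simulate_gene_catalog(spec)
eig, peri = simulate_tracks(catalog, truth, bin_bp=500_000, seed=6)
labels = truth.set_index("gene_id")["class_control"]

for label in ("constitutive", "repressed"):
    out = compartment_correlation(catalog, labels, eig, bin_bp=500_000,
                                  method="spearman", label=label)
    rhos = ", ".join(f"{r:.2f}" for r in out["rho"])
    print(f"{label:>12} density vs eigenvector, rho per chromosome: {rhos}")
print()
print("Positive eigenvector = A compartment. Constitutive density follows it")
print("closely; repressed density runs against it (pericentromeric B).")
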