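"""Tissue expression of antigen-source genes and expression weighting.

Joins presented peptides to a gene-by-tissue expression table, counts genes
expressed above 10 relative expression units (REU) per tissue, and computes
the expression-weighted potential sum(REU * 1/IC50) for one tissue.
"""

import numpy as np

import allopotential as ap

config = ap.SimulationConfig(seed=31, n_genes=12)
genes = [f"GENE{i + 1:03d}" for i in range(12)]
table = ap.simulate_expression(genes, config)

rng = np.random.default_rng(32)
aas = list(ap.AMINO_ACIDS)
records = [
    ap.BindingRecord.make(
        "".join(rng.choice(aas, size=9)),
        "HLA-A*02:01",
        "SMM",
        float(rng.uniform(5, 450)),
        {"gene": genes[i % len(genes)]},
    )
    for i in range(40)
]

counts, unmapped = ap.count_expressed_antigen_genes(records, table, threshold=10.0)
print("genes with a presented peptide AND >10 REU, per tissue:")
for tissue, n in counts.items():
    print(f"  {tissue:16s} {n}")
if unmapped:
    print(f"({len(unmapped)} source genes missing from the table)")

wp = ap.weighted_potential(records, table, "liver")
print(f"\nexpression-weighted potential in liver: {wp.value:.3f}")
print("Each term REU*(1/IC50) is a proxy for the antigenic pressure one"
      " peptide-HLA complex exerts where its source gene is expressed.")
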