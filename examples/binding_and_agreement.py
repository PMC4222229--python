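"""Scoring nonamers against HLA alleles and merging two predictors.

Scores random nonamers with a tuned position-specific matrix, classifies
presentation (<500 nM presented, <50 nM strongly presented), simulates a
correlated second predictor's captured output, and reports the shared
complexes and the between-predictor correlation.
"""

import numpy as np

import allopotential as ap

config = ap.SimulationConfig(seed=21)
matrices = ap.simulate_matrices(config, ["HLA-A*02:01", "HLA-B*07:02"])
genotype = ap.HlaGenotype("patient", ("HLA-A*02:01", "HLA-B*07:02"))

rng = np.random.default_rng(22)
aas = list(ap.AMINO_ACIDS)
nonamers = ["".join(rng.choice(aas, size=9)) for _ in range(400)]

records = ap.binding.score_peptides(nonamers, genotype, matrices)
presented = [r for r in records if r.presentation is not ap.Presentation.NONE]
strong = [r for r in records if r.presentation is ap.Presentation.STRONGLY_PRESENTED]
print(f"{len(records)} peptide-allele pairs scored")
print(f"  presented (<500 nM):          {len(presented)}")
print(f"  strongly presented (<50 nM):  {len(strong)}")

pan_text = ap.simulate_pan_predictions(records, config)
pan_records = ap.parse_pan_predictor_output(pan_text)
shared = ap.shared_complexes(records, pan_records)
print(f"shared complexes presented by BOTH predictors: {len(shared)}")

r, p, n = ap.correlate_predictions(shared, log_scale=True)
print(f"between-predictor correlation on shared complexes: r={r:.2f} (P={p:.2g}, n={n})")
print("Agreement between independent predictors raises confidence that a"
      " complex is a genuine candidate minor antigen.")
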