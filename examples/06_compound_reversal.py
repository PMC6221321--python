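"""Rank compounds whose signatures oppose the dependence signature.

The query is the dependence-associated DEG signature (gene -> signed
fold change); each compound's DEG list (p < 0.05, |FC| > 1.2 at load time)
is compared with a weighted Kolmogorov-Smirnov connectivity score.
Negative scores mean the compound pushes those genes the opposite way;
significance comes from a gene-label permutation null.
"""

import io

import numpy as np

from odm.reversal import QuerySignature, rank_compounds, read_compound_library
from odm.simulate import SimulationConfig, simulate_expression, simulate_regulators_and_compounds

config = SimulationConfig(n_genes=300, de_fraction=0.15, n_compounds=60, seed=9)
dataset, truth = simulate_expression(config)
_, _, compounds = simulate_regulators_and_compounds(truth, config, seed=2)

buf = io.StringIO()
compounds.to_csv(buf, sep="\t", index=False)
buf.seek(0)
library = read_compound_library(buf)   # applies the DEG filter per compound

weights = {}
for genes in truth.effect_associated_genes.values():
    for g in genes:
        amp = truth.amplitudes[g][config.opioids[0]]
        weights[g] = float(np.sign(amp) * 2.0 ** abs(amp))
query = QuerySignature(weights)

ranked = rank_compounds(query, library, n_perm=999, seed=0)
print(f"query: {len(weights)} dependence-associated genes; "
      f"library: {len(library)} compounds\n")
print("top 5 by reversal strength (score < 0 opposes the query):")
for r in ranked[:5]:
    print(f"  {r.compound:10s} score {r.score:+.3f}  shared {r.n_shared:2d}  "
          f"perm_p {r.perm_p:.3g}  opposite: {','.join(r.opposite_genes[:4])}"
          f"{'...' if len(r.opposite_genes) > 4 else ''}")
# CMPD_REV is the planted exact negation of the query - it regulates every
# query gene in the opposite direction, so it tops the ranking with the
# permutation floor p = 1/(n_perm+1).
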