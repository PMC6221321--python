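"""Build a synthetic multi-drug time-course bundle with planted truth.

Writes the full plain-text input bundle (expression matrix, sample sheet,
harm scores, gene sets, annotation, peaks, compound library, ground truth)
and prints what was planted.
"""

from odm.simulate import SimulationConfig, write_bundle

config = SimulationConfig(n_genes=300, de_fraction=0.1, n_compounds=50, seed=11)
paths = write_bundle(config, "example_bundle")

print(f"bundle written to example_bundle/ ({config.n_genes} genes, "
      f"{len(config.drugs)} drugs, {config.n_replicates} replicates at "
      f"{config.time_grid_hours} h)")
for name, path in paths.items():
    print(f"  {name:13s} {path}")

# The ground truth drives every downstream acceptance check: per opioid,
# n_genes * de_fraction genes follow one of six rise/plateau/return
# templates (up/down x immediate-early/middle/late) at linear fold change
# fc_planted; a few genes per dependence effect additionally carry a
# cross-drug response that is an affine image of that effect's harm scores.
import json

truth = json.loads(paths["ground_truth"].read_text())
morphine = truth["structure"]["de_genes"]["morphine"]
print(f"\nplanted DE genes (morphine): {len(morphine)}")
first = list(morphine)[:6]
for g in first:
    print(f"  {g}: {morphine[g]}")
print("dependence-associated genes:",
      truth["structure"]["effect_associated_genes"])
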