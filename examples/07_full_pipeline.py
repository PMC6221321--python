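"""Run the whole pipeline end to end on a synthetic bundle.

Equivalent to `odm simulate --out bundle && odm run --config
bundle/pipeline.yaml --out run`; all seven stage outputs land in the run
directory as provenance-stamped TSVs, and re-running with the same
configuration reproduces them byte for byte.
"""

from odm.pipeline import PipelineConfig, run_pipeline
from odm.simulate import SimulationConfig, write_bundle

config = SimulationConfig(n_genes=400, de_fraction=0.12, n_compounds=80, seed=17)
paths = write_bundle(config, "example_bundle_full")

pipeline = PipelineConfig(
    expression=str(paths["expression"]), samples=str(paths["samples"]),
    harm_scores=str(paths["harm_scores"]), gene_sets=str(paths["gene_sets"]),
    annotation=str(paths["annotation"]), peaks=str(paths["peaks"]),
    compounds=str(paths["compounds"]), n_restarts=300, n_perm=499, seed=17,
)
result = run_pipeline(pipeline, "example_run")

for drug, calls in result.deg_calls.items():
    print(f"{drug}: {int(calls.is_de.sum())} DEGs of {len(calls)} genes")
for drug, res in result.clusterings.items():
    print(f"{drug}: K = {res.K} temporal patterns (ASW {res.asw:.3f}), "
          f"labels {sorted(set(res.labels.values()))}")
for drug, tab in result.regulator_scores.items():
    if len(tab):
        top = tab.iloc[0]
        print(f"{drug}: top regulator {top.regulator} [{top.phase}] "
              f"dependence score {top.signed_score:+.2f} over N={top.n}")
for drug, tab in result.reversal_rankings.items():
    if len(tab):
        top = tab.iloc[0]
        print(f"{drug}: strongest reversal {top.compound} "
              f"(score {top.score:+.3f}, perm_p {top.perm_p:.3g})")
print(f"\nstage outputs in {result.run_dir}/ "
      "(deg_*, clusters_*, asw_by_k_*, enrichment_functional_*, "
      "associations_*, enrichment_regulator_*, regulators_*, reversal_*)")
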