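"""Generator contracts: determinism, planted structure, emitted files."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from odm.dataset import read_expression
from odm.simulate import (
    DEFAULT_EFFECTS,
    PATTERNS,
    SimulationConfig,
    simulate_expression,
    simulate_harm_scores,
    simulate_regulators_and_compounds,
    write_bundle,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs, message",
        [
            ({"time_grid_hours": (1.0, 2.0)}, "time_grid_hours"),
            ({"time_grid_hours": (0.0, 2.0, 1.0)}, "time_grid_hours"),
            ({"n_replicates": 1}, "n_replicates"),
            ({"noise_sd": 0.0}, "noise_sd"),
            ({"de_fraction": 1.0}, "de_fraction"),
            ({"de_fraction": -0.1}, "de_fraction"),
            ({"fc_planted": 0.8}, "fc_planted"),
        ],
    )
    def test_invalid_fields_name_the_offender(self, kwargs, message):
        with pytest.raises(ValueError, match=message):
            SimulationConfig(**kwargs)


class TestExpression:
    def test_null_config_plants_nothing(self):
        cfg = SimulationConfig(n_genes=50, de_fraction=0.0, seed=3,
                               assoc_genes_per_effect=0)
        ds, truth = simulate_expression(cfg)
        assert truth.de_genes == {}
        assert ds.values.shape == (50, 6 * 5 * 3)

    def test_planted_counts_match_de_fraction(self):
        cfg = SimulationConfig(n_genes=100, de_fraction=0.1, seed=1,
                               assoc_genes_per_effect=1)
        _, truth = simulate_expression(cfg)
        for opioid in cfg.opioids:
            assert len(truth.de_genes[opioid]) == 10

    def test_identical_seed_bit_identical(self, small_config):
        ds1, _ = simulate_expression(small_config)
        ds2, _ = simulate_expression(small_config)
        assert ds1.values.equals(ds2.values)

    def test_seed_changes_noise_not_structure(self, small_config, small_bundle):
        _, truth1 = small_bundle
        ds2, truth2 = simulate_expression(small_config, seed=small_config.seed + 1)
        assert truth1.structural_summary()["de_genes"] == truth2.structural_summary()["de_genes"]
        assert truth1.effect_associated_genes == truth2.effect_associated_genes

    def test_control_time0_shared_across_drugs(self, small_bundle):
        ds, _ = small_bundle
        t0 = ds.samples.loc[ds.samples.time_hours == 0]
        by_rep = {}
        for name, row in t0.iterrows():
            by_rep.setdefault(row.replicate, []).append(name)
        for rep, cols in by_rep.items():
            vals = ds.values[cols].to_numpy()
            assert np.allclose(vals, vals[:, [0]])

    def test_every_de_gene_has_one_pattern_per_drug(self, small_bundle):
        _, truth = small_bundle
        for drug, recs in truth.de_genes.items():
            for g, rec in recs.items():
                assert rec["pattern"] in PATTERNS

    def test_near_miss_fc_below_threshold(self, small_bundle):
        small_ds, truth = small_bundle
        assert truth.near_miss_genes
        for drug, genes in truth.near_miss_genes.items():
            assert genes
            for g in genes:
                assert g not in truth.de_genes[drug]

    def test_nonde_gene_noise_is_gaussian(self, small_config, small_bundle):
        """Pooled residuals of unplanted genes pass a normality sanity check."""
        ds, truth = small_bundle
        planted = set()
        for recs in truth.de_genes.values():
            planted |= set(recs)
        null_genes = [g for g in ds.gene_ids if g not in planted][:40]
        resid = []
        for drug in ds.drugs:
            times, Y = ds.matrix_for(drug)
            sub = ds.values.loc[null_genes]
            for t in np.unique(times):
                cols = ds.samples.index[
                    (ds.samples.drug == drug) & (ds.samples.time_hours == t)
                ]
                block = sub[cols].to_numpy()
                resid.append(block - block.mean(axis=1, keepdims=True))
        pooled = np.concatenate([r.ravel() for r in resid])
        # subsample: Shapiro is oversensitive at huge n
        rng = np.random.default_rng(0)
        sample = rng.choice(pooled, size=500, replace=False)
        assert stats.shapiro(sample).pvalue > 0.01


class TestHarmScores:
    def test_requires_effects_and_enough_drugs(self, small_bundle):
        _, truth = small_bundle
        with pytest.raises(ValueError, match="empty"):
            simulate_harm_scores(["a", "b", "c", "d"], [], {}, truth)
        with pytest.raises(ValueError, match="4 drugs"):
            simulate_harm_scores(["a", "b"], ["dependence"], {}, truth)

    def test_unplanted_scores_independent_of_expression(self, small_bundle):
        _, truth = small_bundle
        drugs = ["morphine", "heroin", "cocaine", "nicotine"]
        t1 = simulate_harm_scores(drugs, ["x_eff"], {}, truth, seed=5)
        t2 = simulate_harm_scores(drugs, ["x_eff"], {}, truth, seed=5)
        assert t1.equals(t2)
        assert t1.shape == (1, 4)

    def test_planted_pair_affine_at_zero_noise(self, small_config, small_bundle):
        """With zero table noise the planted score vector is an exact affine
        image of the planted gene's cross-drug amplitudes: Pearson r = 1."""
        _, truth = small_bundle
        eff = small_config.assoc_effects[0]
        gene = truth.effect_associated_genes[eff][0]
        table = simulate_harm_scores(
            list(small_config.drugs), [eff],
            {eff: truth.effect_associated_genes[eff]}, truth, seed=9, noise_sd=0.0,
        )
        amps = np.abs([truth.amplitudes[gene][d] for d in small_config.drugs])
        r = np.corrcoef(table.loc[eff].to_numpy(), amps)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-12)


class TestRegulatorsAndCompounds:
    def test_planted_target_peak_within_window(self, small_config, small_bundle):
        _, truth = small_bundle
        anno, peaks, _ = simulate_regulators_and_compounds(truth, small_config, seed=3)
        pos = anno.set_index("gene")
        for reg, targets in truth.regulator_targets.items():
            pk = peaks.loc[peaks.regulator == reg]
            for g in targets:
                row = pos.loc[g]
                lo, hi = row.start - 1000, row.end + 1000
                hits = pk.loc[(pk.start < hi) & (pk.end > lo)]
                assert len(hits) >= 1
                mid = (hits.start + hits.end) // 2
                if row.strand == "+":
                    assert ((row.start - mid) <= 1000).all()
                else:
                    assert ((mid - row.end) <= 1000).all()

    def test_non_target_gene_has_no_nearby_peak(self, small_config, small_bundle):
        _, truth = small_bundle
        anno, peaks, _ = simulate_regulators_and_compounds(truth, small_config, seed=3)
        all_targets = set().union(*truth.regulator_targets.values())
        non_targets = [g for g in anno.gene if g not in all_targets][:10]
        pos = anno.set_index("gene")
        for g in non_targets:
            row = pos.loc[g]
            lo, hi = row.start - 1000, row.end + 1000
            assert len(peaks.loc[(peaks.start < hi) & (peaks.end > lo)]) == 0

    def test_reverser_negates_planted_signature(self, small_config, small_bundle):
        _, truth = small_bundle
        _, _, compounds = simulate_regulators_and_compounds(truth, small_config, seed=3)
        rev = compounds.loc[compounds.compound == "CMPD_REV"]
        assert truth.reversal_compounds == ["CMPD_REV"]
        for _, row in rev.iterrows():
            amp = truth.amplitudes[row.gene][small_config.opioids[0]]
            assert np.sign(row.signed_fc) == -np.sign(amp)


class TestBundleIO:
    def test_bundle_round_trip(self, tmp_path, small_config):
        paths = write_bundle(small_config, tmp_path)
        ds = read_expression(paths["expression"], paths["samples"])
        assert ds.n_genes == small_config.n_genes
        assert set(ds.drugs) == set(small_config.drugs)
        harm = pd.read_csv(paths["harm_scores"], index_col=0)
        assert list(harm.index) == list(DEFAULT_EFFECTS)
        truth = json.loads(paths["ground_truth"].read_text())
        assert set(truth["structure"]["regulator_targets"]) == {
            f"REG{k:03d}" for k in range(small_config.n_regulators)
        }
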