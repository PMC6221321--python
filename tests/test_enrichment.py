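"""Hypergeometric tails, BH adjustment, GMT parsing, target windows."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from odm.enrichment import (
    GeneSetCollection,
    assign_targets,
    bh_adjust,
    build_regulator_sets,
    enrich,
    hypergeom_upper_tail,
    read_gmt,
)


def enumerate_tail(k, K, n, N):
    """Oracle: P(X >= k) by enumerating all C(N, n) draws."""
    hits = sum(1 for draw in combinations(range(N), n) if sum(1 for x in draw if x < K) >= k)
    return hits / comb(N, n)


class TestHypergeom:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_upper_tail(0, 4, 5, 10) == 1.0

    def test_reference_case_66_over_252(self):
        assert hypergeom_upper_tail(3, 4, 5, 10) == pytest.approx(66 / 252, abs=1e-12)

    def test_full_overlap_of_full_sets(self):
        assert hypergeom_upper_tail(6, 6, 6, 6) == pytest.approx(1.0)

    def test_bounds_rejected(self):
        for bad in [(5, 4, 5, 10), (1, 11, 5, 10), (1, 4, 11, 10), (-1, 4, 5, 10)]:
            with pytest.raises(ValueError):
                hypergeom_upper_tail(*bad)

    def test_matches_enumeration_small_universes(self):
        """Exact agreement with the full-enumeration oracle, N <= 8 here
        (the acceptance suite pushes to N <= 12)."""
        for N in range(1, 9):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_upper_tail(k, K, n, N) == pytest.approx(
                            enumerate_tail(k, K, n, N), abs=1e-12
                        )


class TestBH:
    def test_step_up_worked_example(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.8]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.8], atol=1e-12)

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        assert np.all(bh_adjust(p) >= p - 1e-15)


class TestGMT:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "x.gmt"
        path.write_text("SET1\tdesc\tA\tb\tC\nSET2\tdesc\td\n")
        sets = read_gmt(path)
        assert sets == {"SET1": ["A", "B", "C"], "SET2": ["D"]}

    def test_short_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("SET1\tdesc\tA\nONLYNAME\n")
        with pytest.raises(ValueError, match=":2"):
            read_gmt(path)


def brute_force_targets(peaks, annotation, window):
    """Oracle: per-base overlap between peak bases and window bases."""
    targets = set()
    for _, g in annotation.iterrows():
        lo = max(g.start - window, 0)
        hi = g.end + window
        window_bases = set(range(lo, hi))
        for _, p in peaks.iterrows():
            if p.chrom != g.chrom:
                continue
            if window_bases & set(range(p.start, p.end)):
                targets.add(g.gene)
                break
    return targets


class TestAssignTargets:
    def _anno(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "strand"])

    def _peaks(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "regulator"])

    def test_peak_800bp_upstream_is_target(self):
        anno = self._anno([("chr1", 5000, 7000, "A", "+")])
        peaks = self._peaks([("chr1", 4200, 4300, "R")])
        assert assign_targets(peaks, anno).targets == {"A"}

    def test_peak_1100bp_upstream_is_not_target(self):
        anno = self._anno([("chr1", 5000, 7000, "A", "+")])
        peaks = self._peaks([("chr1", 3500, 3900, "R")])
        assert assign_targets(peaks, anno).targets == set()

    def test_minus_strand_downstream_of_genomic_start(self):
        """On the minus strand the TSS sits at the interval end, so a peak
        800 bp 3' of the genomic start (i.e. past the TTS) is in-window."""
        anno = self._anno([("chr1", 5000, 7000, "A", "-")])
        peaks = self._peaks([("chr1", 4150, 4250, "R")])
        assert assign_targets(peaks, anno).targets == {"A"}

    def test_unknown_chromosome_skipped(self, caplog):
        anno = self._anno([("chr1", 5000, 7000, "A", "+")])
        peaks = self._peaks([("chrX", 5000, 5100, "R")])
        with caplog.at_level("WARNING"):
            res = assign_targets(peaks, anno)
        assert res.targets == set()
        assert any("unknown chromosome" in m for m in caplog.messages)

    def test_matches_brute_force_on_random_toys(self):
        """Window assignment agrees with a per-base overlap oracle on random
        toy genomes, both strands, boundary cases included."""
        rng = np.random.default_rng(42)
        for _ in range(150):
            n_genes = rng.integers(1, 6)
            genes = []
            for i in range(n_genes):
                start = int(rng.integers(0, 30000))
                genes.append(
                    ("chr1", start, start + int(rng.integers(100, 3000)),
                     f"G{i}", "+" if rng.random() < 0.5 else "-")
                )
            anno = self._anno(genes)
            peaks = []
            for j in range(int(rng.integers(1, 6))):
                ps = int(rng.integers(0, 35000))
                peaks.append(("chr1", ps, ps + int(rng.integers(1, 500)), "R"))
            # deliberately add exact boundary peaks around the first gene
            g0 = genes[0]
            w = 1000
            peaks.append(("chr1", max(g0[1] - w - 200, 0), max(g0[1] - w, 1), "R"))
            peaks.append(("chr1", g0[2] + w, g0[2] + w + 100, "R"))
            pk = self._peaks(peaks)
            assert assign_targets(pk, anno, window_bp=w).targets == brute_force_targets(
                pk, anno, w
            )


class TestEnrich:
    def _collection(self):
        universe = {f"G{i}" for i in range(40)}
        sets = {
            "A": {f"G{i}" for i in range(10)},
            "B": {f"G{i}" for i in range(10, 20)},
            "C": {f"G{i}" for i in range(20, 30)},
        }
        return GeneSetCollection(sets=sets, universe=universe)

    def test_query_equal_to_one_set(self):
        coll = self._collection()
        rows = enrich({f"G{i}" for i in range(10)}, coll, mode="functional")
        assert rows.index[0] == "A"
        assert rows.loc["A", "p"] < 1e-6
        assert rows.loc["B", "k"] == 0 and rows.loc["B", "p"] == 1.0

    def test_regulator_mode_adds_fdr(self):
        coll = self._collection()
        rows = enrich({f"G{i}" for i in range(10)}, coll, mode="regulator")
        assert (rows["fdr_p"] >= rows["p"] - 1e-15).all()
        assert rows.loc["A", "significant"]

    def test_empty_query_warns_and_returns_empty(self, caplog):
        coll = self._collection()
        with caplog.at_level("WARNING"):
            rows = enrich({"NOT_A_GENE"}, coll, mode="functional")
        assert rows.empty

    def test_case_folding_at_boundary(self):
        coll = self._collection()
        rows = enrich({f"g{i}" for i in range(10)}, coll, mode="functional")
        assert rows.loc["A", "k"] == 10

    def test_random_queries_give_uniform_p(self):
        """Null calibration: the 'A'-set p-value over random same-size
        queries is stochastically >= uniform (hypergeometric p-values are
        discrete, hence conservative)."""
        rng = np.random.default_rng(1)
        coll = self._collection()
        universe = sorted(coll.universe)
        ps = []
        for _ in range(400):
            q = rng.choice(universe, size=10, replace=False)
            ps.append(enrich(set(q), coll, mode="functional").loc["A", "p"])
        ps = np.asarray(ps)
        for x in (0.05, 0.25, 0.5):
            assert np.mean(ps <= x) <= x + 3 * np.sqrt(x * (1 - x) / len(ps))

    def test_regulator_sets_from_bundle(self, small_config, small_bundle):
        from odm.simulate import simulate_regulators_and_compounds

        _, truth = small_bundle
        anno, peaks, _ = simulate_regulators_and_compounds(truth, small_config, seed=3)
        anno_df = anno.rename(columns={})
        coll = build_regulator_sets(peaks, anno_df)
        for reg, targets in truth.regulator_targets.items():
            assert coll.sets[reg] == {g.upper() for g in targets}
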