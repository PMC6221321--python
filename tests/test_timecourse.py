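"""Local quadratic smoothing, bandwidth selection, simultaneous bands,
and DE calling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odm.simulate import template_ie
from odm.timecourse import (
    DrugFits,
    SingularFitError,
    TimeCourseFit,
    assign_phase,
    call_degs,
    de_decision,
    default_grid,
    fit_dataset,
    fit_local_quadratic,
    hat_matrix,
    select_bandwidth_loocv,
    simultaneous_band,
    tube_critical_value,
    tube_tail,
)
from tests.conftest import make_single_drug_dataset

TIMES = np.repeat([0.0, 1.0, 2.0, 4.0, 8.0], 3)
GRID = default_grid(TIMES)


class TestLocalFit:
    def test_exact_quadratic_matches_global_ols(self):
        """With quadratic truth the local fit equals the global OLS quadratic
        at every evaluation point (the quadratic-limit oracle)."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            beta = rng.normal(size=3)
            y = beta[0] + beta[1] * TIMES + beta[2] * TIMES**2
            fitted, _ = fit_local_quadratic(TIMES, y, bandwidth=8.0, eval_times=GRID)
            expected = beta[0] + beta[1] * GRID + beta[2] * GRID**2
            np.testing.assert_allclose(fitted, expected, atol=1e-6)

    def test_constant_series_zero_halfwidths(self):
        y = np.full(TIMES.size, 3.5)
        fitted, se = fit_local_quadratic(TIMES, y, bandwidth=8.0, eval_times=GRID)
        np.testing.assert_allclose(fitted, 3.5, atol=1e-10)
        np.testing.assert_allclose(se, 0.0, atol=1e-10)

    def test_singular_bandwidth_raises_without_fallback(self):
        with pytest.raises(SingularFitError):
            hat_matrix(TIMES, np.array([6.0]), bandwidth=1.5)

    def test_fallback_rescues_singular_evaluation_points(self):
        L = hat_matrix(TIMES, np.array([6.0]), bandwidth=1.5,
                       fallback_bandwidths=(8.0,))
        assert np.isfinite(L).all()
        # hat weights reproduce constants
        assert L.sum() == pytest.approx(1.0)

    def test_tracks_planted_template_within_3se(self):
        """Monte-Carlo: fitted curve stays within 3 SE of the planted
        immediate-early template at the design points."""
        rng = np.random.default_rng(2)
        tpl = template_ie(np.unique(TIMES))
        ok = 0
        n_runs = 200
        for _ in range(n_runs):
            y = np.repeat(tpl, 3) + rng.normal(0, 0.2, TIMES.size)
            h = select_bandwidth_loocv(TIMES, y, [3.2, 4.4, 5.6, 6.8, 8.0])
            fitted, se = fit_local_quadratic(TIMES, y, h, np.unique(TIMES),
                                             fallback_bandwidths=(8.0, 16.0))
            # allow smoothing bias comparable to one SE on top of 3 SE noise
            ok += np.all(np.abs(fitted - tpl) <= 3 * np.maximum(se, 0.08) + 0.15)
        assert ok / n_runs >= 0.95


class TestBandwidthSelection:
    def test_single_candidate_returned(self):
        y = np.sin(TIMES)
        assert select_bandwidth_loocv(TIMES, y, [5.0]) == 5.0

    def test_quadratic_with_tiny_noise_prefers_largest(self):
        """On bias-free (exactly quadratic) truth the minimal-variance,
        largest candidate wins the plurality of draws."""
        rng = np.random.default_rng(3)
        picks = []
        for _ in range(50):
            y = 1.0 + 0.3 * TIMES - 0.05 * TIMES**2 + rng.normal(0, 0.01, TIMES.size)
            picks.append(select_bandwidth_loocv(TIMES, y, [3.2, 4.4, 5.6, 6.8, 8.0]))
        assert picks.count(8.0) >= 25

    def test_selection_matches_refit_loo_oracle(self):
        """The leverage-shortcut LOO error agrees with brute-force
        leave-one-out refitting, so the selected bandwidth matches the
        oracle's argmin."""
        rng = np.random.default_rng(13)
        candidates = [4.4, 5.6, 6.8, 8.0]
        for _ in range(10):
            y = rng.normal(0, 0.5, TIMES.size) + 0.2 * TIMES
            errors = []
            for h in candidates:
                sq = 0.0
                for i in range(TIMES.size):
                    mask = np.arange(TIMES.size) != i
                    pred, _ = fit_local_quadratic(
                        TIMES[mask], y[mask], h, np.array([TIMES[i]]),
                        fallback_bandwidths=(16.0,),
                    )
                    sq += (y[i] - pred[0]) ** 2
                errors.append(sq / TIMES.size)
            oracle = candidates[int(np.argmin(errors))]
            assert select_bandwidth_loocv(TIMES, y, candidates) == oracle

    def test_spike_selects_smaller_bandwidth_than_flat(self):
        rng = np.random.default_rng(4)
        spike_h, flat_h = [], []
        tpl = 2.0 * template_ie(np.unique(TIMES))
        for _ in range(50):
            noise = rng.normal(0, 0.2, TIMES.size)
            spike_h.append(select_bandwidth_loocv(TIMES, np.repeat(tpl, 3) + noise,
                                                  [3.2, 4.4, 5.6, 6.8, 8.0]))
            flat_h.append(select_bandwidth_loocv(TIMES, noise,
                                                 [3.2, 4.4, 5.6, 6.8, 8.0]))
        assert np.median(spike_h) < np.median(flat_h)


class TestTubeBand:
    def test_single_point_equals_t_quantile(self):
        from scipy import stats

        c = tube_critical_value(0.05, kappa0=0.0, df=10)
        assert c == pytest.approx(stats.t.ppf(0.975, 10), abs=1e-9)

    def test_critical_value_monotone_in_alpha(self):
        c05 = tube_critical_value(0.05, kappa0=3.0, df=12)
        c01 = tube_critical_value(0.01, kappa0=3.0, df=12)
        assert c01 > c05

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            tube_critical_value(0.0, 1.0, 10)

    def test_simultaneous_contains_pointwise(self, small_bundle, small_fits):
        from scipy import stats

        fits = small_fits["morphine"]
        for gene in fits.gene_ids[:10]:
            fit = fits.fit_for(gene)
            half = simultaneous_band(fit, alpha=0.05)
            pointwise = stats.t.ppf(0.975, fit.df_resid) * fit.se_fitted
            assert np.all(half >= pointwise - 1e-12)

    def test_band_coverage_on_null_curves(self):
        """Simultaneous 95% bands cover a flat true curve in >= 93% of
        simulated null series."""
        rng = np.random.default_rng(5)
        n_runs = 300
        covered = 0
        crit_cache = {}
        for _ in range(n_runs):
            y = rng.normal(0, 0.3, TIMES.size)
            h = select_bandwidth_loocv(TIMES, y, [3.2, 4.4, 5.6, 6.8, 8.0])
            fitted, se = fit_local_quadratic(TIMES, y, h, GRID,
                                             fallback_bandwidths=(8.0, 16.0))
            L = hat_matrix(TIMES, GRID, h, fallback_bandwidths=(8.0, 16.0))
            H = hat_matrix(TIMES, TIMES, h, fallback_bandwidths=(8.0, 16.0))
            df = TIMES.size - np.trace(H)
            U = L / np.linalg.norm(L, axis=1, keepdims=True)
            kappa0 = np.arccos(np.clip(np.einsum("ij,ij->i", U[:-1], U[1:]), -1, 1)).sum()
            key = (round(h, 6), round(kappa0, 6), round(df, 6))
            if key not in crit_cache:
                crit_cache[key] = tube_critical_value(0.05, kappa0, df)
            covered += np.all(np.abs(fitted) <= crit_cache[key] * se + 1e-12)
        assert covered / n_runs >= 0.93


class TestPhase:
    @pytest.mark.parametrize(
        "t, phase", [(1.0, "IE"), (2.0, "IE"), (2.5, "M"), (4.0, "M"), (5.0, "L"), (8.0, "L")]
    )
    def test_phase_map(self, t, phase):
        assert assign_phase(t) == phase

    @pytest.mark.parametrize("t", [0.0, -1.0, 8.5])
    def test_out_of_range_rejected(self, t):
        with pytest.raises(ValueError):
            assign_phase(t)


class TestDECalls:
    def test_fold_change_threshold_boundary(self):
        """A tiny p-value cannot rescue a fold change below 1.2."""
        assert not de_decision(adj_p=1e-9, signed_fc=1.19)
        assert not de_decision(adj_p=1e-9, signed_fc=-1.19)
        assert de_decision(adj_p=1e-9, signed_fc=1.2)
        assert de_decision(adj_p=0.06, signed_fc=3.0) is False

    def test_flat_genes_not_called(self):
        rng = np.random.default_rng(6)
        ds = make_single_drug_dataset(5.0 + rng.normal(0, 0.2, (50, 15)))
        calls = call_degs(ds, "morphine")
        assert not calls.is_de.any()

    def test_missing_time0_rejected(self):
        rng = np.random.default_rng(7)
        with pytest.raises(ValueError, match="time-0"):
            ds = make_single_drug_dataset(rng.normal(size=(5, 12)),
                                          time_points=(1, 2, 4, 8))
            call_degs(ds, "morphine")

    def test_planted_genes_recovered_with_phase(self, small_bundle, small_fits):
        ds, truth = small_bundle
        calls = call_degs(ds, "morphine", fits=small_fits["morphine"])
        de = set(calls.index[calls.is_de])
        planted = set(truth.de_genes["morphine"])
        recovered = de & planted
        assert len(recovered) / len(planted) >= 0.85
        correct_phase = sum(
            calls.loc[g, "phase"] == truth.de_genes["morphine"][g]["phase"]
            for g in recovered
        )
        assert correct_phase / len(recovered) >= 0.8
        correct_dir = sum(
            calls.loc[g, "direction"] == truth.de_genes["morphine"][g]["direction"]
            for g in recovered
        )
        assert correct_dir == len(recovered)

    def test_near_miss_genes_stay_below_fc_threshold(self, small_bundle, small_fits):
        ds, truth = small_bundle
        calls = call_degs(ds, "morphine", fits=small_fits["morphine"])
        near = truth.near_miss_genes["morphine"]
        assert (calls.loc[near, "signed_fc"].abs() < 1.35).all()

    @settings(max_examples=20, deadline=None)
    @given(shift=st.floats(min_value=-5, max_value=5, allow_nan=False))
    def test_shift_equivariance(self, shift):
        """Adding a constant to a gene's log2 values changes neither band_p
        nor signed_fc."""
        rng = np.random.default_rng(8)
        Y = 5.0 + rng.normal(0, 0.2, (10, 15))
        Y[0] += np.repeat(template_ie(np.unique(TIMES)), 3)
        ds1 = make_single_drug_dataset(Y)
        Y2 = Y.copy()
        Y2[0] += shift
        ds2 = make_single_drug_dataset(Y2)
        c1 = call_degs(ds1, "morphine")
        c2 = call_degs(ds2, "morphine")
        assert c1.loc["G000000", "band_p"] == pytest.approx(
            c2.loc["G000000", "band_p"], rel=1e-9, abs=1e-12
        )
        assert c1.loc["G000000", "signed_fc"] == pytest.approx(
            c2.loc["G000000", "signed_fc"], rel=1e-9
        )

    def test_tube_tail_between_zero_and_one(self):
        c = np.array([0.0, 1.0, 5.0, 50.0])
        p = tube_tail(c, kappa0=2.0, df=10)
        assert np.all((p > 0) & (p <= 1))
        assert np.all(np.diff(p) < 0)
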