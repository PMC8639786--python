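"""FLNe/SLN metrics, EDR fits, FC~FLNe regression, R^2 decompositions,
SLN-split asymmetry, GC inflow normalization, and the epoch bootstrap."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from rhythmnet.structfun import (
    anatomy_metrics_from_counts,
    bootstrap_over_epochs,
    edr_fit,
    fc_flne_regression,
    filter_min_neurons,
    gc_inflow_normalize,
    multiple_regression_flne,
    predictor_importance,
    sln_split_asymmetry,
    symmetrize_anatomy,
)


def counts_frame(rows):
    return pd.DataFrame(rows, columns=["source", "target", "n_labeled",
                                       "n_supra", "n_infra"])


class TestAnatomyMetrics:
    def test_flne_fractions(self):
        df = counts_frame([("A", "T", 90, 50, 40), ("B", "T", 10, 5, 5)])
        out = anatomy_metrics_from_counts(df)
        assert out.loc[out.source == "A", "flne"].item() == pytest.approx(0.9)
        assert out.loc[out.source == "B", "flne"].item() == pytest.approx(0.1)

    def test_sln_formula(self):
        df = counts_frame([("A", "T", 10, 5, 5), ("B", "T", 10, 8, 2)])
        out = anatomy_metrics_from_counts(df)
        assert out.loc[out.source == "A", "sln"].item() == 0.5
        assert out.loc[out.source == "B", "sln"].item() == 0.8

    def test_14_area_matrix_has_182_directed_91_undirected(self):
        areas = [f"a{i}" for i in range(14)]
        rows = [(s, t, 20, 10, 10) for s in areas for t in areas if s != t]
        out = anatomy_metrics_from_counts(counts_frame(rows))
        assert len(out) == 182
        assert len(symmetrize_anatomy(out)) == 91

    def test_zero_total_target_rejected(self):
        df = counts_frame([("A", "T", 0, 0, 0)])
        with pytest.raises(ValueError, match="zero total"):
            anatomy_metrics_from_counts(df)

    def test_intrinsic_rows_dropped(self):
        df = counts_frame([("T", "T", 1000, 0, 0), ("A", "T", 10, 5, 5)])
        out = anatomy_metrics_from_counts(df)
        assert len(out) == 1
        assert out["flne"].item() == 1.0


class TestMinNeuronFilter:
    def test_boundary_is_exclusive(self):
        df = counts_frame([("A", "T", 9, 4, 5), ("B", "T", 10, 5, 5),
                           ("C", "T", 11, 6, 5)])
        out = filter_min_neurons(anatomy_metrics_from_counts(df), 10)
        assert set(out["source"]) == {"B", "C"}

    def test_removed_fraction_grows_with_lambda(self):
        from rhythmnet.synthgen import AnatomyGenConfig, generate_anatomy, generate_site_layout

        lay = generate_site_layout(8, 2, spacing_mm=4.0)
        fracs = []
        for lam in (0.05, 0.2, 0.5):
            cfg = AnatomyGenConfig(lambda_decay=lam, lognormal_sigma=1.0,
                                   total_neurons_per_injection=2000, seed=3)
            df = generate_anatomy(lay, cfg)
            fracs.append(1 - len(filter_min_neurons(df, 10)) / len(df))
        assert fracs[0] < fracs[1] < fracs[2]


class TestEDRFit:
    def test_exact_noise_free(self):
        d = np.linspace(1, 40, 20)
        fit = edr_fit(np.exp(-0.2 * d), d)
        assert fit.lam == pytest.approx(0.2, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_weights_lambda_zero(self):
        d = np.linspace(1, 40, 10)
        fit = edr_fit(np.full(10, 0.3), d)
        assert fit.lam == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            edr_fit(np.array([1.0, 0.0, 2.0]), np.array([1.0, 2.0, 3.0]))


class TestFcFlneRegression:
    def test_exact_power_law_closed_form(self):
        flne = np.logspace(-5, 0, 30)
        fc = flne**0.5
        res = fc_flne_regression(fc, flne, bonferroni_m=12)
        assert res.r2 == pytest.approx(1.0)
        assert res.slope == pytest.approx(0.5)
        assert res.fold_change == pytest.approx(10**2.5, rel=1e-9)
        assert res.significant

    def test_fold_change_invariant_to_fc_scaling(self):
        rng = np.random.default_rng(0)
        flne = np.logspace(-4, 0, 40)
        fc = flne**0.3 * np.exp(0.2 * rng.standard_normal(40))
        a = fc_flne_regression(fc, flne)
        b = fc_flne_regression(fc * 17.3, flne)
        assert a.fold_change == pytest.approx(b.fold_change, rel=1e-12)

    def test_null_fold_change_ci_contains_one(self):
        # FC independent of FLNe: bootstrap CI of the fold change straddles 1
        rng = np.random.default_rng(1)
        flne = np.logspace(-4, 0, 60)
        n_epochs = 200
        fc_epochs = np.exp(0.5 * rng.standard_normal((60, n_epochs)))

        def resampler(r):
            idx = r.integers(0, n_epochs, n_epochs)
            return fc_epochs[:, idx].mean(axis=1)

        res = fc_flne_regression(fc_epochs.mean(axis=1), flne,
                                 fc_resampler=resampler, n_boot=100, seed=2)
        lo, hi = res.ci_999
        assert lo < 1.0 < hi

    def test_known_slope_recovered_within_ci(self):
        rng = np.random.default_rng(3)
        flne = np.logspace(-4, 0, 60)
        true_slope = 0.4
        n_epochs = 300
        base = flne**true_slope
        fc_epochs = base[:, None] * np.exp(0.4 * rng.standard_normal((60, n_epochs)))

        def resampler(r):
            idx = r.integers(0, n_epochs, n_epochs)
            return fc_epochs[:, idx].mean(axis=1)

        res = fc_flne_regression(fc_epochs.mean(axis=1), flne,
                                 fc_resampler=resampler, n_boot=100, seed=4)
        true_fold = 10 ** (true_slope * 4)  # log10 range of flne is 4
        lo, hi = res.ci_999
        assert lo < true_fold < hi


class TestMultipleRegression:
    def test_orthogonal_predictors_match_simple_slopes(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = 0.7 * x1 - 0.2 * x2 + 0.05 * np.sin(np.arange(n))
        res = multiple_regression_flne(
            10.0**y, np.column_stack([x1, x2]), log_fc=False,
            band_names=["x1", "x2"],
        )
        s1 = np.polyfit(x1, y, 1)[0]
        s2 = np.polyfit(x2, y, 1)[0]
        np.testing.assert_allclose(res.coefficients, [s1, s2], atol=1e-10)
        assert res.vif["x1"] == pytest.approx(1.0)
        assert res.vif["x2"] == pytest.approx(1.0)

    def test_exact_linear_combination_r2_one(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((50, 3))
        y = X @ [0.5, -1.0, 0.2]
        res = multiple_regression_flne(10.0**y, X, log_fc=False)
        assert res.r2_full == pytest.approx(1.0)
        # an irrelevant predictor contributes nothing
        X4 = np.column_stack([X, rng.standard_normal(50)])
        res4 = multiple_regression_flne(10.0**y, X4, log_fc=False,
                                        band_names=list("abcd"))
        assert res4.delta_r2["d"] == pytest.approx(0.0, abs=1e-10)

    def test_near_duplicate_predictor_inflates_vif(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(80)
        X = np.column_stack([x, x + 1e-3 * rng.standard_normal(80)])
        y = x + rng.standard_normal(80)
        res = multiple_regression_flne(10.0**y, X, log_fc=False,
                                       band_names=["a", "b"])
        assert res.vif["a"] > 100

    def test_perfect_collinearity_rejected(self):
        x = np.arange(20.0)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="collinearity"):
            multiple_regression_flne(10.0**x, X, log_fc=False,
                                     band_names=["a", "b"])


class TestPredictorImportance:
    def brute_force_subset_r2(self, X, y):
        """Independent all-subsets R^2 via direct normal equations."""
        out = {}
        p = X.shape[1]
        for k in range(1, p + 1):
            for sub in combinations(range(p), k):
                A = np.column_stack([np.ones(len(y)), X[:, list(sub)]])
                coef = np.linalg.solve(A.T @ A, A.T @ y)
                resid = y - A @ coef
                out[frozenset(sub)] = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        return out

    def test_orthogonal_closed_form(self):
        # two orthogonal predictors: unique effects equal their marginal R^2,
        # no common variance, and all decompositions agree
        n = 400
        rng = np.random.default_rng(7)
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = np.sqrt(0.3) * x1 + np.sqrt(0.2) * x2
        y = y + rng.standard_normal(n) * np.sqrt(1 - y.var())
        y = (y - y.mean()) / y.std()
        imp = predictor_importance(y, np.column_stack([x1, x2]), names=["a", "b"])
        r2a = np.corrcoef(x1, y)[0, 1] ** 2
        r2b = np.corrcoef(x2, y)[0, 1] ** 2
        t = imp.table
        assert t.loc["a", "unique"] == pytest.approx(r2a, abs=1e-10)
        assert t.loc["b", "unique"] == pytest.approx(r2b, abs=1e-10)
        assert t["common"].abs().max() < 1e-10
        np.testing.assert_allclose(t["gendom"], t["unique"], atol=1e-10)
        np.testing.assert_allclose(t["riw"], t["unique"], atol=1e-10)

    def test_decompositions_sum_to_r2(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((120, 5)) @ (np.eye(5) + 0.4)
        y = X @ rng.standard_normal(5) + rng.standard_normal(120)
        imp = predictor_importance(y, X)
        assert imp.table["gendom"].sum() == pytest.approx(imp.r2_full, abs=1e-10)
        assert imp.table["riw"].sum() == pytest.approx(imp.r2_full, abs=1e-10)
        assert sum(imp.commonalities.values()) == pytest.approx(imp.r2_full,
                                                                abs=1e-10)

    def test_commonality_matches_brute_force_lattice(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((60, 4))
        X[:, 1] += 0.6 * X[:, 0]
        y = X @ [1.0, 0.5, -0.3, 0.0] + rng.standard_normal(60)
        imp = predictor_importance(y, X)
        r2 = self.brute_force_subset_r2(X, y)
        full = frozenset(range(4))
        # every subset R^2 must be reconstructed by the commonality components
        for S, val in r2.items():
            recon = sum(c for T, c in imp.commonalities.items() if T & S)
            assert recon == pytest.approx(val, abs=1e-8)
        # unique effect identity against the brute-force lattice
        for i in range(4):
            u = r2[full] - r2[full - {i}]
            assert imp.commonalities[frozenset([i])] == pytest.approx(u, abs=1e-8)

    def test_suppressor_yields_negative_common(self):
        # x2 correlates with x1's noise component but not with y
        rng = np.random.default_rng(10)
        n = 500
        signal = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        x1 = signal + noise
        x2 = noise + 0.1 * rng.standard_normal(n)
        y = signal + 0.3 * rng.standard_normal(n)
        imp = predictor_importance(y, np.column_stack([x1, x2]), names=["x1", "x2"])
        assert imp.commonalities[frozenset([0, 1])] < 0
        assert imp.table.loc["x2", "common"] < 0

    def test_refuses_too_many_predictors(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((40, 13))
        with pytest.raises(ValueError, match="subsets"):
            predictor_importance(rng.standard_normal(40), X)


class TestSlnSplitAsymmetry:
    def test_equal_groups_index_zero(self):
        rng = np.random.default_rng(12)
        flne = np.logspace(-4, 0, 40)
        gc = flne**0.3
        sln = np.concatenate([np.full(20, 0.9), np.full(20, 0.1)])
        # identical FLNe dependence in both groups
        res = sln_split_asymmetry(np.concatenate([gc[:20], gc[:20]]),
                                  np.concatenate([flne[:20], flne[:20]]), sln)
        np.testing.assert_allclose(res.asymmetry_index, 0.0, atol=1e-9)

    def test_fold_three_vs_one_gives_half(self):
        flne = np.logspace(-4, 0, 30)
        span = 4.0
        slope_ff = np.log10(3.0) / span  # fold change 3
        gc_ff = flne**slope_ff
        gc_fb = np.ones_like(flne)  # fold change 1
        sln = np.concatenate([np.full(30, 0.9), np.full(30, 0.1)])
        res = sln_split_asymmetry(np.concatenate([gc_ff, gc_fb]),
                                  np.concatenate([flne, flne]), sln)
        assert res.ff_change_spectrum[0] == pytest.approx(3.0, rel=1e-9)
        assert res.fb_change_spectrum[0] == pytest.approx(1.0, abs=1e-9)
        assert res.asymmetry_index[0] == pytest.approx(0.5, rel=1e-9)

    def test_band_specific_dependence_detected(self):
        # FLNe dependence planted only in the feedforward group of band 0
        rng = np.random.default_rng(13)
        n = 50
        flne = np.logspace(-4, 0, n)
        sln = rng.uniform(0, 1, n)
        gc = np.empty((n, 2))
        gc[:, 0] = np.where(sln > 0.7, flne**0.4, 1.0) * np.exp(
            0.05 * rng.standard_normal(n))
        gc[:, 1] = np.exp(0.05 * rng.standard_normal(n))
        res = sln_split_asymmetry(gc, flne, sln)
        assert res.asymmetry_index[0] > 0.5
        assert abs(res.asymmetry_index[1]) < 0.2

    def test_small_group_skipped(self):
        flne = np.logspace(-2, 0, 10)
        sln = np.full(10, 0.5)  # nobody passes either cutoff
        res = sln_split_asymmetry(flne**0.2, flne, sln)
        assert np.isnan(res.ff_change_spectrum).all()
        assert np.isnan(res.fb_change_spectrum).all()


class TestGcInflowNormalize:
    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(14)
        W = rng.random((5, 5))
        out = gc_inflow_normalize(W)
        sums = np.nansum(out, axis=0)
        np.testing.assert_allclose(sums, 1.0)

    def test_single_source_column(self):
        W = np.zeros((3, 3))
        W[0, 2] = 0.7
        out = gc_inflow_normalize(W)
        assert out[0, 2] == 1.0
        assert np.isnan(out[:, 0]).all()  # zero inflow flagged undefined


class TestBootstrapOverEpochs:
    def test_constant_data_zero_width(self):
        lo, hi, _ = bootstrap_over_epochs(lambda idx: 5.0, n_epochs=100,
                                          n_boot=50, seed=0)
        assert lo == hi == 5.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(15)
        x = rng.standard_normal(200)
        fn = lambda idx: x[idx].mean()
        a = bootstrap_over_epochs(fn, 200, n_boot=60, seed=3)
        b = bootstrap_over_epochs(fn, 200, n_boot=60, seed=3)
        np.testing.assert_array_equal(a[2], b[2])

    def test_gaussian_mean_interval_covers_truth(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(1000)
        lo, hi, _ = bootstrap_over_epochs(lambda idx: x[idx].mean(), 1000,
                                          n_boot=100, ci_level=0.999, seed=4)
        assert lo < 0.0 < hi

    def test_undefined_resamples_redrawn(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(50)

        calls = {"n": 0}

        def flaky(idx):
            calls["n"] += 1
            return np.nan if calls["n"] % 7 == 0 else x[idx].mean()

        lo, hi, est = bootstrap_over_epochs(flaky, 50, n_boot=50, seed=5)
        assert len(est) == 50
        assert np.isfinite(est).all()
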