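import numpy as np
import pandas as pd
import pytest

from metaboage import preprocess as pp
from metaboage.simulate import SimulationConfig, simulate_genotypes, simulate_phenotypes
from metaboage import kinship

from conftest import make_matrix


class TestFilterMissingness:
    def test_strictly_above_threshold_dropped(self):
        vals = np.ones((100, 2))
        vals[:11, 0] = np.nan  # 11% missing -> dropped
        vals[:10, 1] = np.nan  # exactly 10% -> retained
        m, report = pp.filter_missingness(make_matrix(vals), 0.10)
        assert list(m.values.columns) == ["m01"]
        assert report["metabolite"].tolist() == ["m00"]
        assert report["missing_fraction"].iloc[0] == pytest.approx(0.11)

    def test_complete_matrix_noop(self):
        m, report = pp.filter_missingness(make_matrix(np.ones((5, 3))))
        assert m.values.shape == (5, 3)
        assert report.empty

    def test_all_dropped_raises(self):
        vals = np.full((4, 2), np.nan)
        with pytest.raises(ValueError, match="missingness"):
            pp.filter_missingness(make_matrix(vals), 0.10)


class TestFilterHemolysis:
    def test_grade4_removed(self):
        m, report = pp.filter_hemolysis(
            make_matrix(np.ones((4, 2)), hemolysis=np.array([0, 2, 4, 4]))
        )
        assert m.n_samples == 2
        assert len(report) == 2

    def test_all_clean_no_removal(self):
        m, report = pp.filter_hemolysis(make_matrix(np.ones((4, 2))))
        assert m.n_samples == 4 and report.empty

    def test_missing_grade_is_error(self):
        mat = make_matrix(np.ones((3, 2)))
        mat.sample_meta.loc[mat.sample_meta.index[1], "hemolysis"] = np.nan
        with pytest.raises(ValueError, match="hemolysis"):
            pp.filter_hemolysis(mat)

    def test_contamination_filter_restores_mean(self):
        cfg = SimulationConfig(
            n_dogs=200, n_metabolites=8, n_snps=200, seed=6, missing_rate=0.0,
            contamination=True, hemolysis_rates=(0.5, 0.1, 0.1, 0.1, 0.2),
        )
        G, _ = simulate_genotypes(cfg)
        matrix, _, _ = simulate_phenotypes(cfg, G, kinship.compute_grm(G))
        g4 = matrix.sample_meta["hemolysis"] == 4
        clean_mean = np.log(matrix.values.loc[~g4, "met_000"]).mean()
        before = abs(np.log(matrix.values["met_000"]).mean() - clean_mean)
        filtered, _ = pp.filter_hemolysis(matrix)
        after = abs(np.log(filtered.values["met_000"]).mean() - clean_mean)
        assert after < before


class TestLogCenter:
    def test_constant_row_becomes_zero(self):
        m = pp.log_center(make_matrix(np.full((3, 4), 7.0)))
        assert np.allclose(m.values.to_numpy(), 0.0)

    def test_worked_example(self):
        m = pp.log_center(make_matrix([[np.e, np.e**3]]))
        assert np.allclose(m.values.to_numpy(), [[-1.0, 1.0]], atol=1e-12)

    def test_missing_cells_excluded_from_row_mean(self):
        m = pp.log_center(make_matrix([[np.e, np.e**3, np.nan]]))
        row = m.values.to_numpy()[0]
        assert np.allclose(row[:2], [-1.0, 1.0])
        assert np.isnan(row[2])

    def test_row_means_zero(self, small_sim):
        m, _ = pp.filter_missingness(small_sim["matrix"])
        m = pp.log_center(m)
        means = np.nanmean(m.values.to_numpy(), axis=1)
        assert np.abs(means).max() < 1e-10

    def test_nonpositive_named(self):
        with pytest.raises(ValueError, match="m01"):
            pp.log_center(make_matrix([[1.0, -2.0]]))


def _logged(vals, **meta):
    m = make_matrix(np.exp(np.asarray(vals, dtype=float)), **meta)
    return pp.log_center(m)


class TestBatchRunorder:
    def test_injected_drift_removed(self):
        rng = np.random.default_rng(0)
        n = 60
        base = rng.normal(size=(n, 3))
        batch = np.repeat(["A", "B"], 30)
        order = np.concatenate([np.arange(1, 31)] * 2)
        drift = np.where(batch == "B", 2.0, 0.0)[:, None] + 0.1 * order[:, None]
        # values already on the log scale; bypass row-centering to isolate
        # the drift model
        m = make_matrix(base + drift, batch=batch, run_order=order)
        m.state = "logged"
        corrected = pp.batch_runorder_correct(m)
        for b in ("A", "B"):
            rows = batch == b
            for j in range(3):
                r = np.corrcoef(corrected.values.to_numpy()[rows, j], order[rows])[0, 1]
                assert abs(r) < 1e-8
            # residuals recover drift-free values up to a per-batch constant
            diff = corrected.values.to_numpy()[rows, 0] - base[rows, 0]
            assert diff.std() < 0.35 * base[rows, 0].std()

    def test_single_batch_no_drift_centers(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=(10, 2))
        m = make_matrix(np.exp(base), run_order=np.full(10, 3.0))
        m = pp.log_center(m)
        corrected = pp.batch_runorder_correct(m)
        expect = m.values.to_numpy() - m.values.to_numpy().mean(axis=0)
        assert np.allclose(corrected.values.to_numpy(), expect, atol=1e-10)

    def test_two_batch_intercepts_removed(self):
        vals = np.concatenate([np.full(5, 1.0), np.full(5, 3.0)])[:, None]
        m = make_matrix(np.exp(np.hstack([vals, vals * 0.5])),
                        batch=np.repeat(["A", "B"], 5),
                        run_order=np.concatenate([np.arange(1, 6)] * 2))
        m.state = "logged"
        corrected = pp.batch_runorder_correct(m)
        v = corrected.values.to_numpy()
        assert abs(v[:5, 0].mean() - v[5:, 0].mean()) < 1e-10

    def test_small_batch_fallback(self, caplog):
        vals = np.exp(np.array([[1.0, 2.0], [2.0, 1.0], [1.5, np.nan], [2.5, np.nan]]))
        m = make_matrix(vals, batch=["A", "A", "A", "A"])
        m.state = "logged"
        with caplog.at_level("WARNING"):
            corrected = pp.batch_runorder_correct(m)
        assert "intercept-only" in caplog.text
        col1 = corrected.values.to_numpy()[:2, 1]
        assert np.allclose(col1, col1 - col1.mean() + 0.0)

    def test_requires_logged_state(self):
        with pytest.raises(ValueError, match="state"):
            pp.batch_runorder_correct(make_matrix(np.ones((4, 2))))


class TestScaleByBatch:
    def test_pair_scaled_by_sample_sd(self):
        m = make_matrix(np.ones((2, 1)))
        m.values.iloc[:, 0] = [-1.0, 1.0]
        m.state = "batch_corrected"
        scaled = pp.scale_by_batch(m)
        s = np.std([-1.0, 1.0], ddof=1)  # sqrt(2)
        assert np.allclose(scaled.values.to_numpy().ravel(), [-1.0 / s, 1.0 / s])

    def test_unit_variance_batch_unchanged(self):
        rng = np.random.default_rng(2)
        v = rng.normal(size=20)
        v = (v - v.mean()) / v.std(ddof=1)
        m = make_matrix(v[:, None])
        m.state = "batch_corrected"
        scaled = pp.scale_by_batch(m)
        assert np.allclose(scaled.values.to_numpy().ravel(), v, atol=1e-10)

    def test_within_batch_unit_variance(self, small_sim):
        m, _ = pp.filter_missingness(small_sim["matrix"])
        m, _ = pp.filter_hemolysis(m)
        m = pp.scale_by_batch(pp.batch_runorder_correct(pp.log_center(m)))
        for b, idx in m.values.groupby(m.sample_meta["batch"]).groups.items():
            sub = m.values.loc[idx]
            sd = sub.std(ddof=1)
            ok = sub.notna().sum() > 1
            assert np.allclose(sd[ok], 1.0, atol=1e-8)

    def test_zero_variance_left_unscaled(self, caplog):
        m = make_matrix(np.full((5, 1), 2.0))
        m.state = "batch_corrected"
        with caplog.at_level("WARNING"):
            scaled = pp.scale_by_batch(m)
        assert "unscaled" in caplog.text
        assert np.allclose(scaled.values.to_numpy(), 2.0)


class TestKnnImpute:
    def test_neighbors_all_carry_v(self):
        vals = np.zeros((6, 2))
        vals[:, 1] = 5.0
        vals[0, 1] = np.nan
        m = make_matrix(vals)
        m.state = "scaled"
        imputed = pp.knn_impute(m, k=3)
        assert imputed.values.iloc[0, 1] == pytest.approx(5.0)
        assert not imputed.values.isna().any().any()

    def test_k_at_least_n_gives_overall_mean(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(8, 3))
        vals[2, 1] = np.nan
        m = make_matrix(vals)
        m.state = "scaled"
        imputed = pp.knn_impute(m, k=50)
        expect = np.nanmean(vals[:, 1][np.arange(8) != 2][:])
        expect = np.nanmean(np.delete(vals[:, 1], 2))
        assert imputed.values.iloc[2, 1] == pytest.approx(expect)

    def test_beats_mean_imputation(self, small_sim):
        m, _ = pp.filter_missingness(small_sim["matrix"])
        m, _ = pp.filter_hemolysis(m)
        m = pp.scale_by_batch(pp.batch_runorder_correct(pp.log_center(m)))
        rng = np.random.default_rng(4)
        vals = m.values.to_numpy().copy()
        obs = np.argwhere(~np.isnan(vals))
        hide = obs[rng.choice(len(obs), size=200, replace=False)]
        masked = vals.copy()
        masked[hide[:, 0], hide[:, 1]] = np.nan
        m2 = pp.MetaboliteMatrix(
            pd.DataFrame(masked, index=m.values.index, columns=m.values.columns),
            m.sample_meta, state="scaled",
        )
        imputed = pp.knn_impute(m2, k=10)
        truth = vals[hide[:, 0], hide[:, 1]]
        knn_rmse = np.sqrt(np.mean((imputed.values.to_numpy()[hide[:, 0], hide[:, 1]] - truth) ** 2))
        col_means = np.nanmean(masked, axis=0)
        mean_rmse = np.sqrt(np.mean((col_means[hide[:, 1]] - truth) ** 2))
        assert knn_rmse < mean_rmse

    def test_isolated_sample_is_error(self):
        vals = np.array([[1.0, np.nan], [np.nan, 2.0], [np.nan, 3.0]])
        m = make_matrix(vals)
        m.state = "scaled"
        with pytest.raises(ValueError, match="no observed metabolites|no donor"):
            pp.knn_impute(m, k=2)


class TestRegressTechnical:
    def test_injected_travel_effect_removed(self):
        rng = np.random.default_rng(5)
        n = 80
        travel = rng.uniform(14, 60, n)
        base = rng.normal(size=(n, 2))
        vals = base + 0.05 * (travel - travel.mean())[:, None]
        m = make_matrix(vals, travel_time=travel)
        m.state = "imputed"
        adj = pp.regress_technical(m)
        slope = np.polyfit(travel, adj.values.to_numpy()[:, 0], 1)[0]
        assert abs(slope) < 1e-10

    def test_zero_correlation_with_covariates(self, small_sim):
        norm, _ = pp.normalize(small_sim["matrix"])
        for cov in ("travel_time", "arrival_temp", "hemolysis"):
            c = norm.sample_meta[cov].to_numpy(dtype=float)
            if np.ptp(c) == 0:
                continue
            for j in range(0, norm.n_metabolites, 7):
                r = np.corrcoef(norm.values.to_numpy()[:, j], c)[0, 1]
                assert abs(r) < 1e-8

    def test_constant_covariate_dropped(self, caplog):
        m = make_matrix(np.random.default_rng(0).normal(size=(10, 2)))
        m.state = "imputed"
        with caplog.at_level("WARNING"):
            pp.regress_technical(m)  # hemolysis all zero -> constant
        assert "constant" in caplog.text

    def test_collinear_covariates_no_crash(self):
        rng = np.random.default_rng(6)
        travel = rng.uniform(14, 60, 12)
        m = make_matrix(rng.normal(size=(12, 2)), travel_time=travel,
                        arrival_temp=travel * 2.0)  # exactly collinear
        m.state = "imputed"
        adj = pp.regress_technical(m)
        assert np.isfinite(adj.values.to_numpy()).all()

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        m = make_matrix(rng.normal(size=(15, 3)),
                        travel_time=rng.uniform(14, 60, 15),
                        arrival_temp=rng.uniform(5, 28, 15),
                        hemolysis=rng.integers(0, 3, 15))
        m.state = "imputed"
        once = pp.regress_technical(m)
        again = pp.MetaboliteMatrix(once.values, once.sample_meta, state="imputed")
        twice = pp.regress_technical(again)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(), atol=1e-10)


class TestPipelineProperties:
    def test_state_order_enforced(self):
        m = make_matrix(np.ones((4, 2)))
        with pytest.raises(ValueError, match="state"):
            pp.scale_by_batch(m)
        with pytest.raises(ValueError, match="state"):
            pp.knn_impute(m)

    def test_identifiers_preserved(self, small_sim):
        norm, _ = pp.normalize(small_sim["matrix"])
        raw = small_sim["matrix"]
        kept = [s for s in raw.values.index if s in set(norm.values.index)]
        assert list(norm.values.index) == kept
        assert list(norm.values.columns) == [
            c for c in raw.values.columns if c in set(norm.values.columns)
        ]

    def test_full_roundtrip_recovers_driftfree(self, small_sim):
        # affine-per-batch agreement between corrected values and latent truth
        truth = small_sim["truth"]
        m, _ = pp.filter_missingness(small_sim["matrix"])
        m, _ = pp.filter_hemolysis(m)
        m = pp.batch_runorder_correct(pp.log_center(m))
        lat = truth.latent.loc[m.values.index, m.values.columns]
        cors = [m.values[c].corr(lat[c]) for c in m.values.columns]
        assert np.mean(cors) > 0.95
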