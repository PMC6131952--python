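"""Standard curve, quantification, dilution calibration, variation model."""

import math

import numpy as np
import pandas as pd
import pytest

import ampliconvar as av
from ampliconvar.biomass import (VariationModel, build_cv_dataset,
                                 ct_from_copies, expected_copies,
                                 fit_standard_curve, fit_variation_model,
                                 predict_variation, prediction_grid, quantify)

PERFECT_SLOPE = -3.3219


def perfect_curve():
    pairs = [(10.0 ** k, 40 + PERFECT_SLOPE * k) for k in range(2, 8)]
    return fit_standard_curve(pairs)


class TestStandardCurve:
    def test_perfect_efficiency_closed_form(self):
        curve = perfect_curve()
        assert curve.slope == pytest.approx(PERFECT_SLOPE, abs=1e-9)
        assert curve.intercept == pytest.approx(40.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.efficiency == pytest.approx(1.0, abs=1e-4)

    def test_two_standards_insufficient(self):
        with pytest.raises(ValueError):
            fit_standard_curve([(100.0, 33.4), (1000.0, 30.0)])

    def test_zero_copy_wells_excluded(self):
        pairs = [(0.0, np.nan)] + [(10.0 ** k, 40 + PERFECT_SLOPE * k)
                                   for k in range(2, 8)]
        curve = fit_standard_curve(pairs)
        assert 0.0 not in curve.standards
        assert curve.slope == pytest.approx(PERFECT_SLOPE, abs=1e-9)

    def test_positive_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            fit_standard_curve([(100.0, 20.0), (1000.0, 25.0), (10000.0, 30.0)])

    def test_slope_recovered_under_ct_noise(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(100):
            pairs = [(10.0 ** k, 40 + PERFECT_SLOPE * k + rng.normal(0, 0.1))
                     for k in range(2, 8)]
            curve = fit_standard_curve(pairs)
            hits += abs(curve.slope - PERFECT_SLOPE) < 0.15
        assert hits == 100


class TestQuantify:
    def test_known_ct_inverts_to_200_copies_per_ul(self):
        curve = perfect_curve()
        wells = pd.DataFrame({"sample_id": ["s1"] * 3, "well": ["w1", "w2", "w3"],
                              "ct": [30.0343] * 3})
        res = quantify(wells, curve, template_volume_ul=5)
        assert res.at["s1", "copies_per_reaction"] == pytest.approx(1000, rel=1e-4)
        assert res.at["s1", "copies_per_ul"] == pytest.approx(200, rel=1e-4)

    def test_ct_at_intercept_is_one_copy(self):
        curve = perfect_curve()
        wells = pd.DataFrame({"sample_id": ["s1"], "well": ["w1"], "ct": [40.0]})
        res = quantify(wells, curve)
        assert res.at["s1", "copies_per_reaction"] == pytest.approx(1.0, rel=1e-9)
        assert res.at["s1", "copies_per_ul"] == pytest.approx(0.2, rel=1e-9)

    def test_round_trip_identity(self):
        curve = perfect_curve()
        rng = np.random.default_rng(1)
        for copies in 10.0 ** rng.uniform(0.5, 7, 20):
            ct = ct_from_copies(curve, copies)
            wells = pd.DataFrame({"sample_id": ["s"], "well": ["w1"], "ct": [ct]})
            got = quantify(wells, curve).at["s", "copies_per_reaction"]
            assert got == pytest.approx(copies, rel=1e-6)

    def test_undetermined_wells(self):
        curve = perfect_curve()
        wells = pd.DataFrame({"sample_id": ["s1", "s1", "s2"],
                              "well": ["w1", "w2", "w1"],
                              "ct": [30.0, "Undetermined", "Undetermined"]})
        res = quantify(wells, curve)
        assert not res.at["s1", "undetermined"]
        assert res.at["s2", "undetermined"]
        assert res.at["s2", "copies_per_ul"] == 0.0


class TestExpectedCopies:
    def test_naive_expectation(self):
        calib = expected_copies([1.0, 80.0], [1e5, 1200.0])
        assert calib.at[80.0, "naive_expected"] == pytest.approx(1250.0)

    def test_sequential_chain(self):
        calib = expected_copies([1.0, 10.0, 20.0], [1e5, 9000.0, 4000.0])
        # 1:20 made from the measured 1:10: 9000 * 10 / 20
        assert calib.at[20.0, "sequential_expected"] == pytest.approx(4500.0)
        assert calib.at[10.0, "sequential_expected"] == pytest.approx(1e4)

    def test_naive_is_log_linear_with_slope_minus_one(self):
        factors = [1.0, 10.0, 20.0, 50.0, 100.0, 1000.0]
        calib = expected_copies(factors, [1e5] + [np.nan] * 5)
        x = np.log10(factors)
        y = np.log10(calib["naive_expected"].to_numpy())
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(-1.0, abs=1e-12)

    def test_missing_parent_flags_sequential(self):
        calib = expected_copies([1.0, 10.0, 20.0], [1e5, np.nan, 4000.0])
        assert math.isnan(calib.at[20.0, "sequential_expected"])

    def test_stock_required(self):
        with pytest.raises(ValueError):
            expected_copies([10.0, 20.0], [1e4, 5e3])


class TestBuildCVDataset:
    def _toy(self):
        # 2 taxa x 2 levels x 3 replicates, values detected everywhere
        cols, meta = {}, []
        vals = {1.0: [(0.6, 0.4), (0.58, 0.42), (0.62, 0.38)],
                10.0: [(0.55, 0.45), (0.6, 0.4), (0.65, 0.35)]}
        for level, trip in vals.items():
            for i, (a, b) in enumerate(trip):
                sid = f"d{level}_{i}"
                cols[sid] = [a, b]
                meta.append(dict(sample_id=sid, run_id="run18",
                                 sample_type="mock", dilution_factor=level))
        table = av.FeatureTable(pd.DataFrame(cols, index=["sv1", "sv2"]))
        md = av.make_metadata(pd.DataFrame(meta))
        qpcr = pd.DataFrame({"copies_per_ul": [1000.0] * 3 + [100.0] * 3},
                            index=pd.Index(list(cols), name="sample_id"))
        return table, md, qpcr

    def test_all_rows_pass(self):
        table, md, qpcr = self._toy()
        ds = build_cv_dataset(table, md, qpcr, rank="sv", min_detected=3)
        assert len(ds) == 4

    def test_absent_taxon_row_dropped(self):
        table, md, qpcr = self._toy()
        table.counts.loc["sv2", ["d10.0_0", "d10.0_1", "d10.0_2"]] = 0.0
        ds = build_cv_dataset(table, md, qpcr, rank="sv", min_detected=3)
        assert len(ds) == 3
        assert not ((ds["taxon"] == "sv2") & (ds["dilution_factor"] == 10)).any()

    def test_synthetic_dilution_row_count(self, dilution_qc):
        """12 community taxa x 11 levels give ~126 usable rows post-QC."""
        study, qc = dilution_qc
        ds = build_cv_dataset(qc["relabund"], qc["metadata"], study.qpcr,
                              rank="genus")
        assert 100 <= len(ds) <= 132


class TestVariationModel:
    def _exact_dataset(self, b0=1.4, b1=-0.28, b2=-0.55, n=30, noise_sd=0.0,
                       seed=0):
        rng = np.random.default_rng(seed)
        copies = 10.0 ** rng.uniform(0.5, 4.5, n)
        ra = 10.0 ** rng.uniform(-2.5, -0.3, n)  # fraction
        ra_pct = ra * 100
        log_cv = b0 + b1 * np.log10(copies) + b2 * np.log10(ra_pct) \
            + rng.normal(0, noise_sd, n)
        return pd.DataFrame({"taxon": [f"t{i}" for i in range(n)],
                             "dilution_factor": 1.0, "mean_ra": ra,
                             "cv_pct": 10.0 ** log_cv, "copies_per_ul": copies,
                             "n_detected": 3})

    def test_noise_free_recovery_is_exact(self):
        ds = self._exact_dataset()
        model = fit_variation_model(ds)
        assert model.params[0] == pytest.approx(1.4, abs=1e-8)
        assert model.params[1] == pytest.approx(-0.28, abs=1e-8)
        assert model.params[2] == pytest.approx(-0.55, abs=1e-8)
        assert model.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_response_gives_zero_slopes(self):
        ds = self._exact_dataset(b1=0.0, b2=0.0, b0=1.0)
        model = fit_variation_model(ds)
        assert model.params[1] == pytest.approx(0.0, abs=1e-10)
        assert model.params[2] == pytest.approx(0.0, abs=1e-10)
        assert model.r_squared == pytest.approx(0.0, abs=1e-10)

    def test_coefficients_match_brute_force_normal_equations(self):
        ds = self._exact_dataset(noise_sd=0.4, seed=3)
        model = fit_variation_model(ds)
        X = np.column_stack([np.ones(len(ds)),
                             np.log10(ds["copies_per_ul"]),
                             np.log10(ds["mean_ra"] * 100)])
        y = np.log10(ds["cv_pct"])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(model.params, beta, atol=1e-10)

    def test_too_few_rows_error(self):
        with pytest.raises(ValueError):
            fit_variation_model(self._exact_dataset(n=3))

    def test_collinear_predictors_error(self):
        ds = self._exact_dataset(n=10)
        ds["copies_per_ul"] = 100.0
        with pytest.raises(ValueError, match="collinear"):
            fit_variation_model(ds)

    def test_ci_coverage_and_sign_recovery(self):
        """~126-row studies with residual SD 0.5 recover both negative slopes."""
        b1_true, b2_true = -0.2816, -0.54936
        neg = cover1 = cover2 = 0
        n_seeds = 100
        for seed in range(n_seeds):
            ds = self._exact_dataset(b0=1.43238, b1=b1_true, b2=b2_true,
                                     n=126, noise_sd=0.5, seed=1000 + seed)
            model = fit_variation_model(ds)
            neg += model.params[1] < 0 and model.params[2] < 0
            ci = model.conf_int(0.05)
            cover1 += ci[1, 0] <= b1_true <= ci[1, 1]
            cover2 += ci[2, 0] <= b2_true <= ci[2, 1]
        assert neg >= 95
        assert 90 <= cover1 <= 99
        assert 90 <= cover2 <= 99


class TestPrediction:
    def _model(self, b0, b1, b2):
        return VariationModel(params=(b0, b1, b2), bse=(0, 0, 0),
                              tvalues=(0, 0, 0), pvalues=(1, 1, 1),
                              resid_se=0.0, r_squared=1.0, adj_r_squared=1.0,
                              f_stat=0.0, df_model=2, df_resid=10, n_obs=13)

    def test_zero_coefficients_predict_one(self):
        m = self._model(0, 0, 0)
        assert predict_variation(m, 123.0, 4.5) == pytest.approx(1.0)

    def test_cancellation(self):
        m = self._model(1, -1, 0)
        assert predict_variation(m, 10.0, 5.0) == pytest.approx(1.0)

    def test_fixed_coefficient_set_evaluates_exactly(self):
        # direct back-transform of a fixed coefficient set at
        # 10 copies/uL and 1% abundance
        m = self._model(1.43238, -0.2816, -0.54936)
        assert predict_variation(m, 10.0, 1.0) == pytest.approx(
            10 ** 1.15078, rel=1e-6)
        assert predict_variation(m, 10.0, 1.0) == pytest.approx(14.15, abs=0.01)

    def test_nonpositive_inputs_error(self):
        m = self._model(0, 0, 0)
        with pytest.raises(ValueError):
            predict_variation(m, 0.0, 1.0)
        with pytest.raises(ValueError):
            predict_variation(m, 1.0, -1.0)

    def test_default_grid_shape_and_consistency(self):
        m = self._model(1.0, -0.3, -0.5)
        grid = prediction_grid(m)
        assert grid.shape == (3, 5)
        assert grid.at[10.0, 5.0] == pytest.approx(predict_variation(m, 10.0, 5.0))

    def test_negative_biomass_slope_makes_columns_decrease(self):
        m = self._model(1.0, -0.3, -0.5)
        grid = prediction_grid(m)
        for col in grid.columns:
            assert grid[col].is_monotonic_decreasing


def test_dilution_series_distance_and_diversity_trends():
    """Within-level spread rises and diversity falls as biomass drops."""
    from scipy.stats import spearmanr
    from ampliconvar.variability import shannon

    bc_ok = sh_ok = 0
    n_seeds = 20
    for seed in range(n_seeds):
        design = av.StudyDesign(runs=(av.RunDesign("run18", n_negative=24),),
                                dilution_levels=av.simulate.DILUTION_FACTORS,
                                seed=400 + seed)
        study = av.simulate_study(design=design)
        qc = av.qc_pipeline(study.counts, study.metadata)
        md = qc["metadata"]
        md = md[md["dilution_factor"].notna()]
        levels = sorted(md["dilution_factor"].unique())
        mean_bc, mean_h = [], []
        H = shannon(qc["rarefied"])
        for level in levels:
            ids = md.index[md["dilution_factor"] == level]
            dm = av.pairwise_distances(
                qc["relabund"].select_samples(ids), "bray_curtis")
            iu = np.triu_indices(dm.n, 1)
            mean_bc.append(dm.data[iu].mean())
            mean_h.append(H.reindex(ids).dropna().mean())
        rho_bc = spearmanr(levels, mean_bc).statistic
        rho_h = spearmanr(levels, mean_h).statistic
        bc_ok += rho_bc >= 0.9
        # diversity: monotone decline overall, strict stock > 1:1000
        sh_ok += (rho_h < 0) and (mean_h[0] > mean_h[-1])
    assert bc_ok == n_seeds
    assert sh_ok == n_seeds
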