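"""CV tables, one-way ICC, control-chart flags, diversity."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import ampliconvar as av
from ampliconvar.containers import FeatureTable, make_metadata
from ampliconvar.variability import (cv_abundance_association, cv_table,
                                     icc_by_taxon, icc_oneway_values,
                                     levey_jennings, mean_intra_cv, shannon)


def _relab_table(values_by_sample, taxa=("tA", "tB")):
    """Build a relative-abundance table from per-sample proportion lists."""
    counts = pd.DataFrame(values_by_sample, index=list(taxa))
    return FeatureTable(counts)


def _md(samples, runs, types=None):
    return make_metadata(pd.DataFrame({
        "sample_id": samples, "run_id": runs,
        "sample_type": types or ["mock"] * len(samples)}))


def brute_force_icc(values, groups):
    """One-way ANOVA by explicit loops (oracle independent of numpy grouping)."""
    from collections import defaultdict
    byg = defaultdict(list)
    for v, g in zip(values, groups):
        byg[g].append(v)
    N = len(values)
    J = len(byg)
    grand = sum(values) / N
    ssb = sum(len(vs) * (sum(vs) / len(vs) - grand) ** 2 for vs in byg.values())
    ssw = sum(sum((v - sum(vs) / len(vs)) ** 2 for v in vs) for vs in byg.values())
    msb, msw = ssb / (J - 1), ssw / (N - J)
    n0 = (N - sum(len(vs) ** 2 for vs in byg.values()) / N) / (J - 1)
    return (msb - msw) / (msb + (n0 - 1) * msw)


class TestCVTable:
    def test_single_run_hand_arithmetic(self):
        vals = {"s1": [0.08, 0.92], "s2": [0.10, 0.90], "s3": [0.12, 0.88]}
        table = _relab_table(vals)
        md = _md(list(vals), ["r1"] * 3)
        cv = cv_table(table, md, stratify_by="run", rank="sv")
        row = cv[(cv["taxon"] == "tA")].iloc[0]
        assert row["mean_ra"] == pytest.approx(0.10)
        assert row["sd_ra"] == pytest.approx(0.02)
        assert row["cv_pct"] == pytest.approx(20.0)

    def test_two_runs_inter_exceeds_intra(self):
        vals = {"a1": [0.08, 0.92], "a2": [0.10, 0.90], "a3": [0.12, 0.88],
                "b1": [0.16, 0.84], "b2": [0.20, 0.80], "b3": [0.24, 0.76]}
        table = _relab_table(vals)
        md = _md(list(vals), ["r1"] * 3 + ["r2"] * 3)
        intra = cv_table(table, md, stratify_by="run", rank="sv")
        ta = intra[intra["taxon"] == "tA"]
        assert ta["cv_pct"].to_list() == pytest.approx([20.0, 20.0])
        assert mean_intra_cv(intra).at["tA", "mean_cv"] == pytest.approx(20.0)
        inter = cv_table(table, md, stratify_by="none", rank="sv")
        pooled = inter[inter["taxon"] == "tA"].iloc[0]
        # pooled SD 0.0616441... over mean 0.15
        assert pooled["cv_pct"] == pytest.approx(100 * 0.0616441400297 / 0.15,
                                                 rel=1e-6)
        assert pooled["cv_pct"] > 20.0

    def test_constant_taxon_cv_zero_absent_taxon_undefined(self):
        vals = {"s1": [0.5, 0.5, 0.0], "s2": [0.5, 0.5, 0.0]}
        table = _relab_table(vals, taxa=("tA", "tB", "tC"))
        md = _md(list(vals), ["r1", "r1"])
        cv = cv_table(table, md, stratify_by="run", rank="sv")
        assert cv[cv["taxon"] == "tA"].iloc[0]["cv_pct"] == 0.0
        assert math.isnan(cv[cv["taxon"] == "tC"].iloc[0]["cv_pct"])

    def test_small_stratum_skipped_with_warning(self):
        vals = {"s1": [0.5, 0.5], "s2": [0.4, 0.6], "s3": [0.3, 0.7]}
        table = _relab_table(vals)
        md = _md(list(vals), ["r1", "r1", "r2"])
        with pytest.warns(UserWarning, match="r2"):
            cv = cv_table(table, md, stratify_by="run", rank="sv")
        assert set(cv["stratum"]) == {"r1"}

    def test_negative_controls_excluded(self):
        vals = {"s1": [0.5, 0.5], "s2": [0.4, 0.6], "n1": [1.0, 0.0]}
        table = _relab_table(vals)
        md = _md(list(vals), ["r1"] * 3, ["mock", "mock", "negative"])
        cv = cv_table(table, md, stratify_by="run", rank="sv")
        assert cv["n_samples"].unique().tolist() == [2]

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.floats(0.1, 100.0), st.integers(0, 1000))
    def test_cv_scale_invariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        base = rng.uniform(0.01, 1.0, 5)
        vals = {f"s{i}": [v, 1 - v] for i, v in enumerate(base / (base + 1))}
        table = _relab_table(vals)
        md = _md(list(vals), ["r1"] * 5)
        cv1 = cv_table(table, md, stratify_by="run", rank="sv")
        scaled = {k: [scale * a, scale * b] for k, (a, b) in vals.items()}
        counts = pd.DataFrame(scaled, index=["tA", "tB"])
        cv2 = cv_table(FeatureTable(counts / counts.sum()), md,
                       stratify_by="run", rank="sv")
        # proportions renormalised: tA/(tA+tB) invariant under common scale
        assert cv2[cv2["taxon"] == "tA"].iloc[0]["cv_pct"] == pytest.approx(
            cv1[cv1["taxon"] == "tA"].iloc[0]["cv_pct"], rel=1e-9)


class TestICC:
    def test_perfect_agreement(self):
        res = icc_oneway_values([1, 1, 2, 2, 3, 3], ["a", "a", "b", "b", "c", "c"])
        assert res.icc == pytest.approx(1.0)
        assert res.ms_within == 0.0

    def test_hand_anova_example(self):
        res = icc_oneway_values([1, 2, 3, 4, 5, 6], ["a", "a", "b", "b", "c", "c"])
        assert res.ms_between == pytest.approx(8.0)
        assert res.ms_within == pytest.approx(0.5)
        assert res.icc == pytest.approx(7.5 / 8.5)
        assert res.icc == pytest.approx(0.8824, abs=5e-5)

    def test_matches_brute_force_on_random_groupings(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            n = int(rng.integers(6, 40))
            values = rng.normal(size=n)
            groups = rng.integers(0, rng.integers(2, 6), n)
            if len(np.unique(groups)) < 2 or n - len(np.unique(groups)) < 1:
                continue
            got = icc_oneway_values(values, groups).icc
            assert got == pytest.approx(brute_force_icc(list(values), list(groups)),
                                        abs=1e-10)

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        groups = np.repeat([f"g{i}" for i in range(5)], 4)
        values = rng.normal(np.repeat(rng.normal(0, 2, 5), 4), 1.0)
        df = pd.DataFrame({"targets": groups, "y": values,
                           "raters": list(range(4)) * 5})
        icc1 = pg.intraclass_corr(df, targets="targets", raters="raters",
                                  ratings="y").set_index("Type").at["ICC(1,1)", "ICC"]
        assert icc_oneway_values(values, groups).icc == pytest.approx(icc1, abs=1e-9)

    def test_shuffled_labels_drive_icc_to_zero(self):
        rng = np.random.default_rng(9)
        groups = np.repeat(np.arange(6), 5)
        values = np.repeat(rng.normal(0, 3, 6), 5) + rng.normal(0, 0.3, 30)
        assert icc_oneway_values(values, groups).icc > 0.9
        shuffled = []
        for _ in range(100):
            shuffled.append(icc_oneway_values(values, rng.permutation(groups)).icc)
        assert abs(float(np.mean(shuffled))) < 0.1

    def test_identical_values_flagged_undefined(self):
        res = icc_oneway_values([2.0, 2.0, 2.0, 2.0], ["a", "a", "b", "b"])
        assert math.isnan(res.icc)

    def test_per_rank_summary_on_synthetic_study(self, qc_result):
        _, icc_mean = icc_by_taxon(qc_result["relabund"], qc_result["metadata"],
                                   rank="genus")
        assert 0 < icc_mean <= 1


class TestLeveyJennings:
    def test_outlier_flagged_by_direct_arithmetic(self):
        # values {1,1,1,1,1,10}: mean 2.5, sd sqrt(13.5) = 3.674;
        # |10 - 2.5| = 7.5 > 2 * 3.674 = 7.35 -> flagged
        vals = {f"s{i}": [v, 100 - v] for i, v in
                enumerate([1.0, 1.0, 1.0, 1.0, 1.0, 10.0])}
        counts = pd.DataFrame(vals, index=["tA", "tB"])
        table = FeatureTable(counts / counts.sum())
        md = _md(list(vals), [f"r{i}" for i in range(6)])
        stats, flags = levey_jennings(table, md, rank="sv", k_sd=2.0)
        fa = flags[flags["taxon"] == "tA"].set_index("sample_id")
        assert fa["flagged"].sum() == 1
        assert bool(fa.at["s5", "flagged"])

    def test_constant_series_never_flags(self):
        vals = {f"s{i}": [0.25, 0.75] for i in range(5)}
        table = _relab_table(vals)
        md = _md(list(vals), ["r1"] * 5)
        _, flags = levey_jennings(table, md, rank="sv")
        assert not flags["flagged"].any()

    def test_k_zero_flags_every_nonmean_value(self):
        vals = {"s1": [0.2, 0.8], "s2": [0.3, 0.7], "s3": [0.4, 0.6]}
        table = _relab_table(vals)
        md = _md(list(vals), ["r1"] * 3)
        _, flags = levey_jennings(table, md, rank="sv", k_sd=0.0)
        fa = flags[flags["taxon"] == "tA"]
        assert fa["flagged"].tolist() == [True, False, True]


class TestShannon:
    def test_uniform_four(self):
        table = FeatureTable(pd.DataFrame({"s": [25, 25, 25, 25]}))
        assert shannon(table)["s"] == pytest.approx(math.log(4))

    def test_single_sv_zero(self):
        table = FeatureTable(pd.DataFrame({"s": [100]}))
        assert shannon(table)["s"] == 0.0

    def test_zeros_ignored(self):
        table = FeatureTable(pd.DataFrame({"s": [50, 50, 0]}))
        assert shannon(table)["s"] == pytest.approx(math.log(2))

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            shannon(FeatureTable(pd.DataFrame({"s": [0, 0]})))


class TestCVAbundanceAssociation:
    def test_strictly_decreasing_gives_minus_one(self):
        vt = pd.DataFrame({"taxon": list("abcd"), "stratum": ["all"] * 4,
                           "mean_ra": [0.1, 0.2, 0.3, 0.4],
                           "cv_pct": [40, 30, 20, 10],
                           "sd_ra": [0] * 4, "n_samples": [5] * 4,
                           "n_detected": [5] * 4})
        rho, p = cv_abundance_association(vt)
        assert rho == pytest.approx(-1.0)

    def test_constant_cv_returns_nan(self):
        vt = pd.DataFrame({"taxon": list("abc"), "stratum": ["all"] * 3,
                           "mean_ra": [0.1, 0.2, 0.3], "cv_pct": [10, 10, 10],
                           "sd_ra": [0] * 3, "n_samples": [5] * 3,
                           "n_detected": [5] * 3})
        rho, p = cv_abundance_association(vt)
        assert math.isnan(rho)

    def test_matches_rank_then_pearson_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            ra = rng.uniform(0.001, 0.5, 10)
            cv = rng.uniform(1, 100, 10)
            vt = pd.DataFrame({"taxon": [f"t{i}" for i in range(10)],
                               "stratum": ["all"] * 10, "mean_ra": ra,
                               "cv_pct": cv, "sd_ra": np.zeros(10),
                               "n_samples": [5] * 10, "n_detected": [5] * 10})
            rho, _ = cv_abundance_association(vt)
            rx = pd.Series(ra).rank().to_numpy()
            ry = pd.Series(cv).rank().to_numpy()
            brute = np.corrcoef(rx, ry)[0, 1]
            assert rho == pytest.approx(brute, abs=1e-10)


def test_inter_cv_exceeds_mean_intra_on_synthetic_studies():
    """Cross-run variability beats within-run for nearly all abundant taxa."""
    ok = 0
    for seed in range(20):
        study = av.simulate_study(seed=200 + seed)
        qc = av.qc_pipeline(study.counts, study.metadata)
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            intra = cv_table(qc["relabund"], qc["metadata"], "run", "genus")
            inter = cv_table(qc["relabund"], qc["metadata"], "none", "genus")
        mi = mean_intra_cv(intra)
        inter_cv = inter.set_index("taxon")["cv_pct"]
        abundant = mi[mi["mean_ra"] > 0.01]
        frac = float((inter_cv.reindex(abundant.index)
                      > abundant["mean_cv"]).mean())
        if frac >= 0.9:
            ok += 1
    assert ok == 20


def test_higher_abundance_taxa_have_lower_cv():
    """Staggered truth: CV falls with true abundance (negative Spearman)."""
    hits = 0
    for seed in range(50):
        spec = av.mock_community(n_taxa=20, proportions="staggered")
        design = av.StudyDesign(
            runs=tuple(av.RunDesign(f"r{i}", n_mock=6) for i in range(4)),
            seed=300 + seed)
        study = av.simulate_study(spec, design)
        relab = av.relative_abundance(study.counts)
        inter = cv_table(relab, study.metadata, "none", "genus")
        rho, _ = cv_abundance_association(inter)
        if rho < 0:
            hits += 1
    assert hits >= 48  # >= 95% of seeds
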