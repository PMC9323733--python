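"""Normalization, control-probe calibration, replicate outlier elimination
and gene summarization, each checked against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import eaetools.preprocess as pp
from eaetools import simulate as sim


def _null_scan(n_genes=700, noise_sd=0.2, seed=31, **kwargs):
    params = sim.SimulationParams(n_genes=n_genes, frac_down=0.0, frac_up=0.0,
                                  noise_sd=noise_sd, seed=seed, **kwargs)
    truth = sim.build_ground_truth(params)
    scan, truth = sim.simulate_two_channel_scan(truth, params)
    return scan, truth


class TestQsplineNormalize:
    def test_identity_channels_give_zero_ratios(self):
        scan, _ = _null_scan()
        scan["intensity_sample"] = scan["intensity_reference"]
        norm, _ = pp.qspline_normalize(scan)
        ratios = pp.compute_log_ratios(norm)
        assert ratios["log2_ratio"].abs().max() < 1e-9

    def test_constant_twofold_bias_removed(self):
        scan, _ = _null_scan()
        scan["intensity_sample"] = 2.0 * scan["intensity_reference"]
        norm, _ = pp.qspline_normalize(scan)
        ratios = pp.compute_log_ratios(norm)
        assert abs(ratios["log2_ratio"].median()) < 0.01

    def test_power_law_bias_vs_full_quantile_oracle(self):
        # sample = reference^1.1; oracle = full quantile normalization
        # (sorted sample mapped onto sorted reference, spot for spot)
        scan, _ = _null_scan(n_genes=400)
        scan["intensity_sample"] = scan["intensity_reference"] ** 1.1
        norm, curve = pp.qspline_normalize(scan)
        exp = norm["probe_class"] == "experimental"
        s = np.log2(norm.loc[exp, "intensity_sample"].to_numpy())
        r = np.log2(norm.loc[exp, "intensity_reference"].to_numpy())
        grid = curve.quantile_grid
        qs = np.quantile(s, grid, method="inverted_cdf")
        qr = np.quantile(r, grid, method="inverted_cdf")
        assert np.abs(qs - qr).max() < 0.02
        # per-spot agreement with the full-quantile oracle
        raw = np.log2(scan.loc[exp.to_numpy(), "intensity_sample"].to_numpy())
        oracle = np.empty_like(raw)
        oracle[np.argsort(raw, kind="stable")] = np.sort(r)
        assert np.abs(s - oracle).max() < 0.02

    def test_idempotence(self):
        scan, _ = _null_scan(dye_bias_amplitude=0.8)
        once, _ = pp.qspline_normalize(scan)
        twice, _ = pp.qspline_normalize(once)
        d = np.abs(np.log2(twice["intensity_sample"].to_numpy())
                   - np.log2(once["intensity_sample"].to_numpy()))
        assert d.max() < 1e-6

    def test_rank_preservation_exact(self):
        scan, _ = _null_scan(dye_bias_amplitude=0.8)
        norm, _ = pp.qspline_normalize(scan)
        before = stats.rankdata(scan["intensity_sample"])
        after = stats.rankdata(norm["intensity_sample"])
        assert (before == after).all()

    def test_reference_channel_untouched(self):
        scan, _ = _null_scan()
        norm, _ = pp.qspline_normalize(scan)
        np.testing.assert_array_equal(norm["intensity_reference"],
                                      scan["intensity_reference"])

    def test_too_few_spots_rejected(self, make_scan):
        scan = make_scan([(f"g{i}_r1", f"g{i}", 1, "experimental", 100.0, 100.0)
                          for i in range(50)])
        with pytest.raises(ValueError, match="experimental spots"):
            pp.qspline_normalize(scan, n_quantiles=100)


class TestLogRatios:
    def test_arithmetic(self, make_scan):
        scan = make_scan([
            ("a_r1", "a", 1, "experimental", 800.0, 400.0),
            ("b_r1", "b", 1, "experimental", 400.0, 400.0),
        ])
        r = pp.compute_log_ratios(scan)
        np.testing.assert_allclose(r["log2_ratio"], [1.0, 0.0], atol=1e-12)
        np.testing.assert_allclose(
            r["mean_log2_intensity"].iloc[0],
            (np.log2(800) + np.log2(400)) / 2)

    def test_nonpositive_intensity_floored_and_flagged(self, make_scan):
        scan = make_scan([("a_r1", "a", 1, "experimental", -3.0, 400.0)])
        r = pp.compute_log_ratios(scan)
        assert r["floored"].iloc[0]
        assert np.isfinite(r["log2_ratio"].iloc[0])

    def test_additive_background_attenuates_twofold_change(self, make_scan):
        # closed form: log2((x/2 + b) / (x + b)) > -1 for any b > 0
        x, b = 200.0, 50.0
        scan = make_scan([("a_r1", "a", 1, "experimental", x / 2 + b, x + b)])
        r = pp.compute_log_ratios(scan)
        assert -1.0 < r["log2_ratio"].iloc[0] < 0.0


class TestControlCalibration:
    def test_detection_limit_zero_sd_case(self, make_scan):
        spots = [(f"n{i}", "neg_ctrl", i, "negative_control", 64.0, 64.0)
                 for i in range(1, 13)]
        limit, _ = pp.estimate_detection_limit(make_scan(spots))
        assert limit == pytest.approx(6.0, abs=1e-12)

    def test_detection_limit_matches_direct_formula(self, make_scan, rng):
        log2_i = rng.normal(6.0, 0.5, size=500)
        spots = [(f"n{i}", "neg_ctrl", i + 1, "negative_control",
                  2.0 ** v, 2.0 ** v) for i, v in enumerate(log2_i)]
        spots += [(f"g{i}", f"g{i}", 1, "experimental", 2.0 ** 12, 2.0 ** 12)
                  for i in range(20)]
        limit, dyn = pp.estimate_detection_limit(make_scan(spots))
        expected = log2_i.mean() + 2.0 * log2_i.std(ddof=1)
        assert limit == pytest.approx(expected, abs=1e-9)
        assert 6.8 < limit < 7.2
        assert dyn == pytest.approx(12.0 - expected, abs=1e-9)

    def test_missing_negative_controls_is_config_error(self, make_scan):
        scan = make_scan([("g0", "g0", 1, "experimental", 100.0, 100.0)])
        with pytest.raises(pp.ConfigurationError):
            pp.estimate_detection_limit(scan)

    def test_sigma_tech_zero_for_identical_replicates(self, make_scan):
        spots = [("sp0", "sp0", i, "spike_in", 1024.0, 512.0)
                 for i in range(1, 21)]
        assert pp.estimate_technical_variability(make_scan(spots)) == 0.0

    def test_sigma_tech_matches_mad_oracle(self, make_scan):
        dev = np.random.default_rng(0).normal(0.0, 0.1, size=1000)
        spots = [("sp0", "sp0", i + 1, "spike_in", 2.0 ** (10 + d), 2.0 ** 10)
                 for i, d in enumerate(dev)]
        sigma = pp.estimate_technical_variability(make_scan(spots))
        oracle = 1.4826 * np.median(np.abs(dev - np.median(dev)))
        assert sigma == pytest.approx(oracle, rel=1e-9)
        assert 0.09 < sigma < 0.11

    def test_sigma_tech_robust_to_gross_artifact(self, make_scan, rng):
        dev = rng.normal(0.0, 0.1, size=1000)
        clean = [("sp0", "sp0", i + 1, "spike_in", 2.0 ** (10 + d), 2.0 ** 10)
                 for i, d in enumerate(dev)]
        sigma_clean = pp.estimate_technical_variability(make_scan(clean))
        dirty = clean + [("sp0", "sp0", 1001, "spike_in", 2.0 ** 15, 2.0 ** 10)]
        sigma_dirty = pp.estimate_technical_variability(make_scan(dirty))
        assert abs(sigma_dirty - sigma_clean) / sigma_clean < 0.05


class TestReplicateOutliers:
    noise = pp.TechnicalNoiseModel(sigma_tech=0.1, detection_limit=0.0,
                                   dynamic_range=10.0)

    def test_tight_triplet_not_flagged(self, make_ratio_table):
        table = make_ratio_table([("g", i, v, 10.0) for i, v in
                                  enumerate([-1.00, -1.02, -0.98], 1)])
        out = pp.eliminate_replicate_outliers(table, self.noise, k=4.0)
        assert not out["outlier_flag"].any()

    def test_gross_replicate_flagged_and_mean_recovers(self, make_ratio_table):
        table = make_ratio_table([("g", i, v, 10.0) for i, v in
                                  enumerate([-1.00, -1.02, 2.50], 1)])
        noise = pp.TechnicalNoiseModel(sigma_tech=0.05, detection_limit=0.0,
                                       dynamic_range=10.0)
        out = pp.eliminate_replicate_outliers(table, noise, k=4.0)
        assert out["outlier_flag"].tolist() == [False, False, True]
        genes = pp.summarize_genes(out, noise)
        assert genes["mean_log2_ratio"].iloc[0] == pytest.approx(-1.01)
        assert genes["n_surviving"].iloc[0] == 2

    def test_at_most_one_flag_per_gene(self, make_ratio_table):
        # two spots both far out: only the larger deviation is removed
        table = make_ratio_table([("g", 1, 0.0, 10.0), ("g", 2, 3.0, 10.0),
                                  ("g", 3, -2.0, 10.0)])
        out = pp.eliminate_replicate_outliers(table, self.noise, k=4.0)
        assert out["outlier_flag"].sum() == 1
        assert out.loc[out["outlier_flag"], "replicate_index"].iloc[0] == 2

    def test_zero_sigma_skips_with_warning(self, make_ratio_table):
        table = make_ratio_table([("g", 1, 0.0, 10.0), ("g", 2, 5.0, 10.0)])
        degenerate = pp.TechnicalNoiseModel(sigma_tech=0.0, detection_limit=0.0,
                                            dynamic_range=10.0)
        with pytest.warns(UserWarning, match="skipped"):
            out = pp.eliminate_replicate_outliers(table, degenerate)
        assert not out["outlier_flag"].any()


class TestSummarizeGenes:
    noise = pp.TechnicalNoiseModel(sigma_tech=0.1, detection_limit=8.0,
                                   dynamic_range=10.0)

    def test_mean_sd_arithmetic(self, make_ratio_table):
        table = make_ratio_table([("g", i, v, 10.0) for i, v in
                                  enumerate([-1.0, -1.2, -0.8], 1)])
        genes = pp.summarize_genes(table, self.noise)
        assert genes["mean_log2_ratio"].iloc[0] == pytest.approx(-1.0)
        assert genes["sd_log2_ratio"].iloc[0] == pytest.approx(0.2)
        assert genes["expressed"].iloc[0]

    def test_below_detection_limit_not_expressed(self, make_ratio_table):
        table = make_ratio_table([("g", i, 0.0, 6.0) for i in range(1, 4)])
        genes = pp.summarize_genes(table, self.noise)
        assert not genes["expressed"].iloc[0]

    def test_thin_gene_excluded_with_warning(self, make_ratio_table):
        table = make_ratio_table([("g", 1, 0.0, 10.0), ("h", 1, 0.0, 10.0),
                                  ("h", 2, 0.1, 10.0)])
        with pytest.warns(UserWarning, match="excluded"):
            genes = pp.summarize_genes(table, self.noise)
        assert genes["gene_id"].tolist() == ["h"]

    def test_noise_free_ratios_summarize_to_truth_exactly(self):
        params = sim.SimulationParams(n_genes=80, noise_sd=0.0, frac_down=0.2,
                                      frac_up=0.1, seed=41,
                                      neg_control_log2_sd=0.0)
        truth = sim.build_ground_truth(params)
        scan, truth = sim.simulate_two_channel_scan(truth, params)
        ratios = pp.compute_log_ratios(scan)
        limit, dyn = pp.estimate_detection_limit(scan)
        noise = pp.TechnicalNoiseModel(sigma_tech=0.1, detection_limit=limit,
                                       dynamic_range=dyn)
        genes = pp.summarize_genes(
            pp.eliminate_replicate_outliers(ratios, noise), noise)
        merged = genes.merge(truth.genes, on="gene_id")
        np.testing.assert_allclose(merged["mean_log2_ratio"],
                                   merged["true_log2_effect"], atol=1e-9)


def test_dye_bias_trend_removed_by_normalization():
    scan, _ = _null_scan(dye_bias_amplitude=0.8, noise_sd=0.15, seed=51)
    raw = pp.compute_log_ratios(scan)
    norm, _ = pp.qspline_normalize(scan)
    cooked = pp.compute_log_ratios(norm)
    exp = raw["probe_class"] == "experimental"
    rho_raw = stats.spearmanr(raw.loc[exp, "log2_ratio"],
                              raw.loc[exp, "mean_log2_intensity"]).statistic
    rho_norm = stats.spearmanr(cooked.loc[exp, "log2_ratio"],
                               cooked.loc[exp, "mean_log2_intensity"]).statistic
    assert abs(rho_raw) > 0.3
    assert abs(rho_norm) < 0.05


def test_null_array_fraction_beyond_0p6_after_normalization():
    scan, _ = _null_scan(n_genes=1000, dye_bias_amplitude=0.8, noise_sd=0.15,
                         seed=52)
    raw = pp.compute_log_ratios(scan)
    exp = raw["probe_class"] == "experimental"
    frac_raw = (raw.loc[exp, "log2_ratio"].abs() > 0.6).mean()
    res = pp.preprocess_scan(scan)
    frac_norm = (res.genes["mean_log2_ratio"].abs() > 0.6).mean()
    assert frac_raw > 0.05          # substantial distortion before
    assert frac_norm < 0.01         # essentially gone after
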