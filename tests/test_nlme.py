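"""Dummy coding, fixed-effects extension, power variance, LRT, and NLME."""

import numpy as np
import pandas as pd
import pytest

from hdtrial import (SimConfig, SiteConfig, TrialTable, fit_dummy_fixed,
                     fit_nlme, generate_trial, lrt, power_variance)
from hdtrial.candidates import fit as fit_candidate
from hdtrial.nlme import DummyCoding, NLMEFit, VarianceModel, asymptote, \
    coding_from_table, encode


class TestEncode:
    def test_one_hot_against_reference(self):
        coding = DummyCoding("site", ("Changning", "Huaan", "Mengla",
                                      "Pingxiang"), "Changning")
        X = encode(coding, ["Mengla", "Changning", "Pingxiang"])
        assert X.shape == (3, 3)
        assert X[0].sum() == 1 and X[0][coding.coded_levels.index("Mengla")] == 1
        assert (X[1] == 0).all()  # reference level: all-zero indicators

    def test_24_columns_for_25_provenances(self):
        levels = tuple(chr(ord("A") + i) for i in range(25))
        coding = DummyCoding("provenance", levels, "Y")
        X = encode(coding, list(levels))
        assert X.shape == (25, 24)
        assert (X.sum(axis=1) <= 1).all()

    def test_unknown_label_rejected(self):
        coding = DummyCoding("site", ("A", "B"), "A")
        with pytest.raises(KeyError):
            encode(coding, ["C"])

    def test_reference_must_be_a_level(self):
        with pytest.raises(ValueError):
            DummyCoding("site", ("A", "B"), "Z")


def _two_site_trial(x=(2.0, 0.0), sigma=0.0, seed=11, n_blocks=4,
                    trees_per_plot=6):
    sites = [
        SiteConfig(label="S1", asymptote_offset=x[0], n_blocks=n_blocks,
                   dbh_mean=18.0, trees_per_plot=trees_per_plot),
        SiteConfig(label="S2", asymptote_offset=x[1], n_blocks=n_blocks,
                   dbh_mean=16.0, trees_per_plot=trees_per_plot),
    ]
    cfg = SimConfig(sites=sites, provenances=list("ABCDE"),
                    provenance_offsets={"S1": {}, "S2": {}},
                    phi0=20.0, phi1=1.2, phi2=0.03, sigma=sigma,
                    survival_prob=1.0, reference_site="S2", seed=seed)
    return generate_trial(cfg)


class TestFitDummyFixed:
    def test_noise_free_offset_recovery(self):
        table = _two_site_trial()
        coding = DummyCoding("site", ("S1", "S2"), "S2")
        res = fit_dummy_fixed(table, 8, [coding])
        assert res.phi0 == pytest.approx(20.0, abs=1e-6)
        assert res.offsets["site"]["S1"] == pytest.approx(2.0, abs=1e-6)

    def test_reference_swap_leaves_fitted_heights_unchanged(self):
        table = _two_site_trial(sigma=0.6)
        a = fit_dummy_fixed(table, 8, [DummyCoding("site", ("S1", "S2"), "S2")])
        b = fit_dummy_fixed(table, 8, [DummyCoding("site", ("S1", "S2"), "S1")])
        assert np.max(np.abs(a.fitted - b.fitted)) < 1e-8
        assert a.phi0 != pytest.approx(b.phi0)  # parameters do differ

    def test_single_level_factor_collapses_to_base(self):
        table = _two_site_trial()
        sub = TrialTable(table.data[table.data["site"] == "S1"]
                         .reset_index(drop=True))
        coding = DummyCoding("site", ("S1",), "S1")
        res = fit_dummy_fixed(sub, 8, [coding])
        assert res.offsets["site"] == {}
        live = sub.alive()
        base = fit_candidate(8, live["dbh_cm"], live["height_m"])
        assert res.phi0 == pytest.approx(base.params["a"], rel=1e-6)


class TestPowerVariance:
    def test_gamma_zero_constant(self):
        v = power_variance(np.array([2.0, 5.0, 9.0]), sigma=0.7, gamma=0.0)
        np.testing.assert_allclose(v, 0.49)

    def test_closed_form(self):
        assert power_variance(4.0, sigma=1.0, gamma=0.5) == pytest.approx(4.0)

    def test_vector_matches_scalar(self):
        f = np.array([1.5, 3.0, 7.5])
        v = power_variance(f, sigma=0.4, gamma=0.8)
        for fi, vi in zip(f, v):
            assert vi == pytest.approx(power_variance(float(fi), 0.4, 0.8))


class TestLrt:
    def test_published_worked_example(self):
        stat, p = lrt(-2811.776, -2927.487, df=27)
        assert stat == pytest.approx(231.422, abs=1e-9)
        assert p < 0.05

    def test_equal_logliks(self):
        stat, p = lrt(-5261.027, -5261.027, df=3)
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_negative_statistic_warned_not_clamped(self):
        with pytest.warns(UserWarning, match="nested"):
            stat, p = lrt(-100.0, -99.0, df=2)
        assert stat == pytest.approx(-2.0)

    def test_df_validated(self):
        with pytest.raises(ValueError):
            lrt(-1.0, -2.0, df=0)


class TestAsymptote:
    def _fit(self):
        coding = DummyCoding("site", ("Changning", "Huaan", "Mengla",
                                      "Pingxiang"), "Changning")
        return NLMEFit(
            level="site", phi0=23.760, phi1=1.101, phi2=0.037,
            offsets={"Mengla": 4.388, "Pingxiang": 0.493, "Huaan": -0.002},
            std_errors={}, sigma0_block=0.0, sigma1_block=0.01, sigma=0.186,
            gamma=0.885, loglik=0.0, loglik_ml=0.0, aic=0.0, converged=True,
            estimation_method="REML", coding=coding, n=0, n_fixed_params=6)

    def test_offset_level(self):
        assert asymptote(self._fit(), "Mengla") == pytest.approx(29.448)
        assert asymptote(self._fit(), "Huaan") == pytest.approx(
            1.3 + 23.760 - 0.002)

    def test_reference_level(self):
        assert asymptote(self._fit(), "Changning") == pytest.approx(1.3 + 23.760)

    def test_unknown_label(self):
        with pytest.raises(KeyError):
            asymptote(self._fit(), "Nowhere")


def _null_trial(seed, n_blocks=8, trees_per_plot=1, sigma=0.8):
    """Single-site trial with every provenance offset exactly 0."""
    cfg = SimConfig(
        sites=[SiteConfig(label="S", n_blocks=n_blocks, dbh_mean=18.0,
                          trees_per_plot=trees_per_plot)],
        provenances=list("ABCDEFGHIJKLMNOPQRSTUVWXY"),
        provenance_offsets={"S": {}}, phi0=20.0, phi1=1.2, phi2=0.03,
        sigma=sigma, gamma=0.0, survival_prob=1.0, reference_site="S",
        seed=seed)
    return generate_trial(cfg)


class TestFitNlme:
    def test_null_variance_components_recovered_at_boundary(self):
        table = _null_trial(seed=3, n_blocks=6, trees_per_plot=8)
        res = fit_nlme(table, "provenance", method="REML")
        assert res.sigma0_block <= 0.05 * res.phi0
        assert res.sigma1_block <= 0.05 * res.phi1

    def test_homoscedastic_limit_gamma_near_zero(self):
        table = _null_trial(seed=5, n_blocks=10, trees_per_plot=20)
        assert len(table.alive()) == 5000
        res = fit_nlme(table, "provenance", method="REML")
        assert abs(res.gamma) < 0.1

    def test_single_block_gamma_fixed_reproduces_fixed_effects_fit(self):
        table = _null_trial(seed=7, n_blocks=1, trees_per_plot=30)
        coding = coding_from_table(table, "provenance", "Y")
        nlme_res = fit_nlme(table, "provenance", coding=coding, method="ML",
                            variance=VarianceModel(gamma=0.0,
                                                   estimate_gamma=False))
        fixed = fit_dummy_fixed(table, 8, [coding])
        assert nlme_res.phi0 == pytest.approx(fixed.phi0, rel=1e-4)
        assert nlme_res.phi1 == pytest.approx(fixed.rest_params["c"], rel=1e-4)
        assert nlme_res.phi2 == pytest.approx(fixed.rest_params["b"], rel=1e-4)
        for lev, off in nlme_res.offsets.items():
            assert off == pytest.approx(fixed.offsets["provenance"][lev],
                                        abs=1e-3)

    def test_reference_invariance_of_loglik_and_fitted(self):
        table = _two_site_trial(sigma=0.5, seed=19)
        lev = ("S1", "S2")
        a = fit_nlme(table, "site", coding=DummyCoding("site", lev, "S2"),
                     method="ML")
        b = fit_nlme(table, "site", coding=DummyCoding("site", lev, "S1"),
                     method="ML")
        assert a.loglik_ml == pytest.approx(b.loglik_ml, abs=1e-4)
        assert np.max(np.abs(a.fitted - b.fitted)) < 1e-4

    def test_ml_lrt_nonnegative_for_nested_fits(self):
        for seed in (2, 9):
            table = _null_trial(seed=seed, n_blocks=6, trees_per_plot=4)
            live = table.alive()
            base = fit_candidate(8, live["dbh_cm"], live["height_m"])
            ext = fit_nlme(table, "provenance", method="ML")
            stat, _ = lrt(ext.loglik_ml, base.loglik, df=27)
            assert stat >= 0

    def test_provenance_lrt_size_controlled_under_null(self):
        # with no provenance effects, the fixed-effects dummy LRT should
        # reject at the 5% level in at most ~10% of replicates
        from scipy.stats import chi2
        n_reps, rejections = 200, 0
        for rep in range(n_reps):
            table = _null_trial(seed=10_000 + rep, n_blocks=10,
                                trees_per_plot=2)
            live = table.alive()
            base = fit_candidate(8, live["dbh_cm"], live["height_m"])
            coding = coding_from_table(table, "provenance", "Y")
            ext = fit_dummy_fixed(table, 8, [coding])
            stat, p = lrt(ext.loglik, base.loglik, df=24)
            rejections += p < 0.05
        assert rejections / n_reps <= 0.10


class TestAgainstReferenceImplementation:
    """Cross-validation of the mixed-effects fitter against R's nlme.

    The same simulated fixture (deterministic seed) was fitted once with
    nlme::nlme (REML, varPower on fitted values, random asymptote per
    block); its estimates are frozen here as the independent oracle.
    """

    R_ORACLE = {
        "phi0": 26.79028202, "phi1": 1.02294492, "phi2": 0.04014202,
        "k": {"A": 2.51048923, "B": -0.20842394, "C": 0.71166743,
              "D": -0.38981727},
        "gamma": 0.5753197, "sigma": 0.3885709, "loglik": -328.8224,
        "se": {"phi0": 4.854798615, "phi1": 0.130673279, "phi2": 0.006364285},
    }

    def _fixture(self):
        from hdtrial import SimConfig, SiteConfig, generate_trial
        cfg = SimConfig(
            sites=[SiteConfig(label="S", n_blocks=8, dbh_mean=18.0,
                              trees_per_plot=4)],
            provenances=list("ABCDE"),
            provenance_offsets={"S": {"A": 1.2, "B": -0.8, "C": 0.5,
                                      "D": -0.3, "E": 0.0}},
            phi0=21.0, phi1=1.3, phi2=0.03, sigma=0.35, gamma=0.6,
            sigma0_block=0.5, sigma1_block=0.0, survival_prob=1.0,
            reference_site="S", reference_provenance="E", seed=42)
        return generate_trial(cfg)

    def test_estimates_match_reference(self):
        f = fit_nlme(self._fixture(), "provenance", reference="E",
                     method="REML")
        o = self.R_ORACLE
        assert f.phi0 == pytest.approx(o["phi0"], rel=1e-3)
        assert f.phi1 == pytest.approx(o["phi1"], rel=1e-3)
        assert f.phi2 == pytest.approx(o["phi2"], rel=1e-3)
        for lev, k in o["k"].items():
            assert f.offsets[lev] == pytest.approx(k, abs=2e-3)
        assert f.gamma == pytest.approx(o["gamma"], abs=1e-3)
        assert f.sigma == pytest.approx(o["sigma"], abs=1e-3)
        assert f.loglik == pytest.approx(o["loglik"], abs=5e-3)
        # both implementations push the block variance to the boundary
        assert f.sigma0_block == 0.0

    def test_standard_errors_match_reference(self):
        f = fit_nlme(self._fixture(), "provenance", reference="E",
                     method="REML")
        for name, se in self.R_ORACLE["se"].items():
            assert f.std_errors[name] == pytest.approx(se, rel=5e-3)
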