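"""Detection-function evaluation, fitting and goodness of fit."""

import math

import numpy as np
import pytest
from scipy import integrate

from ctds.detection import (
    DetectionConfig,
    DomainError,
    InsufficientDataError,
    average_p,
    detection_g,
    detection_pdf,
    fit_detection,
    gof_chi2,
    half_normal_average_p,
)
from ctds.detection import _nll, _starts  # fit internals, used as oracles only

HN = {"sigma": 8.0}
UNI = {"adjustments": []}


class TestDetectionG:
    def test_g0_is_one_for_every_key(self):
        for cfg, params in [
            (DetectionConfig("half_normal", truncation_w=40), HN),
            (DetectionConfig("uniform", truncation_w=40), UNI),
            (DetectionConfig("hazard_rate", truncation_w=40), {"sigma": 8.0, "shape": 2.5}),
            (DetectionConfig("half_normal", "cosine", 2, 40), {"sigma": 8.0, "adjustments": [0.3, -0.1]}),
        ]:
            assert detection_g(0.0, cfg, params) == pytest.approx(1.0)

    def test_half_normal_closed_form(self):
        cfg = DetectionConfig("half_normal", truncation_w=40)
        assert detection_g(8.0, cfg, HN) == pytest.approx(math.exp(-0.5), abs=1e-12)

    def test_uniform_is_flat(self):
        cfg = DetectionConfig("uniform", truncation_w=40)
        r = np.linspace(0, 40, 17)
        assert np.allclose(detection_g(r, cfg, UNI), 1.0)

    def test_domain_error_outside_truncation(self):
        cfg = DetectionConfig("half_normal", truncation_w=40)
        with pytest.raises(DomainError):
            detection_g(41.0, cfg, HN)
        with pytest.raises(DomainError):
            detection_g(-0.5, cfg, HN)


class TestDetectionPdf:
    def test_uniform_key_triangle_density(self):
        cfg = DetectionConfig("uniform", truncation_w=40)
        assert detection_pdf(20.0, cfg, UNI) == pytest.approx(2 * 20 / 1600, abs=1e-12)

    @pytest.mark.parametrize(
        "cfg,params",
        [
            (DetectionConfig("uniform", truncation_w=40), UNI),
            (DetectionConfig("half_normal", truncation_w=40), HN),
            (DetectionConfig("hazard_rate", truncation_w=40), {"sigma": 10.0, "shape": 3.0}),
            (DetectionConfig("half_normal", "cosine", 1, 40), {"sigma": 8.0, "adjustments": [0.2]}),
        ],
    )
    def test_pdf_normalizes_to_one(self, cfg, params):
        val, _ = integrate.quad(lambda r: detection_pdf(r, cfg, params), 0.0, 40.0, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_wide_half_normal_limits_to_triangle(self):
        cfg = DetectionConfig("half_normal", truncation_w=40)
        tri = DetectionConfig("uniform", truncation_w=40)
        r = np.linspace(1, 39, 20)
        wide = detection_pdf(r, cfg, {"sigma": 4000.0})
        assert np.allclose(wide, detection_pdf(r, tri, UNI), rtol=1e-4)


class TestAverageP:
    def test_closed_form_equals_quadrature(self):
        for sigma in (3.0, 8.0, 20.0):
            cfg = DetectionConfig("half_normal", truncation_w=40)
            assert average_p(cfg, {"sigma": sigma}) == pytest.approx(
                half_normal_average_p(sigma, 40.0), abs=1e-6
            )

    def test_uniform_p_is_one(self):
        assert average_p(DetectionConfig("uniform", truncation_w=40), UNI) == pytest.approx(1.0)

    def test_half_normal_sigma8_value(self):
        # (2*64/1600)(1 - e^-12.5) = 0.08 to 4 decimals
        assert half_normal_average_p(8.0, 40.0) == pytest.approx(0.0800, abs=1e-4)

    def test_p_increases_with_sigma(self):
        ps = [half_normal_average_p(s, 40.0) for s in (2, 4, 8, 16, 32)]
        assert all(b > a for a, b in zip(ps, ps[1:]))


class TestFitDetection:
    def test_sigma_recovered_within_5_percent(self, hn_distances, hn_config):
        fit = fit_detection(hn_distances, hn_config)
        assert fit.params["sigma"] == pytest.approx(8.0, rel=0.05)
        assert fit.converged and fit.monotone_ok

    def test_uniform_loglik_closed_form(self, hn_distances):
        cfg = DetectionConfig("uniform", truncation_w=40)
        fit = fit_detection(hn_distances, cfg)
        assert fit.p_hat == pytest.approx(1.0)
        expected_ll = float(np.sum(np.log(2 * hn_distances / 1600.0)))
        assert fit.loglik == pytest.approx(expected_ll, abs=1e-9)
        assert fit.aic == pytest.approx(-2 * expected_ll)

    def test_fit_is_deterministic(self, hn_distances, hn_config):
        f1 = fit_detection(hn_distances, hn_config)
        f2 = fit_detection(hn_distances, hn_config)
        assert np.array_equal(f1.param_vector, f2.param_vector)
        assert f1.loglik == f2.loglik and f1.aic == f2.aic

    def test_insufficient_data_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_detection([1.0] * 9, DetectionConfig("half_normal", truncation_w=40))

    def test_optimum_beats_every_start(self, hn_distances, hn_config):
        fit = fit_detection(hn_distances, hn_config)
        r = np.asarray(hn_distances)
        for x0 in _starts(hn_config, r):
            assert -fit.loglik <= _nll(x0, r, hn_config) + 1e-9

    def test_accepted_fit_g_monotone_with_g0_one(self, hn_distances):
        for cfg in [
            DetectionConfig("half_normal", truncation_w=40),
            DetectionConfig("hazard_rate", truncation_w=40),
            DetectionConfig("half_normal", "cosine", 1, 40),
        ]:
            fit = fit_detection(hn_distances, cfg)
            if not fit.monotone_ok:
                continue  # flagged fits are rejected from selection by design
            g = fit.g(np.linspace(0, 40, 100))
            assert g[0] == pytest.approx(1.0)
            assert np.all(np.diff(g) <= 1e-6)
            assert np.all((g >= -1e-6) & (g <= 1 + 1e-6))

    def test_aic_ordering_invariant_to_unit_rescaling(self, hn_distances):
        # fitting in decametres instead of metres must not reorder models
        scale = 0.1
        configs_m = [
            DetectionConfig("half_normal", truncation_w=40),
            DetectionConfig("hazard_rate", truncation_w=40),
            DetectionConfig("uniform", "cosine", 1, 40),
        ]
        aic_m = [fit_detection(hn_distances, c).aic for c in configs_m]
        configs_dm = [
            DetectionConfig(c.key, c.expansion, c.n_adjust, c.truncation_w * scale)
            for c in configs_m
        ]
        aic_dm = [
            fit_detection(np.asarray(hn_distances) * scale, c, zero_offset=0.25 * scale).aic
            for c in configs_dm
        ]
        assert np.argsort(aic_m).tolist() == np.argsort(aic_dm).tolist()

    def test_zero_distances_offset_not_dropped(self, hn_config):
        rng = np.random.default_rng(5)
        r = np.round(rng.rayleigh(8.0, 400) * 2) / 2
        r = r[r <= 40]
        n_zero = int(np.sum(r == 0))
        assert n_zero > 0  # rounding to 0.5 m produces true zeros
        fit = fit_detection(r, hn_config)
        assert fit.n_zero_adjusted == n_zero
        assert fit.n_obs == len(r)


class TestGof:
    def test_perfect_agreement_gives_zero_chi2(self):
        # uniform key on w=40: after merging (expected >= 5 rule) the bins are
        # [0,24),[24,32),[32,40] with probabilities 0.36/0.28/0.36 of n=25
        cfg = DetectionConfig("uniform", truncation_w=40)
        r = np.concatenate([
            np.linspace(3.1, 23.3, 9),    # 9 obs: expected 25*0.36 = 9
            np.linspace(24.7, 31.3, 7),   # 7 obs: expected 7
            np.linspace(32.6, 39.1, 9),   # 9 obs: expected 9
        ])
        fit = fit_detection(r, cfg)
        gof = gof_chi2(fit, r, n_bins=5)
        assert gof.chi2 == pytest.approx(0.0, abs=1e-9)
        assert gof.p_value == pytest.approx(1.0)
        assert gof.df == 2
        assert gof.expected.sum() == pytest.approx(len(r))

    def test_df_decreases_with_extra_parameter(self, hn_distances):
        f0 = fit_detection(hn_distances, DetectionConfig("half_normal", truncation_w=40))
        f1 = fit_detection(hn_distances, DetectionConfig("half_normal", "cosine", 1, 40))
        g0 = gof_chi2(f0, hn_distances)
        g1 = gof_chi2(f1, hn_distances)
        if len(g0.observed) == len(g1.observed):
            assert g1.df == g0.df - 1

    def test_calibration_under_true_model(self):
        """Under half-normal truth the GOF p-value should rarely fall below
        the study alpha: simulated 92/100 replicates with p > 0.1."""
        cfg = DetectionConfig("half_normal", truncation_w=40.0)
        n_pass = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            r = rng.rayleigh(8.0, 2000)
            r = r[r <= 40.0][:1000]
            fit = fit_detection(r, cfg)
            n_pass += gof_chi2(fit, r).p_value > 0.1
        assert n_pass >= 90

    def test_resolution_aligned_cutpoints_keep_calibration(self):
        """Distances recorded on a 0.5 m grid put atoms on naive equal-width
        cutpoints; the resolution-aware cutpoints must stay calibrated."""
        cfg = DetectionConfig("half_normal", truncation_w=40.0)
        reject = 0
        for rep in range(50):
            rng = np.random.default_rng(3000 + rep)
            r = np.round(rng.rayleigh(6.0, 1500) / 0.5) * 0.5
            r = r[r <= 40.0][:600]
            fit = fit_detection(r, cfg)
            reject += gof_chi2(fit, r).p_value < 0.1
        assert reject <= 12  # near-nominal 10% rejection at alpha = 0.1
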