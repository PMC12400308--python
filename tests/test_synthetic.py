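"""Synthetic generators: closed-form behaviour, determinism, orderings."""

import numpy as np
import pytest
from scipy.optimize import brentq

from cdphotostab import (SyntheticConfig, datasets, fit_breakpoint,
                         fit_first_order, fit_interaction)


class TestTimeCourse:
    def test_zero_time_identity(self, paper_cfg):
        tc = paper_cfg.generate_time_course(6.0)
        assert tc.times[0] == 0.0
        assert tc.responses[0] == paper_cfg.r0

    def test_half_life_closed_form(self):
        cfg = SyntheticConfig(noise_cv=0.0, k0_by_ph={7.0: 1e-3},
                              k2_by_cd={}, t_max=693.1, n_timepoints=4)
        tc = cfg.generate_time_course(7.0)
        # ln2/k = 693.147 min; at t = 693.1 the remaining fraction is 0.5000
        assert tc.responses[-1] / cfg.r0 == pytest.approx(0.5000, abs=5e-5)

    def test_published_grid_kobs(self, paper_cfg):
        # k0(pH 6) = 2.11e-3 min^-1 and k2(gamma, pH 6) = 1.04 M^-1 min^-1
        # imply kobs = 0.81e-3 at 1.25 mM, close to the printed 0.85e-3
        tc = paper_cfg.generate_time_course(6.0, "gamma", 1.25e-3)
        k = fit_first_order(tc).k
        assert k == pytest.approx(0.81e-3, rel=1e-9)
        assert k == pytest.approx(0.85e-3, abs=5e-5)

    def test_nonpositive_kobs_rejected(self):
        cfg = SyntheticConfig(k0_by_ph={7.0: 1e-3}, k2_by_cd={"gamma": 0.5},
                              cd_concs=(1e-3,))
        with pytest.raises(ValueError, match="pH 7.0.*gamma"):
            cfg.generate_time_course(7.0, "gamma", 3e-3)

    def test_invalid_config_grid_rejected(self):
        # config whose own grid implies negative decay is rejected outright
        with pytest.raises(ValueError, match="non-positive kobs"):
            SyntheticConfig(k0_by_ph={7.0: 1e-3}, k2_by_cd={"gamma": 2.0},
                            cd_concs=(1e-3,))

    def test_kobs_strictly_decreasing_in_conc_and_ordered_across_cds(
            self, paper_cfg):
        # stabilization order alpha < beta < gamma means kobs alpha > beta > gamma
        for ph in (2.0, 6.0, 12.0):
            ks = {cd: [fit_first_order(
                paper_cfg.generate_time_course(ph, cd, c)).k
                for c in paper_cfg.cd_concs]
                for cd in ("alpha", "beta", "gamma")}
            for cd, vals in ks.items():
                assert np.all(np.diff(vals) < 0), (ph, cd)
            assert np.all(np.array(ks["alpha"]) > np.array(ks["beta"]))
            assert np.all(np.array(ks["beta"]) > np.array(ks["gamma"]))


class TestQuenchingGenerators:
    def test_stern_volmer_closed_form(self, paper_cfg):
        s = paper_cfg.generate_quenching_series("gamma", concs=[1.25e-3])
        assert s.f0 / s.f[0] == pytest.approx(1 + 3.06e3 * 1.25e-3)
        assert s.f0 / s.f[0] == pytest.approx(4.825)

    def test_zero_ksv_no_quenching(self, paper_cfg):
        s = paper_cfg.generate_quenching_series("none", ksv=0.0)
        assert np.allclose(s.f, s.f0)

    def test_binding_closed_form(self, paper_cfg):
        s = paper_cfg.generate_binding_series(concs=[1e-3], bind_k=3.62e3,
                                              bind_n=1.03)
        assert (s.f0 - s.f[0]) / s.f[0] == pytest.approx(
            3.62e3 * (1e-3) ** 1.03)
        assert (s.f0 - s.f[0]) / s.f[0] == pytest.approx(2.943, abs=1e-3)

    def test_binding_n1_reduces_to_stern_volmer(self, paper_cfg):
        q = list(paper_cfg.cd_concs)
        sv = paper_cfg.generate_quenching_series("gamma", concs=q, ksv=3.62e3)
        bd = paper_cfg.generate_binding_series(concs=q, bind_k=3.62e3,
                                               bind_n=1.0)
        assert np.allclose(sv.f, bd.f)

    def test_empty_concentrations_rejected(self, paper_cfg):
        with pytest.raises(ValueError, match="empty"):
            paper_cfg.generate_quenching_series("gamma", concs=[])


class TestJobGenerator:
    def test_symmetry_about_half(self, paper_cfg):
        s = paper_cfg.generate_job_series(n_points=11)
        assert np.allclose(s.delta_a, s.delta_a[::-1])

    def test_strong_binding_stoichiometric_limit(self, paper_cfg):
        # K -> inf: complex = min(H, G); at x = 0.25, T = 1e-4 -> 2.5e-5 M
        s = paper_cfg.generate_job_series(n_points=7, assoc_k=1e12)
        x = s.mole_fractions
        i = np.argmin(np.abs(x - 0.25))
        c = s.delta_a[i] / paper_cfg.job_delta_eps
        assert c == pytest.approx(0.25 * 1e-4, rel=1e-4)

    def test_quadratic_root_matches_numeric_equilibrium(self, paper_cfg):
        k, t = 3.62e3, 1e-4
        s = paper_cfg.generate_job_series(n_points=11, assoc_k=k)
        for x, da in zip(s.mole_fractions, s.delta_a):
            h, g = x * t, (1 - x) * t
            c_num = brentq(lambda c: k * (h - c) * (g - c) - c, 0,
                           min(h, g) * (1 - 1e-12))
            assert da / paper_cfg.job_delta_eps == pytest.approx(
                c_num, rel=1e-9)


class TestConductivityGenerator:
    def test_exact_two_segment_refit(self, paper_cfg):
        s = paper_cfg.generate_conductivity_series()
        fit = fit_breakpoint(s)
        assert fit.sse == pytest.approx(0.0, abs=1e-18)
        assert fit.breakpoint == pytest.approx(2.0e-3)

    def test_equal_slopes_degenerate_to_line(self):
        cfg = SyntheticConfig(noise_cv=0.0, cond_slopes=(-3.0, -3.0))
        s = cfg.generate_conductivity_series()
        coef = np.polyfit(s.concs, s.conductivity, 1)
        assert np.allclose(np.polyval(coef, s.concs), s.conductivity)

    def test_breakpoint_outside_range_rejected(self):
        cfg = SyntheticConfig(cond_breakpoint=5e-3)
        with pytest.raises(ValueError, match="outside"):
            cfg.generate_conductivity_series()


class TestCalibrationGenerator:
    def test_noiseless_recovers_line_exactly(self):
        cfg = SyntheticConfig(calib_sd=0.0, calib_slope=2.56e10,
                              calib_intercept=8.48e3)
        s = cfg.generate_calibration()
        coef = np.polyfit(s.nominal_concs, s.responses, 1)
        assert coef[0] == pytest.approx(2.56e10, rel=1e-12)
        assert coef[1] == pytest.approx(8.48e3, rel=1e-9)

    def test_replicate_structure(self, noisy_cfg):
        s = noisy_cfg.generate_calibration(replicates=3)
        assert set(np.unique(s.replicate)) == {0, 1, 2}
        assert s.nominal_concs.size == 30

    def test_bad_replicates_rejected(self, noisy_cfg):
        with pytest.raises(ValueError, match="replicates"):
            noisy_cfg.generate_calibration(replicates=0)


class TestDeterminismAndNoise:
    def test_fixed_seed_bit_identical(self):
        a = datasets.paper2025().generate_time_course(7.0, "gamma", 1e-3)
        b = datasets.paper2025().generate_time_course(7.0, "gamma", 1e-3)
        assert np.array_equal(a.responses, b.responses)

    def test_series_streams_independent(self):
        # drawing a quench series must not change the time-course stream
        cfg1, cfg2 = datasets.paper2025(), datasets.paper2025()
        cfg2.generate_quenching_series("gamma")
        a = cfg1.generate_time_course(7.0, "gamma", 1e-3)
        b = cfg2.generate_time_course(7.0, "gamma", 1e-3)
        assert np.array_equal(a.responses, b.responses)

    def test_noise_cv_controls_scatter(self):
        cfg = datasets.paper2025()
        cfg.noise_cv = 0.10
        tc = cfg.generate_time_course(7.0)
        resid = np.log(tc.responses) + cfg.k0_by_ph[7.0] * tc.times \
            - np.log(cfg.r0)
        assert 0.0 < np.std(resid) < 0.4

    def test_noiseless_roundtrip_recovers_k0_k2_exactly(self, paper_cfg):
        ph = 9.0
        pairs = [(c, fit_first_order(
            paper_cfg.generate_time_course(ph, "beta", c)).k)
            for c in paper_cfg.cd_concs]
        fit = fit_interaction(pairs, ph, "beta")
        assert fit.k2 == pytest.approx(
            paper_cfg.k2_for("beta", ph), rel=1e-9)
        assert fit.k_at_zero_cd == pytest.approx(
            paper_cfg.k0_by_ph[ph], rel=1e-9)
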