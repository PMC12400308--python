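"""First-order fits, the secondary (k2) regression and the pH profile."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cdphotostab import (RateFit, TimeCourse, build_profile, datasets,
                         fit_first_order, fit_interaction, minimum_rate_ph,
                         stabilization_percent)


def _ols_oracle(x, y):
    """Closed-form two-parameter least squares (sigma formulas)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = x.size
    sx, sy, sxx, sxy = x.sum(), y.sum(), (x * x).sum(), (x * y).sum()
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


class TestFitFirstOrder:
    def test_exact_exponential(self):
        t = np.arange(0, 600, 100.0)
        tc = TimeCourse(times=t, responses=50 * np.exp(-2e-3 * t))
        fit = fit_first_order(tc)
        assert fit.k == pytest.approx(2.000e-3, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.se_k == pytest.approx(0.0, abs=1e-12)

    def test_constant_responses(self):
        tc = TimeCourse(times=[0, 10, 20], responses=[5.0, 5.0, 5.0])
        fit = fit_first_order(tc)
        assert fit.k == 0.0
        assert fit.se_k == 0.0

    def test_noisy_within_3se_and_matches_grid_search(self, noisy_cfg):
        tc = noisy_cfg.generate_time_course(6.0)  # true k0 = 2.11e-3
        fit = fit_first_order(tc)
        assert abs(fit.k - 2.11e-3) <= 3 * fit.se_k
        # independent oracle: grid search of the log-space SSE over k
        y = np.log(tc.responses)
        grid = np.linspace(1e-3, 3e-3, 20001)
        sse = [np.sum((y - (y.mean() + -k * (tc.times - tc.times.mean()))) ** 2)
               for k in grid]
        k_grid = grid[int(np.argmin(sse))]
        assert fit.k == pytest.approx(k_grid, abs=1e-7)

    def test_rejects_bad_series(self):
        with pytest.raises(ValueError, match=">= 3"):
            TimeCourse(times=[0, 1], responses=[1, 1])
        with pytest.raises(ValueError, match="> 0"):
            TimeCourse(times=[0, 1, 2], responses=[1.0, -1.0, 1.0])
        with pytest.raises(ValueError, match="increasing"):
            TimeCourse(times=[0, 2, 1], responses=[1, 1, 1.0])


class TestFitInteraction:
    @pytest.mark.parametrize("ph,cd,expected", [
        (2.0, "alpha", 0.49), (12.0, "beta", 1.47), (12.0, "gamma", 2.14),
        (2.0, "beta", 0.65), (7.0, "gamma", 0.92), (6.0, "alpha", 0.28),
        (2.0, "gamma", 1.35),
    ])
    def test_published_grid_reproduces_k2(self, ph, cd, expected):
        df = datasets.kobs_table()
        grp = df[(df.ph == ph) & (df.cd_type == cd)]
        fit = fit_interaction(list(zip(grp.cd_conc_M, grp.kobs_per_min)),
                              ph, cd)
        assert round(fit.k2, 2) == expected

    def test_constant_kobs(self):
        fit = fit_interaction([(1e-3, 2e-3), (2e-3, 2e-3), (3e-3, 2e-3)],
                              7.0, "beta")
        assert fit.k2 == 0.0
        assert fit.k_at_zero_cd == pytest.approx(2e-3)

    def test_singular_design_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            fit_interaction([(1e-3, 1.0), (1e-3, 2.0), (1e-3, 3.0)],
                            7.0, "beta")

    def test_intercept_consistent_with_k0_all_rows(self):
        # linear stabilization model: extrapolated zero-CD rate within 10%
        # of the measured CD-free k0 at every pH
        df = datasets.kobs_table()
        for (ph, cd), grp in df.groupby(["ph", "cd_type"]):
            fit = fit_interaction(list(zip(grp.cd_conc_M, grp.kobs_per_min)),
                                  ph, cd)
            k0 = datasets.K0_BY_PH[ph]
            assert abs(fit.k_at_zero_cd - k0) / k0 < 0.10, (ph, cd)

    @given(st.lists(st.tuples(
        st.floats(1e-5, 1e-2), st.floats(1e-4, 1e-2)),
        min_size=3, max_size=8))
    def test_ols_matches_sigma_formula_oracle(self, pairs):
        concs = np.unique([p[0] for p in pairs])
        if concs.size < 2 or np.ptp(concs) < 1e-5:
            return  # (near-)singular designs are rejected, not compared
        fit = fit_interaction(pairs, 7.0, "gamma")
        slope, intercept = _ols_oracle([p[0] for p in pairs],
                                       [p[1] for p in pairs])
        assert fit.k2 == pytest.approx(-slope, rel=1e-12, abs=1e-15)
        assert fit.k_at_zero_cd == pytest.approx(intercept, rel=1e-12)


class TestProfile:
    @staticmethod
    def _k0_fits():
        return [RateFit(k=k, ln_intercept=0, r_squared=1, se_k=0, n_points=6,
                        ph=ph, cd_type="none", cd_conc=0.0)
                for ph, k in datasets.K0_BY_PH.items()]

    def test_published_k0_column_profile(self):
        profile = build_profile(self._k0_fits())
        assert len(profile.ph_grid) == 11
        assert minimum_rate_ph(profile).ph == 6.0

    def test_order_invariance(self):
        fits = self._k0_fits()
        a = build_profile(fits)
        b = build_profile(list(reversed(fits)))
        assert a.k0 == b.k0

    def test_conflicting_duplicates_rejected(self):
        fits = self._k0_fits()
        clash = RateFit(k=9.9e-3, ln_intercept=0, r_squared=1, se_k=0,
                        n_points=6, ph=6.0, cd_type="none", cd_conc=0.0)
        with pytest.raises(ValueError, match="conflicting"):
            build_profile(fits + [clash])

    def test_monotone_series_minimum_at_first_ph(self):
        fits = [RateFit(k=1e-3 * (i + 1), ln_intercept=0, r_squared=1,
                        se_k=0, n_points=6, ph=float(ph), cd_type="none")
                for i, ph in enumerate((2, 4, 6, 8))]
        m = minimum_rate_ph(build_profile(fits))
        assert m.ph == 2.0 and not m.tie

    def test_all_equal_series_flagged_tie(self):
        fits = [RateFit(k=1e-3, ln_intercept=0, r_squared=1, se_k=0,
                        n_points=6, ph=float(ph), cd_type="none")
                for ph in (2, 4, 6)]
        m = minimum_rate_ph(build_profile(fits))
        assert m.ph == 2.0 and m.tie

    def test_single_cd_subset(self):
        fits = self._k0_fits() + [
            RateFit(k=1e-3, ln_intercept=0, r_squared=1, se_k=0, n_points=6,
                    ph=ph, cd_type="gamma", cd_conc=1e-3) for ph in (6.0, 7.0)]
        profile = build_profile(fits)
        assert set(profile.series("gamma")) == {6.0, 7.0}


class TestStabilizationPercent:
    def test_published_gamma_ph6(self):
        # k0 = 2.11e-3, kobs = 0.85e-3 -> 59.7% rate reduction
        assert stabilization_percent(2.11e-3, 0.85e-3) == pytest.approx(
            59.7, abs=0.05)

    @pytest.mark.parametrize("kobs,expected", [(2.11e-3, 0.0), (0.0, 100.0)])
    def test_bounds(self, kobs, expected):
        assert stabilization_percent(2.11e-3, kobs) == pytest.approx(expected)

    def test_zero_k0_rejected(self):
        with pytest.raises(ValueError):
            stabilization_percent(0.0, 1e-3)
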