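"""Piecewise-linear change-point regression on 1-year binned series."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from hippnorm import (
    BinnedSeries,
    bin_series,
    fit_k_joinpoints,
    generate_cohort,
    joinpoint_ci,
    max_feasible_joinpoints,
    select_model,
)

from conftest import clean_spec


def hinge_series(rng=None, noise=0.0, pre=-6.0, dm=-32.0, break_age=64.5,
                 lo=45.5, hi=79.5, base=7500.0):
    mids = np.arange(lo, hi + 0.5, 1.0)
    y = base + pre * (mids - lo) + dm * np.maximum(0.0, mids - break_age)
    if noise and rng is not None:
        y = y + rng.normal(0, noise, mids.size)
    return BinnedSeries(
        bin_start=mids - 0.5,
        bin_mid=mids,
        mean_volume=y,
        n_in_bin=np.full(mids.size, 250),
    )


class TestBinSeries:
    def test_single_year_single_bin(self):
        df = pd.DataFrame({"age": [60.1, 60.5, 60.9], "sex": "female", "v": [1.0, 2.0, 3.0]})
        s = bin_series(df, "v")
        assert s.n_bins == 1
        assert s.mean_volume[0] == pytest.approx(2.0)
        assert s.n_in_bin[0] == 3

    def test_noise_free_linear_bins_on_generating_line(self):
        # ages placed symmetrically inside each 1-year bin
        ages = np.concatenate([[a + 0.25, a + 0.75] for a in range(45, 80)])
        df = pd.DataFrame({"age": ages, "sex": "female", "v": 9000.0 - 15.0 * ages})
        s = bin_series(df, "v")
        np.testing.assert_allclose(s.mean_volume, 9000.0 - 15.0 * s.bin_mid, rtol=1e-12)

    def test_duplicated_cohort_gives_identical_series(self, rng):
        df = pd.DataFrame(
            {"age": rng.uniform(45, 80, 300), "sex": "female",
             "v": rng.normal(7000, 300, 300)}
        )
        a = bin_series(df, "v")
        b = bin_series(pd.concat([df, df], ignore_index=True), "v")
        np.testing.assert_allclose(a.mean_volume, b.mean_volume)
        assert np.array_equal(2 * a.n_in_bin, b.n_in_bin)


class TestFitKJoinpoints:
    def test_linear_data_k0_exact(self):
        s = hinge_series(dm=0.0, pre=-11.0)
        fit = fit_k_joinpoints(s, 0)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.segment_slopes[0] == pytest.approx(-11.0)

    def test_noise_free_break_recovered_exactly(self):
        """Two segments with slopes -6 and -38 breaking in the 64-65 bin:
        k = 1 recovers the break bin exactly and a slope change of -32."""
        s = hinge_series(pre=-6.0, dm=-32.0, break_age=64.5)
        fit = fit_k_joinpoints(s, 1)
        assert fit.rss == pytest.approx(0.0, abs=1e-9)
        assert fit.taus[0] == pytest.approx(64.5)
        assert fit.slope_changes[0] == pytest.approx(-32.0)
        assert fit.segment_slopes[0] == pytest.approx(-6.0)
        assert fit.segment_slopes[1] == pytest.approx(-38.0)

    def test_rss_nested_models_monotone(self, rng):
        s = hinge_series(rng=rng, noise=40.0)
        rss = [fit_k_joinpoints(s, k).rss for k in range(4)]
        assert all(a >= b - 1e-9 for a, b in zip(rss, rss[1:]))

    def test_infeasible_k_errors_with_rule(self):
        s = hinge_series(lo=45.5, hi=54.5)  # 10 bins: k=1 ok, k=2 not
        with pytest.raises(ValueError, match="points"):
            fit_k_joinpoints(s, 2)

    def test_continuity_at_joinpoints(self, rng):
        s = hinge_series(rng=rng, noise=30.0)
        fit = fit_k_joinpoints(s, 2)
        b = fit.beta
        for j, tau in enumerate(fit.taus):
            # left and right segment equations evaluated at the joinpoint
            left = b[0] + b[1] * tau + sum(b[2 + i] * (tau - fit.taus[i])
                                           for i in range(j) if tau > fit.taus[i])
            right = left + b[2 + j] * 0.0
            assert right == pytest.approx(left, rel=1e-9)
            # fitted curve is continuous: prediction from the design agrees
        x_eps = np.array([fit.taus[0] - 1e-9, fit.taus[0] + 1e-9])
        from hippnorm.joinpoint import _design

        pred = _design(x_eps, fit.taus) @ b
        assert abs(pred[1] - pred[0]) < 1e-6

    def test_grid_search_equals_bruteforce_oracle(self, rng):
        """Independent oracle: hat-function (piecewise-linear interpolation)
        basis spans the same model space; exhaustive enumeration over the
        same admissible placements must give the same optimum."""
        s = hinge_series(rng=rng, noise=50.0, lo=45.5, hi=74.5)  # 30 bins
        n = s.n_bins
        x, y = s.bin_mid, s.mean_volume

        def oracle_rss(k):
            best = (np.inf, None)
            for combo in combinations(range(2, n - 2), k):
                if any(b - a < 3 for a, b in zip(combo, combo[1:])):
                    continue
                knots = np.concatenate([[x[0]], x[list(combo)], [x[-1]]])
                # hat basis: value of the piecewise-linear function at knots
                B = np.empty((n, len(knots)))
                for j in range(len(knots)):
                    e = np.zeros(len(knots))
                    e[j] = 1.0
                    B[:, j] = np.interp(x, knots, e)
                beta, *_ = np.linalg.lstsq(B, y, rcond=None)
                rss = float(np.sum((y - B @ beta) ** 2))
                if rss < best[0] - 1e-12:
                    best = (rss, combo)
            return best

        for k in (1, 2):
            fit = fit_k_joinpoints(s, k)
            rss_o, combo_o = oracle_rss(k)
            assert fit.rss == pytest.approx(rss_o, rel=1e-9)
            assert fit.tau_indices == combo_o


class TestSelectModel:
    def test_alpha_zero_selects_k0(self, rng):
        s = hinge_series(rng=rng, noise=10.0)
        m = select_model(s, alpha=0.0, n_perm=49, seed=0)
        assert m.k == 0

    def test_too_few_permutations_errors(self):
        s = hinge_series()
        with pytest.raises(ValueError, match="19"):
            select_model(s, n_perm=10)

    def test_reproducible_with_seed(self, rng):
        s = hinge_series(rng=rng, noise=30.0)
        a = select_model(s, n_perm=99, seed=7)
        b = select_model(s, n_perm=99, seed=7)
        assert a.k == b.k
        assert a.ladder_pvalues == b.ladder_pvalues
        np.testing.assert_array_equal(a.joinpoint_ages, b.joinpoint_ages)

    def test_degrees_of_freedom_convention(self, rng):
        # 25 bins and one joinpoint: t on 25 - 2(1+1) = 21 degrees of freedom
        s = hinge_series(rng=rng, noise=15.0, lo=45.5, hi=69.5)
        assert s.n_bins == 25
        m = select_model(s, n_perm=99, seed=1)
        if m.k == 1:
            assert m.df == 21

    def test_clean_cohort_trajectory_recovers_geometry(self):
        """End-to-end: a synthetic cohort with the hinge geometry of the
        female hippocampal trajectory yields k = 1 with the break bin within
        3 years and a slope change near the generating -32.44 mm^3/yr."""
        spec = clean_spec(n_female=12_000, noise_sd=500.0, pre_slope=-5.0,
                          slope_change=-16.22, seed=13)
        c = generate_cohort(spec)
        s = bin_series(c, "hippocampus_bilateral", "female")
        m = select_model(s, n_perm=199, seed=3)
        assert m.k >= 1
        j = int(np.argmin(np.abs(m.joinpoint_ages - 64.5)))
        assert abs(m.joinpoint_ages[j] - 64.5) <= 3.0
        assert m.slope_changes[j] == pytest.approx(-32.44, abs=12.0)
        lo, hi = m.joinpoint_cis[j]
        assert lo <= m.joinpoint_ages[j] <= hi


class TestJoinpointCI:
    def test_noise_free_break_ci_collapses(self):
        s = hinge_series(pre=-6.0, dm=-32.0)
        fit = fit_k_joinpoints(s, 1)
        (lo, hi), = joinpoint_ci(s, fit)
        assert (lo, hi) == (64.0, 65.0)

    def test_ci_contains_estimate(self, rng):
        s = hinge_series(rng=rng, noise=40.0)
        fit = fit_k_joinpoints(s, 1)
        (lo, hi), = joinpoint_ci(s, fit)
        assert lo <= fit.taus[0] <= hi

    def test_ci_width_shrinks_with_noise(self):
        widths = []
        for noise in (60.0, 15.0, 2.0):
            w = []
            for rep in range(10):
                r = np.random.default_rng(rep)
                s = hinge_series(rng=r, noise=noise)
                fit = fit_k_joinpoints(s, 1)
                (lo, hi), = joinpoint_ci(s, fit)
                w.append(hi - lo)
            widths.append(np.mean(w))
        assert widths[0] >= widths[1] >= widths[2]

    def test_k0_model_errors(self):
        s = hinge_series(dm=0.0)
        fit = fit_k_joinpoints(s, 0)
        with pytest.raises(ValueError, match="k >= 1"):
            joinpoint_ci(s, fit)


def test_max_feasible_joinpoints_rules():
    assert max_feasible_joinpoints(6) == 0  # fewer than 7 points
    assert max_feasible_joinpoints(7) == 1
    assert max_feasible_joinpoints(13) == 1
    assert max_feasible_joinpoints(14) == 2
    assert max_feasible_joinpoints(35) == 4  # capped at k_max
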