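import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

import fossilbd as fb
from fossilbd.errors import ConfigError, DomainError
from fossilbd.series import CovariateSeries


class TestRescale01:
    def test_basic(self):
        s = CovariateSeries(np.array([4.0, 2.0, 0.0]), np.array([2.0, 4.0, 6.0]))
        out = fb.rescale01(s)
        np.testing.assert_allclose(out.values, [0.0, 0.5, 1.0])

    def test_constant_maps_to_zeros_with_flag(self):
        s = CovariateSeries(np.array([2.0, 0.0]), np.array([5.0, 5.0]))
        out = fb.rescale01(s)
        np.testing.assert_array_equal(out.values, [0.0, 0.0])
        assert out.constant_flag

    def test_idempotent_on_unit_series(self):
        s = CovariateSeries(np.array([2.0, 1.0, 0.0]), np.array([0.0, 0.4, 1.0]))
        np.testing.assert_array_equal(fb.rescale01(s).values, s.values)


class TestSealevelChangeRate:
    def _series(self, values, step=1.0):
        n = len(values)
        ages = np.arange(n - 1, -1, -1, dtype=float) * step
        return CovariateSeries(ages, np.asarray(values, float), label="sl")

    def test_constant_gives_zeros(self):
        out = fb.sealevel_change_rate(self._series([3.0] * 6))
        assert np.allclose(out.values, 0.0)

    def test_linear_trend_gives_constant_rate(self):
        out = fb.sealevel_change_rate(self._series([0, 2, 4, 6, 8]))
        assert np.allclose(out.values, 2.0)

    def test_sawtooth_oracle(self):
        # amplitude a with period 2 steps: |diff| = a at every step
        out = fb.sealevel_change_rate(self._series([0, 3, 0, 3, 0], step=0.5))
        assert np.allclose(out.values, 6.0)  # 3 per 0.5 Myr

    def test_assigned_to_younger_age(self):
        out = fb.sealevel_change_rate(self._series([0, 1, 3]))
        np.testing.assert_allclose(out.ages, [1.0, 0.0])
        np.testing.assert_allclose(out.values, [1.0, 2.0])

    def test_nonuniform_grid_raises(self):
        s = CovariateSeries(np.array([5.0, 2.0, 0.0]), np.array([1.0, 2.0, 3.0]))
        with pytest.raises(DomainError, match="resample"):
            fb.sealevel_change_rate(s)


def _grid_covariates(values_by_label, top=20.0, n=21):
    grid = np.linspace(top, 0.0, n)
    series = [CovariateSeries(grid, np.asarray(v, float), label=k)
              for k, v in values_by_label.items()]
    return fb.CovariateSet(series, rescale=False)


class TestMbdLoglik:
    LIFESPANS = pd.DataFrame({"ts": [18.0, 9.5, 4.0], "te": [6.0, 0.0, 1.5]})

    def test_zero_gamma_reduces_to_constant_rate_bd(self):
        covs = _grid_covariates({"x": np.linspace(0, 1, 21)})
        params = fb.MBDParams(0.3, 0.2, [0.0], [0.0], link="exponential")
        expected = fb.bd_loglik(self.LIFESPANS, fb.RateSeries.constant(0.3, 0.2))
        assert fb.mbd_loglik(self.LIFESPANS, covs, params) == pytest.approx(expected, abs=1e-12)

    def test_unit_covariate_exponential_closed_form(self):
        covs = _grid_covariates({"x": np.ones(21)})
        params = fb.MBDParams(0.3, 0.2, [0.0], [math.log(2.0)], link="exponential")
        expected = fb.bd_loglik(self.LIFESPANS, fb.RateSeries.constant(0.3, 0.4))
        assert fb.mbd_loglik(self.LIFESPANS, covs, params) == pytest.approx(expected, abs=1e-12)

    def test_matches_quadrature_oracle(self, rng):
        """3 lineages, 2 covariates, 20 grid cells against quadrature of
        the continuous-time integrand."""
        grid = np.linspace(20.0, 0.0, 21)
        x1 = rng.random(21)
        x2 = rng.random(21)
        covs = _grid_covariates({"a": x1, "b": x2})
        params = fb.MBDParams(0.4, 0.25, [0.8, -0.5], [0.3, 0.6], link="exponential")

        def cell_value(x, t):
            # each value extends from its own grid age toward younger ages
            idx = np.searchsorted(grid[::-1], t, side="left")
            idx = min(idx, 20)
            return x[::-1][idx]

        def lam(t):
            return 0.4 * math.exp(0.8 * cell_value(x1, t) - 0.5 * cell_value(x2, t))

        def mu(t):
            return 0.25 * math.exp(0.3 * cell_value(x1, t) + 0.6 * cell_value(x2, t))

        ts = self.LIFESPANS["ts"].to_numpy()
        te = self.LIFESPANS["te"].to_numpy()

        def integrand(t):
            N = np.sum((te <= t) & (ts >= t))
            return (lam(t) + mu(t)) * N

        pieces = np.sort(np.unique(np.concatenate([grid, ts, te])))
        integral = sum(
            integrate.quad(integrand, a, b, limit=100)[0]
            for a, b in zip(pieces[:-1], pieces[1:])
        )
        events = sum(math.log(lam(t)) for t in ts) + sum(
            math.log(mu(t)) for t in te if t > 0
        )
        got = fb.mbd_loglik(self.LIFESPANS, covs, params)
        assert got == pytest.approx(events - integral, rel=1e-6)

    def test_linear_link_floors_rates(self):
        covs = _grid_covariates({"x": np.ones(21)})
        params = fb.MBDParams(0.3, 0.2, [-5.0], [0.0], link="linear")
        got = fb.mbd_loglik(self.LIFESPANS, covs, params)
        assert np.isfinite(got)  # floored at 1e-5, not log(negative)

    def test_gauge_identity_exponential_link(self):
        """Adding c to a covariate while multiplying lambda0 by e^{-gamma c}
        leaves the likelihood unchanged."""
        base = np.linspace(0.2, 0.9, 21)
        c, g = 0.37, 0.8
        covs1 = _grid_covariates({"x": base})
        covs2 = _grid_covariates({"x": base + c})
        p1 = fb.MBDParams(0.3, 0.2, [g], [0.0], link="exponential")
        p2 = fb.MBDParams(0.3 * math.exp(-g * c), 0.2, [g], [0.0], link="exponential")
        assert fb.mbd_loglik(self.LIFESPANS, covs1, p1) == pytest.approx(
            fb.mbd_loglik(self.LIFESPANS, covs2, p2), abs=1e-10
        )

    def test_grid_not_covering_span_raises(self):
        covs = _grid_covariates({"x": np.ones(11)}, top=10.0, n=11)
        params = fb.MBDParams(0.3, 0.2, [0.0], [0.0])
        with pytest.raises(DomainError, match="cover"):
            fb.mbd_loglik(self.LIFESPANS, covs, params)


class TestShrinkageWeight:
    def test_limits_and_closed_forms(self):
        assert fb.shrinkage_weight(1e-8, 1e-8) == pytest.approx(0.0, abs=1e-12)
        assert fb.shrinkage_weight(1.0, 1.0) == pytest.approx(0.5)
        assert fb.shrinkage_weight(3.0, 1.0) == pytest.approx(0.9)

    def test_nonpositive_scale_raises(self):
        with pytest.raises(DomainError):
            fb.shrinkage_weight(0.0, 1.0)
        with pytest.raises(DomainError):
            fb.shrinkage_weight(1.0, -1.0)


class TestHarmonicMean:
    def test_equal_samples(self):
        assert fb.harmonic_mean_logml([-3.2] * 10) == pytest.approx(-3.2, abs=1e-12)

    def test_two_sample_closed_form(self):
        got = fb.harmonic_mean_logml([0.0, -math.log(2.0)])
        assert got == pytest.approx(-math.log(1.5), abs=1e-12)
        assert got == pytest.approx(-0.40546, abs=1e-5)

    def test_permutation_invariant(self, rng):
        ll = rng.normal(-100, 5, 50)
        assert fb.harmonic_mean_logml(ll) == pytest.approx(
            fb.harmonic_mean_logml(rng.permutation(ll)), abs=1e-10
        )


@pytest.fixture(scope="module")
def coupled_setup():
    pA = fb.SimParams(t_root=25, lam=0.42, mu=0.15, n0=3, seed=21, family="Driver")
    pB = fb.SimParams(t_root=25, lam=0.35, mu=0.12, n0=2, seed=22, family="Resp")
    hA, hB, dA = fb.simulate_coupled_clades(pA, pB, 0.0, 1.0, link="exponential")
    noise = fb.simulate_covariate(dA.ages, "random_walk", {"sigma": 0.5}, seed=9,
                                  label="noise")
    covs = fb.CovariateSet.build([dA, noise], grid=np.arange(25.0, -0.01, -0.5))
    return hB, covs


class TestMbdMcmc:
    def test_driver_recovered_with_correct_sign_and_weight(self, coupled_setup):
        hB, covs = coupled_setup
        cfg = fb.MCMCConfig(n_generations=6000, sample_every=5, seed=5)
        post = fb.mbd_mcmc(hB.lineages, covs, link="exponential", cfg=cfg)
        g = post.gamma("extinction", covs.labels[0])
        lo, hi = fb.hpd_interval(g, 0.95)
        assert lo <= 1.0 <= hi  # true gamma_mu inside the 95% HPD
        assert np.median(g) > 0
        assert np.median(post.weight("extinction", covs.labels[0])) > 0.7

    def test_noise_covariate_shrunk(self, coupled_setup):
        hB, covs = coupled_setup
        cfg = fb.MCMCConfig(n_generations=6000, sample_every=5, seed=5)
        post = fb.mbd_mcmc(hB.lineages, covs, link="exponential", cfg=cfg)
        assert np.median(post.weight("extinction", "noise")) < 0.5
        assert np.median(post.weight("speciation", "noise")) < 0.5

    def test_seed_reproducible(self, coupled_setup):
        hB, covs = coupled_setup
        cfg = fb.MCMCConfig(n_generations=600, sample_every=5, seed=3)
        a = fb.mbd_mcmc(hB.lineages, covs, cfg=cfg).samples
        b = fb.mbd_mcmc(hB.lineages, covs, cfg=cfg).samples
        pd.testing.assert_frame_equal(a, b)

    def test_zero_covariates_matches_constant_rate_bd(self, coupled_setup):
        """With no covariates the MBD posterior of (lambda0, mu0) overlaps
        the constant-rate birth-death posterior on the same lifespans."""
        hB, _ = coupled_setup
        lf = hB.lineages
        grid = np.array([np.ceil(lf["ts"].max()), 0.0])
        covs = fb.CovariateSet([], grid=grid)
        cfg = fb.MCMCConfig(n_generations=4000, sample_every=5, seed=6)
        post = fb.mbd_mcmc(lf, covs, cfg=cfg)
        bd_cfg = fb.MCMCConfig(n_generations=30_000, sample_every=30, seed=7,
                               rj_poisson_mean=0.1)
        bd_post = fb.rj_mcmc_rates(lf, bd_cfg)
        grid_eval = np.array([5.0])
        lam_bd = np.array([s["rates"].lam.at(grid_eval)[0] for s in bd_post.samples])
        lam_lo, lam_hi = fb.hpd_interval(lam_bd, 0.95)
        mbd_lo, mbd_hi = fb.hpd_interval(post.samples["lambda0"].to_numpy(), 0.95)
        assert max(lam_lo, mbd_lo) < min(lam_hi, mbd_hi)  # overlapping HPDs

    def test_prior_shape_has_mass_at_both_ends(self):
        """Prior-only horseshoe weights pile up near 0 and near 1."""
        grid = np.arange(10.0, -0.1, -1.0)
        covs = fb.CovariateSet(
            [CovariateSeries(grid, np.linspace(0, 1, grid.size), label="x"),
             CovariateSeries(grid, np.linspace(1, 0, grid.size), label="y")],
            rescale=False,
        )
        lf = pd.DataFrame({"ts": [5.0], "te": [0.0]})
        cfg = fb.MCMCConfig(n_generations=30_000, sample_every=5, seed=7,
                            burn_in_fraction=0.1)
        post = fb.mbd_mcmc(lf, covs, cfg=cfg, prior_only=True)
        w = np.concatenate(
            [post.samples[f"w_{b}_{j}"] for b in ("l", "m") for j in range(2)]
        )
        assert np.mean(w < 0.1) >= 0.2
        assert np.mean(w > 0.9) >= 0.2

    def test_turnover_effect_definition_and_oracle(self, coupled_setup):
        hB, covs = coupled_setup
        cfg = fb.MCMCConfig(n_generations=1000, sample_every=5, seed=4)
        post = fb.mbd_mcmc(hB.lineages, covs, cfg=cfg)
        label = covs.labels[0]
        t = fb.turnover_effect(post, label)
        oracle = post.gamma("speciation", label) + post.gamma("extinction", label)
        np.testing.assert_allclose(t, oracle)
        with pytest.raises(ConfigError):
            fb.turnover_effect(post, "nope")

    def test_pooling_concatenates_equal_weight(self, coupled_setup):
        hB, covs = coupled_setup
        cfgs = [fb.MCMCConfig(n_generations=600, sample_every=5, seed=s) for s in (1, 2)]
        posts = [fb.mbd_mcmc(hB.lineages, covs, cfg=c) for c in cfgs]
        pooled = fb.pool_posteriors(posts)
        assert len(pooled) == 2 * min(len(p) for p in posts)
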