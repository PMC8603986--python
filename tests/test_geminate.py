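"""Distributed rebinding kinetics, inversion, and kinetic schemes."""

import warnings

import numpy as np
import pytest

import hemekin as hk
from hemekin.constants import Conditions

C297 = Conditions(297.0)
A_REF = 1e9  # s^-1, documented synthetic Arrhenius prefactor


def two_exp_oracle(t, H, g, A, cond):
    """Hand-coded explicit sum for a two-component distribution."""
    k = [A * np.exp(-h / cond.thermal_energy) for h in H]
    return g[0] * np.exp(-k[0] * t) + g[1] * np.exp(-k[1] * t)


class TestSurvival:
    def test_delta_distribution_is_pure_exponential(self):
        d = hk.EnthalpyDistribution(H=np.array([12.0]), g=np.array([1.0]), A=A_REF)
        t = np.logspace(-8, -4, 20)
        k = A_REF * np.exp(-12.0 / C297.thermal_energy)
        np.testing.assert_allclose(
            hk.survival_distributed(t, d, C297).N, np.exp(-k * t), rtol=1e-14
        )

    def test_survival_is_one_at_time_zero(self):
        d = hk.EnthalpyDistribution.gaussian(12.0, 2.0, A_REF)
        assert hk.survival_distributed(np.array([0.0]), d, C297).N[0] == pytest.approx(1.0, abs=1e-14)

    def test_bimodal_matches_explicit_two_exponential_sum(self):
        H = np.array([8.0, 16.0])
        g = np.array([0.3, 0.7])
        d = hk.EnthalpyDistribution(H=H, g=g, A=A_REF)
        t = np.logspace(-9, -1, 20)
        np.testing.assert_allclose(
            hk.survival_distributed(t, d, C297).N,
            two_exp_oracle(t, H, g, A_REF, C297),
            rtol=1e-12,
        )

    def test_completely_monotone_decay(self):
        # N' <= 0 and N'' >= 0 for any non-negative weights
        d = hk.EnthalpyDistribution.gaussian(12.0, 3.0, A_REF)
        t = np.linspace(0, 1e-5, 400)
        N = hk.survival_distributed(t, d, C297).N
        d1 = np.diff(N)
        d2 = np.diff(N, n=2)
        assert np.all(d1 <= 1e-15)
        assert np.all(d2 >= -1e-15)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            hk.EnthalpyDistribution(H=np.array([]), g=np.array([]), A=A_REF)


class TestInitialRate:
    def test_delta_distribution_closed_form(self):
        d = hk.EnthalpyDistribution(H=np.array([10.0]), g=np.array([1.0]), A=A_REF)
        expect = A_REF * np.exp(-10.0 / C297.thermal_energy)
        assert hk.initial_rate(d, C297) == pytest.approx(expect, rel=1e-14)

    def test_matches_finite_difference_of_survival(self):
        # step small enough that truncation is < 1e-6 relative, large
        # enough that 1 - N(eps) is well above double-precision rounding
        d = hk.EnthalpyDistribution.gaussian(12.0, 2.0, A_REF)
        rate = hk.initial_rate(d, C297)
        eps = 1e-7 / rate
        N = hk.survival_distributed(np.array([0.0, eps]), d, C297).N
        assert (N[0] - N[1]) / eps == pytest.approx(rate, rel=1e-6)


class TestEnthalpyDistributionFit:
    def test_noiseless_single_exponential_recovers_delta(self):
        single = hk.EnthalpyDistribution(H=np.array([12.0]), g=np.array([1.0]), A=A_REF)
        k = single.rates(C297)[0]
        t = np.logspace(np.log10(0.01 / k), np.log10(10 / k), 60)
        curve = hk.survival_distributed(t, single, C297)
        est = hk.fit_enthalpy_distribution([curve], A=A_REF)
        g, H = est.distribution_.g, est.distribution_.H
        assert H.size == 32  # default substate count
        i = int(np.argmax(g))
        assert g[max(i - 1, 0) : i + 2].sum() >= 0.99
        assert abs(H[i] - 12.0) <= H[1] - H[0]

    def test_gaussian_recovery_from_three_temperatures(self):
        truth = hk.EnthalpyDistribution.gaussian(12.0, 2.0, A_REF, h_min=0, h_max=30, n_bins=200)
        temps = [140.0, 200.0, 297.0]
        grids = []
        for T in temps:
            kt = Conditions(T).thermal_energy
            k_fast = A_REF * np.exp(-(12.0 - 6.0) / kt)
            k_slow = A_REF * np.exp(-(12.0 + 6.0) / kt)
            grids.append(np.logspace(np.log10(0.01 / k_fast), np.log10(10 / k_slow), 80))
        curves = hk.gen_survival_set(truth, temps, grids, hk.NoiseSpec(sd=0.005, seed=1))
        est = hk.fit_enthalpy_distribution(curves)  # A free
        d = est.distribution_
        assert est.converged_
        assert d.mean() == pytest.approx(12.0, rel=0.10)
        assert d.std() == pytest.approx(2.0, rel=0.10)

    def test_noiseless_fit_roundtrips_forward_model(self):
        truth = hk.EnthalpyDistribution.gaussian(14.0, 1.5, A_REF, h_min=0, h_max=30, n_bins=32)
        t = np.logspace(-9, -2, 70)
        curve = hk.survival_distributed(t, truth, C297)
        est = hk.fit_enthalpy_distribution([curve], A=A_REF, reg=0.0)
        model = est.predict(t, 297.0)
        chi2 = float(np.sum((model - curve.N) ** 2))
        assert chi2 < 1e-8

    def test_rejects_fewer_than_two_bins(self):
        t = np.logspace(-9, -2, 10)
        curve = hk.survival_distributed(
            t, hk.EnthalpyDistribution.gaussian(12, 2, A_REF), C297
        )
        with pytest.raises(ValueError, match="n_bins"):
            hk.fit_enthalpy_distribution([curve], n_bins=1)


class TestRateDistributionInversion:
    T = np.logspace(-6, -2, 80)

    def test_noiseless_single_exponential_unimodal_on_grid(self):
        N = np.exp(-1e4 * self.T)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = hk.invert_rate_distribution(
                hk.SurvivalCurve(t=self.T, N=N), method="ridge", lam=1e-6
            )
        k, w = est.distribution_.k, est.distribution_.w
        i = int(np.argmax(w))
        step = k[1] / k[0]
        assert k[i] / 1e4 <= step and 1e4 / k[i] <= step

    def test_two_exponentials_recovered_as_two_modes(self):
        rng = np.random.default_rng(3)
        N = 0.5 * np.exp(-1e3 * self.T) + 0.5 * np.exp(-1e5 * self.T)
        N = np.clip(N + rng.normal(0, 0.01, self.T.size), 0, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = hk.invert_rate_distribution(
                hk.SurvivalCurve(t=self.T, N=N, sd=np.full(self.T.size, 0.01)),
                method="maxent",
            )
        k, w = est.distribution_.k, est.distribution_.w
        modes = [
            k[j]
            for j in range(1, k.size - 1)
            if w[j] > w[j - 1] and w[j] >= w[j + 1] and w[j] > 0.1 * w.max()
        ]
        # both true rates found within half a decade by some mode
        for true in (1e3, 1e5):
            assert any(abs(np.log10(m / true)) < 0.5 for m in modes)

    def test_zero_data_weight_returns_flat_prior(self):
        N = np.exp(-1e4 * self.T)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = hk.invert_rate_distribution(
                hk.SurvivalCurve(t=self.T, N=N),
                method="maxent",
                sd=np.full(self.T.size, np.inf),
            )
        np.testing.assert_allclose(est.distribution_.w, 1.0 / est.distribution_.k.size)

    def test_ill_posedness_reported_not_silent(self):
        N = np.exp(-1e4 * self.T)
        with pytest.warns(UserWarning, match="ill-posed"):
            est = hk.invert_rate_distribution(
                hk.SurvivalCurve(t=self.T, N=N), method="ridge"
            )
        assert est.effective_rank_ < est.distribution_.k.size

    def test_noise_widens_recovered_peak(self):
        def log_width(sd, seed=5):
            rng = np.random.default_rng(seed)
            N = np.clip(
                0.999 * np.exp(-1e4 * self.T) + rng.normal(0, sd, self.T.size), 0, 1
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est = hk.invert_rate_distribution(
                    hk.SurvivalCurve(t=self.T, N=N, sd=np.full(self.T.size, max(sd, 1e-4))),
                    method="maxent",
                )
            w = est.distribution_.w
            w = w / w.sum()
            logk = np.log(est.distribution_.k)
            mu = np.sum(w * logk)
            return float(np.sqrt(np.sum(w * (logk - mu) ** 2)))

        widths = [log_width(s) for s in (0.001, 0.01, 0.05)]
        assert widths[0] < widths[1] < widths[2]


class TestKineticScheme:
    def test_two_state_decay(self):
        s = hk.KineticScheme(
            states=["A", "B"],
            rates={("A", "B"): 1.0},
            initial={"A": 1.0},
            absorbing=frozenset({"B"}),
        )
        df = hk.scheme_solve(s, np.array([1.0]))
        assert df["A"].iloc[0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_zero_rates_freeze_populations(self):
        s = hk.KineticScheme(
            states=["A", "B"], rates={("A", "B"): 0.0}, initial={"A": 0.4, "B": 0.6}
        )
        df = hk.scheme_solve(s, np.array([0.0, 5.0, 50.0]))
        np.testing.assert_allclose(df["A"], 0.4, atol=1e-14)
        np.testing.assert_allclose(df["B"], 0.6, atol=1e-14)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="negative rate"):
            hk.KineticScheme(states=["A", "B"], rates={("A", "B"): -1.0}, initial={"A": 1.0})

    def test_population_conserved_in_closed_scheme(self):
        s = hk.KineticScheme(
            states=["A", "B", "C"],
            rates={("A", "B"): 2.0, ("B", "A"): 1.0, ("B", "C"): 0.5, ("C", "B"): 0.25},
            initial={"A": 1.0},
        )
        df = hk.scheme_solve(s, np.logspace(-3, 2, 40))
        np.testing.assert_allclose(df.sum(axis=1), 1.0, atol=1e-10)

    def test_matrix_exponential_matches_fine_step_integration(self):
        s = hk.two_geminate_scheme(
            k_bind_fast=5e7, k_bind_slow=2e4, k_12=1e7, k_21=5e6,
            k_escape=2e6, k_relax=3e6,
        )
        Q = s.rate_matrix()
        p = s.initial_vector()
        dt = 1e-4 / max(s.rates.values())
        t_end = 1e-6
        nstep = int(round(t_end / dt))
        save = {int(round(x / dt)) for x in np.linspace(0, t_end, 11)}
        res = {}
        for i in range(nstep + 1):
            if i in save:
                res[i * dt] = p.copy()
            k1 = Q @ p
            k2 = Q @ (p + 0.5 * dt * k1)
            k3 = Q @ (p + 0.5 * dt * k2)
            k4 = Q @ (p + dt * k3)
            p = p + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        tt = np.array(sorted(res))
        df = hk.scheme_solve(s, tt)
        for t in tt:
            np.testing.assert_allclose(df.loc[t].to_numpy(), res[t], atol=1e-8)


class TestGeminateYield:
    def test_branching_ratio_with_twenty_fold_escape(self):
        # escape 20x faster than rebinding -> yield 1/21 ~ 4%
        s = hk.KineticScheme(
            states=["bound", "gem", "solvent"],
            rates={("gem", "bound"): 1.0, ("gem", "solvent"): 20.0},
            initial={"gem": 1.0},
            absorbing=frozenset({"bound", "solvent"}),
        )
        y = hk.geminate_yield(s)
        assert y == pytest.approx(1.0 / 21.0, rel=1e-12)
        assert y == pytest.approx(0.048, abs=0.001)

    def test_no_escape_gives_unit_yield(self):
        s = hk.KineticScheme(
            states=["bound", "gem", "solvent"],
            rates={("gem", "bound"): 1.0, ("gem", "solvent"): 0.0},
            initial={"gem": 1.0},
            absorbing=frozenset({"bound", "solvent"}),
        )
        assert hk.geminate_yield(s) == pytest.approx(1.0, rel=1e-12)

    def test_matches_long_time_trajectory_limit(self):
        s = hk.two_geminate_scheme(
            k_bind_fast=5e7, k_bind_slow=2e4, k_12=1e7, k_21=5e6,
            k_escape=2e6, k_relax=3e6,
        )
        y = hk.geminate_yield(s)
        t_long = 100.0 / min(s.rates.values())
        traj = hk.scheme_solve(s, np.array([t_long]))["bound"].iloc[0]
        assert y == pytest.approx(traj, abs=1e-6)

    def test_yields_sum_to_one(self):
        s = hk.two_geminate_scheme()
        y_bound = hk.geminate_yield(s, bound="bound", escaped="solvent")
        y_escape = hk.geminate_yield(s, bound="solvent", escaped="bound")
        assert y_bound + y_escape == pytest.approx(1.0, abs=1e-10)

    def test_requires_absorbing_states(self):
        s = hk.KineticScheme(
            states=["bound", "gem"], rates={("gem", "bound"): 1.0}, initial={"gem": 1.0}
        )
        with pytest.raises(ValueError, match="absorbing"):
            hk.geminate_yield(s, bound="bound", escaped="gem")
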