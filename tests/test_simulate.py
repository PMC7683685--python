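"""Simulator oracles: first-passage density, direct sampler, trace generator."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid
from scipy.stats import kstest

from dynforce import (
    BondModel,
    InvalidConfigError,
    TrapConfig,
    analytic_force_pdf,
    analytic_survival,
    detect_events,
    sample_unbinding_forces,
    simulate_pull_trace,
    simulate_stall_forces,
    simulate_velocities,
)


class TestAnalyticForcePdf:
    def test_ideal_bond_gives_exponential_density(self, trap_rigid, ideal_bond):
        """k(F)=k0 at constant r -> p(F) = (k0/r) exp(-k0 F / r), mean r/k0."""
        r = trap_rigid.apparent_loading_rate
        f = np.linspace(0, 30, 6001)
        p = analytic_force_pdf(ideal_bond, trap_rigid, f)
        expected = (3.5 / r) * np.exp(-3.5 * f / r)
        assert np.max(np.abs(p - expected)) < 1e-4
        assert np.trapezoid(f * p, f) == pytest.approx(r / 3.5, rel=1e-3)

    def test_slip_bond_mode_matches_gumbel_formula(self, trap_rigid):
        """Bell slip bond mode at F_scale ln(r/(k0 F_scale)) when positive."""
        k0, fs = 0.4, 1.2
        r = trap_rigid.apparent_loading_rate
        f = np.arange(0, 15, 0.001)
        p = analytic_force_pdf(BondModel.slip(k0, fs), trap_rigid, f)
        mode = f[np.argmax(p)]
        assert mode == pytest.approx(fs * np.log(r / (k0 * fs)), abs=0.01)

    @pytest.mark.parametrize(
        "bond",
        [BondModel.ideal(3.5), BondModel.slip(0.5, 1.0), BondModel.slip_ideal(0.3, 0.8, 2.0)],
        ids=["ideal", "slip", "slip-ideal"],
    )
    def test_density_normalizes_over_working_range(self, trap_rigid, bond):
        f = np.linspace(0, 20, 8001)
        p = analytic_force_pdf(bond, trap_rigid, f)
        assert np.all(p >= 0)
        assert np.trapezoid(p, f) >= 0.999

    def test_density_matches_quadrature_of_integral_form(self, trap_rigid, slip_bond):
        """Cross-check against independent quadrature of k/r and exp(-H)."""
        f = np.linspace(0, 12, 2401)
        r = trap_rigid.apparent_loading_rate
        kr = slip_bond.rate(f) / r
        h = cumulative_trapezoid(kr, f, initial=0.0)
        assert np.allclose(analytic_force_pdf(slip_bond, trap_rigid, f), kr * np.exp(-h), rtol=1e-4)

    def test_zero_loading_rate_raises_naming_the_field(self, ideal_bond):
        trap = TrapConfig(motor_stiffness=np.inf)
        trap.v_stage = 0.0  # bypass constructor validation to hit the guard
        with pytest.raises(ZeroDivisionError, match="v_stage"):
            analytic_force_pdf(ideal_bond, trap, np.linspace(0, 5, 100))


class TestSampler:
    def test_ideal_bond_sample_mean(self, trap_rigid, ideal_bond):
        r = trap_rigid.apparent_loading_rate
        x = sample_unbinding_forces(ideal_bond, trap_rigid, 100_000, seed=1)
        mu = r / 3.5
        sem = mu / np.sqrt(100_000)  # exponential: sd = mean
        assert abs(x.mean() - mu) < 3 * sem

    def test_single_draw_is_deterministic(self, trap_rigid, slip_bond):
        a = sample_unbinding_forces(slip_bond, trap_rigid, 1, seed=7)
        b = sample_unbinding_forces(slip_bond, trap_rigid, 1, seed=7)
        assert a == b

    @pytest.mark.parametrize(
        "bond",
        [BondModel.ideal(3.5), BondModel.slip(0.5, 1.0), BondModel.slip_ideal(0.3, 0.8, 2.0)],
        ids=["ideal", "slip", "slip-ideal"],
    )
    def test_sampler_agrees_with_analytic_cdf(self, trap_rigid, bond):
        grid = np.arange(0.0, 40.0, 0.002)
        surv = analytic_survival(bond, trap_rigid, grid)
        x = sample_unbinding_forces(bond, trap_rigid, 10_000, seed=2)
        res = kstest(x, lambda v: np.interp(v, grid, 1.0 - surv))
        assert res.pvalue > 0.01

    def test_defective_catch_bond_raises(self, trap_rigid):
        # weak catch bond: survival plateaus above zero, no proper rupture law
        with pytest.raises(RuntimeError, match="f_max"):
            sample_unbinding_forces(BondModel.catch(2.0, 1.0), trap_rigid, 10, seed=0)


class TestPullTrace:
    def test_no_binding_means_pure_noise(self, slip_bond):
        trap = TrapConfig(k_on=0.0, noise_sd=0.05, motor_stiffness=np.inf)
        tr = simulate_pull_trace(trap, slip_bond, 30.0, seed=3)
        assert tr.truth == []
        assert np.abs(tr.force).max() < 0.05 * 6
        assert detect_events(tr) == []

    def test_deterministic_limit_ramps_at_effective_rate(self):
        """noise 0, negligible hazard: bound force is a triangle ramp at r_eff."""
        trap = TrapConfig(noise_sd=0.0, k_on=50.0, motor_stiffness=0.2, seed=0)
        bond = BondModel.ideal(1e-9, f_max=100.0)
        tr = simulate_pull_trace(trap, bond, 13.0, seed=4)
        r_eff = trap.v_stage / (1.0 / trap.k_trap + 1.0 / 0.2)
        slopes = np.diff(tr.force) / tr.dt
        slopes = slopes[np.abs(slopes) > 0.1 * r_eff]
        exact = np.isclose(np.abs(slopes), r_eff, rtol=1e-6)
        # everything except the isolated sweep-turnaround samples ramps at r_eff
        assert exact.mean() > 0.995
        assert np.abs(slopes).max() <= r_eff * (1 + 1e-9)

    def test_trace_reproducible_given_seed(self, trap_rigid, slip_bond):
        a = simulate_pull_trace(trap_rigid, slip_bond, 30.0, seed=5)
        b = simulate_pull_trace(trap_rigid, slip_bond, 30.0, seed=5)
        assert np.array_equal(a.force, b.force)
        assert a.truth == b.truth

    def test_primary_event_forces_match_direct_sampler(self, trap_rigid, slip_bond):
        """End-to-end: detected primary rupture forces vs the direct sampler."""
        trap = TrapConfig(motor_stiffness=np.inf, noise_sd=0.03, k_on=1.0)
        tr = simulate_pull_trace(trap, slip_bond, 600.0, seed=6)
        det = [e.rupture_force for e in detect_events(tr) if e.is_primary and e.rupture_force > 0.5]
        ref = sample_unbinding_forces(slip_bond, trap, 20_000, seed=8)
        ref = ref[ref > 0.5]
        assert len(det) > 200
        assert kstest(det, ref).pvalue > 0.01

    def test_low_sample_rate_rejected(self, slip_bond):
        with pytest.raises(InvalidConfigError, match="sample_rate"):
            simulate_pull_trace(TrapConfig(sample_rate=40.0), slip_bond, 30.0, seed=0)

    def test_duration_must_cover_one_sweep(self, trap_rigid, slip_bond):
        with pytest.raises(ValueError, match="sweep"):
            simulate_pull_trace(trap_rigid, slip_bond, 0.5, seed=0)


class TestMotilityDraws:
    def test_zero_sigma_is_constant(self):
        assert np.all(simulate_velocities(110.0, 0.0, 10, seed=1) == 110.0)
        assert np.all(simulate_stall_forces(4.5, 0.0, 5, seed=1) == 4.5)

    def test_velocity_fit_recovers_mean(self):
        from dynforce import gaussian_velocity_fit

        v = simulate_velocities(110.0, 33.7, 284, seed=9)
        mu, _ = gaussian_velocity_fit(v)
        assert abs(mu - 110.0) < 3 * 33.7 / np.sqrt(284)

    def test_reproducible_and_truncatable(self):
        a = simulate_velocities(5.0, 10.0, 500, seed=3, truncate_at_zero=True)
        b = simulate_velocities(5.0, 10.0, 500, seed=3, truncate_at_zero=True)
        assert np.array_equal(a, b)
        assert np.all(a >= 0)

    @pytest.mark.parametrize("bad", [dict(sigma=-1.0, n=5), dict(sigma=1.0, n=0)])
    def test_invalid_args_raise(self, bad):
        with pytest.raises(ValueError):
            simulate_velocities(100.0, bad["sigma"], bad["n"], seed=0)
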