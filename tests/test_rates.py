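"""Histogram, KDE and the force-to-rate transform."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from dynforce import (
    BondModel,
    ForceSample,
    TrapConfig,
    analytic_force_pdf,
    empirical_rate_oracle,
    kde_pdf,
    normalized_histogram,
    rate_curve,
    sample_unbinding_forces,
)


class TestNormalizedHistogram:
    def test_two_forces_split_two_bins(self):
        h = normalized_histogram(ForceSample([0.5, 1.5]))
        assert h.values[0] == 0.5 and h.values[1] == 0.5
        assert np.all(np.diff(h.bin_edges) == 1.0) and h.bin_edges[0] == 0.0

    def test_single_bin_holds_all_mass(self):
        h = normalized_histogram(ForceSample([2.1, 2.5, 2.9]))
        assert h.values[2] == 1.0 and h.values.sum() == 1.0

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            normalized_histogram(ForceSample(np.empty(0)))

    def test_bin_masses_match_analytic_density(self, trap_rigid, ideal_bond):
        """Histogram bins vs quadrature of the first-passage density, 3 SE."""
        n = 10_000
        x = sample_unbinding_forces(ideal_bond, trap_rigid, n, seed=3)
        h = normalized_histogram(ForceSample(x))
        fgrid = np.linspace(0, h.bin_edges[-1], 20_001)
        p = analytic_force_pdf(ideal_bond, trap_rigid, fgrid)
        for i in range(min(5, h.values.size)):
            lo, hi = h.bin_edges[i], h.bin_edges[i + 1]
            m = (fgrid >= lo) & (fgrid <= hi)
            mass = np.trapezoid(p[m], fgrid[m])
            se = np.sqrt(mass * (1 - mass) / n)
            assert abs(h.values[i] - mass) < 3 * se + 1e-4


class TestKde:
    def test_density_integrates_to_one(self, trap_rigid, slip_bond):
        x = sample_unbinding_forces(slip_bond, trap_rigid, 500, seed=4)
        f, d = kde_pdf(ForceSample(x))
        assert np.all(d >= 0)
        assert np.trapezoid(d, f) == pytest.approx(1.0, abs=1e-3)
        fa, da = kde_pdf(ForceSample(x), adaptive=True)
        assert np.trapezoid(da, fa) == pytest.approx(1.0, abs=1e-3)

    def test_repeated_value_peaks_at_value(self):
        f, d = kde_pdf(ForceSample(np.full(20, 3.0)), bandwidth=0.3)
        assert f[np.argmax(d)] == pytest.approx(3.0, abs=0.05)
        left = np.interp(2.5, f, d)
        right = np.interp(3.5, f, d)
        assert left == pytest.approx(right, rel=1e-3)  # symmetric away from F=0

    def test_exponential_density_recovered(self, trap_rigid, ideal_bond):
        mu = trap_rigid.apparent_loading_rate / 3.5
        x = sample_unbinding_forces(ideal_bond, trap_rigid, 10_000, seed=5)
        f, d = kde_pdf(ForceSample(x))
        true = np.exp(-f / mu) / mu
        h = 0.9 * min(x.std(ddof=1), np.subtract(*np.percentile(x, [75, 25])) / 1.34) * x.size**-0.2
        # the reflection estimator's derivative vanishes at F=0, so within one
        # bandwidth of the boundary it carries an O(h) bias for this density
        away = f >= h
        assert np.max(np.abs(d[away] - true[away])) < 0.05 * true.max()
        assert np.max(np.abs(d - true)) < 0.10 * true.max()

    def test_small_sample_rejected_naming_minimum(self):
        with pytest.raises(ValueError, match="10"):
            kde_pdf(ForceSample(np.linspace(0.5, 2, 5)))

    def test_bad_bandwidth_rejected(self):
        with pytest.raises(ValueError, match="bandwidth"):
            kde_pdf(ForceSample(np.linspace(0.5, 2, 20)), bandwidth=-1.0)


class TestRateCurve:
    def test_ideal_bond_rate_is_flat(self, trap_rigid, ideal_bond):
        x = sample_unbinding_forces(ideal_bond, trap_rigid, 5000, seed=6)
        rc = rate_curve(ForceSample(x), trap_rigid)
        assert rc.f_grid[0] >= 0.5
        assert np.max(np.abs(rc.rate - 3.5)) / 3.5 < 0.15
        assert np.all(rc.n_effective >= 0.05 * 5000 * 0.99)

    def test_rate_scales_linearly_with_loading_rate(self, trap_rigid, ideal_bond):
        x = sample_unbinding_forces(ideal_bond, trap_rigid, 2000, seed=7)
        fast = TrapConfig(v_stage=2 * trap_rigid.v_stage, motor_stiffness=np.inf)
        a = rate_curve(ForceSample(x), trap_rigid, bandwidth=0.25)
        b = rate_curve(ForceSample(x), fast, bandwidth=0.25)
        assert np.allclose(b.rate, 2 * a.rate)

    def test_force_and_bandwidth_rescaling(self, trap_rigid, ideal_bond):
        """Scaling forces and bandwidth by c maps k(F) -> k(F/c)/c at fixed r."""
        c = 2.0
        x = sample_unbinding_forces(ideal_bond, trap_rigid, 3000, seed=8)
        a = rate_curve(ForceSample(x), trap_rigid, bandwidth=0.3, f_min=0.5)
        b = rate_curve(ForceSample(c * x), trap_rigid, bandwidth=c * 0.3, f_min=c * 0.5)
        common = a.f_grid[(a.f_grid * c >= b.f_grid[0]) & (a.f_grid * c <= b.f_grid[-1])]
        interp_b = np.interp(c * common, b.f_grid, b.rate)
        interp_a = np.interp(common, a.f_grid, a.rate)
        assert np.allclose(interp_b, interp_a / c, rtol=0.02)

    def test_curve_invariant_to_sample_order(self, trap_rigid, slip_bond):
        x = sample_unbinding_forces(slip_bond, trap_rigid, 1000, seed=9)
        a = rate_curve(ForceSample(x), trap_rigid)
        b = rate_curve(ForceSample(np.random.default_rng(0).permutation(x)), trap_rigid)
        assert np.allclose(a.rate, b.rate, rtol=1e-9)  # up to summation order

    def test_survival_is_monotone_from_one(self, trap_rigid, slip_bond):
        x = sample_unbinding_forces(slip_bond, trap_rigid, 1000, seed=10)
        f, d = kde_pdf(ForceSample(x), adaptive=True)
        surv = 1 - cumulative_trapezoid(d, f, initial=0.0)
        assert surv[0] == 1.0
        assert np.all(np.diff(surv) <= 1e-12)

    def test_unreachable_floor_raises(self, trap_rigid, slip_bond):
        x = sample_unbinding_forces(slip_bond, trap_rigid, 100, seed=11)
        with pytest.raises(ValueError, match="survival"):
            rate_curve(ForceSample(x), trap_rigid, survival_floor=2.0)


class TestHazardOracle:
    def test_exponential_sample_is_flat(self, trap_rigid, ideal_bond):
        x = sample_unbinding_forces(ideal_bond, trap_rigid, 5000, seed=12)
        f, k = empirical_rate_oracle(ForceSample(x), trap_rigid)
        inner = (f > 0.3) & (k > 0)
        assert np.median(np.abs(k[inner] - 3.5) / 3.5) < 0.15

    def test_agrees_with_kde_transform(self, trap_rigid, slip_bond):
        x = sample_unbinding_forces(slip_bond, trap_rigid, 5000, seed=13)
        samp = ForceSample(x)
        rc = rate_curve(samp, trap_rigid)
        f, k = empirical_rate_oracle(samp, trap_rigid)
        m = (f >= rc.f_grid[0]) & (f <= rc.f_grid[-1])
        rel = np.abs(np.interp(f[m], rc.f_grid, rc.rate) - k[m]) / k[m]
        assert np.median(rel) < 0.15

    def test_minimum_sample_size_enforced(self, trap_rigid):
        with pytest.raises(ValueError, match="50"):
            empirical_rate_oracle(ForceSample(np.linspace(0.5, 3, 49)), trap_rigid)
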