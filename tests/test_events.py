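"""Event detection: constructed traces, simulator ground truth, filters."""

import numpy as np
import pytest

from dynforce import (
    BondModel,
    Trace,
    TrapConfig,
    UnbindEvent,
    detect_events,
    filter_primary,
    simulate_pull_trace,
)

SR = 2000.0


def ramp_trace(f_start: float, f_stop: float, rate: float = 5.6, pad: float = 0.5) -> Trace:
    """Noiseless |force| ramp from f_start to f_stop, instant drop, padding."""
    dt = 1.0 / SR
    n_pad = int(pad * SR)
    ramp = np.arange(f_start, f_stop, rate * dt)
    force = np.concatenate([np.zeros(n_pad) if f_start == 0 else np.full(n_pad, 0.0), ramp, np.zeros(n_pad)])
    if f_start > 0:  # pre-loaded from the first sample: no leading baseline
        force = np.concatenate([ramp, np.zeros(n_pad)])
    t = np.arange(force.size) * dt
    return Trace(t=t, stage=np.zeros_like(t), force=force, meta={})


class TestConstructedTraces:
    def test_clean_ramp_is_one_primary_event(self):
        ev = detect_events(ramp_trace(0.0, 3.0))
        assert len(ev) == 1
        e = ev[0]
        assert e.rupture_force == pytest.approx(3.0, abs=0.01)
        assert e.f_start == 0.0
        assert e.is_primary
        assert e.direction == "backward"

    def test_preloaded_ramp_is_secondary(self):
        ev = detect_events(ramp_trace(1.0, 3.0))
        assert len(ev) == 1
        assert ev[0].f_start == pytest.approx(1.0, abs=0.01)
        assert not ev[0].is_primary

    def test_negative_force_gives_forward_direction(self):
        tr = ramp_trace(0.0, 3.0)
        tr.force = -tr.force
        ev = detect_events(tr)
        assert len(ev) == 1 and ev[0].direction == "forward"

    def test_subthreshold_excursion_ignored(self):
        ev = detect_events(ramp_trace(0.0, 0.25))
        assert ev == []

    def test_offset_invariance(self):
        """A DC offset below half the threshold changes no event times."""
        tr = ramp_trace(0.0, 3.0)
        ev0 = detect_events(tr)
        tr.force = tr.force + 0.1
        ev1 = detect_events(tr)
        assert len(ev0) == len(ev1) == 1
        assert ev1[0].t_rupture == pytest.approx(ev0[0].t_rupture, abs=2 / SR)
        assert ev1[0].rupture_force == pytest.approx(ev0[0].rupture_force, abs=0.11)

    def test_detection_is_idempotent(self):
        tr = ramp_trace(0.0, 3.0)
        assert detect_events(tr) == detect_events(tr)

    def test_empty_trace_gives_empty_list(self):
        tr = Trace(t=np.array([]), stage=np.array([]), force=np.array([]), meta={})
        assert detect_events(tr) == []

    def test_nonuniform_grid_raises(self):
        t = np.array([0.0, 0.001, 0.003, 0.004, 0.02])
        tr = Trace(t=t, stage=np.zeros(5), force=np.zeros(5), meta={})
        with pytest.raises(ValueError, match="uniform"):
            detect_events(tr)


class TestSimulatorGroundTruth:
    def test_ruptures_recovered_from_noisy_traces(self):
        """>= 99% of comfortably-detectable ruptures recovered within 2
        samples, with rupture-force errors within 3 noise SD."""
        trap = TrapConfig(motor_stiffness=np.inf, noise_sd=0.05, k_on=1.0)
        bond = BondModel.slip(0.5, 1.0)
        n_el = n_found = n_good_force = 0
        for s in range(30):
            tr = simulate_pull_trace(trap, bond, 60.0, seed=100 + s)
            ev = detect_events(tr)
            td = np.array([e.t_rupture for e in ev]) if ev else np.array([np.inf])
            for u in tr.truth:
                if u.f_max <= 0.45:
                    continue
                n_el += 1
                lag = np.min(np.abs(td - u.t_rupture))
                if lag <= 2 * tr.dt:
                    n_found += 1
                    e = ev[int(np.argmin(np.abs(td - u.t_rupture)))]
                    err = min(abs(e.rupture_force - u.f_max), abs(e.rupture_force - u.rupture_force))
                    n_good_force += err < 3 * trap.noise_sd
        assert n_el > 500
        assert n_found / n_el >= 0.99
        assert n_good_force / n_el >= 0.99

    def test_noiseless_forces_recovered_exactly(self):
        trap = TrapConfig(motor_stiffness=np.inf, noise_sd=0.0, k_on=0.5)
        tr = simulate_pull_trace(trap, BondModel.slip(0.5, 1.0), 120.0, seed=11)
        ev = detect_events(tr)
        truth = [u for u in tr.truth if u.f_max > 0.3]
        assert len(ev) == len(truth)
        for e, u in zip(ev, truth):
            assert e.rupture_force == u.f_max
            assert e.is_primary == u.is_primary

    def test_rebinds_under_preload_become_secondary_events(self):
        """Fast relaxation + very high rebinding produces pre-loaded events;
        the detected secondary fraction tracks the simulator's bookkeeping."""
        trap = TrapConfig(motor_stiffness=np.inf, noise_sd=0.03, k_on=150.0)
        bond = BondModel.slip(0.05, 1.2)
        tr = simulate_pull_trace(trap, bond, 120.0, seed=13, relax_time=0.0005)
        truth = [u for u in tr.truth if u.f_max > 0.45]
        ev = detect_events(tr)
        frac_truth = np.mean([not u.is_primary for u in truth])
        frac_det = np.mean([not e.is_primary for e in ev])
        assert frac_truth > 0.03  # the scenario does generate secondaries
        assert abs(frac_det - frac_truth) < 0.05


class TestFilterPrimary:
    def _event(self, t0, primary):
        return UnbindEvent(t0, t0 + 0.1, 1.0, 0.0 if primary else 0.5, "backward", primary)

    def test_all_primary_is_identity(self):
        evs = [self._event(i * 1.0, True) for i in range(5)]
        assert filter_primary(evs) == evs

    def test_mixed_input_keeps_flagged_subset_in_order(self):
        flags = [True, False, True, True, False, True]
        evs = [self._event(i * 1.0, p) for i, p in enumerate(flags)]
        out = filter_primary(evs)
        assert [e.t_bind for e in out] == [i * 1.0 for i, p in enumerate(flags) if p]

    def test_simulator_truth_fraction_is_exact(self):
        """Events carrying the simulator's own flags filter to exactly the
        logged primary fraction."""
        trap = TrapConfig(motor_stiffness=np.inf, noise_sd=0.02, k_on=100.0)
        tr = simulate_pull_trace(trap, BondModel.slip(0.05, 1.2), 60.0, seed=21, relax_time=0.0005)
        evs = [
            UnbindEvent(u.t_bind, u.t_rupture, max(u.f_max, 0.31), u.f_start, u.direction, u.is_primary)
            for u in tr.truth
        ]
        assert len(filter_primary(evs)) == sum(u.is_primary for u in tr.truth)

    def test_empty_input(self):
        assert filter_primary([]) == []
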