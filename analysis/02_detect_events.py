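#!/usr/bin/env python
"""Validate event detection against the simulator's ground truth.

Simulates noisy pulling traces with a slip bond, runs the detector, filters
to primary events and checks (a) what fraction of true ruptures above the
detection floor is recovered and (b) that the recovered primary rupture-force
distribution matches the direct first-passage sampler (two-sample KS test).

Writes results/event_detection_validation.json and the pooled detected
events to results/sim/detected_events.csv.
"""

import argparse
import json
from pathlib import Path

import numpy as np
from scipy.stats import ks_2samp

from dynforce import BondModel, TrapConfig, detect_events, filter_primary, sample_unbinding_forces, simulate_pull_trace
from dynforce import io as dfio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--traces", type=int, default=20)
    ap.add_argument("--duration", type=float, default=60.0)
    args = ap.parse_args()

    trap = TrapConfig(motor_stiffness=np.inf, noise_sd=0.05, k_on=1.0)
    bond = BondModel.slip(0.5, 1.0)
    seeds = np.random.SeedSequence(args.seed).generate_state(args.traces + 1) % (2**31)

    all_events, n_true, n_found = [], 0, 0
    for s in seeds[:-1]:
        tr = simulate_pull_trace(trap, bond, args.duration, seed=int(s))
        ev = detect_events(tr)
        all_events.extend(ev)
        td = np.array([e.t_rupture for e in ev]) if ev else np.array([np.inf])
        for u in tr.truth:
            if u.f_max > 0.45:
                n_true += 1
                n_found += bool(np.min(np.abs(td - u.t_rupture)) <= 2 * tr.dt)

    primary = filter_primary(all_events)
    det_forces = np.array([e.rupture_force for e in primary if e.rupture_force > 0.5])
    ref = sample_unbinding_forces(bond, trap, 20_000, seed=int(seeds[-1]))
    ks = ks_2samp(det_forces, ref[ref > 0.5])

    Path("results/sim").mkdir(parents=True, exist_ok=True)
    dfio.write_events(sorted(all_events, key=lambda e: e.t_bind), "results/sim/detected_events.csv")
    report = {
        "n_traces": args.traces,
        "trace_duration_s": args.duration,
        "true_ruptures_above_floor": n_true,
        "recovered_fraction": round(n_found / n_true, 4),
        "n_detected": len(all_events),
        "n_primary": len(primary),
        "ks_vs_direct_sampler_p": round(float(ks.pvalue), 4),
    }
    Path("results/event_detection_validation.json").write_text(json.dumps(report, indent=2) + "\n")
    print(json.dumps(report, indent=2))
    print("detector recovers the injected ruptures and the primary-event force "
          "distribution is statistically indistinguishable from the direct sampler"
          if ks.pvalue > 0.01 else "WARNING: detected distribution deviates from sampler")


if __name__ == "__main__":
    main()
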