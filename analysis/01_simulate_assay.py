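#!/usr/bin/env python
"""Simulate the constant-pulling assay for the three emulated binding states.

Generates per-direction primary unbinding-force samples for conditions whose
mean forces sit at the crosslinked-reference values (weak 0.7 pN,
intermediate 1.6 pN, strong-backward 2.7 pN), matching the event counts of
the real experiments (~300 per direction), plus one demonstration trace.

Writes force lists to results/sim/ and the demo trace to scratch/sim/.
"""

import argparse
from pathlib import Path

import numpy as np

from dynforce import BondModel, TrapConfig, sample_unbinding_forces, simulate_pull_trace
from dynforce import io as dfio
from dynforce.reference import FIG3A_TRAP

CONDITIONS = {
    # condition -> (forward mean pN, backward mean pN)
    "weak_binding": (0.7, 0.7),  # beta-registry-like, e.g. hydrolysis-dead AAA4
    "intermediate_binding": (1.6, 1.6),  # gamma-registry-like, ATP-binding-dead AAA4
    "strong_backward": (1.6, 2.7),  # wild-type-like apo: alpha under backward load
}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=300, help="events per direction")
    args = ap.parse_args()

    trap = TrapConfig(k_trap=FIG3A_TRAP["k_trap"], v_stage=FIG3A_TRAP["v_stage"], motor_stiffness=np.inf)
    outdir = Path("results/sim")
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = iter(np.random.SeedSequence(args.seed).generate_state(100) % (2**31))

    print(f"apparent loading rate: {trap.apparent_loading_rate:.3g} pN/s")
    for name, (mean_fwd, mean_bwd) in CONDITIONS.items():
        for direction, mean in (("forward", mean_fwd), ("backward", mean_bwd)):
            bond = BondModel.ideal(trap.apparent_loading_rate / mean)
            forces = sample_unbinding_forces(bond, trap, args.n, seed=int(next(seeds)))
            path = outdir / f"{name}_{direction}.csv"
            dfio.write_forces(forces, path)
            print(f"{name}/{direction}: n={args.n}, mean={forces.mean():.2f} pN -> {path}")

    # demonstration trace: intermediate-strength bond, 60 s of sweeping
    bond = BondModel.ideal(trap.apparent_loading_rate / 1.6)
    trace = simulate_pull_trace(trap, bond, 60.0, seed=int(next(seeds)))
    scratch = Path("scratch/sim")
    scratch.mkdir(parents=True, exist_ok=True)
    dfio.write_trace(trace, scratch / "demo_trace.tsv")
    print(f"demo trace: {len(trace.truth)} binding events -> {scratch / 'demo_trace.tsv'}")


if __name__ == "__main__":
    main()
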