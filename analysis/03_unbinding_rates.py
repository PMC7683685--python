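#!/usr/bin/env python
"""Unbinding-force histograms and force-dependent unbinding rates.

For each simulated condition/direction from 01_simulate_assay.py: 1-pN
normalized histogram, bootstrap CI of the mean unbinding force, and the
compliance-corrected rate curve k(F) = r(F) p(F) / S(F) with pointwise
bootstrap bands.  Rates are reported above 0.5 pN down to the 5% survival
floor.

Writes results/rates/<condition>_<direction>.csv, a summary table to
results/unbinding_summary.csv, and quick-look figures to scratch/figures/.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from dynforce import ForceSample, TrapConfig, boot_ci_mean, boot_rate_ci, normalized_histogram
from dynforce import io as dfio
from dynforce.reference import FIG3A_TRAP


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--b-rate", type=int, default=200)
    args = ap.parse_args()

    trap = TrapConfig(k_trap=FIG3A_TRAP["k_trap"], v_stage=FIG3A_TRAP["v_stage"], motor_stiffness=np.inf)
    indir = Path("results/sim")
    files = sorted(indir.glob("*_forward.csv")) + sorted(indir.glob("*_backward.csv"))
    if not files:
        raise SystemExit("no simulated force files found; run analysis/01_simulate_assay.py first")

    Path("results/rates").mkdir(parents=True, exist_ok=True)
    figdir = Path("scratch/figures")
    figdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, path in enumerate(files):
        condition, direction = path.stem.rsplit("_", 1)
        forces = dfio.read_forces(path)
        samp = ForceSample(forces, direction=direction, condition=condition)
        hist = normalized_histogram(samp)
        ci = boot_ci_mean(forces, B=4000, seed=args.seed + i)
        curve = boot_rate_ci(samp, trap, B=args.b_rate, seed=args.seed + 100 + i)
        dfio.write_rates([curve], Path("results/rates") / f"{condition}_{direction}.csv")
        rows.append(
            {
                "condition": condition,
                "direction": direction,
                "n": samp.n,
                "mean_pN": round(ci.mean, 3),
                "ci_lo_pN": round(ci.lo, 3),
                "ci_hi_pN": round(ci.hi, 3),
                "rate_grid_min_pN": round(curve.f_grid[0], 2),
                "rate_grid_max_pN": round(curve.f_grid[-1], 2),
            }
        )
        print(f"{condition}/{direction}: mean {ci.mean:.2f} pN [{ci.lo:.2f}, {ci.hi:.2f}], "
              f"rates on [{curve.f_grid[0]:.2f}, {curve.f_grid[-1]:.2f}] pN")

        fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(5, 6), sharex=True)
        ax1.bar(hist.bin_edges[:-1], hist.values, width=1.0, align="edge", alpha=0.6)
        ax1.set_ylabel("probability / bin")
        ax1.set_title(f"{condition} {direction} (n={samp.n})")
        ax2.plot(curve.f_grid, curve.rate, lw=1.5)
        ax2.fill_between(curve.f_grid, curve.ci_lo, curve.ci_hi, alpha=0.3)
        ax2.set_yscale("log")
        ax2.set_xlabel("force (pN)")
        ax2.set_ylabel("unbinding rate (1/s)")
        fig.tight_layout()
        fig.savefig(figdir / f"{condition}_{direction}.png", dpi=110)
        plt.close(fig)

    pd.DataFrame(rows).to_csv("results/unbinding_summary.csv", index=False)
    print("summary -> results/unbinding_summary.csv; figures -> scratch/figures/")


if __name__ == "__main__":
    main()
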