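#!/usr/bin/env python
"""Assign stalk registries to the simulated conditions.

Runs the per-direction registry classifier on the force samples from
01_simulate_assay.py against the crosslinked-reference profiles (alpha 2.7 pN
backward; gamma 1.6 pN; beta 0.7 pN) and writes the calls in the
"backward/forward" reporting format.

Writes results/registry_calls.json.
"""

import argparse
import json
from pathlib import Path

from dynforce import ForceSample, classify_registry
from dynforce import io as dfio


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    indir = Path("results/sim")
    conditions = sorted({p.stem.rsplit("_", 1)[0] for p in indir.glob("*_forward.csv")})
    if not conditions:
        raise SystemExit("no simulated force files found; run analysis/01_simulate_assay.py first")

    calls = {}
    for i, cond in enumerate(conditions):
        fwd = ForceSample(dfio.read_forces(indir / f"{cond}_forward.csv"), "forward", cond)
        bwd = ForceSample(dfio.read_forces(indir / f"{cond}_backward.csv"), "backward", cond)
        call = classify_registry(fwd, bwd, seed=args.seed + i)
        calls[cond] = {
            "summary_backward/forward": call.summary,
            "backward": call.backward_label,
            "forward": call.forward_label,
            "ci_pN": {d: [round(v, 3) for v in t] for d, t in call.ci.items()},
        }
        print(f"{cond:24s} -> {call.summary}")

    Path("results/registry_calls.json").write_text(
        json.dumps(calls, indent=2, ensure_ascii=False) + "\n"
    )
    print("calls -> results/registry_calls.json")


if __name__ == "__main__":
    main()
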