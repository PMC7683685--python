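"""Plain-text file formats and configuration parsing.

Everything is delimited text or JSON: traces as TSV with ``#`` metadata
lines, events and rates as CSV, reports as JSON carrying a hash of the
configuration that produced them.  Values round-trip to 6 significant
digits.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bonds import BondModel, BondSegment
from .events import UnbindEvent
from .rates import RateCurve
from .simulate import Trace
from .trap import TrapConfig

__all__ = [
    "write_trace",
    "read_trace",
    "write_events",
    "read_events",
    "write_forces",
    "read_forces",
    "write_rates",
    "write_report",
    "config_hash",
    "trap_from_dict",
    "bond_from_dict",
    "load_config",
]

EVENT_COLUMNS = ["t_bind_s", "t_rupture_s", "rupture_force_pN", "F_start_pN", "direction", "is_primary"]
RATE_COLUMNS = ["force_pN", "rate_per_s", "ci_lo", "ci_hi", "direction", "condition"]


def write_trace(trace: Trace, path) -> None:
    """TSV with ``#`` key=value metadata lines and a header row."""
    path = Path(path)
    with path.open("w") as fh:
        for section, val in trace.meta.items():
            if isinstance(val, dict):
                for k, v in val.items():
                    fh.write(f"# {section}.{k}={v}\n")
            else:
                fh.write(f"# {section}={val}\n")
        fh.write("time_s\tstage_nm\tforce_pN\n")
        for t, s, f in zip(trace.t, trace.stage, trace.force):
            fh.write(f"{t:.6g}\t{s:.6g}\t{f:.6g}\n")


def read_trace(path) -> Trace:
    path = Path(path)
    meta: dict = {}
    with path.open() as fh:
        rows = fh.readlines()
    data_start = 0
    for i, line in enumerate(rows):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            section, _, name = key.strip().rpartition(".")
            target = meta.setdefault(section, {}) if section else meta
            target[name] = _parse_scalar(val.strip())
        else:
            data_start = i
            break
    header = rows[data_start].strip().split("\t")
    required = ["time_s", "stage_nm", "force_pN"]
    missing = [c for c in required if c not in header]
    if missing:
        raise ValueError(f"trace file {path} is missing required columns: {', '.join(missing)}")
    body = np.loadtxt(rows[data_start + 1 :], delimiter="\t")
    body = np.atleast_2d(body)
    cols = {c: body[:, header.index(c)] for c in required}
    return Trace(t=cols["time_s"], stage=cols["stage_nm"], force=cols["force_pN"], meta=meta)


def write_events(events: list[UnbindEvent], path) -> None:
    df = pd.DataFrame(
        [
            {
                "t_bind_s": e.t_bind,
                "t_rupture_s": e.t_rupture,
                "rupture_force_pN": e.rupture_force,
                "F_start_pN": e.f_start,
                "direction": e.direction,
                "is_primary": e.is_primary,
            }
            for e in events
        ],
        columns=EVENT_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.6g")


def read_events(path) -> list[UnbindEvent]:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path} is missing required columns: {', '.join(missing)}")
    events = []
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        if row["direction"] not in ("forward", "backward"):
            raise ValueError(f"{path} line {line_no}: unknown direction {row['direction']!r}")
        try:
            events.append(
                UnbindEvent(
                    t_bind=float(row["t_bind_s"]),
                    t_rupture=float(row["t_rupture_s"]),
                    rupture_force=float(row["rupture_force_pN"]),
                    f_start=float(row["F_start_pN"]),
                    direction=str(row["direction"]),
                    is_primary=bool(row["is_primary"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path} line {line_no}: {exc}") from exc
    return events


def write_forces(forces, path) -> None:
    np.savetxt(path, np.asarray(forces, dtype=float), fmt="%.6g", header="force_pN", comments="")


def read_forces(path) -> np.ndarray:
    """One force magnitude per line (optional ``force_pN`` header)."""
    path = Path(path)
    with path.open() as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    if lines and not _is_number(lines[0].split(",")[0]):
        lines = lines[1:]
    vals = []
    for i, ln in enumerate(lines, start=1):
        tok = ln.split(",")[0]
        if not _is_number(tok):
            raise ValueError(f"{path} line {i}: not a number: {tok!r}")
        vals.append(float(tok))
    arr = np.asarray(vals, dtype=float)
    if np.any(arr <= 0):
        bad = int(np.argmax(arr <= 0)) + 1
        raise ValueError(f"{path} line {bad}: rupture forces must be positive magnitudes")
    return arr


def write_rates(curves: list[RateCurve], path) -> None:
    frames = []
    for c in curves:
        frames.append(
            pd.DataFrame(
                {
                    "force_pN": c.f_grid,
                    "rate_per_s": c.rate,
                    "ci_lo": c.ci_lo if c.ci_lo is not None else np.nan,
                    "ci_hi": c.ci_hi if c.ci_hi is not None else np.nan,
                    "direction": c.meta.get("direction", ""),
                    "condition": c.meta.get("condition", ""),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_report(report: dict, path, config: dict | None = None) -> None:
    out = dict(report)
    if config is not None:
        out["config_hash"] = config_hash(config)
    Path(path).write_text(json.dumps(out, indent=2, sort_keys=True, default=_json_default) + "\n")


# -- configuration -----------------------------------------------------------


def trap_from_dict(d: dict) -> TrapConfig:
    known = {k: d[k] for k in (
        "k_trap", "v_stage", "sweep_amplitude", "motor_stiffness", "k_on", "sample_rate", "noise_sd", "seed"
    ) if k in d}
    if isinstance(known.get("motor_stiffness"), str):
        known["motor_stiffness"] = float(known["motor_stiffness"])
    return TrapConfig(**known)


def bond_from_dict(d: dict) -> BondModel:
    if "segments" in d:
        segs = [
            BondSegment(s["f_lo"], s["f_hi"], s["k0"], float(s.get("f_scale", "inf")))
            for s in d["segments"]
        ]
        return BondModel(segs, label=d.get("label", ""), continuous=d.get("continuous", True))
    kind = d.get("type", "slip")
    kw = {k: v for k, v in d.items() if k not in ("type", "label")}
    factory = {
        "ideal": BondModel.ideal,
        "slip": BondModel.slip,
        "catch": BondModel.catch,
        "slip-ideal": BondModel.slip_ideal,
        "slip-ideal-slip": BondModel.slip_ideal_slip,
    }.get(kind)
    if factory is None:
        raise ValueError(f"unknown bond type {kind!r}")
    return factory(**kw)


def load_config(path) -> dict:
    cfg = json.loads(Path(path).read_text())
    if "trap" in cfg:
        cfg["trap_config"] = trap_from_dict(cfg["trap"])
    if "bond" in cfg:
        cfg["bond_model"] = bond_from_dict(cfg["bond"])
    return cfg


def _parse_scalar(s: str):
    for cast in (int, float):
        try:
            return cast(s)
        except ValueError:
            continue
    if s in ("True", "False"):
        return s == "True"
    return s


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
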