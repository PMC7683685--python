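"""Stochastic simulator of the constant-pulling unbinding assay.

The assay: a bead carrying a single motor domain is held in a harmonic trap
while the stage sweeps back and forth parallel to a microtubule at constant
speed.  When the motor binds, force on the bond ramps at the effective
(compliance-corrected) loading rate with a sign set by the sweep phase, and
rupture is a first-passage event with hazard k(|F|) given by a
:class:`~dynforce.bonds.BondModel`.

Under a constant loading rate r the rupture-force density has the closed
first-passage form

    p(F) = k(F)/r(F) * exp(-integral_0^F k(f)/r(f) df),

which serves both as the direct sampler (inverse-CDF on the survival) and as
the analytic oracle for everything downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.integrate import cumulative_trapezoid
from scipy.stats import truncnorm

from .bonds import BondModel
from .trap import InvalidConfigError, TrapConfig, effective_loading_rate

__all__ = [
    "Trace",
    "TrueEvent",
    "analytic_force_pdf",
    "analytic_survival",
    "sample_unbinding_forces",
    "simulate_pull_trace",
    "simulate_velocities",
    "simulate_stall_forces",
]

_DENSE_DF = 0.002  # pN; internal quadrature grid spacing


@dataclass(frozen=True)
class TrueEvent:
    """Ground-truth binding/rupture episode logged by the simulator."""

    t_bind: float
    t_rupture: float
    rupture_force: float  # pN, magnitude at the rupture sample
    f_max: float  # pN, running maximum of |F| over the episode
    f_start: float  # pN, magnitude of pre-load at binding
    direction: str  # "backward" (+) or "forward" (-)
    is_primary: bool


@dataclass
class Trace:
    """Uniformly sampled stage-position / force time series."""

    t: np.ndarray  # s
    stage: np.ndarray  # nm
    force: np.ndarray  # pN, signed (+ = backward load)
    meta: dict = field(default_factory=dict)
    truth: list[TrueEvent] | None = None

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


def _hazard_over_rate(bond: BondModel, trap: TrapConfig, f_max: float):
    """Dense grid of F, k(F)/r(F) and the cumulative hazard H(F)."""
    f = np.arange(0.0, f_max + _DENSE_DF, _DENSE_DF)
    r = np.asarray(effective_loading_rate(f, trap), dtype=float)
    r = np.broadcast_to(r, f.shape)
    if np.any(r <= 0):
        raise ZeroDivisionError(
            "effective loading rate is zero; check TrapConfig.v_stage and TrapConfig.motor_stiffness"
        )
    kr = bond.rate(f) / r
    H = cumulative_trapezoid(kr, f, initial=0.0)
    return f, kr, H


def analytic_force_pdf(bond: BondModel, trap: TrapConfig, f_grid) -> np.ndarray:
    """First-passage rupture-force density p(F) on ``f_grid``, 1/pN.

    ``p(F) = k(F)/r(F) * exp(-H(F))`` with ``H`` the cumulative hazard in
    force.  Non-negative; integrates to 1 as the grid upper end grows.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    f, kr, H = _hazard_over_rate(bond, trap, float(np.max(f_grid)))
    dens = kr * np.exp(-H)
    return np.interp(f_grid, f, dens)


def analytic_survival(bond: BondModel, trap: TrapConfig, f_grid) -> np.ndarray:
    """Survival S(F) = exp(-H(F)) of the bond against the force ramp."""
    f_grid = np.asarray(f_grid, dtype=float)
    f, _, H = _hazard_over_rate(bond, trap, float(np.max(f_grid)))
    return np.interp(f_grid, f, np.exp(-H))


def sample_unbinding_forces(
    bond: BondModel,
    trap: TrapConfig,
    n: int,
    seed: int | None = None,
    f_max: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` i.i.d. rupture forces by inverse-CDF on the survival.

    This is the simulator-side oracle: it samples exactly from
    :func:`analytic_force_pdf` without time-stepping a trace.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if f_max is None:
        f_max = max(bond.f_max, 10.0)
        while True:
            f, _, H = _hazard_over_rate(bond, trap, f_max)
            if np.exp(-H[-1]) < 1e-9 or f_max >= 200.0:
                break
            f_max *= 2.0
        if np.exp(-H[-1]) > 1e-6:
            raise RuntimeError(
                "survival does not vanish below 200 pN for this bond; pass f_max explicitly"
            )
    else:
        f, _, H = _hazard_over_rate(bond, trap, f_max)
    u = rng.uniform(size=n)
    return np.interp(-np.log(u), H, f)  # clips to f_max in the negligible far tail


def simulate_pull_trace(
    trap: TrapConfig,
    bond: BondModel,
    duration: float,
    seed: int | None = None,
    relax_time: float = 0.0,
) -> Trace:
    """Simulate one constant-pulling trace of ``duration`` seconds.

    The stage follows a triangle wave of configured amplitude and speed.
    While unbound the measured force is zero-mean noise; binding initiates as
    a Poisson event at ``trap.k_on``; while bound, |F| ramps at the effective
    loading rate with the sign of the current sweep direction and ruptures
    with per-step survival ``exp(-k(|F|) dt)``.  After rupture the force
    relaxes to baseline — instantly by default, or exponentially with time
    constant ``relax_time`` (s), in which case rebinding during the decay
    produces pre-loaded (secondary, F_start > 0) events.

    Ground-truth episodes are logged on ``Trace.truth``.
    """
    if callable(trap.motor_stiffness):
        raise InvalidConfigError("trace simulation requires a scalar motor_stiffness")
    app = trap.apparent_loading_rate
    if trap.sample_rate < 10.0 * app:
        raise InvalidConfigError(
            f"sample_rate {trap.sample_rate} Hz resolves fewer than 10 samples per pN "
            f"at the apparent loading rate {app:.3g} pN/s"
        )
    period = 4.0 * trap.sweep_amplitude / trap.v_stage
    if duration < period:
        raise ValueError(f"duration {duration} s is shorter than one sweep period ({period:.3g} s)")

    rng = np.random.default_rng(trap.seed if seed is None else seed)
    dt = 1.0 / trap.sample_rate
    n = int(round(duration * trap.sample_rate))
    t = np.arange(n) * dt
    stage = trap.sweep_amplitude * signal.sawtooth(2.0 * np.pi * t / period, width=0.5)
    k_series = effective_loading_rate(0.0, trap) / trap.v_stage  # pN/nm seen by the bond

    force = np.zeros(n)
    events: list[TrueEvent] = []
    tau = float(relax_time)
    # state of the post-rupture relaxation
    f_decay = 0.0  # signed force at index i0_decay
    i0_decay = 0

    p_bind = -np.expm1(-trap.k_on * dt)
    i = 0
    while i < n:
        ib = n if p_bind == 0.0 else i + int(rng.geometric(p_bind))
        # unbound stretch [i, ib): relaxation tail (or zero)
        if tau > 0.0 and f_decay != 0.0:
            j = np.arange(i, min(ib, n))
            force[j] = f_decay * np.exp(-(j - i0_decay) * dt / tau)
        if ib >= n:
            break
        f_start = force[ib - 1] * np.exp(-dt / tau) if (tau > 0.0 and f_decay != 0.0) else 0.0
        if abs(f_start) < 1e-3:
            f_start = 0.0
        # bound segment: deterministic ramp from the binding point, walked in
        # chunks so long traces stay O(n) overall
        target = -np.log(rng.uniform())
        chunk = max(1024, int(round(0.5 * period * trap.sample_rate)))
        h_acc, start, ir, f_rupt, f_peak = 0.0, ib, -1, 0.0, abs(f_start)
        while start < n:
            end = min(n, start + chunk)
            seg = f_start + k_series * (stage[start:end] - stage[ib])
            h = h_acc + np.cumsum(bond.rate(np.abs(seg)) * dt)
            j = int(np.searchsorted(h, target))
            if j < seg.size:
                force[start : start + j + 1] = seg[: j + 1]
                f_peak = max(f_peak, float(np.max(np.abs(seg[: j + 1]))))
                ir, f_rupt = start + j, float(seg[j])
                break
            force[start:end] = seg
            f_peak = max(f_peak, float(np.max(np.abs(seg))))
            h_acc = float(h[-1])
            start = end
        if ir < 0:  # still bound when the trace ends
            break
        events.append(
            TrueEvent(
                t_bind=t[ib],
                t_rupture=t[ir],
                rupture_force=abs(f_rupt),
                f_max=f_peak,
                f_start=abs(f_start),
                direction="backward" if f_rupt >= 0 else "forward",
                is_primary=abs(f_start) < 0.3,
            )
        )
        f_decay, i0_decay = (f_rupt, ir + 1) if tau > 0.0 else (0.0, ir + 1)
        if tau > 0.0:
            f_decay = f_rupt * np.exp(-dt / tau)  # value at the first sample after rupture
        i = ir + 1

    if trap.noise_sd > 0:
        force = force + rng.normal(0.0, trap.noise_sd, size=n)
    meta = {"trap": trap.to_dict(), "bond": bond.label, "duration_s": duration, "relax_time_s": tau}
    return Trace(t=t, stage=stage, force=force, meta=meta, truth=events)


def simulate_velocities(
    mu: float,
    sigma: float,
    n: int,
    seed: int | None = None,
    truncate_at_zero: bool = False,
) -> np.ndarray:
    """Gaussian single-molecule velocity draws, nm/s (optionally truncated at 0)."""
    _check_gauss(sigma, n)
    rng = np.random.default_rng(seed)
    if sigma == 0:
        return np.full(n, float(mu))
    if truncate_at_zero:
        a = (0.0 - mu) / sigma
        return truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, size=n, random_state=rng)
    return rng.normal(mu, sigma, size=n)


def simulate_stall_forces(mu: float, sigma: float, n: int, seed: int | None = None) -> np.ndarray:
    """Gaussian stall-force draws, pN."""
    _check_gauss(sigma, n)
    rng = np.random.default_rng(seed)
    if sigma == 0:
        return np.full(n, float(mu))
    return rng.normal(mu, sigma, size=n)


def _check_gauss(sigma: float, n: int) -> None:
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n < 1:
        raise ValueError("n must be >= 1")
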