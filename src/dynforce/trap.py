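"""Optical-trap assay configuration and the compliance-corrected loading rate.

Sign convention used throughout the package: positive force is backward
(hindering) load toward the microtubule plus end, negative force is forward
(assisting) load.  Analyses operate on force magnitudes per direction.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from typing import Callable, Union

import numpy as np

__all__ = ["TrapConfig", "InvalidConfigError", "effective_loading_rate"]


class InvalidConfigError(ValueError):
    """Raised when a trap/simulation configuration is physically invalid."""


Stiffness = Union[float, Callable[[np.ndarray], np.ndarray]]


@dataclass
class TrapConfig:
    """Constant-pulling assay configuration.

    Parameters
    ----------
    k_trap
        Trap stiffness, pN/nm.  The study's assay used 0.03-0.06 pN/nm.
    v_stage
        Stage sweep speed, nm/s.  The apparent loading rate is
        ``k_trap * v_stage`` (5.6 pN/s at 0.036 pN/nm and 156 nm/s).
    sweep_amplitude
        Half peak-to-peak amplitude of the triangular stage sweep, nm.
    motor_stiffness
        Stiffness of the motor + bead linkage treated as a linear spring in
        series with the trap, pN/nm.  ``inf`` means a rigid linkage, in which
        case the true loading rate equals the apparent rate.  May also be a
        callable k_m(F) for a force-dependent linkage.
    k_on
        Microtubule binding rate of the motor while unbound, 1/s.
    sample_rate
        Acquisition rate, Hz.
    noise_sd
        White Gaussian measurement noise on the force channel, pN.
    seed
        Base seed for stochastic simulation.
    """

    k_trap: float = 0.036
    v_stage: float = 156.0
    sweep_amplitude: float = 250.0
    motor_stiffness: Stiffness = 0.2
    k_on: float = 1.0
    sample_rate: float = 2000.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_trap <= 0:
            raise InvalidConfigError(f"k_trap must be positive, got {self.k_trap}")
        if self.v_stage <= 0:
            raise InvalidConfigError(f"v_stage must be positive, got {self.v_stage}")
        if self.sweep_amplitude <= 0:
            raise InvalidConfigError("sweep_amplitude must be positive")
        if not callable(self.motor_stiffness) and self.motor_stiffness <= 0:
            raise InvalidConfigError(f"motor_stiffness must be positive, got {self.motor_stiffness}")
        if self.sample_rate <= 0:
            raise InvalidConfigError("sample_rate must be positive")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be non-negative")
        if self.k_on < 0:
            raise InvalidConfigError("k_on must be non-negative")

    @property
    def apparent_loading_rate(self) -> float:
        """k_trap * v_stage, pN/s — the loading rate for a rigid linkage."""
        return self.k_trap * self.v_stage

    def to_dict(self) -> dict:
        d = asdict(self)
        if callable(d["motor_stiffness"]):
            d["motor_stiffness"] = "callable"
        return d


def effective_loading_rate(force, trap: TrapConfig):
    """True (compliance-corrected) loading rate r(F) in pN/s.

    The trap and the motor/bead linkage act as springs in series, so the
    stiffness seen by the bond is ``k_series = (1/k_trap + 1/k_motor)^-1``
    and ``r(F) = v_stage * k_series``.  For a linear motor spring the result
    is force-independent; it is always bounded by the apparent loading rate,
    with equality only for a rigid (infinite-stiffness) linkage.

    Parameters
    ----------
    force
        Force magnitude(s), pN; only used when ``motor_stiffness`` is a
        callable k_m(F).
    trap
        Assay configuration.
    """
    f = np.asarray(force, dtype=float)
    if callable(trap.motor_stiffness):
        k_m = np.asarray(trap.motor_stiffness(f), dtype=float)
        if np.any(k_m <= 0):
            raise InvalidConfigError("motor_stiffness(F) must be positive everywhere")
    else:
        k_m = trap.motor_stiffness
    with np.errstate(divide="ignore"):
        k_series = 1.0 / (1.0 / trap.k_trap + 1.0 / k_m)
    r = trap.v_stage * k_series
    r = np.broadcast_to(np.asarray(r, dtype=float), f.shape) if f.ndim else r
    return np.asarray(r, dtype=float) if f.ndim else float(r)
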