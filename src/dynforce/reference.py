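"""Published summary values for the constructs this package models.

These printed means define the study conditions that the synthetic-data
generator emulates (velocities and stall forces of wild-type and AAA+-mutant
dynein, and the assay's trap settings).  Velocity entries are
``(mean nm/s, SEM nm/s, N)``; the population SD used for simulation is
``SEM * sqrt(N)``.  Stall entries are ``(mean pN, N)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "VELOCITY_NM_S",
    "STALL_FORCE_PN",
    "FIG3A_TRAP",
    "velocity_sigma",
    "velocity_ratio_pct",
    "stall_reduction_pct",
]

# single-molecule velocities (motility assay, 1 mM ATP)
VELOCITY_NM_S: dict[str, tuple[float, float, int]] = {
    "WT": (110.0, 2.0, 284),
    "AAA3_KA": (11.6, 0.5, 243),
    "AAA3_EQ": (4.8, 0.3, 295),
    "AAA4_EQ": (89.0, 3.0, 307),
}

# stall forces of the full-length homodimeric constructs
STALL_FORCE_PN: dict[str, tuple[float, int]] = {
    "WT": (4.5, 189),
    "AAA3_KA": (2.2, 119),
    "AAA3_EQ": (1.8, 130),
}

# unbinding-assay trap settings (apparent loading rate 5.6 pN/s)
FIG3A_TRAP: dict[str, float] = {"k_trap": 0.036, "v_stage": 156.0}


def velocity_sigma(construct: str) -> float:
    """Population SD implied by the printed mean +- SEM at sample size N."""
    mean, sem, n = VELOCITY_NM_S[construct]
    return sem * float(np.sqrt(n))


def velocity_ratio_pct(construct: str = "AAA4_EQ", reference: str = "WT") -> float:
    """Velocity of ``construct`` as a percentage of ``reference``."""
    return 100.0 * VELOCITY_NM_S[construct][0] / VELOCITY_NM_S[reference][0]


def stall_reduction_pct(construct: str = "AAA3_EQ", reference: str = "WT") -> float:
    """Stall-force reduction of ``construct`` relative to ``reference``, percent."""
    return 100.0 * (1.0 - STALL_FORCE_PN[construct][0] / STALL_FORCE_PN[reference][0])
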