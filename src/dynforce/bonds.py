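"""Piecewise-Bell models of the force-dependent unbinding rate k(F).

A bond is described by contiguous force segments ``[F_lo, F_hi)``; within a
segment the unbinding rate follows Bell's law

    k(F) = k0_eff * exp((F - F_lo) / F_scale),

so ``F_scale > 0`` gives a slip segment (rate grows with load), ``F_scale =
inf`` an ideal segment (rate independent of load) and ``F_scale < 0`` a catch
segment (rate falls with load).  With the ``continuous`` flag the effective
prefactor of each segment after the first is pinned to the rate at the end of
the previous segment, so k is continuous on the whole covered range.

Forces are magnitudes in pN, rates in 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BondSegment", "BondModel"]


@dataclass(frozen=True)
class BondSegment:
    """One Bell segment of a piecewise bond model."""

    f_lo: float
    f_hi: float
    k0: float
    f_scale: float  # pN; np.inf => force-independent (ideal), < 0 => catch

    def __post_init__(self) -> None:
        if not (self.f_hi > self.f_lo >= 0.0):
            raise ValueError(f"segment bounds must satisfy 0 <= f_lo < f_hi, got [{self.f_lo}, {self.f_hi})")
        if self.k0 < 0:
            raise ValueError("segment k0 must be non-negative")
        if self.f_scale == 0:
            raise ValueError("segment f_scale must be non-zero (use inf for an ideal segment)")


@dataclass
class BondModel:
    """Piecewise Bell parameterization of the unbinding rate k(F).

    Parameters
    ----------
    segments
        Ordered, contiguous segments covering ``[0, F_max)``.
    label
        Free-text phenotype label ("slip", "ideal", "slip-ideal", ...).
    continuous
        If True (default), each segment's prefactor is rescaled so that
        k(F) is continuous across segment boundaries; the first segment
        always uses its own ``k0``.
    """

    segments: list[BondSegment]
    label: str = ""
    continuous: bool = True
    _k_eff: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("BondModel needs at least one segment")
        if self.segments[0].f_lo != 0.0:
            raise ValueError("first segment must start at F = 0")
        for a, b in zip(self.segments, self.segments[1:]):
            if not math.isclose(a.f_hi, b.f_lo, rel_tol=0, abs_tol=1e-12):
                raise ValueError(f"segments must be contiguous: [{a.f_lo},{a.f_hi}) then [{b.f_lo},{b.f_hi})")
        k_eff = np.empty(len(self.segments))
        k_eff[0] = self.segments[0].k0
        for i, seg in enumerate(self.segments[1:], start=1):
            if self.continuous:
                prev = self.segments[i - 1]
                k_eff[i] = k_eff[i - 1] * _bell(prev.f_hi - prev.f_lo, prev.f_scale)
            else:
                k_eff[i] = seg.k0
        self._k_eff = k_eff

    @property
    def f_max(self) -> float:
        return self.segments[-1].f_hi

    def rate(self, force):
        """Unbinding rate k(|F|) in 1/s, vectorized over force magnitudes.

        Forces at or beyond the last segment's upper bound extrapolate with
        that segment's law (the model covers [0, F_max) exactly but the
        extrapolation keeps samplers well-defined in the far tail).
        """
        f = np.abs(np.asarray(force, dtype=float))
        out = np.empty_like(f)
        lows = np.array([s.f_lo for s in self.segments])
        idx = np.clip(np.searchsorted(lows, f, side="right") - 1, 0, len(self.segments) - 1)
        for i, seg in enumerate(self.segments):
            m = idx == i
            if np.any(m):
                out[m] = self._k_eff[i] * _bell(f[m] - seg.f_lo, seg.f_scale)
        return out if out.ndim else float(out)

    __call__ = rate

    # -- factories for the phenotypes discussed in the study ---------------

    @classmethod
    def ideal(cls, k0: float, f_max: float = 20.0) -> "BondModel":
        """Force-independent bond: k(F) = k0."""
        return cls([BondSegment(0.0, f_max, k0, np.inf)], label="ideal")

    @classmethod
    def slip(cls, k0: float, f_scale: float, f_max: float = 20.0) -> "BondModel":
        """Single Bell slip bond: k(F) = k0 * exp(F / f_scale)."""
        return cls([BondSegment(0.0, f_max, k0, f_scale)], label="slip")

    @classmethod
    def catch(cls, k0: float, f_scale: float, f_max: float = 20.0) -> "BondModel":
        """Catch bond: rate decreases with force, k(F) = k0 * exp(-F / f_scale)."""
        return cls([BondSegment(0.0, f_max, k0, -abs(f_scale))], label="catch")

    @classmethod
    def slip_ideal(cls, k0: float, f_scale: float, f_break: float, f_max: float = 20.0) -> "BondModel":
        """Slip up to ``f_break``, force-independent above (the alpha-registry phenotype)."""
        segs = [
            BondSegment(0.0, f_break, k0, f_scale),
            BondSegment(f_break, f_max, k0, np.inf),
        ]
        return cls(segs, label="slip-ideal")

    @classmethod
    def slip_ideal_slip(
        cls,
        k0: float,
        f_scale_lo: float,
        f_break1: float,
        f_break2: float,
        f_scale_hi: float,
        f_max: float = 20.0,
    ) -> "BondModel":
        """Slip to ``f_break1``, ideal to ``f_break2``, slip again above."""
        segs = [
            BondSegment(0.0, f_break1, k0, f_scale_lo),
            BondSegment(f_break1, f_break2, k0, np.inf),
            BondSegment(f_break2, f_max, k0, f_scale_hi),
        ]
        return cls(segs, label="slip-ideal-slip")


def _bell(df, f_scale):
    # exp(df / f_scale) with f_scale possibly +-inf (-> 1.0)
    with np.errstate(over="ignore"):
        return np.exp(np.asarray(df, dtype=float) / f_scale)
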