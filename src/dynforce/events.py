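"""Detection of binding/rupture episodes in constant-pulling traces.

An episode starts when the force magnitude rises through ``bind_threshold``
(the assay's ~0.3 pN detection floor) and ends at a rupture: an abrupt drop
of at least ``drop_fraction`` of the episode's running-maximum force within
two samples.  ``F_start`` — the pre-load at binding — is read at the local
force minimum immediately preceding the threshold crossing; episodes with
``F_start`` below the primary tolerance are primary events (the bond's force
history starts from zero), the rest are secondary rebinds and are excluded
from unbinding-force statistics by :func:`filter_primary`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import Trace

__all__ = ["UnbindEvent", "detect_events", "filter_primary"]


@dataclass(frozen=True)
class UnbindEvent:
    t_bind: float  # s
    t_rupture: float  # s
    rupture_force: float  # pN, magnitude (running max over the episode)
    f_start: float  # pN, magnitude of force at binding
    direction: str  # "forward" | "backward"
    is_primary: bool

    def __post_init__(self) -> None:
        if self.t_rupture <= self.t_bind:
            raise ValueError("t_rupture must exceed t_bind")
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")


def detect_events(
    trace: Trace,
    bind_threshold: float = 0.3,
    min_bound_time: float = 0.01,
    drop_fraction: float = 0.8,
    primary_tol: float | None = None,
    smooth_time: float = 0.002,
) -> list[UnbindEvent]:
    """Extract unbinding events from a trace.

    Parameters
    ----------
    trace
        Uniformly sampled trace (raises on a non-uniform time grid).
    bind_threshold
        Detection floor, pN; also the reporting floor — episodes whose force
        never exceeds it are discarded.
    min_bound_time
        Minimum episode duration, s; shorter excursions are treated as noise.
    drop_fraction
        Fraction of the running-maximum force that must be lost within two
        samples to call a rupture.
    primary_tol
        F_start below this is a primary event; defaults to ``bind_threshold``.
    smooth_time
        Boxcar width, s, used for onset tracking (rupture checks use the raw
        signal so the two-sample drop criterion is not blurred).
    """
    t = np.asarray(trace.t, dtype=float)
    if t.size == 0:
        return []
    if t.size > 2:
        steps = np.diff(t)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("trace time grid is not uniform")
    if primary_tol is None:
        primary_tol = bind_threshold
    dt = trace.dt if t.size > 1 else 0.0
    raw = np.asarray(trace.force, dtype=float)
    mag = np.abs(raw)
    w = max(1, int(round(smooth_time / dt))) if dt > 0 else 1
    g = np.convolve(mag, np.ones(w) / w, mode="same") if w > 1 else mag
    min_samples = max(1, int(round(min_bound_time / dt))) if dt > 0 else 1

    n = t.size
    # noise scale from first differences (robust to the slow force ramps)
    sigma = 1.4826 * np.median(np.abs(np.diff(raw))) / np.sqrt(2.0) if n > 10 else 0.0
    hyst = max(3.0 * sigma / np.sqrt(w), 1e-3 * bind_threshold)

    def _walk_min(start: int, step: int) -> int:
        """Hysteresis walk to the local minimum of g in direction ``step``."""
        j = best = start
        run_min = g[start]
        while 0 <= j + step < n and g[j + step] < run_min + hyst:
            j += step
            if g[j] < run_min:
                run_min, best = g[j], j
        return best

    events: list[UnbindEvent] = []
    i = 0
    while i < n:
        if g[i] <= bind_threshold:
            i += 1
            continue
        # onset: binding happened at the nearest local minimum of the
        # force magnitude — behind the threshold crossing for events loaded
        # from baseline, ahead of it for rebinds on a decaying force
        jb, jf = _walk_min(i, -1), _walk_min(i, +1)
        j = jb if g[jb] <= g[jf] else jf
        f_start = float(np.min(mag[max(0, j - w) : j + w + 1]))
        # track until rupture: an abrupt collapse losing >= drop_fraction of
        # the just-before level within ~2 samples.  A collapse that settles
        # at baseline closes the episode; one that settles above baseline is
        # a rupture followed by a rebind under pre-load, which opens a new
        # (secondary) episode.  A slow return to baseline (e.g. unloading
        # across a stage reversal) closes the episode without an event.
        run_max = mag[max(i, j)]
        k = max(i, j)
        while k + 1 < n:
            k += 1
            run_max = max(run_max, mag[k])
            pre = float(np.max(g[max(k - 3, j) : k])) if k > j else g[j]
            post = float(np.min(mag[k : k + 4]))
            if pre > bind_threshold and (pre - post) >= drop_fraction * pre:
                k_settle = k + int(np.argmin(mag[k : k + 4]))
                # the rupture sample: last one still at the pre-drop level
                ir = k_settle
                while ir > j and mag[ir] < 0.5 * pre:
                    ir -= 1
                run_max = max(run_max, float(np.max(mag[k : ir + 1])) if ir >= k else 0.0)
                if (ir - j) >= min_samples and run_max > bind_threshold:
                    events.append(
                        UnbindEvent(
                            t_bind=t[j],
                            t_rupture=t[ir],
                            rupture_force=run_max,
                            f_start=f_start,
                            direction="backward" if raw[ir] >= 0 else "forward",
                            is_primary=f_start < primary_tol,
                        )
                    )
                if post >= bind_threshold:  # rebind under pre-load
                    j = k_settle
                    f_start = mag[j]
                    run_max = f_start
                    k = j
                    continue
                k = k_settle
                break
            if mag[k] < bind_threshold and g[k] < bind_threshold:
                break  # sustained return to baseline, no abrupt collapse
        i = k + 1
    return events


def filter_primary(events: list[UnbindEvent]) -> list[UnbindEvent]:
    """Order-preserving subset of events whose force history starts at zero."""
    return [e for e in events if e.is_primary]
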