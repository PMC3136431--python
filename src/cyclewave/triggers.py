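"""Oscillation-initiation mechanisms.

Two triggers are modeled:

* the post-fertilization **calcium wave** — a planar front sweeping from
  the fertilization point at speed ``v``; behind the front the full
  kinetics apply, ahead of it the active-APC equation is gated off
  (CSF-arrested medium);
* the **diffusive-spread threshold trigger** — oscillations commence at a
  node once local active Cdk1 exceeds a multiple of its pre-fertilization
  value (or the node lies in an initially active region); once commenced a
  node never reverts (monotone latch).
"""
from __future__ import annotations

import dataclasses
from typing import Union

import numpy as np

__all__ = ["WaveSpec", "ThresholdTriggerSpec", "ThresholdTrigger",
           "apc_gate", "INSTANTANEOUS"]

#: symbolic speed for a wave that has already passed everywhere
INSTANTANEOUS = "instantaneous"


@dataclasses.dataclass(frozen=True)
class WaveSpec:
    """A planar calcium-wave front.

    ``speed`` is in mm/min (or :data:`INSTANTANEOUS`).  ``origin`` and
    ``axis`` define the central axis through the fertilization point onto
    which positions are projected; in 1D they default to the left end of
    the interval and the +x direction.
    """

    speed: Union[float, str]
    origin: tuple[float, ...] = (0.0,)
    axis: tuple[float, ...] = (1.0,)
    start_time: float = 0.0

    def __post_init__(self):
        if self.speed != INSTANTANEOUS and not (float(self.speed) > 0.0):
            raise ValueError(f"wave speed must be > 0 or 'instantaneous', "
                             f"got {self.speed!r}")
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError("axis vector must be non-zero")

    def projected_distance(self, positions: np.ndarray) -> np.ndarray:
        """Distance of each position along the central axis from the
        origin (same length unit as the positions, mm by convention)."""
        pos = np.atleast_2d(np.asarray(positions, dtype=float))
        origin = np.asarray(self.origin, dtype=float)
        axis = np.asarray(self.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        if pos.shape[-1] != origin.shape[0]:
            raise ValueError(f"positions have dimension {pos.shape[-1]}, "
                             f"origin has {origin.shape[0]}")
        return (pos - origin) @ axis


def apc_gate(positions: np.ndarray, t: float, wave: WaveSpec) -> np.ndarray:
    """Step-function calcium-wave gate: 1 behind (or on) the front, 0 ahead.

    A point is gated on iff its projected distance x from the fertilization
    point satisfies x <= v * (t - start_time) — inclusive, so the origin
    itself is gated from the start.  The spatial solvers multiply the
    active-APC rate equation by this indicator.
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t!r}")
    x = wave.projected_distance(positions)
    if wave.speed == INSTANTANEOUS:
        return np.ones_like(x)
    front = float(wave.speed) * max(t - wave.start_time, 0.0)
    return (x <= front).astype(float)


@dataclasses.dataclass(frozen=True)
class ThresholdTriggerSpec:
    """Configuration of the diffusive-spread trigger.

    ``threshold_factor`` multiplies the pre-fertilization active-Cdk1
    concentration (default 4).  ``active_fraction`` is the fraction of the
    domain, adjacent to the high-coordinate end, that starts with full
    kinetics (default 0.1); ``active_mask`` may override it with an
    explicit per-node mask.
    """

    threshold_factor: float = 4.0
    active_fraction: float = 0.1
    active_mask: np.ndarray | None = None

    def __post_init__(self):
        if not self.threshold_factor > 1.0:
            raise ValueError("threshold factor must exceed 1")
        if not (0.0 <= self.active_fraction <= 1.0):
            raise ValueError("active fraction must lie in [0, 1]")


class ThresholdTrigger:
    """Monotone latch over the nodes of a domain.

    A node latches when its active-Cdk1 concentration reaches
    ``threshold_factor`` times the pre-fertilization reference, or if it
    belongs to the initially active region; a latched node never unlatches.
    Latched nodes run the full kinetics (gate 1), unlatched nodes stay
    CSF-arrested (gate 0).
    """

    def __init__(self, spec: ThresholdTriggerSpec, coords_along_axis: np.ndarray,
                 reference_ct: float):
        x = np.asarray(coords_along_axis, dtype=float)
        self.spec = spec
        self.threshold = spec.threshold_factor * float(reference_ct)
        if spec.active_mask is not None:
            mask = np.asarray(spec.active_mask, dtype=bool)
            if mask.shape != x.shape:
                raise ValueError("active_mask shape does not match node count")
            self.latched = mask.copy()
        else:
            # terminal fraction of the domain adjacent to the far end
            lo = x.max() - spec.active_fraction * (x.max() - x.min())
            self.latched = x >= lo if spec.active_fraction > 0 else np.zeros_like(x, bool)

    def update(self, ct_values: np.ndarray) -> np.ndarray:
        """Latch every node whose active Cdk1 meets the threshold; return
        the gate array (1.0 latched, 0.0 arrested)."""
        self.latched |= np.asarray(ct_values) >= self.threshold
        return self.gate

    @property
    def gate(self) -> np.ndarray:
        return self.latched.astype(float)
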