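"""Azimuth ↔ interaural time difference (ITD) geometry.

A plane sound wavefront incident at azimuth ``α`` reaches the two ears with
a time difference ``Δt = (d/v)·sin α`` for ear separation ``d`` and speed of
sound ``v`` (far-field approximation).  Positive ``α`` means the source is
on the right, so the right ear leads and ``Δt > 0``.

Angles are in degrees at this interface, ITDs in microseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["EarGeometry", "itd_from_angle", "angle_from_itd", "max_itd"]


@dataclass(frozen=True)
class EarGeometry:
    """Ear-to-ear distance ``d`` (m) and speed of sound ``v`` (m/s)."""

    d: float = 0.2
    v: float = 343.0

    def __post_init__(self) -> None:
        if not self.d > 0:
            raise ValueError("ear distance d must be > 0")
        if not self.v > 0:
            raise ValueError("speed of sound v must be > 0")


DEFAULT_GEOMETRY = EarGeometry()


def max_itd(geom: EarGeometry = DEFAULT_GEOMETRY) -> float:
    """Largest physically possible ITD, ``d/v``, in μs (source at ±90°)."""
    return geom.d / geom.v * 1e6


def itd_from_angle(alpha_deg: float, geom: EarGeometry = DEFAULT_GEOMETRY) -> float:
    """ITD (μs) of a plane wave at azimuth ``alpha_deg`` ∈ [−90°, 90°].

    Positive angle = source on the right = right ear leads = positive ITD.
    """
    if not -90.0 <= alpha_deg <= 90.0:
        raise ValueError(f"azimuth {alpha_deg}° outside [-90°, 90°]")
    return max_itd(geom) * math.sin(math.radians(alpha_deg))


def angle_from_itd(itd_us: float, geom: EarGeometry = DEFAULT_GEOMETRY) -> float:
    """Azimuth (degrees) whose plane-wave ITD equals ``itd_us``.

    Exact inverse of :func:`itd_from_angle` on its domain; an ITD beyond
    ``±d/v`` is physically impossible and raises ``ValueError``.
    """
    bound = max_itd(geom)
    if abs(itd_us) > bound:
        raise ValueError(
            f"|ITD| = {abs(itd_us)} μs exceeds the physical bound d/v = "
            f"{bound:.3f} μs"
        )
    return math.degrees(math.asin(itd_us / bound))
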