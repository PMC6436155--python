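"""Stimulation protocols: piecewise-constant base inclination over time.

The canonical transient protocol is a rest at the vertical, a tilt to
``theta_incl`` for a duration ``dt``, and a return to the vertical, all
applied as instantaneous base rotations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant base inclination plus a gravity level.

    ``segments`` is an ordered list of ``(start_time_min, base_angle_deg)``
    pairs; the first segment must start at t = 0 and start times must be
    strictly increasing. ``g_eff`` overrides the gravity level of the
    model parameters when set.
    """

    segments: tuple[tuple[float, float], ...]
    duration: float
    g_eff: float | None = None

    def __post_init__(self) -> None:
        segs = tuple((float(t), float(a)) for t, a in self.segments)
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise InvalidParameterError("protocol needs at least one segment")
        if segs[0][0] != 0.0:
            raise InvalidParameterError(
                f"first segment must start at t=0, got {segs[0][0]}")
        starts = [t for t, _ in segs]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise InvalidParameterError("segment start times must strictly increase")
        for _, angle in segs:
            if not -180.0 <= angle <= 180.0:
                raise InvalidParameterError(
                    f"base angle {angle} deg outside [-180, 180]")
        if not (self.duration > 0) or not math.isfinite(self.duration):
            raise InvalidParameterError(f"duration must be > 0, got {self.duration}")
        if self.g_eff is not None and not (self.g_eff > 0):
            raise InvalidParameterError(f"g_eff must be > 0, got {self.g_eff}")

    def base_angle_deg(self, t) -> np.ndarray | float:
        """Base inclination (degrees) at time(s) ``t`` (min)."""
        starts = np.array([s for s, _ in self.segments])
        angles = np.array([a for _, a in self.segments])
        idx = np.searchsorted(starts, np.asarray(t, dtype=float), side="right") - 1
        idx = np.clip(idx, 0, len(angles) - 1)
        out = angles[idx]
        return float(out) if np.isscalar(t) else out

    def base_angle_rad(self, t):
        return np.deg2rad(self.base_angle_deg(t))


def permanent_inclination(theta_incl: float, duration: float,
                          g_eff: float | None = None) -> StimulusProtocol:
    """A permanent tilt applied at t = 0 and held for the whole run."""
    return StimulusProtocol(segments=((0.0, theta_incl),),
                            duration=duration, g_eff=g_eff)


def build_protocol(theta_incl: float, dt: float, rest_before: float = 0.0,
                   observe_after: float = 600.0,
                   g_eff: float | None = None) -> StimulusProtocol:
    """Three-segment transient protocol 0 -> theta_incl (for ``dt``) -> 0.

    ``dt = 0`` yields a null (always vertical) protocol; ``dt = inf``
    yields a two-segment permanent inclination.

    Parameters
    ----------
    theta_incl : float
        Stimulation angle (degrees).
    dt : float
        Stimulation duration (min); ``math.inf`` for a permanent tilt.
    rest_before : float
        Rest at the vertical before the tilt (min).
    observe_after : float
        Observation window after the end of the stimulus (min); for a
        permanent tilt, the window after its onset.
    """
    for name, value in (("dt", dt), ("rest_before", rest_before),
                        ("observe_after", observe_after)):
        if value < 0 or math.isnan(value):
            raise InvalidParameterError(f"{name} must be >= 0, got {value}")
    if dt == 0:
        return StimulusProtocol(segments=((0.0, 0.0),),
                                duration=max(rest_before + observe_after, 1e-9),
                                g_eff=g_eff)
    if math.isinf(dt):
        segs = ((0.0, 0.0), (rest_before, float(theta_incl))) if rest_before > 0 \
            else ((0.0, float(theta_incl)),)
        return StimulusProtocol(segments=segs,
                                duration=rest_before + observe_after, g_eff=g_eff)
    segs = [(0.0, 0.0), (rest_before, float(theta_incl)),
            (rest_before + dt, 0.0)]
    if rest_before == 0:
        segs = segs[1:]
        segs[0] = (0.0, float(theta_incl))
    return StimulusProtocol(segments=tuple(segs),
                            duration=rest_before + dt + observe_after,
                            g_eff=g_eff)
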