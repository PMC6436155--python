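"""Parameter containers for the shoot-gravitropism model.

Units follow the conventions used throughout the package: time in minutes,
lengths in millimetres (organ scale) or micrometres (statolith-pile scale),
angles in degrees at every public interface, gravity as a dimensionless
multiple of Earth gravity.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

from .errors import InvalidParameterError

EARTH_G = 9.81  # m s^-2


@dataclass(frozen=True)
class ModelParameters:
    """Physiological and geometric parameters of one simulated organ.

    Parameters
    ----------
    R : float
        Organ radius (mm).
    L : float
        Organ length (mm), held constant over a simulation window (bending
        is fast compared to elongation).
    tau_growth : float
        Growth time (min), the inverse of the mean relative elongation
        rate.
    beta : float
        Dimensionless gravitropic gain.
    tau_memory : float
        Time constant (min) of the exponential memory kernel that
        integrates the statolith-pile angle into the gravitropic signal.
    tau_reaction : float
        Pure delay (min) between statolith displacement and the first
        change of the growth signal.
    tau_aval_ref : float
        Statolith-avalanche relaxation time (min) at 1 g.
    g_eff : float
        Effective gravity, in multiples of Earth gravity.
    epsilon_dot : float, optional
        Mean relative elongation rate (1/min). Derived as
        ``1/tau_growth`` when omitted.
    """

    R: float = 0.8
    L: float = 20.0
    tau_growth: float = 1200.0
    beta: float = 0.8
    tau_memory: float = 13.0
    tau_reaction: float = 13.0
    tau_aval_ref: float = 1.04
    g_eff: float = 1.0
    epsilon_dot: float | None = None

    def __post_init__(self) -> None:
        for name in ("R", "L", "tau_growth", "beta", "tau_memory",
                     "tau_aval_ref", "g_eff"):
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise InvalidParameterError(
                    f"{name} must be strictly positive, got {value!r}")
        if self.tau_reaction < 0 or not math.isfinite(self.tau_reaction):
            raise InvalidParameterError(
                f"tau_reaction must be >= 0, got {self.tau_reaction!r}")
        if self.epsilon_dot is None:
            object.__setattr__(self, "epsilon_dot", 1.0 / self.tau_growth)
        elif not (self.epsilon_dot > 0):
            raise InvalidParameterError(
                f"epsilon_dot must be strictly positive, got {self.epsilon_dot!r}")

    @property
    def tau_aval(self) -> float:
        """Effective avalanche time (min): ``tau_aval_ref / g_eff``."""
        return self.tau_aval_ref / self.g_eff

    @property
    def tau_growth_star(self) -> float:
        """Modified growth time ``tau_growth * R / (beta * L)`` (min),
        the natural bending time scale of the tip."""
        return self.tau_growth * self.R / (self.beta * self.L)

    @property
    def elongation_velocity(self) -> float:
        """Mean elongation velocity ``epsilon_dot * L`` (mm/min)."""
        return self.epsilon_dot * self.L

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        if "tau_growth" in changes and "epsilon_dot" not in changes:
            changes.setdefault("epsilon_dot", None)
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def wheat_calibration(**overrides) -> ModelParameters:
    """Calibrated parameter set for wheat coleoptiles.

    R = 0.8 mm, L = 20 mm, tau_growth = 1200 min, beta = 0.8,
    tau_memory = 13 min, tau_reaction = 13 min, tau_aval_ref = 1.04 min.
    """
    return ModelParameters().replace(**overrides) if overrides else ModelParameters()


@dataclass(frozen=True)
class AvalanchePhysicalParameters:
    """Microscopic parameters behind the avalanche time scale.

    The avalanche time results from a balance between the buoyancy-reduced
    weight of the statolith pile and the viscous drag of the cytoplasm:
    ``tau_aval = alpha * eta / (delta_rho * H * g)``. The pile mass is
    absorbed into the dimensionless pre-factor ``alpha``.

    Units: eta in mPa*s, delta_rho and rho_fluid in kg/m^3, H and L_pile in
    micrometres, U in micrometres per minute.
    """

    alpha: float = 1.0
    eta: float = 10.0          # mPa*s, cytoplasm viscosity
    delta_rho: float = 500.0   # kg/m^3, starch minus cytoplasm
    H: float = 10.0            # um, pile thickness
    rho_fluid: float = 1.0e3   # kg/m^3
    U: float = 10.0            # um/min, peak avalanche speed
    L_pile: float = 20.0       # um

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if not (value > 0) or not math.isfinite(value):
                raise InvalidParameterError(
                    f"{f.name} must be strictly positive, got {value!r}")
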