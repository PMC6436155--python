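"""Response metrics: gravitropic sensitivity, dose-response curves,
asymptotic regimes and the (tau_aval, dt) phase diagram.

The central quantity is the dimensionless gravitropic sensitivity

    beta_tilde = R * (max d(theta)/dt) / (sin(theta_incl) * <dL/dt>)

where the tip-angle rate is the maximum slope during the first rising
phase of the counter-bending response and <dL/dt> = epsilon_dot * L is the
mean elongation velocity. The sine normalization removes the dependence on
the inclination angle.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TipTrajectory, simulate_shoot
from .errors import InvalidParameterError
from .params import ModelParameters
from .protocol import build_protocol

logger = logging.getLogger(__name__)

#: Stimulations at least this many memory times long are treated as permanent.
PERMANENT_DT_FACTOR = 100.0


class Regime(enum.Enum):
    """Asymptotic response regimes in the (tau_aval, dt) plane."""

    MEMORY_DOSE = "MEMORY_DOSE"          # beta_tilde ~ beta * dt / tau_memory
    SATURATED_SINE = "SATURATED_SINE"    # beta_tilde ~ beta (sine law)
    AVALANCHE_DOSE = "AVALANCHE_DOSE"    # beta_tilde ~ beta * dt / tau_aval
    GROWTH_LIMITED = "GROWTH_LIMITED"    # beta_tilde ~ beta*sqrt(tau*_growth/tau_aval)


@dataclass
class DoseResponseCurve:
    """Gravitropic sensitivity as a function of stimulation duration."""

    points: pd.DataFrame        # columns: dt_min, g_eff, beta_tilde
    theta_incl: float
    params: ModelParameters | None = None
    replicates: dict = field(default_factory=dict)  # dt -> per-replicate values

    @property
    def dt(self) -> np.ndarray:
        return self.points["dt_min"].to_numpy()

    @property
    def beta_tilde(self) -> np.ndarray:
        return self.points["beta_tilde"].to_numpy()


@dataclass
class PhaseDiagram:
    """Sensitivity and regime label over a log-spaced (tau_aval, dt) grid."""

    tau_aval_axis: np.ndarray
    dt_axis: np.ndarray
    beta_tilde: np.ndarray      # shape (len(dt_axis), len(tau_aval_axis))
    regime: np.ndarray          # same shape, dtype object of Regime

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (tau_aval_min, dt_min, beta_tilde, regime)."""
        rows = []
        for i, dt in enumerate(self.dt_axis):
            for j, ta in enumerate(self.tau_aval_axis):
                rows.append((ta, dt, self.beta_tilde[i, j],
                             self.regime[i, j].value))
        return pd.DataFrame(rows, columns=["tau_aval_min", "dt_min",
                                           "beta_tilde", "regime"])


# ---------------------------------------------------------------------------
# Sensitivity from a trajectory
# ---------------------------------------------------------------------------

def gravitropic_sensitivity(traj: TipTrajectory, params: ModelParameters,
                            theta_incl: float,
                            smooth_window: int | None = None) -> float:
    """Dimensionless sensitivity beta_tilde from a tip-angle trajectory.

    The counter-bending response ``theta_base - theta_tip`` (sign-aligned
    with the stimulus) is differentiated by centered differences; the
    maximum slope is taken over the first rising phase, i.e. before the
    first maximum of the response. For noisy input a Savitzky-Golay filter
    of odd length ``smooth_window`` is applied first.

    Returns 0 with a warning for a flat trajectory; raises for a zero
    stimulation angle.
    """
    if theta_incl == 0:
        raise InvalidParameterError("theta_incl must be nonzero")
    sign = 1.0 if theta_incl > 0 else -1.0
    bend = sign * traj.bending  # deg, positive counter-bending
    if smooth_window is not None and smooth_window >= 5:
        from scipy.signal import savgol_filter
        bend = savgol_filter(bend, smooth_window, 3)
    if np.max(np.abs(bend)) < 1e-12:
        warnings.warn("flat trajectory: returning beta_tilde = 0", stacklevel=2)
        return 0.0
    i_peak = int(np.argmax(bend))
    if i_peak < 2:
        i_peak = len(bend) - 1
    slope = np.gradient(bend[: i_peak + 1], traj.t[: i_peak + 1])  # deg/min
    max_slope = np.deg2rad(np.max(slope))                          # rad/min
    return float(params.R * max_slope /
                 (abs(math.sin(math.radians(theta_incl))) * params.elongation_velocity))


# ---------------------------------------------------------------------------
# Simulation horizons
# ---------------------------------------------------------------------------

def _response_horizon(params: ModelParameters, g_eff: float) -> float:
    """Observation window (min) comfortably past the first-maximum slope
    of the response, for any regime: covers the memory lag, the fast
    avalanche, and the quarter-period of the growth-limited oscillation."""
    tau_a = params.tau_aval_ref / g_eff
    tau_s = params.tau_growth_star
    return (10.0 * params.tau_memory
            + math.pi * math.sqrt(tau_s * tau_a)
            + 5.0 * min(tau_a, tau_s)
            + 2.0 * tau_s)


def _effective_stimulus(params: ModelParameters, dt: float, g_eff: float) -> float:
    """Cap very long stimulations at a duration safely past the first
    response maximum; the sensitivity window is unaffected."""
    if not math.isinf(dt) and dt <= PERMANENT_DT_FACTOR * params.tau_memory:
        return dt
    cap = (params.tau_reaction + _response_horizon(params, g_eff)
           + PERMANENT_DT_FACTOR * params.tau_memory)
    return min(dt, cap) if not math.isinf(dt) else cap


def simulate_transient(params: ModelParameters, dt: float, theta_incl: float,
                       g_eff: float = 1.0, n_nodes: int = 64,
                       time_step: float | None = None) -> TipTrajectory:
    """Simulate the canonical transient protocol (tilt for ``dt``, return
    to vertical) with an observation window adapted to the time scales.
    ``dt = inf`` gives a permanent inclination."""
    dt_eff = _effective_stimulus(params, dt, g_eff)
    horizon = params.tau_reaction + _response_horizon(params, g_eff)
    proto = build_protocol(theta_incl, math.inf if math.isinf(dt) else dt_eff,
                           rest_before=0.0, observe_after=horizon, g_eff=g_eff)
    return simulate_shoot(params, proto, n_nodes=n_nodes, dt=time_step)


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

def dose_response_curve(params: ModelParameters, dt_list, theta_incl: float = 45.0,
                        g_eff: float = 1.0, n_nodes: int = 64,
                        time_step: float | None = None) -> DoseResponseCurve:
    """Sensitivity beta_tilde for each stimulation duration in ``dt_list``.

    Runs one noiseless full-model simulation per duration and applies
    :func:`gravitropic_sensitivity`. ``math.inf`` entries map to a
    permanent stimulus. In the noiseless model the curve is nondecreasing
    in dt and saturates at the permanent-inclination value.
    """
    dt_list = list(dt_list)
    if not dt_list or any((d <= 0 or math.isnan(d)) for d in dt_list):
        raise InvalidParameterError("dt_list must be nonempty with positive entries")
    rows = []
    for d in dt_list:
        try:
            traj = simulate_transient(params, d, theta_incl, g_eff,
                                      n_nodes=n_nodes, time_step=time_step)
        except Exception as exc:
            raise type(exc)(f"{exc} (while simulating dt={d} min)") from exc
        bt = gravitropic_sensitivity(traj, params, theta_incl)
        rows.append((d, g_eff, bt))
    frame = pd.DataFrame(rows, columns=["dt_min", "g_eff", "beta_tilde"])
    return DoseResponseCurve(points=frame, theta_incl=theta_incl, params=params)


# ---------------------------------------------------------------------------
# Asymptotic regimes
# ---------------------------------------------------------------------------

def classify_regime(tau_aval: float, dt: float,
                    params: ModelParameters) -> tuple[Regime, bool]:
    """Regime label for one (tau_aval, dt) cell, with a boundary flag.

    The label follows the asymptotic cases: a memory-limited dose regime
    (both tau_aval and dt below tau_memory), the saturated sine law (long
    stimulus, avalanche faster than bending), an avalanche-limited dose
    regime (slow avalanche, short stimulus), and a growth-limited regime
    (avalanche slower than bending, long stimulus). Ties break toward the
    dose regimes. The flag marks cells within a factor of 2 of a boundary.
    """
    if tau_aval <= 0 or dt <= 0:
        raise InvalidParameterError("tau_aval and dt must be positive")
    tau_m = params.tau_memory
    tau_s = params.tau_growth_star
    gl_knee = math.sqrt(tau_s * tau_aval)
    if tau_aval <= tau_m:
        label = Regime.MEMORY_DOSE if dt <= tau_m else Regime.SATURATED_SINE
        ratios = [tau_aval / tau_m, dt / tau_m]
    elif dt <= min(tau_aval, gl_knee):
        label = Regime.AVALANCHE_DOSE
        ratios = [tau_aval / tau_m, dt / min(tau_aval, gl_knee)]
    elif tau_aval <= tau_s:
        label = Regime.SATURATED_SINE
        ratios = [tau_aval / tau_m, tau_aval / tau_s, dt / tau_aval]
    else:
        label = Regime.GROWTH_LIMITED
        ratios = [tau_aval / tau_s, dt / gl_knee]
    # near any bounding inequality of this regime no single asymptotic
    # formula is accurate; flag within a factor of 2
    boundary = any(0.5 <= r <= 2.0 for r in ratios)
    return label, boundary


def asymptotic_sensitivity(params: ModelParameters, dt: float,
                           tau_aval: float | None = None
                           ) -> tuple[float, Regime, bool]:
    """Closed-form beta_tilde of the regime containing (tau_aval, dt).

    Returns ``(estimate, regime, boundary_flag)``; the flag signals
    parameters within a factor of 2 of a regime boundary, where no single
    asymptotic formula is accurate.
    """
    tau_a = params.tau_aval if tau_aval is None else tau_aval
    label, boundary = classify_regime(tau_a, dt, params)
    beta = params.beta
    if label is Regime.MEMORY_DOSE:
        est = beta * dt / params.tau_memory
    elif label is Regime.AVALANCHE_DOSE:
        est = beta * dt / tau_a
    elif label is Regime.SATURATED_SINE:
        est = beta
    else:  # GROWTH_LIMITED
        est = beta * math.sqrt(params.tau_growth_star / tau_a)
    return est, label, boundary


def crossover_gravity(params: ModelParameters) -> tuple[float, float]:
    """Gravity levels (multiples of g) at which the avalanche time crosses
    the memory time and the growth time.

    Below ``g_memory = tau_aval_ref / tau_memory`` the avalanche becomes
    the slowest signalling step and the dose-response turns
    gravity-dependent; below ``g_growth = tau_aval_ref / tau_growth`` the
    avalanche outlasts even the bending dynamics.
    """
    return (params.tau_aval_ref / params.tau_memory,
            params.tau_aval_ref / params.tau_growth)


# ---------------------------------------------------------------------------
# Phase diagram
# ---------------------------------------------------------------------------

def phase_diagram(params: ModelParameters, tau_aval_grid=None, dt_grid=None,
                  theta_incl: float = 45.0, n_nodes: int = 64) -> PhaseDiagram:
    """Sensitivity and regime label over a log-spaced (tau_aval, dt) grid.

    Each cell runs one noiseless full-model simulation with the cell's
    avalanche time (at 1 g) and stimulation duration. Solver failures are
    recorded as NaN cells rather than aborting the sweep.
    """
    if tau_aval_grid is None:
        tau_aval_grid = np.geomspace(1e-1, 1e5, 24)
    if dt_grid is None:
        dt_grid = np.geomspace(1.0, 1e5, 24)
    tau_aval_grid = np.asarray(tau_aval_grid, dtype=float)
    dt_grid = np.asarray(dt_grid, dtype=float)
    bt = np.full((dt_grid.size, tau_aval_grid.size), np.nan)
    labels = np.empty(bt.shape, dtype=object)
    for j, ta in enumerate(tau_aval_grid):
        cell_params = params.replace(tau_aval_ref=float(ta), g_eff=1.0)
        for i, d in enumerate(dt_grid):
            labels[i, j] = classify_regime(float(ta), float(d), params)[0]
            try:
                traj = simulate_transient(cell_params, float(d), theta_incl,
                                          1.0, n_nodes=n_nodes)
                bt[i, j] = gravitropic_sensitivity(traj, cell_params, theta_incl)
            except Exception as exc:  # pragma: no cover - defensive per-cell
                logger.warning("phase diagram cell (tau_aval=%g, dt=%g) failed: %s",
                               ta, d, exc)
    return PhaseDiagram(tau_aval_axis=tau_aval_grid, dt_axis=dt_grid,
                        beta_tilde=bt, regime=labels)
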