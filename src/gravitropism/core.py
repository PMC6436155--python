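"""Core dynamics: statolith avalanche, delayed memory signal, and the full
shoot bending model.

The model couples four fields along the curvilinear abscissa s of the organ:

    R dC/dt        = -(1/tau_growth) * G_s
    dG_s/dt        =  (1/tau_memory) * (beta * sin(A_stato(t - tau_reaction)) - G_s)
    dA_stato/dt    = -(1/tau_aval)   * sin(A_stato - A_stem)
    A_stem(s, t)   =  integral_0^s C ds' + A_stem(0, t)

where C is the curvature, A_stem the local inclination, A_stato the
statolith-pile angle relative to the cell axis, and G_s the gravitropic
signal driving differential growth. Gravity enters only through
tau_aval = tau_aval_ref / g_eff. The base inclination A_stem(0, t) is the
imposed stimulus. The system exhibits negative feedback: a permanently
inclined organ bends back toward the direction of effective gravity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, InvalidParameterError, NumericalStabilityError
from .params import AvalanchePhysicalParameters, ModelParameters
from .protocol import StimulusProtocol

logger = logging.getLogger(__name__)

__all__ = [
    "AvalancheTrace", "TipTrajectory", "ShootState",
    "effective_avalanche_time", "reynolds_number", "reynolds_order",
    "solve_avalanche", "avalanche_closed_form",
    "update_gravitropic_signal", "gravitropic_signal_ode",
    "gravitropic_signal_quadrature", "simulate_shoot", "simulate_tip_reduced",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------

@dataclass
class AvalancheTrace:
    """Statolith pile-angle relaxation at the cellular scale.

    All angles in degrees. ``psi = A_stem - A_stato`` is the inclination of
    the pile free surface from the horizontal; in the noiseless model with a
    constant imposed inclination it decays monotonically to zero.
    """

    t: np.ndarray
    A_stato: np.ndarray
    A_stem: np.ndarray
    g_eff: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def psi(self) -> np.ndarray:
        return self.A_stem - self.A_stato

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.A_stato = np.asarray(self.A_stato, dtype=float)
        A_stem = np.asarray(self.A_stem, dtype=float)
        if A_stem.ndim == 0:
            A_stem = np.full_like(self.t, float(A_stem))
        self.A_stem = A_stem


@dataclass
class TipTrajectory:
    """Tip-angle time series of one simulated (or measured) organ.

    ``theta_tip`` is the inclination of the organ at s = L relative to the
    effective-gravity direction, in degrees; ``theta_base`` is the imposed
    base inclination. Time samples are uniform.
    """

    t: np.ndarray
    theta_tip: np.ndarray
    theta_base: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.theta_tip = np.asarray(self.theta_tip, dtype=float)
        self.theta_base = np.asarray(self.theta_base, dtype=float)
        if not (np.diff(self.t) > 0).all():
            raise InvalidParameterError("trajectory times must strictly increase")

    @property
    def bending(self) -> np.ndarray:
        """Counter-bending response ``theta_base - theta_tip`` (degrees),
        positive when the organ bends against a positive inclination."""
        return self.theta_base - self.theta_tip


@dataclass
class ShootState:
    """Snapshot of the spatial fields along the organ at one time."""

    t: float
    s_grid: np.ndarray      # mm
    C: np.ndarray           # 1/mm
    A_stem: np.ndarray      # rad
    A_stato: np.ndarray     # rad
    G_s: np.ndarray         # dimensionless


# ---------------------------------------------------------------------------
# Scalar operations
# ---------------------------------------------------------------------------

def effective_avalanche_time(params, g_eff: float | None = None) -> float:
    """Avalanche relaxation time (min) at gravity level ``g_eff``.

    For :class:`ModelParameters` this is ``tau_aval_ref / g_eff``; for
    :class:`AvalanchePhysicalParameters` it is the viscous/gravity balance
    ``alpha * eta / (delta_rho * H * g_eff * g0)`` converted to minutes.
    The result is strictly decreasing in gravity: slower gravity, slower
    avalanche.
    """
    if g_eff is None:
        if isinstance(params, ModelParameters):
            g_eff = params.g_eff
        else:
            g_eff = 1.0
    if not (g_eff > 0) or not math.isfinite(g_eff):
        raise InvalidParameterError(f"g_eff must be strictly positive, got {g_eff!r}")
    if isinstance(params, ModelParameters):
        return params.tau_aval_ref / g_eff
    if isinstance(params, AvalanchePhysicalParameters):
        eta_si = params.eta * 1e-3                 # mPa*s -> Pa*s
        h_si = params.H * 1e-6                     # um -> m
        from .params import EARTH_G
        tau_s = params.alpha * eta_si / (params.delta_rho * h_si * g_eff * EARTH_G)
        return tau_s / 60.0
    raise InvalidParameterError(f"unsupported parameter object {type(params)!r}")


def reynolds_number(phys: AvalanchePhysicalParameters) -> float:
    """Reynolds number ``rho * U * L_pile / eta`` of the statolith flow.

    Accepts ``U = 0`` (no flow) but rejects nonpositive values of the
    other inputs via the parameter container. For the observed cytoplasm
    values the result is of order 1e-6: the avalanche is overdamped and
    inertia-free.
    """
    if phys.U < 0:
        raise InvalidParameterError("avalanche speed U must be >= 0")
    u_si = phys.U * 1e-6 / 60.0        # um/min -> m/s
    l_si = phys.L_pile * 1e-6          # um -> m
    eta_si = phys.eta * 1e-3           # mPa*s -> Pa*s
    return phys.rho_fluid * u_si * l_si / eta_si


def reynolds_order(phys: AvalanchePhysicalParameters) -> int:
    """Nearest power of ten of the Reynolds number (round of log10)."""
    re = reynolds_number(phys)
    if re <= 0:
        raise InvalidParameterError("order of magnitude undefined for Re <= 0")
    return int(round(math.log10(re)))


# ---------------------------------------------------------------------------
# Avalanche relaxation (cell scale)
# ---------------------------------------------------------------------------

def avalanche_closed_form(t, tau_aval: float, psi0_deg: float) -> np.ndarray:
    """Closed-form free-surface angle (degrees) of the relaxing pile.

    Separating the viscous relaxation ODE d(psi)/dt = -sin(psi)/tau gives
    ``tan(psi/2) = tan(psi0/2) * exp(-t/tau)``. Used as the analytic oracle
    for the numerical solver.
    """
    t = np.asarray(t, dtype=float)
    half = math.tan(math.radians(psi0_deg) / 2.0) * np.exp(-t / tau_aval)
    return np.rad2deg(2.0 * np.arctan(half))


def solve_avalanche(tau_aval: float, A_stem: float, A_stato0: float,
                    t_grid, g_eff: float = 1.0,
                    dt: float | None = None) -> AvalancheTrace:
    """Integrate the pile relaxation dA_stato/dt = -sin(A_stato - A_stem)/tau.

    Angles at the interface are degrees; integration is in radians with a
    fixed-step RK4 scheme (default step ``tau_aval / 100``) and linear
    sampling onto ``t_grid``. With a constant imposed inclination the pile
    free surface relaxes monotonically to the horizontal (no repose angle).
    """
    if not (tau_aval > 0) or not math.isfinite(tau_aval):
        raise InvalidParameterError(f"tau_aval must be > 0, got {tau_aval!r}")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1 or not (np.diff(t_grid) > 0).all():
        raise InvalidParameterError("t_grid must be 1-D and strictly increasing")
    if t_grid[0] < 0:
        raise InvalidParameterError("t_grid must start at t >= 0")
    h = tau_aval / 100.0 if dt is None else float(dt)
    if h <= 0:
        raise InvalidParameterError(f"step dt must be > 0, got {h!r}")

    a_stem = math.radians(A_stem)
    t_end = float(t_grid[-1])
    n_steps = max(1, int(math.ceil(t_end / h))) if t_end > 0 else 0
    h = t_end / n_steps if n_steps else h

    def f(s):
        return -np.sin(s - a_stem) / tau_aval

    s = math.radians(A_stato0)
    t_fine = np.empty(n_steps + 1)
    s_fine = np.empty(n_steps + 1)
    t_fine[0], s_fine[0] = 0.0, s
    for k in range(n_steps):
        k1 = f(s)
        k2 = f(s + 0.5 * h * k1)
        k3 = f(s + 0.5 * h * k2)
        k4 = f(s + h * k3)
        s = s + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        t_fine[k + 1] = (k + 1) * h
        s_fine[k + 1] = s

    a_stato = np.interp(t_grid, t_fine, s_fine)
    return AvalancheTrace(t=t_grid, A_stato=np.rad2deg(a_stato),
                          A_stem=np.full_like(t_grid, float(A_stem)),
                          g_eff=g_eff,
                          meta={"tau_aval": tau_aval, "dt": h})


# ---------------------------------------------------------------------------
# Memory integration (signal scale)
# ---------------------------------------------------------------------------

def update_gravitropic_signal(G_s: float, A_stato_delayed: float,
                              params: ModelParameters, dt: float) -> float:
    """Advance the gravitropic signal by one step of length ``dt`` (min).

    Integrates dG_s/dt = (beta*sin(A_stato(t - tau_reaction)) - G_s)/tau_memory
    with the delayed input (radians) held constant over the step, for which
    the exponential update is exact:

        G' = target + (G - target) * exp(-dt / tau_memory)

    At steady state with a constant pile angle theta the signal converges
    to ``beta * sin(theta)``.
    """
    if dt <= 0:
        raise InvalidParameterError(f"dt must be > 0, got {dt!r}")
    target = params.beta * math.sin(A_stato_delayed)
    decay = math.exp(-dt / params.tau_memory)
    return target + (G_s - target) * decay


def gravitropic_signal_ode(a_stato, t_grid, params: ModelParameters,
                           dt: float | None = None) -> np.ndarray:
    """Gravitropic signal G_s on ``t_grid`` from the first-order ODE form.

    ``a_stato`` is a callable returning the pile angle (radians) at any
    time; times before t = 0 must be covered (pre-stimulus equilibrium).
    The delayed input is sampled at substep midpoints, which keeps the
    piecewise-constant exponential update second-order accurate.
    """
    if not callable(a_stato):
        raise ContractError("a_stato must be a callable history of span >= tau_reaction")
    t_grid = np.asarray(t_grid, dtype=float)
    h = params.tau_memory / 1000.0 if dt is None else float(dt)
    t_end = float(t_grid[-1])
    # keep h itself (a divisor of tau_memory) so that step inputs aligned
    # with the delay land exactly on substep boundaries
    n = max(1, int(math.ceil(t_end / h - 1e-12)))
    g = 0.0
    t_fine = np.arange(n + 1) * h
    g_fine = np.empty(n + 1)
    g_fine[0] = g
    for k in range(n):
        t_mid = (k + 0.5) * h
        a_delayed = float(a_stato(t_mid - params.tau_reaction))
        g = update_gravitropic_signal(g, a_delayed, params, h)
        g_fine[k + 1] = g
    return np.interp(t_grid, t_fine, g_fine)


def gravitropic_signal_quadrature(a_stato, t, params: ModelParameters) -> float:
    """Gravitropic signal at time ``t`` from the explicit memory integral.

    Evaluates the exponential-kernel convolution

        G_s(t) = (beta/tau_memory) * int_{-inf}^{t - tau_reaction}
                 exp(-(t - tau_reaction - t')/tau_memory) sin(A_stato(t')) dt'

    by adaptive quadrature, truncating the kernel at 45 memory times.
    Serves as the independent cross-check of the ODE form.
    """
    from scipy.integrate import quad

    tau_m = params.tau_memory

    def integrand(u):  # u = t - tau_reaction - t'
        return math.exp(-u / tau_m) * math.sin(a_stato(t - params.tau_reaction - u))

    # split at t' = 0, where the input typically switches on from the
    # pre-stimulus equilibrium, so the kink sits on a panel boundary
    u_max = 45.0 * tau_m
    u_split = t - params.tau_reaction
    value = 0.0
    if 0.0 < u_split < u_max:
        value += quad(integrand, 0.0, u_split, limit=400)[0]
        value += quad(integrand, u_split, u_max, limit=400)[0]
    else:
        value += quad(integrand, 0.0, u_max, limit=400)[0]
    return params.beta * value / tau_m


# ---------------------------------------------------------------------------
# Full shoot simulation
# ---------------------------------------------------------------------------

def _cumtrapz0(y: np.ndarray, ds: float) -> np.ndarray:
    """Cumulative trapezoid with a leading zero (curvature -> angle)."""
    out = np.empty_like(y)
    out[0] = 0.0
    np.cumsum(0.5 * ds * (y[1:] + y[:-1]), out=out[1:])
    return out


def default_time_step(params: ModelParameters, g_eff: float | None = None) -> float:
    """Default integration step: min(tau_aval, tau_memory)/20, shortened
    so that an integer number of steps spans the reaction delay."""
    g = params.g_eff if g_eff is None else g_eff
    dt = min(params.tau_aval_ref / g, params.tau_memory) / 20.0
    if params.tau_reaction > 0:
        dt = params.tau_reaction / math.ceil(params.tau_reaction / dt)
    return dt


def simulate_shoot(params: ModelParameters, protocol: StimulusProtocol,
                   n_nodes: int = 64, dt: float | None = None,
                   store_states: bool = False,
                   snapshot_every: int = 200) -> TipTrajectory:
    """Simulate the full shoot model for an arbitrary stimulation protocol.

    Fields are discretized on ``n_nodes`` points along [0, L]; curvature is
    mapped to local inclination by cumulative trapezoid integration, and
    the coupled system is advanced with a fixed-step RK4 scheme. The
    delayed pile angle is read from a ring buffer of past fields with
    linear interpolation at ``t - tau_reaction`` (pre-simulation history is
    the vertical equilibrium, all fields zero).

    Returns a :class:`TipTrajectory` whose ``theta_tip`` is the local
    inclination at s = L in degrees; snapshots of the spatial fields are
    attached to ``meta['states']`` when ``store_states`` is true.

    Raises :class:`NumericalStabilityError` naming the offending step if
    the fields blow up.
    """
    if n_nodes < 2:
        raise InvalidParameterError("n_nodes must be >= 2")
    g_eff = protocol.g_eff if protocol.g_eff is not None else params.g_eff
    tau_aval = params.tau_aval_ref / g_eff
    h = default_time_step(params, g_eff) if dt is None else float(dt)
    if h <= 0:
        raise InvalidParameterError(f"dt must be > 0, got {h!r}")
    n_steps = int(math.ceil(protocol.duration / h))
    tau_r = params.tau_reaction
    m_delay = int(round(tau_r / h)) if tau_r > 0 else 0
    if tau_r > 0 and not math.isclose(m_delay * h, tau_r, rel_tol=1e-9):
        # non-commensurate step: fall back to interpolation between rows
        m_delay = int(math.floor(tau_r / h))
    if tau_r > 0 and m_delay < 1:
        raise InvalidParameterError(
            f"dt={h} exceeds tau_reaction={tau_r}; refine the time step")

    logger.info("simulate_shoot: dt=%.6g min, %d steps, %d nodes, g_eff=%g",
                h, n_steps, n_nodes, g_eff)

    s_grid = np.linspace(0.0, params.L, n_nodes)
    ds = s_grid[1] - s_grid[0]
    C = np.zeros(n_nodes)        # 1/mm
    G = np.zeros(n_nodes)        # dimensionless
    S = np.zeros(n_nodes)        # rad, pile angle

    buf_len = m_delay + 3
    hist = np.zeros((buf_len, n_nodes))  # ring buffer of S fields
    theta_tip = np.empty(n_steps + 1)
    theta_base = np.empty(n_steps + 1)
    t_out = np.arange(n_steps + 1) * h
    theta_base[:] = protocol.base_angle_deg(t_out)
    theta_tip[0] = theta_base[0]
    states: list[ShootState] = []

    inv_tau_m = 1.0 / params.tau_memory
    inv_tau_a = 1.0 / tau_aval
    c_coef = -1.0 / (params.R * params.tau_growth)
    beta = params.beta

    def delayed_S(t_q: float) -> np.ndarray | float:
        """Pile-angle field at time t_q from the ring buffer (0 before t=0)."""
        if tau_r == 0:
            raise AssertionError("delayed_S unused when tau_reaction == 0")
        if t_q <= 0.0:
            return 0.0
        x = t_q / h
        k0 = int(math.floor(x))
        w = x - k0
        row0 = hist[k0 % buf_len]
        if w == 0.0:
            return row0
        return (1.0 - w) * row0 + w * hist[(k0 + 1) % buf_len]

    def rhs(t_q, C_q, G_q, S_q, S_del):
        a_stem = protocol.base_angle_rad(t_q) + _cumtrapz0(C_q, ds)
        dC = c_coef * G_q
        if tau_r > 0:
            drive = np.sin(S_del) if isinstance(S_del, np.ndarray) else math.sin(S_del)
        else:
            drive = np.sin(S_q)
        dG = inv_tau_m * (beta * drive - G_q)
        dS = -inv_tau_a * np.sin(S_q - a_stem)
        return dC, dG, dS

    for k in range(n_steps):
        t = k * h
        hist[k % buf_len] = S
        if tau_r > 0:
            d0 = delayed_S(t - tau_r)
            d1 = delayed_S(t + 0.5 * h - tau_r)
            d2 = delayed_S(t + h - tau_r)
        else:
            d0 = d1 = d2 = None
        k1 = rhs(t, C, G, S, d0)
        k2 = rhs(t + 0.5 * h, C + 0.5 * h * k1[0], G + 0.5 * h * k1[1],
                 S + 0.5 * h * k1[2], d1)
        k3 = rhs(t + 0.5 * h, C + 0.5 * h * k2[0], G + 0.5 * h * k2[1],
                 S + 0.5 * h * k2[2], d1)
        k4 = rhs(t + h, C + h * k3[0], G + h * k3[1], S + h * k3[2], d2)
        C = C + (h / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        G = G + (h / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        S = S + (h / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])

        t_next = (k + 1) * h
        a_stem = protocol.base_angle_rad(t_next) + _cumtrapz0(C, ds)
        theta_tip[k + 1] = math.degrees(a_stem[-1])
        if (k + 1) % 512 == 0 or k + 1 == n_steps:
            if not (np.isfinite(C[-1]) and abs(a_stem[-1]) < 20.0):
                raise NumericalStabilityError(
                    f"field blow-up at t={t_next:.3g} min with dt={h:.6g} min; "
                    "reduce the time step")
        if store_states and ((k + 1) % snapshot_every == 0 or k + 1 == n_steps):
            states.append(ShootState(t=t_next, s_grid=s_grid.copy(), C=C.copy(),
                                     A_stem=a_stem.copy(), A_stato=S.copy(),
                                     G_s=G.copy()))

    meta = {"params": params, "protocol": protocol, "dt": h,
            "n_nodes": n_nodes, "g_eff": g_eff}
    if store_states:
        meta["states"] = states
    return TipTrajectory(t=t_out, theta_tip=theta_tip, theta_base=theta_base,
                         meta=meta)


def simulate_tip_reduced(params: ModelParameters, protocol: StimulusProtocol,
                         dt: float | None = None) -> TipTrajectory:
    """Simulate the tip-angle reduction of the model (uniform curvature).

    Approximating the curvature as homogeneous, ``C ~ theta_tip / L``,
    collapses the spatial fields to three scalars at the tip:

        d(theta_tip)/dt = -G_s / (beta * tau*_growth)
        dG_s/dt         =  (beta * sin(A_stato(t - tau_reaction)) - G_s) / tau_memory
        dA_stato/dt     = -sin(A_stato - theta_tip) / tau_aval

    with ``tau*_growth = tau_growth * R / (beta * L)``. This is the
    reduction behind the asymptotic regime formulas; in the slow-avalanche
    (growth-limited) limit with a fast memory it admits the closed-form
    oscillation ``theta_tip = theta_incl * cos(t / sqrt(tau*_growth *
    tau_aval))``. It is accurate while the curvature stays close to
    uniform, i.e. during the first rising phase of the response; the full
    spatial model departs from it once bending is large.
    """
    g_eff = protocol.g_eff if protocol.g_eff is not None else params.g_eff
    tau_aval = params.tau_aval_ref / g_eff
    h = default_time_step(params, g_eff) if dt is None else float(dt)
    if h <= 0:
        raise InvalidParameterError(f"dt must be > 0, got {h!r}")
    tau_r = params.tau_reaction
    if tau_r > 0 and h > tau_r:
        raise InvalidParameterError(
            f"dt={h} exceeds tau_reaction={tau_r}; refine the time step")
    n_steps = int(math.ceil(protocol.duration / h))
    t_out = np.arange(n_steps + 1) * h
    base = protocol.base_angle_rad(t_out)
    tau_s = params.tau_growth_star
    inv_tau_m = 1.0 / params.tau_memory
    beta = params.beta

    hist = np.zeros(n_steps + 1)  # A_stato history for the delayed drive
    theta = np.empty(n_steps + 1)
    # tip angle follows rigid base rotations instantaneously; the dynamic
    # state is the bending theta - base
    bend = 0.0
    g_s = 0.0
    s_ang = 0.0
    theta[0] = math.degrees(base[0])

    def s_delayed(t_q: float) -> float:
        if tau_r == 0:
            return s_ang
        tq = t_q - tau_r
        if tq <= 0:
            return 0.0
        x = tq / h
        k0 = int(math.floor(x))
        w = x - k0
        k1 = min(k0 + 1, n_steps)
        return (1.0 - w) * hist[k0] + w * hist[k1]

    for k in range(n_steps):
        t = k * h

        def f(b, g, s, t_q):
            drive = math.sin(s if tau_r == 0 else s_delayed(t_q))
            th_tip = float(protocol.base_angle_rad(t_q)) + b
            return (-g / (beta * tau_s),
                    inv_tau_m * (beta * drive - g),
                    -math.sin(s - th_tip) / tau_aval)

        k1 = f(bend, g_s, s_ang, t)
        k2 = f(bend + 0.5 * h * k1[0], g_s + 0.5 * h * k1[1],
               s_ang + 0.5 * h * k1[2], t + 0.5 * h)
        k3 = f(bend + 0.5 * h * k2[0], g_s + 0.5 * h * k2[1],
               s_ang + 0.5 * h * k2[2], t + 0.5 * h)
        k4 = f(bend + h * k3[0], g_s + h * k3[1], s_ang + h * k3[2], t + h)
        bend += (h / 6.0) * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        g_s += (h / 6.0) * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        s_ang += (h / 6.0) * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        hist[k + 1] = s_ang
        theta[k + 1] = math.degrees(base[k + 1] + bend)
        if not math.isfinite(bend) or abs(bend) > 20.0:
            raise NumericalStabilityError(
                f"tip-reduced blow-up at t={t + h:.3g} min with dt={h:.6g} min")

    return TipTrajectory(t=t_out, theta_tip=theta,
                         theta_base=np.rad2deg(base),
                         meta={"params": params, "protocol": protocol,
                               "dt": h, "reduced": True, "g_eff": g_eff})
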