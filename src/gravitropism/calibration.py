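"""Parameter estimation from angle time series.

Two fitted models are exposed in a Model/Results style: an exponential
relaxation model for the statolith pile angle (estimating the avalanche
time), and a dose-response model that refits the gravitropic gain and the
memory time by repeated full-model simulation. A threshold-based onset
detector recovers the reaction delay, and a recovery report summarizes
parameter-recovery simulation studies.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import AvalancheTrace, TipTrajectory
from .errors import ContractError, InvalidParameterError
from .metrics import dose_response_curve, DoseResponseCurve, gravitropic_sensitivity
from .params import ModelParameters

logger = logging.getLogger(__name__)

__all__ = ["FitResult", "AvalancheRelaxationModel", "DoseResponseModel",
           "fit_avalanche_tau", "detect_reaction_time", "fit_dose_response",
           "recovery_report"]


@dataclass
class FitResult:
    """Estimates, uncertainties and diagnostics of one fit.

    ``estimates`` maps parameter names to values (time scales in minutes);
    ``stderr`` holds Gauss-Newton standard errors where available. A fit
    with ``converged=False`` must not be used downstream.
    """

    estimates: dict
    residual_norm: float
    converged: bool
    n_points: int
    method: str
    stderr: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Fit method: {self.method}",
                 f"Converged: {self.converged}   n = {self.n_points}   "
                 f"residual norm = {self.residual_norm:.4g}",
                 f"{'parameter':<14}{'estimate':>12}{'std err':>12}"]
        for name, value in self.estimates.items():
            se = self.stderr.get(name)
            se_s = f"{se:12.4g}" if se is not None else f"{'--':>12}"
            lines.append(f"{name:<14}{value:12.6g}{se_s}")
        for key, val in self.flags.items():
            lines.append(f"flag: {key} = {val}")
        return "\n".join(lines)


def _gn_stderr(res, names: list[str]) -> dict:
    """Standard errors from the Gauss-Newton approximation of the Hessian."""
    try:
        m, n = res.jac.shape
        if m <= n:
            return {}
        s2 = 2.0 * res.cost / (m - n)
        cov = s2 * np.linalg.inv(res.jac.T @ res.jac)
        return {name: float(math.sqrt(cov[i, i])) for i, name in enumerate(names)}
    except np.linalg.LinAlgError:
        return {}


# ---------------------------------------------------------------------------
# Avalanche time
# ---------------------------------------------------------------------------

class AvalancheRelaxationModel:
    """Saturating-exponential model of the pile-angle relaxation.

    Fits ``A_stato(t) = A_stem * (1 - exp(-t/tau))`` to a relaxation
    trace by nonlinear least squares, the exponential surrogate used to
    calibrate the avalanche time. The initial guess comes from a
    log-linear regression on the free-surface angle psi(t).
    """

    def __init__(self, trace: AvalancheTrace):
        self.trace = trace
        self.t = np.asarray(trace.t, dtype=float)
        self.a_stato = np.asarray(trace.A_stato, dtype=float)
        self.a_stem = float(np.median(np.asarray(trace.A_stem, dtype=float)))
        if self.t.size < 3:
            raise InvalidParameterError("trace too short to fit (need >= 3 points)")

    def _initial_tau(self) -> float:
        psi = self.a_stem - self.a_stato
        mask = psi > max(0.02 * abs(self.a_stem), 1e-6)
        if mask.sum() < 2:
            return max(float(self.t[-1]) / 3.0, 1e-6)
        slope = np.polyfit(self.t[mask], np.log(psi[mask]), 1)[0]
        if slope >= 0:
            return max(float(self.t[-1]) / 3.0, 1e-6)
        return -1.0 / slope

    def fit(self) -> FitResult:
        spread = np.ptp(self.a_stato)
        if spread < max(1e-9, 1e-6 * abs(self.a_stem)):
            return FitResult(estimates={"tau_aval": math.nan},
                             residual_norm=math.nan, converged=False,
                             n_points=self.t.size, method="exp-least-squares",
                             flags={"reason": "flat trace"})
        tau0 = self._initial_tau()

        def resid(logtau):
            tau = math.exp(logtau[0])
            return self.a_stem * (1.0 - np.exp(-self.t / tau)) - self.a_stato

        res = least_squares(resid, x0=[math.log(tau0)], xtol=1e-12, ftol=1e-12)
        tau_hat = math.exp(res.x[0])
        # delta-method back-transform of the log-scale standard error
        se_log = _gn_stderr(res, ["log_tau"]).get("log_tau")
        stderr = {"tau_aval": tau_hat * se_log} if se_log is not None else {}
        return FitResult(estimates={"tau_aval": tau_hat},
                         residual_norm=float(np.linalg.norm(res.fun)),
                         converged=bool(res.success),
                         n_points=self.t.size, method="exp-least-squares",
                         stderr=stderr,
                         flags={"initial_tau": tau0})


def fit_avalanche_tau(trace: AvalancheTrace) -> FitResult:
    """Estimate the avalanche time from one relaxation trace."""
    return AvalancheRelaxationModel(trace).fit()


# ---------------------------------------------------------------------------
# Reaction delay
# ---------------------------------------------------------------------------

def detect_reaction_time(traj: TipTrajectory, threshold: float | None = None,
                         min_consecutive: int = 2,
                         smooth_window: int | None = None) -> float | None:
    """First time the bending rate persistently exceeds a threshold.

    The counter-bending response is differentiated by centered
    differences; the onset is the first sample whose absolute rate
    (deg/min) exceeds ``threshold`` for ``min_consecutive`` consecutive
    samples. The default threshold is 5% of the peak rate; a vanishing
    threshold on noiseless model output returns the reaction delay
    exactly, because the response is identically zero before it.

    For noisy input pass an odd ``smooth_window`` (Savitzky-Golay) and a
    threshold above the rate estimate's noise floor, roughly
    ``noise_sd * sqrt(2) / (2 * sampling_interval)`` before smoothing.
    Any positive threshold detects late by the time the true rate needs
    to reach it (of order tau_memory); the detector never fires before
    the delay once false alarms are controlled. Returns ``None`` when no
    crossing occurs.
    """
    bend = traj.bending
    if smooth_window is not None and smooth_window >= 5:
        from scipy.signal import savgol_filter
        bend = savgol_filter(bend, smooth_window, 2)
    rate = np.abs(np.gradient(bend, traj.t))
    peak = float(rate.max())
    if peak == 0.0:
        return None
    thr = 0.05 * peak if threshold is None else float(threshold)
    above = rate > thr
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_consecutive:
            return float(traj.t[i - min_consecutive + 1])
    return None


# ---------------------------------------------------------------------------
# Dose-response refit
# ---------------------------------------------------------------------------

class DoseResponseModel:
    """Refit (beta, tau_memory) to an observed dose-response curve.

    Every residual evaluation re-simulates the full model over the
    curve's stimulation durations, exactly as the calibration procedure
    prescribes; the remaining parameters are held fixed. Optimization is
    least squares on (log beta, log tau_memory) with multi-start over
    log-spaced memory times.
    """

    def __init__(self, curve: DoseResponseCurve, params_fixed: ModelParameters,
                 n_nodes: int = 48, n_starts: int = 3,
                 time_step: float | None = None):
        if len(curve.points) < 2:
            raise InvalidParameterError("dose-response curve needs >= 2 points")
        self.curve = curve
        self.params_fixed = params_fixed
        self.n_nodes = n_nodes
        self.n_starts = n_starts
        self.time_step = time_step

    def _residuals(self, x) -> np.ndarray:
        beta, tau_m = math.exp(x[0]), math.exp(x[1])
        p = self.params_fixed.replace(beta=beta, tau_memory=tau_m)
        model = dose_response_curve(p, self.curve.dt,
                                    theta_incl=self.curve.theta_incl,
                                    g_eff=float(self.curve.points["g_eff"].iloc[0]),
                                    n_nodes=self.n_nodes,
                                    time_step=self.time_step)
        return model.beta_tilde - self.curve.beta_tilde

    def fit(self) -> FitResult:
        observed = self.curve.beta_tilde
        plateau = float(np.max(observed))
        if plateau <= 0:
            raise InvalidParameterError("dose-response curve has no response")
        beta0 = plateau
        tau_starts = np.geomspace(3.0, 40.0, self.n_starts)
        best = None
        for tau0 in tau_starts:
            res = least_squares(self._residuals,
                                x0=[math.log(beta0), math.log(tau0)],
                                xtol=1e-8, ftol=1e-10, diff_step=1e-4)
            if best is None or res.cost < best.cost:
                best = res
            if best.cost < (1e-5 * plateau) ** 2:
                break
        beta_hat, tau_hat = math.exp(best.x[0]), math.exp(best.x[1])
        se_log = _gn_stderr(best, ["log_beta", "log_tau_memory"])
        stderr = {}
        if se_log:
            stderr = {"beta": beta_hat * se_log["log_beta"],
                      "tau_memory": tau_hat * se_log["log_tau_memory"]}
        flags = {}
        # plateau degeneracy: curve carries no information about tau_memory
        # when even its shortest stimulation is already saturated
        if float(np.min(observed)) > 0.95 * plateau:
            flags["tau_memory_identifiable"] = False
            warnings.warn("all dose-response points on the plateau: "
                          "tau_memory is not identifiable", stacklevel=2)
        return FitResult(estimates={"beta": beta_hat, "tau_memory": tau_hat},
                         residual_norm=float(np.linalg.norm(best.fun)),
                         converged=bool(best.success),
                         n_points=len(observed),
                         method="dose-response-least-squares",
                         stderr=stderr, flags=flags)


def fit_dose_response(curve: DoseResponseCurve,
                      params_fixed: ModelParameters, **kwargs) -> FitResult:
    """Refit the gain and memory time to a dose-response curve."""
    return DoseResponseModel(curve, params_fixed, **kwargs).fit()


# ---------------------------------------------------------------------------
# Recovery summaries
# ---------------------------------------------------------------------------

def recovery_report(generating: list[ModelParameters] | ModelParameters,
                    fitted: list[FitResult]) -> pd.DataFrame:
    """Bias and RMSE of fitted parameters against their generators.

    ``generating`` is either one parameter set shared by all fits or a
    list matched one-to-one with ``fitted``. Only parameters present in
    the fit estimates are reported.
    """
    if not fitted:
        raise ContractError("empty fit ensemble")
    if isinstance(generating, ModelParameters):
        generating = [generating] * len(fitted)
    if len(generating) != len(fitted):
        raise ContractError(
            f"{len(generating)} generators for {len(fitted)} fits")
    rows = []
    names = sorted({k for f in fitted for k in f.estimates})
    for name in names:
        pairs = [(getattr(g, name if name != "tau_aval" else "tau_aval_ref"),
                  f.estimates[name])
                 for g, f in zip(generating, fitted)
                 if f.converged and name in f.estimates]
        if not pairs:
            continue
        true = np.array([p[0] for p in pairs])
        est = np.array([p[1] for p in pairs])
        err = est - true
        rows.append({"parameter": name, "n": len(pairs),
                     "true_mean": true.mean(), "estimate_mean": est.mean(),
                     "bias": err.mean(),
                     "relative_bias": float((err / true).mean()),
                     "rmse": float(np.sqrt((err ** 2).mean()))})
    return pd.DataFrame(rows)
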