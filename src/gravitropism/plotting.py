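"""Matplotlib views of trajectories, dose-response curves and the phase
diagram. All functions take and return an Axes so they compose."""

from __future__ import annotations

import numpy as np

from .core import TipTrajectory
from .metrics import DoseResponseCurve, PhaseDiagram, Regime


def plot_trajectory(traj: TipTrajectory, ax=None, label=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(traj.t, traj.theta_tip - traj.theta_base, label=label)
    ax.set_xlabel("time (min)")
    ax.set_ylabel(r"$\theta_{tip} - \theta_{base}$ (deg)")
    if label:
        ax.legend()
    return ax


def plot_dose_response(curve: DoseResponseCurve, ax=None, **kwargs):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.dt, curve.beta_tilde, marker="o", **kwargs)
    ax.set_xlabel(r"stimulation duration $\Delta t$ (min)")
    ax.set_ylabel(r"gravitropic sensitivity $\tilde\beta$")
    return ax


def plot_phase_diagram(diagram: PhaseDiagram, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    with np.errstate(divide="ignore"):
        z = np.log10(diagram.beta_tilde)
    mesh = ax.pcolormesh(diagram.tau_aval_axis, diagram.dt_axis, z,
                         shading="nearest")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel(r"$\tau_{aval}$ (min)")
    ax.set_ylabel(r"$\Delta t$ (min)")
    ax.figure.colorbar(mesh, ax=ax, label=r"$\log_{10}\tilde\beta$")
    return ax
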