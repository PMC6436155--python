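"""File I/O: delimited time-series tables, YAML configs, run manifests.

Conventions at every file boundary: comma-separated UTF-8 with a header
row, time in minutes (``t_min``), angles in degrees with a ``_deg``
suffix, gravity as a dimensionless multiple of Earth gravity.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import AvalancheTrace, TipTrajectory
from .params import ModelParameters
from .protocol import StimulusProtocol

TIP_COLUMNS = ["t_min", "theta_base_deg", "theta_tip_deg"]
AVALANCHE_COLUMNS = ["t_min", "A_stem_deg", "A_stato_deg", "psi_deg", "g_eff"]


class TimeseriesFormatError(ValueError):
    """A delimited time-series file violates the expected schema."""


def _validate_frame(df: pd.DataFrame, required: list[str], path) -> pd.DataFrame:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TimeseriesFormatError(f"{path}: missing columns {missing}")
    for col in required:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax())
            raise TimeseriesFormatError(
                f"{path}: non-numeric value in column '{col}' at row {row}")
        df[col] = coerced
    t = df["t_min"].to_numpy()
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise TimeseriesFormatError(
            f"{path}: time not strictly increasing at t_min={t[bad[0] + 1]} "
            f"(row {bad[0] + 1})")
    return df


def read_timeseries(path, kind: str):
    """Read a tip-trajectory or avalanche-trace CSV.

    ``kind`` is ``'tip'`` or ``'avalanche'``. Columns are unit-suffixed;
    time must strictly increase. Parse errors name the offending row and
    column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if kind == "tip":
        df = _validate_frame(df, TIP_COLUMNS, path)
        return TipTrajectory(t=df["t_min"].to_numpy(),
                             theta_tip=df["theta_tip_deg"].to_numpy(),
                             theta_base=df["theta_base_deg"].to_numpy(),
                             meta={"source": str(path)})
    if kind == "avalanche":
        df = _validate_frame(df, AVALANCHE_COLUMNS, path)
        return AvalancheTrace(t=df["t_min"].to_numpy(),
                              A_stato=df["A_stato_deg"].to_numpy(),
                              A_stem=df["A_stem_deg"].to_numpy(),
                              g_eff=float(df["g_eff"].iloc[0]),
                              meta={"source": str(path)})
    raise ValueError(f"unknown kind {kind!r}; expected 'tip' or 'avalanche'")


def write_trajectory(traj: TipTrajectory, path) -> None:
    pd.DataFrame({"t_min": traj.t, "theta_base_deg": traj.theta_base,
                  "theta_tip_deg": traj.theta_tip}).to_csv(path, index=False)


def write_avalanche(trace: AvalancheTrace, path) -> None:
    pd.DataFrame({"t_min": trace.t, "A_stem_deg": trace.A_stem,
                  "A_stato_deg": trace.A_stato, "psi_deg": trace.psi,
                  "g_eff": trace.g_eff}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configs and manifests
# ---------------------------------------------------------------------------

_MODEL_KEYS = {f.name for f in dataclasses.fields(ModelParameters)}
_PROTOCOL_KEYS = {"segments", "duration", "g_eff",
                  "theta_incl", "dt", "rest_before", "observe_after"}


def load_model_params(path) -> ModelParameters:
    """Load :class:`ModelParameters` from a YAML/JSON mapping.

    Keys mirror the field names (times in minutes, lengths in mm);
    unknown keys are rejected.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise TimeseriesFormatError(f"{path}: expected a mapping")
    unknown = set(doc) - _MODEL_KEYS
    if unknown:
        raise TimeseriesFormatError(f"{path}: unknown keys {sorted(unknown)}")
    return ModelParameters(**doc)


def load_protocol(path) -> StimulusProtocol:
    """Load a :class:`StimulusProtocol` from YAML/JSON.

    Either explicit ``segments`` (pairs of start-minute and base angle in
    degrees) with a ``duration``, or the transient shorthand
    ``theta_incl``/``dt``/``rest_before``/``observe_after``.
    """
    from .protocol import build_protocol

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise TimeseriesFormatError(f"{path}: expected a mapping")
    unknown = set(doc) - _PROTOCOL_KEYS
    if unknown:
        raise TimeseriesFormatError(f"{path}: unknown keys {sorted(unknown)}")
    if "segments" in doc:
        return StimulusProtocol(
            segments=tuple((float(t), float(a)) for t, a in doc["segments"]),
            duration=float(doc["duration"]), g_eff=doc.get("g_eff"))
    dt = doc.get("dt", 0.0)
    dt = float("inf") if dt in ("inf", "permanent") else float(dt)
    return build_protocol(theta_incl=float(doc.get("theta_incl", 0.0)), dt=dt,
                          rest_before=float(doc.get("rest_before", 0.0)),
                          observe_after=float(doc.get("observe_after", 600.0)),
                          g_eff=doc.get("g_eff"))


def write_manifest(path, **entries) -> None:
    """Write a JSON sidecar recording the resolved settings of a run."""
    from . import __version__

    def _clean(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return _clean(dataclasses.asdict(obj))
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    doc = {"tool": "gravitropism", "version": __version__}
    doc.update(_clean(entries))
    Path(path).write_text(json.dumps(doc, indent=2, default=str) + "\n")
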