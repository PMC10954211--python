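"""Fluorescence time-series statistics for trap screening experiments.

Traces are tidy DataFrames with columns ``time_min``, ``signal_au``,
``replicate`` and ``condition``.  The statistics mirror a plate-reader
screening workflow: normalisation to the untrapped No-KL control, fold
change over the no-keys sample at a fixed time after key addition,
percent activation against a full-activation reference, sliding-window
maximum rates, and Boolean gate classification of an activation map.

All statistics are invariant to uniform rescaling of the raw signal
(percent activation to any affine transform), so they are comparable
across instruments and gain settings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GateCall",
    "TRACE_COLUMNS",
    "normalize_to_control",
    "plateau_value",
    "fold_change",
    "percent_activation",
    "max_rate",
    "classify_gate",
    "mean_trace",
]

TRACE_COLUMNS = ("time_min", "signal_au", "replicate", "condition")

#: pre-addition plateau = mean of this many final pre-addition points
PLATEAU_POINTS = 3
#: default sliding window (points) for the maximum-rate estimator
RATE_WINDOW = 3


def _check_trace(df: pd.DataFrame) -> None:
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace is missing columns {missing}")


def mean_trace(df: pd.DataFrame, condition: str | None = None) -> pd.DataFrame:
    """Replicate-mean (+-SD) trace for one condition."""
    _check_trace(df)
    if condition is not None:
        df = df[df["condition"] == condition]
        if df.empty:
            raise ValueError(f"condition {condition!r} not present")
    g = df.groupby("time_min")["signal_au"]
    out = pd.DataFrame({"time_min": g.mean().index,
                        "signal_au": g.mean().to_numpy(),
                        "sd": g.std(ddof=1).fillna(0.0).to_numpy()})
    return out.reset_index(drop=True)


def plateau_value(df: pd.DataFrame, condition: str,
                  before: float | None = None,
                  n_points: int = PLATEAU_POINTS) -> float:
    """Mean plateau signal: the last ``n_points`` grid points of the
    condition's replicate-mean trace, restricted to times < ``before``
    (e.g. the key-addition time) when given."""
    m = mean_trace(df, condition)
    if before is not None:
        m = m[m["time_min"] < before]
    if len(m) < 1:
        raise ValueError("no points available for plateau estimate")
    return float(m["signal_au"].tail(n_points).mean())


def normalize_to_control(df: pd.DataFrame, control_condition: str = "No-KL",
                         before: float | None = None) -> pd.DataFrame:
    """Divide every signal by the control condition's mean plateau.

    The untrapped No-KL construct defines 1.0 on the normalised scale.
    """
    _check_trace(df)
    if control_condition not in set(df["condition"]):
        raise ValueError(f"control condition {control_condition!r} not present")
    ref = plateau_value(df, control_condition, before=before)
    if ref <= 0:
        raise ValueError("control plateau is not positive")
    out = df.copy()
    out["signal_au"] = out["signal_au"] / ref
    return out


def _value_at(df: pd.DataFrame, condition: str, t_eval: float) -> float:
    m = mean_trace(df, condition)
    t = m["time_min"].to_numpy()
    if not (t.min() - 1e-9 <= t_eval <= t.max() + 1e-9):
        raise ValueError(f"t_eval={t_eval} outside the measured grid "
                         f"[{t.min()}, {t.max()}]")
    return float(np.interp(t_eval, t, m["signal_au"].to_numpy()))


def fold_change(df: pd.DataFrame, condition: str, baseline_condition: str,
                t_eval: float) -> float:
    """Replicate-mean signal ratio condition / no-keys baseline at ``t_eval``.

    ``t_eval`` is an absolute time on the trace grid (pass key-addition
    time + 50 min for the standard screening statistic); values inside
    the grid are linearly interpolated.
    """
    num = _value_at(df, condition, t_eval)
    den = _value_at(df, baseline_condition, t_eval)
    if den == 0:
        raise ValueError("baseline signal is zero at t_eval")
    return num / den


def percent_activation(df: pd.DataFrame, condition: str,
                       no_keys_condition: str, full_condition: str,
                       t_eval: float) -> float:
    """Activation fraction (signal - no_keys) / (full - no_keys) at ``t_eval``.

    The full-activation reference is by default the both-keys condition
    of the same design (the trap only reaches full activation with both
    inputs); affine-invariant in the raw signal.  The raw (unclipped)
    fraction is returned.
    """
    s = _value_at(df, condition, t_eval)
    s0 = _value_at(df, no_keys_condition, t_eval)
    s1 = _value_at(df, full_condition, t_eval)
    if s1 <= s0:
        raise ValueError("full-activation reference does not exceed no-keys baseline")
    return (s - s0) / (s1 - s0)


def max_rate(trace: pd.DataFrame, window: int = RATE_WINDOW) -> float:
    """Maximum sliding-window least-squares slope of signal vs time (a.u./min).

    ``window`` consecutive points per fit; a 2-point window reduces to
    the maximum finite difference.
    """
    _check_trace(trace)
    m = mean_trace(trace)
    t = m["time_min"].to_numpy()
    s = m["signal_au"].to_numpy()
    if window < 2:
        raise ValueError("window must be at least 2 points")
    if len(t) < window:
        raise ValueError("trace shorter than the rate window")
    best = -np.inf
    for i in range(len(t) - window + 1):
        tw, sw = t[i:i + window], s[i:i + window]
        tc = tw - tw.mean()
        denom = (tc ** 2).sum()
        if denom == 0:
            continue
        best = max(best, float((tc * (sw - sw.mean())).sum() / denom))
    return best


@dataclass(frozen=True)
class GateCall:
    """Boolean gate classification of an activation map."""

    gate: str
    threshold: float
    activations: dict[str, float] = field(default_factory=dict)
    fold_changes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if self.gate not in ("AND", "OR", "none"):
            raise ValueError("gate must be AND, OR or none")


def classify_gate(activations: dict[str, float], threshold: float = 0.30,
                  fold_changes: dict[str, float] | None = None) -> GateCall:
    """Call the Boolean gate type from single-key / both-keys activations.

    AND: both single-key activations below ``threshold`` and the
    both-keys activation at least ``1 - threshold``; OR: any single key
    alone reaches ``1 - threshold``; otherwise none.  The 30% default
    threshold is the screening convention for the cooperative trap.
    """
    needed = {"A", "B", "AB"}
    if not needed <= set(activations):
        raise ValueError(f"activations must contain conditions {sorted(needed)}")
    a, b, ab = activations["A"], activations["B"], activations["AB"]
    hi = 1.0 - threshold
    if a >= hi or b >= hi:
        gate = "OR"
    elif a < threshold and b < threshold and ab >= hi:
        gate = "AND"
    else:
        gate = "none"
    return GateCall(gate=gate, threshold=threshold,
                    activations=dict(activations),
                    fold_changes=dict(fold_changes or {}))
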