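"""Ensemble summaries: mean activation, oscillation metrics, convergence.

Averaging the Boolean state of each node over many independent stochastic
runs gives a per-time activation probability in [0, 1].  In an oscillating
system, noise desynchronises the runs, so the ensemble mean appears as a
damped oscillation settling near the duty cycle of the deterministic limit
even though individual runs keep oscillating.  The metrics here quantify
that contrast:

* per-period amplitude (max − min of the mean trace within a period
  window) and phase (offset of the maximum, earliest on ties);
* convergence (trailing-window range below a tolerance) and the first
  time the window criterion holds;
* a desynchronization index 4·p·(1−p) that is 0 when all runs agree and 1
  at maximal disagreement.

Period windows are aligned to the deterministic reference cycle (detected
exactly, not estimated spectrally).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TrajectoryEnsemble

__all__ = [
    "EnsembleSummary",
    "ensemble_mean",
    "detect_cycle",
    "period_amplitude_phase",
    "oscillation_summary",
    "detect_convergence",
    "first_convergence_time",
    "desynchronization_index",
]


@dataclass
class EnsembleSummary:
    """Per-time per-node mean activation; ``frame`` is (steps+1) × nodes."""

    frame: pd.DataFrame

    def __post_init__(self):
        vals = self.frame.to_numpy()
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("ensemble means must lie in [0, 1]")

    def trace(self, node: str) -> np.ndarray:
        return self.frame[node].to_numpy()

    @property
    def n_steps(self) -> int:
        return len(self.frame) - 1


def ensemble_mean(ensemble: TrajectoryEnsemble) -> EnsembleSummary:
    """Arithmetic mean over runs per (time, node)."""
    frame = pd.DataFrame(ensemble.mean(), columns=ensemble.nodes)
    frame.index.name = "time"
    return EnsembleSummary(frame)


def detect_cycle(trajectory: np.ndarray) -> tuple[int, int]:
    """First recurrence of a full state in a deterministic trajectory.

    Returns ``(start, period)``: the trajectory satisfies
    ``x[t + period] == x[t]`` for all ``t >= start``.  Raises if no state
    recurs within the trajectory.
    """
    seen: dict[bytes, int] = {}
    for t in range(trajectory.shape[0]):
        key = np.asarray(trajectory[t], dtype=bool).tobytes()
        if key in seen:
            return seen[key], t - seen[key]
        seen[key] = t
    raise ValueError("no cycle detected within the trajectory")


def period_amplitude_phase(
    summary: EnsembleSummary,
    node: str,
    period_length: int,
    period_index: int,
    start: int = 0,
) -> tuple[float, int]:
    """Amplitude and phase of one period window of a node's mean trace.

    Window ``period_index`` (1-based) covers steps
    ``[start + (period_index-1)·L, start + period_index·L)``.  Amplitude is
    max − min within the window; phase is the offset of the maximum
    (earliest on ties).
    """
    if period_index < 1:
        raise ValueError("period_index is 1-based")
    if period_length < 1:
        raise ValueError("period_length must be >= 1")
    lo = start + (period_index - 1) * period_length
    hi = lo + period_length
    trace = summary.trace(node)
    if hi > trace.shape[0]:
        raise ValueError(
            f"period window [{lo}, {hi}) exceeds series length {trace.shape[0]}"
        )
    window = trace[lo:hi]
    amplitude = float(window.max() - window.min())
    phase = int(np.argmax(window))
    return amplitude, phase


def oscillation_summary(
    summary: EnsembleSummary,
    nodes: list[str],
    period_length: int,
    n_periods: int,
    start: int = 0,
) -> pd.DataFrame:
    """Long-format per-node per-period amplitude/phase table."""
    records = []
    for node in nodes:
        for p in range(1, n_periods + 1):
            amp, phase = period_amplitude_phase(summary, node, period_length, p, start)
            records.append({"node": node, "period": p, "amplitude": amp, "phase": phase})
    return pd.DataFrame.from_records(records)


def detect_convergence(
    summary: EnsembleSummary,
    node: str,
    tolerance: float = 0.05,
    window: int = 50,
) -> tuple[bool, float]:
    """Trailing-window convergence check.

    Converged when max − min of the node's mean trace over the final
    ``window`` steps is at most ``tolerance``; the level is the
    trailing-window mean.
    """
    trace = summary.trace(node)
    if window > trace.shape[0]:
        raise ValueError(f"window {window} exceeds series length {trace.shape[0]}")
    tail = trace[-window:]
    return bool(tail.max() - tail.min() <= tolerance), float(tail.mean())


def first_convergence_time(
    summary: EnsembleSummary,
    node: str,
    tolerance: float = 0.05,
    window: int = 50,
) -> int | None:
    """Smallest t such that max − min over [t, t + window) is within
    tolerance; None if the trace never settles."""
    trace = summary.trace(node)
    if window > trace.shape[0]:
        raise ValueError(f"window {window} exceeds series length {trace.shape[0]}")
    view = np.lib.stride_tricks.sliding_window_view(trace, window)
    spans = view.max(axis=1) - view.min(axis=1)
    hits = np.nonzero(spans <= tolerance)[0]
    return int(hits[0]) if hits.size else None


def desynchronization_index(ensemble: TrajectoryEnsemble, node: str, t: int) -> float:
    """Cross-run disagreement 4·p·(1−p) at (t, node); 0 = all runs agree."""
    if ensemble.runs < 2:
        raise ValueError("desynchronization index needs >= 2 runs")
    col = ensemble.nodes.index(node)
    p = float(ensemble.values[:, t, col].mean())
    return 4.0 * p * (1.0 - p)
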