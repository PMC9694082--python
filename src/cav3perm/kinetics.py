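"""Monoexponential fitting of activation, inactivation and deactivation.

The model is I(t) = A exp(-(t - t0)/tau) + C over a user- or auto-selected
window; t0 is the window start.  Initial values come from a log-linear
regression on |I - C_hat| with C_hat the terminal mean, which makes the
nonlinear refinement robust on clean traces and honest about failure on
pathological ones (fits never fail silently: ``converged`` is part of the
result).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .sweeps import SweepSet

__all__ = ["KineticsFit", "DegenerateTraceError", "fit_monoexponential", "auto_window"]

PHASES = ("activation", "inactivation", "deactivation")
MAX_ITERATIONS = 500
PARAM_TOL = 1e-8


class DegenerateTraceError(ValueError):
    """Trace is flat (or otherwise uninformative) within the fit window."""


@dataclass
class KineticsFit:
    """Result of one monoexponential fit."""

    tau_ms: float
    amplitude_pA: float
    offset_pA: float
    phase: str
    window_ms: tuple[float, float]
    rss_pA2: float
    converged: bool
    message: str = ""


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(A, tau, C) from log-linear regression on |y - terminal mean|."""
    n_tail = max(3, t.size // 10)
    c0 = float(np.mean(y[-n_tail:]))
    resid = y - c0
    a0 = float(resid[0])
    mag = np.abs(resid)
    usable = mag > 1e-3 * mag.max()
    if usable.sum() >= 2:
        slope, logint = np.polyfit(t[usable] - t[0], np.log(mag[usable]), 1)
        if slope < 0:
            tau0 = -1.0 / slope
            a0 = float(np.sign(a0 if a0 != 0 else 1.0) * np.exp(logint))
            return a0, tau0, c0
    # fall back to a third of the window
    return a0, max((t[-1] - t[0]) / 3.0, 1e-3), c0


def fit_monoexponential(
    trace,
    time_ms,
    window_ms: tuple[float, float],
    phase: str = "inactivation",
) -> KineticsFit:
    """Least-squares monoexponential fit over ``window_ms``.

    Growing phases (activation) naturally fit with A of opposite sign to the
    plateau offset.  Raises :class:`DegenerateTraceError` on flat traces;
    non-convergence is reported via ``converged=False``, never dropped.
    """
    if phase not in PHASES:
        raise ValueError(f"phase must be one of {PHASES}")
    trace = np.asarray(trace, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    lo, hi = window_ms
    sel = (time_ms >= lo) & (time_ms <= hi)
    t, y = time_ms[sel], trace[sel]
    if t.size < 10:
        raise ValueError(f"fit window must contain >= 10 samples, has {t.size}")
    spread = float(np.ptp(y))
    if spread < 1e-12 * max(1.0, float(np.max(np.abs(y)))) or spread == 0.0:
        raise DegenerateTraceError("flat trace in fit window")

    t0 = t[0]
    a0, tau0, c0 = _initial_guess(t, y)

    def residuals(p):
        a, log_tau, c = p
        return a * np.exp(-(t - t0) / np.exp(log_tau)) + c - y

    result = least_squares(
        residuals,
        x0=[a0, np.log(tau0), c0],
        method="lm",
        xtol=PARAM_TOL,
        ftol=PARAM_TOL,
        gtol=PARAM_TOL,
        max_nfev=MAX_ITERATIONS,
    )
    a, log_tau, c = result.x
    tau = float(np.exp(log_tau))
    rss = float(np.sum(result.fun**2))
    return KineticsFit(
        tau_ms=tau,
        amplitude_pA=float(a),
        offset_pA=float(c),
        phase=phase,
        window_ms=(float(lo), float(hi)),
        rss_pA2=rss,
        converged=bool(result.success),
        message=result.message,
    )


def auto_window(
    sweeps: SweepSet,
    step_mV: float,
    phase: str,
    guard_ms: float = 2.0,
) -> tuple[float, float]:
    """Default fit window from protocol metadata and the peak time.

    Inactivation: [peak time, step end].  Activation: [step onset + guard,
    peak time].  Deactivation requires an explicit window (repolarization
    epochs are not part of the standard step protocol).
    """
    from .permeability import peak_current  # local import to avoid a cycle

    if phase == "deactivation":
        raise ValueError("deactivation windows must be given explicitly")
    proto = sweeps.metadata.get("protocol")
    if not proto:
        raise ValueError("auto windows need protocol metadata")
    onset = float(proto["baseline_ms"])
    step_end = onset + float(proto["step_duration_ms"])
    _, t_peak = peak_current(
        sweeps.trace(step_mV), sweeps.time_ms, (onset + guard_ms, step_end), "auto"
    )
    if phase == "inactivation":
        return (t_peak, step_end)
    return (onset + guard_ms, t_peak)
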