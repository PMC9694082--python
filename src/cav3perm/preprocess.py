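"""Trace conditioning: 500 Hz Gaussian filtering and offline leak subtraction.

Both transforms are linear, so their order does not matter (a property the
test suite checks).  The Gaussian filter uses the -3 dB cutoff convention
common to electrophysiology acquisition suites: the kernel's standard
deviation in time is sigma_t = sqrt(ln 2)/(2 pi f_c), so the amplitude
response at f_c is exactly 1/sqrt(2).  The leak model is an ordinary
least-squares line fitted to steady-state currents of subthreshold sweeps,
where a T-type conductance is closed and only the ohmic background remains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .sweeps import SweepSet

__all__ = [
    "LeakModel",
    "gaussian_filter",
    "filter_sweepset",
    "estimate_leak",
    "subtract_leak",
    "preprocess",
]

GAUSSIAN_TRUNCATE_SIGMAS = 4.0
STEADY_STATE_WINDOW_MS = 5.0  # final 5 ms of the step
DEFAULT_SUBTHRESHOLD_RANGE = (-110.0, -90.0)


@dataclass
class LeakModel:
    """Ohmic background: conductance (nS), reversal (mV), fit provenance."""

    conductance_nS: float
    reversal_mV: float
    fit_voltages_mV: list[float] = field(default_factory=list)
    residual_rms_pA: float = 0.0
    reversal_defined: bool = True

    def current_pA(self, v_mV):
        return self.conductance_nS * (np.asarray(v_mV, dtype=float) - self.reversal_mV)


def gaussian_filter(trace, sampling_rate_hz: float, cutoff_hz: float = 500.0) -> np.ndarray:
    """Low-pass a trace with a unit-area Gaussian kernel (-3 dB at ``cutoff_hz``).

    Kernel truncated at +/-4 sigma with reflection padding; the output has
    the same length as the input.  Raises if the cutoff reaches Nyquist.
    """
    if not cutoff_hz < sampling_rate_hz / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist ({sampling_rate_hz / 2} Hz)"
        )
    sigma_t_s = math.sqrt(math.log(2.0)) / (2.0 * math.pi * cutoff_hz)
    sigma_samples = sigma_t_s * sampling_rate_hz
    return gaussian_filter1d(
        np.asarray(trace, dtype=float),
        sigma=sigma_samples,
        mode="reflect",
        truncate=GAUSSIAN_TRUNCATE_SIGMAS,
    )


def _sampling_rate(sweeps: SweepSet) -> float:
    proto = sweeps.metadata.get("protocol")
    if proto and "sampling_rate_hz" in proto:
        return float(proto["sampling_rate_hz"])
    dt = np.diff(sweeps.time_ms)
    return 1e3 / float(np.median(dt))


def filter_sweepset(sweeps: SweepSet, cutoff_hz: float = 500.0) -> SweepSet:
    """Gaussian-filter every trace; edge-affected span recorded in history."""
    fs = _sampling_rate(sweeps)
    filtered = {v: gaussian_filter(tr, fs, cutoff_hz) for v, tr in sweeps.traces.items()}
    sigma_t_ms = 1e3 * math.sqrt(math.log(2.0)) / (2.0 * math.pi * cutoff_hz)
    return sweeps.with_traces(
        filtered,
        {
            "op": "gaussian_filter",
            "cutoff_hz": cutoff_hz,
            "convention": "-3 dB amplitude at cutoff",
            "edge_affected_ms": GAUSSIAN_TRUNCATE_SIGMAS * sigma_t_ms,
        },
    )


def _step_window_samples(sweeps: SweepSet) -> tuple[float, float]:
    """(baseline_ms, step_end_ms) from metadata, else inferred from time base."""
    proto = sweeps.metadata.get("protocol")
    if proto:
        base = float(proto["baseline_ms"])
        return base, base + float(proto["step_duration_ms"])
    return 0.0, float(sweeps.time_ms[-1])


def estimate_leak(
    sweeps: SweepSet,
    subthreshold_range: tuple[float, float] = DEFAULT_SUBTHRESHOLD_RANGE,
) -> LeakModel:
    """OLS fit of steady-state current vs step voltage over subthreshold sweeps.

    Steady-state current is the mean over the final 5 ms of the step.
    Conductance is the slope (nS); reversal is -intercept/slope, reported as
    0 with ``reversal_defined=False`` when the slope is ~0.
    """
    lo, hi = min(subthreshold_range), max(subthreshold_range)
    base_ms, end_ms = _step_window_samples(sweeps)
    sel = (sweeps.time_ms >= end_ms - STEADY_STATE_WINDOW_MS) & (sweeps.time_ms <= end_ms)
    if not np.any(sel):
        raise ValueError("steady-state window is empty; check protocol metadata")

    volts, currents = [], []
    for v in sorted(sweeps.traces):
        if lo <= v <= hi:
            volts.append(v)
            currents.append(float(np.mean(sweeps.traces[v][sel])))
    if len(set(volts)) < 2:
        raise ValueError(
            f"need >= 2 distinct subthreshold step voltages in [{lo}, {hi}] mV, "
            f"found {sorted(set(volts))}"
        )
    volts_arr = np.asarray(volts)
    curr_arr = np.asarray(currents)
    slope, intercept = np.polyfit(volts_arr, curr_arr, 1)
    resid = curr_arr - (slope * volts_arr + intercept)
    rms = float(np.sqrt(np.mean(resid**2)))
    if abs(slope) < 1e-12:
        return LeakModel(0.0, 0.0, volts, rms, reversal_defined=False)
    return LeakModel(float(slope), float(-intercept / slope), volts, rms)


def subtract_leak(sweeps: SweepSet, leak: LeakModel) -> SweepSet:
    """Remove g_leak * (V_cmd(t) - E_leak) from every sample of every sweep.

    The commanded voltage is holding during the baseline and the step value
    afterwards, taken from protocol metadata (pure step value if absent).
    """
    proto = sweeps.metadata.get("protocol")
    corrected = {}
    for v, tr in sweeps.traces.items():
        if proto:
            v_cmd = np.where(
                sweeps.time_ms < float(proto["baseline_ms"]),
                float(proto["holding_mV"]),
                v,
            )
        else:
            v_cmd = np.full_like(tr, v)
        corrected[v] = tr - leak.current_pA(v_cmd)
    return sweeps.with_traces(
        corrected,
        {
            "op": "subtract_leak",
            "conductance_nS": leak.conductance_nS,
            "reversal_mV": leak.reversal_mV,
            "fit_voltages_mV": list(leak.fit_voltages_mV),
        },
    )


def preprocess(
    sweeps: SweepSet,
    cutoff_hz: float = 500.0,
    subthreshold_range: tuple[float, float] = DEFAULT_SUBTHRESHOLD_RANGE,
) -> SweepSet:
    """Standard conditioning chain: Gaussian filter, then leak subtraction."""
    filtered = filter_sweepset(sweeps, cutoff_hz)
    leak = estimate_leak(filtered, subthreshold_range)
    return subtract_leak(filtered, leak)
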