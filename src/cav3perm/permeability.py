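"""Peak I-V analysis, bi-ionic reversal potentials and permeability ratios.

The analysis chain mirrors how selectivity is quantified from whole-cell
recordings:

1. peak current per step voltage (after filtering and leak subtraction),
   with a capacitive guard excluding the first 2 ms of the step;
2. reversal potential by ordinary least squares over the linear limbs of the
   peak I-V bracketing the sign change ("linear conductance" extrapolation);
3. the Fatt-Ginsborg bi-ionic relation converting the reversal potential
   into a calcium-to-monovalent permeability ratio

       P_Ca / P_X = ([X]_in / (4 [Ca]_out)) * u * (u + 1),
       u = exp(E_rev F / (R T)),

   valid when the only permeant species are external Ca2+ and one internal
   monovalent X+;
4. the Na+-for-NMDG+ fold change in peak current at a fixed test potential,
   a per-cell ratio averaged across cells (mean +/- SEM).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import PhysicalConstants
from .sweeps import SweepSet

__all__ = [
    "IVCurve",
    "ErevFit",
    "PermeabilityResult",
    "FoldChangeResult",
    "NoSignChangeError",
    "peak_current",
    "build_iv",
    "estimate_erev",
    "permeability_ratio",
    "erev_from_permeability_ratio",
    "analyze_biionic_series",
    "fold_change",
]

CAPACITIVE_GUARD_MS = 2.0


class NoSignChangeError(ValueError):
    """Peak I-V has no sign change: no reversal in the sampled range."""


@dataclass
class IVCurve:
    """Peak currents per step voltage, with extraction provenance."""

    step_voltages_mV: np.ndarray
    peak_currents_pA: np.ndarray
    peak_times_ms: np.ndarray
    extraction_window_ms: tuple[float, float]
    polarity_rule: str = "auto"

    def __post_init__(self) -> None:
        self.step_voltages_mV = np.asarray(self.step_voltages_mV, dtype=float)
        self.peak_currents_pA = np.asarray(self.peak_currents_pA, dtype=float)
        self.peak_times_ms = np.asarray(self.peak_times_ms, dtype=float)

    @property
    def minimum_voltage_mV(self) -> float:
        """Step voltage of the largest inward (most negative) peak."""
        return float(self.step_voltages_mV[np.argmin(self.peak_currents_pA)])


@dataclass
class ErevFit:
    """Local linear fit of the peak I-V around its sign change."""

    erev_mV: float
    slope_nS: float
    fit_points: list[tuple[float, float]]
    flagged: bool = False  # fewer bracketing points than requested


@dataclass
class PermeabilityResult:
    """Fatt-Ginsborg outcome for one internal monovalent species."""

    internal_ion: str
    erev_mV: float
    p_ca_over_p_x: float
    x_internal_mM: float
    ca_external_mM: float
    temperature_K: float
    fit_points: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class FoldChangeResult:
    """Per-cell Na-vs-NMDG peak-current ratios with group summary."""

    per_cell_ratios: list[float]
    mean: float
    sem: float
    n: int
    test_potential_mV: float
    n_excluded: int = 0


# ------------------------------------------------------------------ peaks


def peak_current(
    trace,
    time_ms,
    window_ms: tuple[float, float],
    polarity: str = "auto",
) -> tuple[float, float]:
    """Extremum of a conditioned trace within a time window.

    ``polarity`` selects the inward (most negative) or outward (most
    positive) extremum; ``auto`` takes whichever deviates further from zero.
    Returns (current_pA, time_ms).
    """
    if polarity not in ("auto", "inward", "outward"):
        raise ValueError(f"unknown polarity rule {polarity!r}")
    trace = np.asarray(trace, dtype=float)
    time_ms = np.asarray(time_ms, dtype=float)
    lo, hi = window_ms
    sel = (time_ms >= lo) & (time_ms <= hi)
    if not np.any(sel):
        raise ValueError(f"empty extraction window {window_ms}")
    seg, t_seg = trace[sel], time_ms[sel]
    i_min, i_max = np.argmin(seg), np.argmax(seg)
    if polarity == "inward":
        idx = i_min
    elif polarity == "outward":
        idx = i_max
    else:
        idx = i_min if abs(seg[i_min]) >= abs(seg[i_max]) else i_max
    return float(seg[idx]), float(t_seg[idx])


def _default_window(sweeps: SweepSet, guard_ms: float) -> tuple[float, float]:
    proto = sweeps.metadata.get("protocol")
    if proto:
        base = float(proto["baseline_ms"])
        return base + guard_ms, base + float(proto["step_duration_ms"])
    return guard_ms, float(sweeps.time_ms[-1])


def build_iv(
    sweeps: SweepSet,
    window_ms: tuple[float, float] | None = None,
    polarity: str = "auto",
    guard_ms: float = CAPACITIVE_GUARD_MS,
    measure: str = "extremum",
) -> IVCurve:
    """Peak current for every sweep, sorted by step voltage.

    The default window spans the step, excluding the first ``guard_ms``
    after step onset (capacitive guard).

    ``measure='extremum'`` takes each sweep's own extremum (the classic peak
    I-V).  ``measure='isochronal'`` reads every sweep at the peak latency of
    the largest-amplitude sweep instead; because the gating transient peaks
    at nearly the same time across step voltages, this is the standard way
    to keep near-reversal points from being dominated by the noise extremum
    of an essentially flat trace.
    """
    if measure not in ("extremum", "isochronal"):
        raise ValueError(f"unknown measure {measure!r}")
    if window_ms is None:
        window_ms = _default_window(sweeps, guard_ms)
    volts = np.sort(sweeps.step_voltages_mV)
    peaks, times = [], []
    for v in volts:
        i, t = peak_current(sweeps.trace(v), sweeps.time_ms, window_ms, polarity)
        peaks.append(i)
        times.append(t)
    if measure == "isochronal":
        ref = int(np.argmax(np.abs(peaks)))
        t_ref = times[ref]
        # mean over +/-1 ms around the reference latency: the gating factor
        # is essentially constant there while uncorrelated noise averages out
        sel = np.abs(sweeps.time_ms - t_ref) <= 1.0
        peaks = [float(np.mean(sweeps.trace(v)[sel])) for v in volts]
        times = [t_ref] * len(volts)
    return IVCurve(volts, np.array(peaks), np.array(times), window_ms,
                   f"{polarity}/{measure}")


# ---------------------------------------------------------------- reversal


def _crossing_index(currents: np.ndarray) -> int:
    """Index k such that currents <= k are 'negative side', > k 'positive side'.

    Chosen to minimize the magnitude-weighted sign misclassification: each
    point votes with weight |I|, so large genuine currents dominate over
    near-zero points whose sign is set by noise or numerical residue.
    """
    n = currents.size
    if not (currents < 0).any() or not (currents > 0).any():
        raise NoSignChangeError("no reversal in sampled range: peak I-V does not change sign")
    pos_mass = np.cumsum(np.where(currents > 0, currents, 0.0))
    neg_mass = np.cumsum(np.where(currents < 0, -currents, 0.0))
    total_neg = neg_mass[-1]
    # cost(k) = positive mass at or below k + negative mass above k
    costs = pos_mass[: n - 1] + (total_neg - neg_mass[: n - 1])
    return int(np.argmin(costs))


def estimate_erev(iv: IVCurve, n_below: int = 2, n_above: int = 2) -> ErevFit:
    """Reversal potential from the linear limbs of the peak I-V.

    Ordinary least squares over the ``n_below`` last negative-current points
    and the ``n_above`` first positive-current points around the sign
    change; E_rev = -intercept/slope and the slope is the local "linear
    conductance" in nS.  Fewer available points than requested (minimum 1
    per side) set ``flagged=True``.
    """
    if n_below < 1 or n_above < 1:
        raise ValueError("n_below and n_above must be >= 1")
    v = iv.step_voltages_mV
    i = iv.peak_currents_pA
    k = _crossing_index(i)

    below_idx = [j for j in range(k + 1) if i[j] < 0][-n_below:]
    above_idx = [j for j in range(k + 1, v.size) if i[j] > 0][:n_above]
    if not below_idx or not above_idx:
        raise NoSignChangeError("could not bracket the reversal with signed points")
    flagged = len(below_idx) < n_below or len(above_idx) < n_above

    sel = np.array(below_idx + above_idx)
    slope, intercept = np.polyfit(v[sel], i[sel], 1)
    if slope == 0:
        raise NoSignChangeError("degenerate flat fit around the sign change")
    erev = -intercept / slope
    return ErevFit(
        erev_mV=float(erev),
        slope_nS=float(slope),
        fit_points=[(float(v[j]), float(i[j])) for j in sel],
        flagged=flagged,
    )


# ---------------------------------------------------- Fatt-Ginsborg relation


def permeability_ratio(
    erev_mV: float,
    x_internal_mM: float,
    ca_external_mM: float,
    constants: PhysicalConstants = PhysicalConstants(),
) -> float:
    """P_Ca/P_X from a bi-ionic reversal potential.

    Exact evaluation of the constant-field bi-ionic relation; strictly
    increasing in ``erev_mV`` (a more depolarized reversal means relatively
    more calcium influx).
    """
    if x_internal_mM <= 0 or ca_external_mM <= 0:
        raise ValueError("concentrations must be positive")
    u = math.exp(erev_mV / constants.thermal_voltage_mV)
    return (x_internal_mM / (4.0 * ca_external_mM)) * u * (u + 1.0)


def erev_from_permeability_ratio(
    p_ca_over_p_x: float,
    x_internal_mM: float,
    ca_external_mM: float,
    constants: PhysicalConstants = PhysicalConstants(),
) -> float:
    """Closed-form inverse of :func:`permeability_ratio`, in mV.

    Solves u(u+1) = 4 [Ca]_out r / [X]_in for u > 0:
    u = (-1 + sqrt(1 + 16 [Ca]_out r / [X]_in)) / 2.
    """
    if p_ca_over_p_x <= 0:
        raise ValueError("p_ca_over_p_x must be positive")
    if x_internal_mM <= 0 or ca_external_mM <= 0:
        raise ValueError("concentrations must be positive")
    c = 4.0 * ca_external_mM * p_ca_over_p_x / x_internal_mM
    u = (-1.0 + math.sqrt(1.0 + 4.0 * c)) / 2.0
    return constants.thermal_voltage_mV * math.log(u)


def analyze_biionic_series(
    recordings: dict[str, SweepSet],
    solutions: dict[str, dict] | None = None,
    constants: PhysicalConstants = PhysicalConstants(),
    n_below: int = 2,
    n_above: int = 2,
    window_ms: tuple[float, float] | None = None,
    measure: str = "extremum",
) -> list[PermeabilityResult]:
    """Per internal ion: peak I-V -> E_rev -> P_Ca/P_X.

    ``recordings`` maps the internal monovalent species to its preprocessed
    SweepSet.  Concentrations come from each SweepSet's solution metadata
    unless overridden by ``solutions`` (mapping ion -> {'x_internal_mM': ...,
    'ca_external_mM': ...}).
    """
    results = []
    for ion, sweeps in recordings.items():
        if solutions is not None and ion in solutions:
            x_in = float(solutions[ion]["x_internal_mM"])
            ca_out = float(solutions[ion]["ca_external_mM"])
        else:
            sol = sweeps.metadata.get("solutions", {})
            try:
                x_in = float(sol["internal_mM"][ion])
                ca_out = float(sol["external_mM"]["Ca"])
            except KeyError as exc:
                raise KeyError(
                    f"no solution metadata for {ion}; pass `solutions` explicitly"
                ) from exc
        temp = float(sweeps.metadata.get("temperature_K", constants.temperature))
        consts = constants if temp == constants.temperature else PhysicalConstants(
            constants.faraday, constants.gas_constant, temp
        )
        iv = build_iv(sweeps, window_ms=window_ms, measure=measure)
        fit = estimate_erev(iv, n_below=n_below, n_above=n_above)
        results.append(
            PermeabilityResult(
                internal_ion=ion,
                erev_mV=fit.erev_mV,
                p_ca_over_p_x=permeability_ratio(fit.erev_mV, x_in, ca_out, consts),
                x_internal_mM=x_in,
                ca_external_mM=ca_out,
                temperature_K=consts.temperature,
                fit_points=fit.fit_points,
            )
        )
    return results


# -------------------------------------------------------------- fold change


def fold_change(
    cells: list[tuple[float, float]],
    test_potential_mV: float,
) -> FoldChangeResult:
    """Na-for-NMDG fold change in peak current, per cell then averaged.

    ``cells`` holds (peak_in_Na_external, peak_in_NMDG_external) pairs in pA
    at the test potential.  The ratio is |I_Na|/|I_NMDG| per cell; cells with
    a zero NMDG peak are excluded with a warning; pairs of opposite polarity
    are rejected.
    """
    ratios = []
    n_excluded = 0
    for i_na, i_nmdg in cells:
        if i_nmdg == 0:
            warnings.warn("cell excluded: zero peak in NMDG external (ratio undefined)")
            n_excluded += 1
            continue
        if i_na != 0 and (i_na > 0) != (i_nmdg > 0):
            raise ValueError(
                f"peaks of opposite polarity within one cell: {i_na}, {i_nmdg} pA"
            )
        ratios.append(abs(i_na) / abs(i_nmdg))
    if not ratios:
        raise ValueError("no usable cells for fold change")
    arr = np.asarray(ratios)
    mean = float(arr.mean())
    sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return FoldChangeResult(
        per_cell_ratios=ratios,
        mean=mean,
        sem=sem,
        n=len(ratios),
        test_potential_mV=test_potential_mV,
        n_excluded=n_excluded,
    )
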