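"""Synthetic whole-cell voltage-clamp recordings with known ground truth.

The simulator composes three ingredients into each sweep:

* a constant-field (Goldman-Hodgkin-Katz) open-channel current for an
  arbitrary mixture of mono- and divalent cations, with the permeability of
  each species as ground truth;
* Hodgkin-Huxley-style m*h gating (Boltzmann steady states, first-order
  voltage-dependent relaxation) shaped like a low-voltage-activated T-type
  conductance;
* an ohmic leak plus additive i.i.d. Gaussian recording noise, fully
  determined by an integer seed.

Because the open-channel model is exactly the constant-field flux, the
bi-ionic reversal potential of a simulated cell obeys the Fatt-Ginsborg
relation analytically, which makes every downstream stage (leak subtraction,
I-V extraction, reversal-potential fitting, permeability ratios) testable by
parameter recovery.

Sign convention: membrane current is positive outward, so an external-only
cation at negative voltages produces a negative (inward) current.  The lumped
permeability carries units of pA/mM so that currents emerge in pA; only
permeability *ratios* are scientifically meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.optimize import brentq

from .constants import PhysicalConstants
from .sweeps import SweepSet

__all__ = [
    "IonSpecies",
    "VoltageProtocol",
    "SigmoidTau",
    "GatingParams",
    "ChannelModel",
    "NoReversalError",
    "ghk_current",
    "model_erev",
    "gating_factor",
    "simulate_sweep",
    "simulate_experiment",
]

SIGN_CONVENTION = "positive-outward; influx driven by external concentration is negative"


class NoReversalError(ValueError):
    """Total channel current does not change sign on the search bracket."""


@dataclass(frozen=True)
class IonSpecies:
    """One permeant (or impermeant) cation.

    ``permeability`` is a lumped permeability x membrane-area scale in
    pA/mM per unit driving term; set it to 0 for impermeant species such as
    NMDG+ or TEA+.
    """

    name: str
    valence: int
    conc_in: float  # mM
    conc_out: float  # mM
    permeability: float = 0.0

    def __post_init__(self) -> None:
        if self.valence not in (1, 2):
            raise ValueError(f"supported cation valences are +1 and +2, got {self.valence}")
        if self.conc_in < 0 or self.conc_out < 0:
            raise ValueError("concentrations must be non-negative")
        if self.permeability < 0:
            raise ValueError("permeability must be non-negative")
        if self.permeability > 0 and self.conc_in == 0 and self.conc_out == 0:
            raise ValueError(f"{self.name}: permeant species needs a nonzero concentration")


@dataclass(frozen=True)
class VoltageProtocol:
    """Step family: hold, then one depolarizing step per sweep.

    Defaults follow the standard T-type protocol: hold -110 mV (no
    steady-state inactivation), 300 ms steps from -80 to +80 mV.
    """

    holding_mV: float = -110.0
    step_start_mV: float = -80.0
    step_stop_mV: float = 80.0
    step_increment_mV: float = 5.0
    step_duration_ms: float = 300.0
    baseline_ms: float = 10.0
    sampling_rate_hz: float = 10_000.0

    def __post_init__(self) -> None:
        if self.step_increment_mV <= 0:
            raise ValueError("step_increment_mV must be positive")
        if self.step_stop_mV < self.step_start_mV:
            raise ValueError("step_stop_mV must be >= step_start_mV")
        if self.step_duration_ms <= 0 or self.baseline_ms <= 0:
            raise ValueError("durations must be positive")

    @property
    def n_sweeps(self) -> int:
        return int(np.floor((self.step_stop_mV - self.step_start_mV) / self.step_increment_mV)) + 1

    @property
    def step_voltages_mV(self) -> np.ndarray:
        return self.step_start_mV + self.step_increment_mV * np.arange(self.n_sweeps)

    def time_ms(self) -> np.ndarray:
        n = int(round((self.baseline_ms + self.step_duration_ms) * self.sampling_rate_hz / 1e3))
        return np.arange(n) * 1e3 / self.sampling_rate_hz

    def command_voltage(self, step_mV: float) -> np.ndarray:
        """Commanded voltage at each sample (holding during baseline)."""
        t = self.time_ms()
        return np.where(t < self.baseline_ms, self.holding_mV, float(step_mV))


@dataclass(frozen=True)
class SigmoidTau:
    """Voltage-dependent time constant tau(v) = base + amp/(1+exp((v-v_mid)/slope)), ms.

    A serializable stand-in for an arbitrary tau(v) callable; slower at
    hyperpolarized voltages, saturating at ``base`` for strong steps.
    """

    base_ms: float
    amp_ms: float
    v_mid_mV: float
    slope_mV: float

    def __call__(self, v: float) -> float:
        return self.base_ms + self.amp_ms / (1.0 + np.exp((v - self.v_mid_mV) / self.slope_mV))


TauLike = float | SigmoidTau | Callable[[float], float]


def _tau_at(tau: TauLike, v: float) -> float:
    value = tau(v) if callable(tau) else float(tau)
    if not value > 0:
        raise ValueError(f"time constant must be positive, got {value} at {v} mV")
    return value


@dataclass(frozen=True)
class GatingParams:
    """Boltzmann activation/inactivation with first-order relaxation."""

    act_v_half: float  # mV
    act_slope: float  # mV, > 0 for depolarization-activated
    inact_v_half: float  # mV
    inact_slope: float  # mV, > 0 for depolarization-inactivated
    tau_act: TauLike = 2.0  # ms
    tau_inact: TauLike = 20.0  # ms

    def __post_init__(self) -> None:
        if self.act_slope == 0 or self.inact_slope == 0:
            raise ValueError("Boltzmann slopes must be nonzero")

    def m_inf(self, v):
        return 1.0 / (1.0 + np.exp((self.act_v_half - np.asarray(v, dtype=float)) / self.act_slope))

    def h_inf(self, v):
        return 1.0 / (1.0 + np.exp((np.asarray(v, dtype=float) - self.inact_v_half) / self.inact_slope))

    def describe(self) -> dict:
        d = {
            "act_v_half_mV": self.act_v_half,
            "act_slope_mV": self.act_slope,
            "inact_v_half_mV": self.inact_v_half,
            "inact_slope_mV": self.inact_slope,
        }
        for key, tau in (("tau_act", self.tau_act), ("tau_inact", self.tau_inact)):
            if isinstance(tau, SigmoidTau):
                d[key] = asdict(tau)
            elif callable(tau):
                d[key] = repr(tau)
            else:
                d[key] = float(tau)
        return d


@dataclass(frozen=True)
class ChannelModel:
    """Everything needed to simulate one cell, noise seed included."""

    ions: tuple[IonSpecies, ...]
    gating: GatingParams
    leak_conductance_nS: float = 0.0
    leak_reversal_mV: float = 0.0
    noise_sd_pA: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.leak_conductance_nS < 0:
            raise ValueError("leak_conductance_nS must be >= 0")
        if self.noise_sd_pA < 0:
            raise ValueError("noise_sd_pA must be >= 0")

    def describe(self) -> dict:
        return {
            "ions": [asdict(ion) for ion in self.ions],
            "gating": self.gating.describe(),
            "leak_conductance_nS": self.leak_conductance_nS,
            "leak_reversal_mV": self.leak_reversal_mV,
            "noise_sd_pA": self.noise_sd_pA,
            "seed": self.seed,
            "sign_convention": SIGN_CONVENTION,
        }


# ------------------------------------------------------------------ GHK flux


def ghk_current(ion: IonSpecies, v_mV, constants: PhysicalConstants = PhysicalConstants()):
    """Constant-field current for one ion species, in pA.

    I = P * z * x * ([in] - [out] e^(-x)) / (1 - e^(-x)) with
    x = z v F / (R T); the removable singularity at v = 0 is evaluated by
    its limit P * z * ([in] - [out]).  Positive current is outward.
    """
    v = np.asarray(v_mV, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("voltage must be finite")
    x = ion.valence * v / constants.thermal_voltage_mV
    with np.errstate(over="raise"):
        denom = -np.expm1(-x)
    limit = ion.permeability * ion.valence * (ion.conc_in - ion.conc_out)
    safe = np.where(x == 0.0, 1.0, denom)
    general = (
        ion.permeability
        * ion.valence
        * x
        * (ion.conc_in - ion.conc_out * np.exp(-x))
        / safe
    )
    out = np.where(x == 0.0, limit, general)
    return float(out) if np.isscalar(v_mV) else out


def total_channel_current(ions, v_mV, constants: PhysicalConstants = PhysicalConstants()):
    """Sum of GHK currents over species (leak excluded)."""
    return sum(ghk_current(ion, v_mV, constants) for ion in ions)


def model_erev(
    model: ChannelModel,
    constants: PhysicalConstants = PhysicalConstants(),
    bracket_mV: tuple[float, float] = (-150.0, 150.0),
) -> float:
    """Ground-truth reversal potential of the open-channel current, in mV.

    Finds the zero of the summed GHK current (leak excluded) by bracketed
    root-finding on ``bracket_mV``.  Raises :class:`NoReversalError` when the
    total current never changes sign there (all-impermeant models,
    single-sided fluxes).
    """
    permeant = tuple(ion for ion in model.ions if ion.permeability > 0)
    if not permeant:
        raise NoReversalError("no permeant species")
    grid = np.linspace(bracket_mV[0], bracket_mV[1], 601)
    total = total_channel_current(permeant, grid, constants)
    sign = np.sign(total)
    idx = np.nonzero(np.diff(sign) != 0)[0]
    if idx.size == 0:
        raise NoReversalError("total channel current has no sign change on the bracket")
    lo, hi = grid[idx[0]], grid[idx[0] + 1]
    f = lambda v: total_channel_current(permeant, v, constants)
    root = brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)
    # tighten to the stated |I| tolerance relative to peak current scale
    scale = np.max(np.abs(total))
    if abs(f(root)) > 1e-10 * max(scale, 1.0):
        raise RuntimeError("root refinement failed to reach |I| tolerance")
    return float(root)


# ------------------------------------------------------------------- gating


def gating_factor(t_ms, v: float, g: GatingParams, v_hold: float):
    """Open probability m(t)*h(t) at time ``t_ms`` after stepping to ``v``.

    Both gates relax exponentially from their steady state at ``v_hold``
    toward the Boltzmann steady state at ``v``; always in [0, 1].
    """
    t = np.asarray(t_ms, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    m0, m_inf = g.m_inf(v_hold), g.m_inf(v)
    h0, h_inf = g.h_inf(v_hold), g.h_inf(v)
    m = m_inf + (m0 - m_inf) * np.exp(-t / _tau_at(g.tau_act, v))
    h = h_inf + (h0 - h_inf) * np.exp(-t / _tau_at(g.tau_inact, v))
    out = m * h
    return float(out) if np.isscalar(t_ms) else out


# ---------------------------------------------------------------- simulation


def _sweep_rng(seed: int, seed_offset: int) -> np.random.Generator:
    """Deterministic per-sweep substream from (seed, sweep index)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(seed_offset)]))


def simulate_sweep(
    model: ChannelModel,
    protocol: VoltageProtocol,
    step_mV: float,
    seed_offset: int = 0,
    constants: PhysicalConstants = PhysicalConstants(),
) -> np.ndarray:
    """One current trace in pA: gating x GHK + ohmic leak + Gaussian noise.

    Identical (model, protocol, step_mV, seed, seed_offset) give bit-identical
    traces.  The baseline segment sits at holding, where the channel carries
    its (tiny) steady-state current.
    """
    t = protocol.time_ms()
    v_cmd = protocol.command_voltage(step_mV)
    on_step = t >= protocol.baseline_ms

    i_chan = np.empty_like(t)
    g_hold = gating_factor(0.0, protocol.holding_mV, model.gating, protocol.holding_mV)
    i_chan[~on_step] = g_hold * total_channel_current(model.ions, protocol.holding_mV, constants)
    t_step = t[on_step] - protocol.baseline_ms
    i_open = total_channel_current(model.ions, float(step_mV), constants)
    i_chan[on_step] = gating_factor(t_step, float(step_mV), model.gating, protocol.holding_mV) * i_open

    i_leak = model.leak_conductance_nS * (v_cmd - model.leak_reversal_mV)  # nS * mV = pA
    trace = i_chan + i_leak
    if model.noise_sd_pA > 0:
        rng = _sweep_rng(model.seed, seed_offset)
        trace = trace + rng.normal(0.0, model.noise_sd_pA, size=trace.shape)
    return trace


def simulate_experiment(
    model: ChannelModel,
    protocol: VoltageProtocol = VoltageProtocol(),
    out_path: str | Path | None = None,
    constants: PhysicalConstants = PhysicalConstants(),
    solutions: dict | None = None,
    label: str | None = None,
) -> SweepSet:
    """Simulate one sweep per step voltage and (optionally) persist the set.

    The returned SweepSet carries full provenance: protocol, model
    parameters, solutions in mM, seed, temperature and sign convention.
    """
    from . import __version__

    steps = protocol.step_voltages_mV
    traces = {
        float(v): simulate_sweep(model, protocol, float(v), seed_offset=i, constants=constants)
        for i, v in enumerate(steps)
    }
    if solutions is None:
        solutions = {
            "external_mM": {ion.name: ion.conc_out for ion in model.ions},
            "internal_mM": {ion.name: ion.conc_in for ion in model.ions},
        }
    metadata = {
        "generator": f"cav3perm {__version__}",
        "label": label,
        "protocol": asdict(protocol),
        "model": model.describe(),
        "solutions": solutions,
        "temperature_K": constants.temperature,
        "history": [],
    }
    sweeps = SweepSet(
        time_ms=protocol.time_ms(),
        step_voltages_mV=steps,
        traces=traces,
        metadata=metadata,
    )
    if out_path is not None:
        sweeps.save(out_path)
    return sweeps
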