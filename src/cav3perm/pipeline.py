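"""End-to-end assays: simulate -> preprocess -> analyze, per named preset.

These helpers chain the simulator, the conditioning steps and the analysis
operations exactly as a recording session would be processed: every
simulated cell is Gaussian-filtered at 500 Hz, leak-subtracted via the
subthreshold linear fit, and only then measured.  Simulated protocols extend
the step family down to -110 mV so that subthreshold sweeps exist for the
leak fit; the analysis itself only uses the standard -80..+80 mV range
plus the reversal region.
"""

from __future__ import annotations

import numpy as np

from .constants import PhysicalConstants
from .permeability import (
    FoldChangeResult,
    PermeabilityResult,
    analyze_biionic_series,
    build_iv,
    fold_change,
    peak_current,
)
from .preprocess import preprocess
from .presets import (
    LEAK_FIT_PROTOCOL,
    DEFAULT_NOISE_SD_PA,
    biionic_model,
    fold_change_model,
    resolve_preset,
)
from .simulate import VoltageProtocol, simulate_experiment

__all__ = ["run_fold_change_assay", "run_biionic_assay", "simulate_preprocessed_cell"]


def _cell_seed(seed: int, cell: int, salt: int) -> int:
    """Deterministic per-cell seed below 2**31."""
    return (seed * 1_000_003 + salt * 7919 + cell) % (2**31 - 1)


def simulate_preprocessed_cell(model, protocol=LEAK_FIT_PROTOCOL, constants=PhysicalConstants(),
                               solutions=None, label=None):
    """Simulate one cell and run the standard conditioning chain."""
    raw = simulate_experiment(model, protocol, constants=constants, solutions=solutions,
                              label=label)
    return preprocess(raw)


def run_fold_change_assay(
    preset: str,
    n_cells: int = 10,
    seed: int = 0,
    noise_sd_pA: float = DEFAULT_NOISE_SD_PA,
    protocol: VoltageProtocol = LEAK_FIT_PROTOCOL,
    constants: PhysicalConstants = PhysicalConstants(),
) -> FoldChangeResult:
    """Na-vs-NMDG fold change for ``n_cells`` simulated cells of a preset.

    Each cell is recorded twice (Na+ then NMDG+ external) with independent
    noise streams; peaks are taken at the preset's display test potential
    (-40 mV molluscan, -30 mV human).
    """
    spec = resolve_preset(preset)
    pairs = []
    for cell in range(n_cells):
        peaks = {}
        for salt_idx, ext in enumerate(("Na", "NMDG")):
            model = fold_change_model(
                spec, ext, seed=_cell_seed(seed, cell, salt_idx), noise_sd_pA=noise_sd_pA
            )
            sweeps = simulate_preprocessed_cell(model, protocol, constants,
                                                label=f"{spec.name}/{ext}/cell{cell}")
            window = None  # default step window with capacitive guard
            iv = build_iv(sweeps)
            # peak at the test potential only
            i_pk, _ = peak_current(
                sweeps.trace(spec.test_potential_mV),
                sweeps.time_ms,
                iv.extraction_window_ms,
                polarity="inward",
            )
            peaks[ext] = i_pk
        pairs.append((peaks["Na"], peaks["NMDG"]))
    return fold_change(pairs, spec.test_potential_mV)


def run_biionic_assay(
    preset: str,
    internal_ions: tuple[str, ...] = ("Li", "Na", "K", "Cs"),
    n_cells: int = 1,
    seed: int = 0,
    noise_sd_pA: float = DEFAULT_NOISE_SD_PA,
    protocol: VoltageProtocol = LEAK_FIT_PROTOCOL,
    constants: PhysicalConstants = PhysicalConstants(),
) -> dict[str, list[PermeabilityResult]]:
    """Bi-ionic permeametry for a preset: per internal ion, per cell results."""
    spec = resolve_preset(preset)
    out: dict[str, list[PermeabilityResult]] = {}
    for salt_idx, ion in enumerate(internal_ions):
        results = []
        for cell in range(n_cells):
            model = biionic_model(
                spec, ion, seed=_cell_seed(seed, cell, 100 + salt_idx), noise_sd_pA=noise_sd_pA
            )
            sweeps = simulate_preprocessed_cell(model, protocol, constants,
                                                label=f"{spec.name}/biionic-{ion}/cell{cell}")
            results.extend(analyze_biionic_series({ion: sweeps}, constants=constants))
        out[ion] = results
    return out


def summarize_biionic(results: dict[str, list[PermeabilityResult]]) -> dict[str, dict]:
    """Mean +/- SEM of E_rev and P_Ca/P_X per internal ion."""
    summary = {}
    for ion, res in results.items():
        erevs = np.array([r.erev_mV for r in res])
        ratios = np.array([r.p_ca_over_p_x for r in res])
        n = erevs.size
        summary[ion] = {
            "n": int(n),
            "erev_mV_mean": float(erevs.mean()),
            "erev_mV_sem": float(erevs.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
            "p_ca_over_p_x_mean": float(ratios.mean()),
            "p_ca_over_p_x_sem": float(ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        }
    return summary
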