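"""Named channel presets and the two recording configurations.

Presets emulate the qualitative phenotypes of the Cav3 splice variants and
mutants studied with whole-cell patch clamp: the sodium-permeable turret-
lysine variants ("12a-like" and the alanine-to-lysine mutant), the
calcium-selective variants ("12b-like" and the lysine-to-alanine mutant),
the human Cav3.2-like channel, and the selectivity-filter D-to-N mutant.
Presets differ in their monovalent-to-calcium permeability ratios (and, as
flavour, in gating speed); the published per-population fold-change numbers
are attached as reference annotations only, never used as fitted targets.

Two solution sets are provided:

* fold-change configuration: external 2 mM Ca2+ with 135 mM NMDG+ or Na+
  and 25 mM TEA+, internal 110 mM Cs+ - the Na+-for-NMDG+ substitution
  assay;
* bi-ionic configuration: external 4 mM Ca2+ with 155 mM TEA+, internal
  100 mM Li+/Na+/K+/Cs+ - reversal-potential permeametry.

NMDG+ and TEA+ are impermeant by default (NMDG+ is only weakly permeant in
practice; a small nonzero permeability can be injected for sensitivity
checks via ``p_nmdg``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .simulate import ChannelModel, GatingParams, IonSpecies, SigmoidTau, VoltageProtocol

__all__ = [
    "PresetSpec",
    "PRESETS",
    "resolve_preset",
    "fold_change_model",
    "biionic_model",
    "recovery_study_model",
    "RECOVERY_GATING",
    "RECOVERY_LEAK_RANGE",
    "RECOVERY_PROTOCOL",
    "fold_change_solutions",
    "biionic_solutions",
    "DEFAULT_PROTOCOL",
    "LEAK_FIT_PROTOCOL",
    "DEFAULT_NOISE_SD_PA",
    "DEFAULT_LEAK_NS",
]

# Paper-style display protocol: steps -80..+80 mV from -110 mV hold.
DEFAULT_PROTOCOL = VoltageProtocol()

# Analysis protocol: the step family is extended down to -110 mV so that
# sweeps exist below -90 mV where the channel is closed, giving the offline
# linear leak fit its subthreshold points.
LEAK_FIT_PROTOCOL = VoltageProtocol(step_start_mV=-110.0)

DEFAULT_NOISE_SD_PA = 3.0  # typical post-filter whole-cell RMS noise
DEFAULT_LEAK_NS = 0.5

# Gating tuned so the simulated peak inward current falls near -40 mV for
# the molluscan presets and near -30 mV for the human preset (T-type
# channels activate ~10 mV more depolarized in human Cav3.2).  Tuning is
# documentation, not an assertion.
MOLLUSCAN_GATING_SLOW = GatingParams(  # turret-lysine variants: slower kinetics
    act_v_half=-44.0,
    act_slope=5.5,
    inact_v_half=-72.0,
    inact_slope=5.5,
    tau_act=SigmoidTau(2.0, 10.0, -55.0, 9.0),
    tau_inact=SigmoidTau(18.0, 60.0, -65.0, 9.0),
)
MOLLUSCAN_GATING_FAST = GatingParams(  # calcium-selective variants
    act_v_half=-52.0,
    act_slope=5.5,
    inact_v_half=-72.0,
    inact_slope=5.5,
    tau_act=SigmoidTau(1.2, 7.0, -55.0, 9.0),
    tau_inact=SigmoidTau(11.0, 40.0, -65.0, 9.0),
)
HUMAN_GATING = GatingParams(
    act_v_half=-42.0,
    act_slope=5.5,
    inact_v_half=-62.0,
    inact_slope=5.5,
    tau_act=SigmoidTau(1.2, 7.0, -45.0, 9.0),
    tau_inact=SigmoidTau(11.0, 40.0, -55.0, 9.0),
)


# Parameter-recovery oracle channel.  Its activation saturates just below the
# bi-ionic reversal band (cliff-like Boltzmann at -84 mV) and is fully closed
# below -100 mV, so (a) the peak I-V around the reversal is the open-channel
# GHK I-V up to a voltage-independent gating factor, which is the regime the
# linear-extrapolation reversal estimator assumes, and (b) subthreshold
# sweeps carry pure leak for the offline leak fit.  The recovery protocol
# extends the step family to -140 mV: the long subthreshold lever arm keeps
# the extrapolated leak line's error small at the reversal voltages.
# Display presets below keep physiological gating instead; their reversal
# estimates inherit a small gating-curvature bias, as real recordings do.
# Inactivation is kept T-type-placed but very slow, so the transient peaks
# within a few ms of step onset at every voltage: that keeps the per-sweep
# extremum and the isochronal (shared-latency) I-V measures consistent.
RECOVERY_GATING = GatingParams(
    act_v_half=-84.0,
    act_slope=1.2,
    inact_v_half=-72.0,
    inact_slope=5.5,
    tau_act=1.5,
    tau_inact=150.0,
)
RECOVERY_LEAK_RANGE = (-140.0, -100.0)
RECOVERY_PROTOCOL = VoltageProtocol(step_start_mV=-140.0)


@dataclass(frozen=True)
class PresetSpec:
    """One named channel phenotype.

    ``p_ca_over_p_x`` holds the ground-truth P_Ca/P_X ratio per internal
    monovalent species; the absolute calcium permeability scale ``p_ca`` is
    arbitrary (only ratios matter).  ``reference`` carries published
    population statistics (mean +/- SEM, n) as annotations.
    """

    name: str
    gating: GatingParams
    p_ca: float
    p_ca_over_p_x: dict[str, float]
    test_potential_mV: float = -40.0
    reference: dict = field(default_factory=dict)
    aliases: tuple[str, ...] = ()

    def monovalent_permeability(self, ion: str) -> float:
        return self.p_ca / self.p_ca_over_p_x[ion]


PRESETS: dict[str, PresetSpec] = {}


def _register(spec: PresetSpec) -> None:
    PRESETS[spec.name] = spec


_register(
    PresetSpec(
        name="12a-like",
        gating=MOLLUSCAN_GATING_SLOW,
        p_ca=10.0,
        p_ca_over_p_x={"Li": 2.0, "Na": 2.5, "K": 3.0, "Cs": 25.0},
        test_potential_mV=-40.0,
        reference={"fold_change_na_vs_nmdg": {"mean": 15.62, "sem": 0.57, "n": 21}},
    )
)
_register(
    PresetSpec(
        name="12b-like",
        gating=MOLLUSCAN_GATING_FAST,
        p_ca=10.0,
        p_ca_over_p_x={"Li": 35.0, "Na": 45.0, "K": 50.0, "Cs": 90.0},
        test_potential_mV=-40.0,
        reference={
            "fold_change_na_vs_nmdg": {"mean": 2.32, "sem": 0.03, "n": 26},
            # reported a second time with different n/SEM in another context
            "fold_change_na_vs_nmdg_alt": {"mean": 2.32, "sem": 0.054, "n": 22},
        },
    )
)
_register(
    PresetSpec(
        name="12b_A-to-K-like",
        gating=MOLLUSCAN_GATING_SLOW,
        p_ca=10.0,
        p_ca_over_p_x={"Li": 2.3, "Na": 3.0, "K": 3.5, "Cs": 28.0},
        test_potential_mV=-40.0,
        reference={"fold_change_na_vs_nmdg": {"mean": 13.49, "sem": 1.14, "n": 14}},
        aliases=("A1078K-like", "A1089K-like"),
    )
)
_register(
    PresetSpec(
        name="12a_K-to-A-like",
        gating=MOLLUSCAN_GATING_FAST,
        p_ca=10.0,
        p_ca_over_p_x={"Li": 32.0, "Na": 42.0, "K": 48.0, "Cs": 85.0},
        test_potential_mV=-40.0,
        reference={"fold_change_na_vs_nmdg": {"mean": 2.24, "sem": 0.10, "n": 9}},
        aliases=("K1067A-like",),
    )
)
_register(
    PresetSpec(
        name="hCav3.2-like",
        gating=HUMAN_GATING,
        p_ca=10.0,
        p_ca_over_p_x={"Li": 50.0, "Na": 60.0, "K": 70.0, "Cs": 100.0},
        test_potential_mV=-30.0,
        reference={"fold_change_na_vs_nmdg": {"mean": 1.32, "sem": 0.044, "n": 16}},
    )
)
_register(
    PresetSpec(
        name="D-to-N-like",
        gating=MOLLUSCAN_GATING_FAST,
        p_ca=10.0,
        p_ca_over_p_x={"Li": 6.0, "Na": 8.0, "K": 9.0, "Cs": 45.0},
        test_potential_mV=-40.0,
        reference={"fold_change_na_vs_nmdg": {"mean": 8.56, "sem": 0.73, "n": 17}},
        aliases=("D1087N-like", "D1098N-like"),
    )
)


def resolve_preset(name: str) -> PresetSpec:
    if name in PRESETS:
        return PRESETS[name]
    for spec in PRESETS.values():
        if name in spec.aliases:
            return spec
    raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")


# ------------------------------------------------------------- solutions


def fold_change_solutions(external_monovalent: str) -> dict:
    """Na-vs-NMDG solutions: 2 Ca / 135 Na-or-NMDG / 25 TEA out, 110 Cs in (mM)."""
    if external_monovalent not in ("Na", "NMDG"):
        raise ValueError("external_monovalent must be 'Na' or 'NMDG'")
    return {
        "external_mM": {"Ca": 2.0, external_monovalent: 135.0, "TEA": 25.0},
        "internal_mM": {"Cs": 110.0},
    }


def biionic_solutions(internal_ion: str) -> dict:
    """Bi-ionic solutions: 4 Ca / 155 TEA out, 100 mM monovalent in (mM)."""
    if internal_ion not in ("Li", "Na", "K", "Cs"):
        raise ValueError("internal_ion must be one of Li, Na, K, Cs")
    return {
        "external_mM": {"Ca": 4.0, "TEA": 155.0},
        "internal_mM": {internal_ion: 100.0},
    }


# ---------------------------------------------------------------- models


def fold_change_model(
    preset: str | PresetSpec,
    external_monovalent: str,
    seed: int = 0,
    noise_sd_pA: float = DEFAULT_NOISE_SD_PA,
    leak_nS: float = DEFAULT_LEAK_NS,
    p_nmdg: float = 0.0,
) -> ChannelModel:
    """Cell model in the Na-vs-NMDG configuration.

    ``p_nmdg`` optionally gives NMDG+ a small permeability for sensitivity
    checks (default 0: impermeant).
    """
    spec = resolve_preset(preset) if isinstance(preset, str) else preset
    sol = fold_change_solutions(external_monovalent)
    ext, internal = sol["external_mM"], sol["internal_mM"]
    ions = [
        IonSpecies("Ca", 2, conc_in=0.0, conc_out=ext["Ca"], permeability=spec.p_ca),
        IonSpecies("Cs", 1, conc_in=internal["Cs"], conc_out=0.0,
                   permeability=spec.monovalent_permeability("Cs")),
        IonSpecies("TEA", 1, conc_in=0.0, conc_out=ext["TEA"], permeability=0.0),
    ]
    if external_monovalent == "Na":
        ions.append(IonSpecies("Na", 1, conc_in=0.0, conc_out=ext["Na"],
                               permeability=spec.monovalent_permeability("Na")))
    else:
        ions.append(IonSpecies("NMDG", 1, conc_in=0.0, conc_out=ext["NMDG"],
                               permeability=p_nmdg))
    return ChannelModel(
        ions=tuple(ions),
        gating=spec.gating,
        leak_conductance_nS=leak_nS,
        leak_reversal_mV=0.0,
        noise_sd_pA=noise_sd_pA,
        seed=seed,
    )


def recovery_study_model(
    p_ca_over_p_x: float,
    internal_ion: str = "Na",
    seed: int = 0,
    noise_sd_pA: float = 0.0,
    leak_nS: float = DEFAULT_LEAK_NS,
) -> ChannelModel:
    """Bi-ionic cell with the parameter-recovery oracle gating.

    Ground truth P_Ca/P_X is ``p_ca_over_p_x``; analyze with the leak fit
    range ``RECOVERY_LEAK_RANGE``.
    """
    spec = PresetSpec(
        name=f"recovery-r{p_ca_over_p_x:g}",
        gating=RECOVERY_GATING,
        p_ca=10.0,
        p_ca_over_p_x={internal_ion: float(p_ca_over_p_x)},
    )
    return biionic_model(spec, internal_ion, seed=seed, noise_sd_pA=noise_sd_pA, leak_nS=leak_nS)


def biionic_model(
    preset: str | PresetSpec,
    internal_ion: str,
    seed: int = 0,
    noise_sd_pA: float = DEFAULT_NOISE_SD_PA,
    leak_nS: float = DEFAULT_LEAK_NS,
) -> ChannelModel:
    """Cell model in the bi-ionic configuration (external Ca2+, internal X+)."""
    spec = resolve_preset(preset) if isinstance(preset, str) else preset
    sol = biionic_solutions(internal_ion)
    ions = (
        IonSpecies("Ca", 2, conc_in=0.0, conc_out=sol["external_mM"]["Ca"],
                   permeability=spec.p_ca),
        IonSpecies(internal_ion, 1, conc_in=sol["internal_mM"][internal_ion], conc_out=0.0,
                   permeability=spec.monovalent_permeability(internal_ion)),
        IonSpecies("TEA", 1, conc_in=0.0, conc_out=sol["external_mM"]["TEA"],
                   permeability=0.0),
    )
    return ChannelModel(
        ions=ions,
        gating=spec.gating,
        leak_conductance_nS=leak_nS,
        leak_reversal_mV=0.0,
        noise_sd_pA=noise_sd_pA,
        seed=seed,
    )
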