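"""Gating, sweep synthesis, persistence and determinism of the simulator."""

import numpy as np
import pytest

from cav3perm.presets import (
    PRESETS,
    biionic_model,
    biionic_solutions,
    fold_change_model,
    resolve_preset,
)
from cav3perm.simulate import (
    ChannelModel,
    GatingParams,
    IonSpecies,
    VoltageProtocol,
    gating_factor,
    simulate_experiment,
    simulate_sweep,
)
from cav3perm.sweeps import load_sweepset


class TestGatingFactor:
    def test_starts_closed_from_hyperpolarized_holding(self, simple_gating):
        occ = gating_factor(0.0, -40.0, simple_gating, v_hold=-110.0)
        assert occ == pytest.approx(0.0, abs=1e-4)

    def test_boltzmann_midpoint_is_half(self):
        g = GatingParams(-50.0, 5.0, inact_v_half=200.0, inact_slope=5.0,
                         tau_act=1.0, tau_inact=1e9)  # h pinned at 1
        occ = gating_factor(1e5, -50.0, g, v_hold=-110.0)
        assert occ == pytest.approx(0.5, rel=1e-4)

    def test_long_time_limit_is_steady_state_product(self, simple_gating):
        v = -20.0
        m_inf = simple_gating.m_inf(v)
        h_inf = simple_gating.h_inf(v)
        occ = gating_factor(1e5, v, simple_gating, v_hold=-110.0)
        assert occ == pytest.approx(m_inf * h_inf, rel=1e-9)

    def test_closed_form_relaxation(self, simple_gating):
        """m(t) follows the exponential relaxation solution exactly."""
        v, vh, t = -30.0, -110.0, 7.3
        m0 = simple_gating.m_inf(vh)
        m_inf = simple_gating.m_inf(v)
        h0 = simple_gating.h_inf(vh)
        h_inf = simple_gating.h_inf(v)
        expected = (m_inf + (m0 - m_inf) * np.exp(-t / 2.0)) * (
            h_inf + (h0 - h_inf) * np.exp(-t / 20.0)
        )
        assert gating_factor(t, v, simple_gating, vh) == pytest.approx(expected, rel=1e-12)

    def test_occupancy_bounded(self, simple_gating):
        t = np.linspace(0.0, 500.0, 200)
        for v in (-100.0, -50.0, 0.0, 60.0):
            occ = gating_factor(t, v, simple_gating, -110.0)
            assert np.all(occ >= 0.0) and np.all(occ <= 1.0)

    def test_negative_time_rejected(self, simple_gating):
        with pytest.raises(ValueError):
            gating_factor(-1.0, -40.0, simple_gating, -110.0)


class TestSimulateSweep:
    def test_all_zero_when_nothing_conducts(self, simple_gating, short_protocol):
        model = ChannelModel(
            ions=(IonSpecies("Na", 1, 0.0, 140.0, permeability=0.0),),
            gating=simple_gating,
        )
        trace = simulate_sweep(model, short_protocol, -40.0)
        assert np.all(trace == 0.0)

    def test_leak_only_is_ohms_law(self, simple_gating, short_protocol):
        model = ChannelModel(
            ions=(IonSpecies("Na", 1, 0.0, 140.0, permeability=0.0),),
            gating=simple_gating,
            leak_conductance_nS=1.0,
            leak_reversal_mV=0.0,
        )
        trace = simulate_sweep(model, short_protocol, 50.0)
        t = short_protocol.time_ms()
        on_step = t >= short_protocol.baseline_ms
        assert np.allclose(trace[on_step], 50.0)
        assert np.allclose(trace[~on_step], -110.0)

    def test_same_seed_bit_identical_different_seed_not(self, simple_gating, short_protocol):
        def make(seed):
            model = ChannelModel(
                ions=(IonSpecies("Ca", 2, 0.0, 4.0, permeability=5.0),),
                gating=simple_gating,
                noise_sd_pA=2.0,
                seed=seed,
            )
            return simulate_sweep(model, short_protocol, -40.0, seed_offset=3)

        assert np.array_equal(make(7), make(7))
        assert not np.array_equal(make(7), make(8))

    def test_sweep_substreams_differ(self, simple_gating, short_protocol):
        model = ChannelModel(
            ions=(IonSpecies("Ca", 2, 0.0, 4.0, permeability=5.0),),
            gating=simple_gating,
            noise_sd_pA=2.0,
            seed=7,
        )
        a = simulate_sweep(model, short_protocol, -40.0, seed_offset=0)
        b = simulate_sweep(model, short_protocol, -40.0, seed_offset=1)
        assert not np.array_equal(a, b)


class TestSimulateExperiment:
    def test_sweep_count_from_protocol(self, ohmic_model):
        protocol = VoltageProtocol(step_start_mV=-80.0, step_stop_mV=80.0,
                                   step_increment_mV=5.0, step_duration_ms=20.0,
                                   baseline_ms=2.0)
        assert protocol.n_sweeps == 33
        sweeps = simulate_experiment(ohmic_model, protocol)
        assert sweeps.n_sweeps == 33

    def test_write_read_round_trip(self, ohmic_model, short_protocol, tmp_path):
        sweeps = simulate_experiment(ohmic_model, short_protocol,
                                     out_path=tmp_path / "cell0")
        back = load_sweepset(tmp_path / "cell0")
        assert np.array_equal(back.time_ms, sweeps.time_ms)
        for v in sweeps.traces:
            assert np.array_equal(back.trace(v), sweeps.trace(v))
        assert back.metadata["protocol"] == sweeps.metadata["protocol"]

    def test_resimulation_is_bit_identical(self, simple_gating, short_protocol):
        def run():
            model = ChannelModel(
                ions=(IonSpecies("Ca", 2, 0.0, 4.0, permeability=5.0),),
                gating=simple_gating, noise_sd_pA=3.0, seed=11,
            )
            return simulate_experiment(model, short_protocol)

        a, b = run(), run()
        for v in a.traces:
            assert np.array_equal(a.trace(v), b.trace(v))

    def test_biionic_preset_metadata_carries_solutions(self, short_protocol):
        model = biionic_model("12a-like", "Na", noise_sd_pA=0.0)
        sweeps = simulate_experiment(model, short_protocol,
                                     solutions=biionic_solutions("Na"))
        sol = sweeps.metadata["solutions"]
        assert sol["external_mM"]["Ca"] == 4.0
        assert sol["internal_mM"]["Na"] == 100.0


class TestPresets:
    def test_all_presets_resolve_and_alias(self):
        for name in PRESETS:
            assert resolve_preset(name).name == name
        assert resolve_preset("A1089K-like").name == "12b_A-to-K-like"

    def test_nmdg_impermeant_by_default(self):
        model = fold_change_model("12a-like", "NMDG", noise_sd_pA=0.0)
        nmdg = next(ion for ion in model.ions if ion.name == "NMDG")
        assert nmdg.permeability == 0.0

    def test_nmdg_sensitivity_knob(self):
        model = fold_change_model("12a-like", "NMDG", noise_sd_pA=0.0, p_nmdg=0.05)
        nmdg = next(ion for ion in model.ions if ion.name == "NMDG")
        assert nmdg.permeability == 0.05

    def test_reference_annotations_present(self):
        ref = resolve_preset("12a-like").reference["fold_change_na_vs_nmdg"]
        assert ref["n"] == 21
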