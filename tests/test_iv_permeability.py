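"""Peak I-V extraction, reversal-potential fitting and permeability ratios."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cav3perm.constants import PhysicalConstants
from cav3perm.permeability import (
    IVCurve,
    NoSignChangeError,
    build_iv,
    erev_from_permeability_ratio,
    estimate_erev,
    fold_change,
    peak_current,
    permeability_ratio,
)
from cav3perm.presets import LEAK_FIT_PROTOCOL, biionic_model, resolve_preset
from cav3perm.simulate import gating_factor, simulate_experiment, total_channel_current

C = PhysicalConstants()


class TestPeakCurrent:
    def test_flat_zero_trace(self):
        t = np.arange(100) / 10.0
        i, t_pk = peak_current(np.zeros(100), t, (2.0, 8.0))
        assert i == 0.0
        assert t_pk == 2.0

    def test_monotonic_decay_peaks_at_window_start(self):
        t = np.arange(1000) / 10.0
        trace = -100.0 * np.exp(-t / 30.0)
        i, t_pk = peak_current(trace, t, (10.0, 90.0), polarity="inward")
        assert i == pytest.approx(-100.0 * math.exp(-1.0 / 3.0))
        assert t_pk == 10.0

    def test_transient_peak_matches_dense_model(self):
        """Sampled peak lies within one sample of the analytic optimum."""
        model = biionic_model("12a-like", "Na", noise_sd_pA=0.0, leak_nS=0.0)
        proto = LEAK_FIT_PROTOCOL
        sweeps = simulate_experiment(model, proto)
        v = -40.0
        i_pk, t_pk = peak_current(sweeps.trace(v), sweeps.time_ms,
                                  (proto.baseline_ms + 2.0, proto.baseline_ms + 300.0))
        t_dense = np.linspace(0.0, 300.0, 300_001)
        g = gating_factor(t_dense, v, model.gating, proto.holding_mV)
        i_open = total_channel_current(model.ions, v)
        t_best = t_dense[np.argmax(np.abs(g * i_open))] + proto.baseline_ms
        assert abs(t_pk - t_best) <= 0.1  # one sample at 10 kHz
        assert i_pk == pytest.approx(np.min(g * i_open), rel=1e-3)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            peak_current(np.zeros(10), np.arange(10.0), (100.0, 200.0))


class TestBuildIV:
    def test_ohmic_cell_gives_straight_line(self, ohmic_model):
        sweeps = simulate_experiment(ohmic_model, LEAK_FIT_PROTOCOL)
        iv = build_iv(sweeps, polarity="auto")
        slope = np.polyfit(iv.step_voltages_mV, iv.peak_currents_pA, 1)[0]
        assert slope == pytest.approx(2.0, rel=1e-6)

    def test_one_point_per_sweep(self):
        sweeps = simulate_experiment(
            biionic_model("12b-like", "Na", noise_sd_pA=0.0), LEAK_FIT_PROTOCOL
        )
        iv = build_iv(sweeps)
        assert iv.peak_currents_pA.size == sweeps.n_sweeps

    def test_tuned_peak_voltage_of_display_preset(self):
        """The sodium-permeable preset peaks near -40 mV, noiseless."""
        sweeps = simulate_experiment(
            biionic_model("12a-like", "Na", noise_sd_pA=0.0, leak_nS=0.0),
            LEAK_FIT_PROTOCOL,
        )
        iv = build_iv(sweeps)
        assert abs(iv.minimum_voltage_mV - resolve_preset("12a-like").test_potential_mV) <= 5.0


class TestEstimateErev:
    def test_exact_on_collinear_points(self):
        iv = IVCurve(np.array([-10.0, 0.0, 10.0, 20.0]),
                     np.array([-2.0, -1.0, 0.5, 1.5]),
                     np.zeros(4), (0.0, 1.0))
        fit = estimate_erev(iv)
        # least squares on a perfect line through those points
        slope, intercept = np.polyfit(iv.step_voltages_mV, iv.peak_currents_pA, 1)
        assert fit.erev_mV == pytest.approx(-intercept / slope, rel=1e-12)

    def test_exact_line_example(self):
        iv = IVCurve(np.array([-10.0, 0.0, 10.0, 20.0]),
                     np.array([-2.0, -1.0, 0.0, 1.0]),
                     np.zeros(4), (0.0, 1.0))
        # the +10 point carries exactly zero current: the fit uses the
        # bracketing signed points and recovers the collinear reversal
        fit = estimate_erev(iv)
        assert fit.erev_mV == pytest.approx(10.0, abs=1e-9)

    def test_noiseless_biionic_erev_within_half_mV(self):
        from cav3perm.simulate import model_erev

        model = biionic_model("12b-like", "Na", noise_sd_pA=0.0, leak_nS=0.0)
        sweeps = simulate_experiment(model, LEAK_FIT_PROTOCOL)
        fit = estimate_erev(build_iv(sweeps))
        assert fit.erev_mV == pytest.approx(model_erev(model), abs=0.5)

    def test_all_negative_iv_raises(self):
        iv = IVCurve(np.array([-10.0, 0.0, 10.0]), np.array([-5.0, -3.0, -1.0]),
                     np.zeros(3), (0.0, 1.0))
        with pytest.raises(NoSignChangeError):
            estimate_erev(iv)

    def test_invariant_to_current_rescaling(self):
        v = np.arange(-20.0, 25.0, 5.0)
        i = np.array([-8.0, -6.0, -4.5, -2.0, 1.0, 2.5, 4.0, 6.0, 9.0])
        a = estimate_erev(IVCurve(v, i, np.zeros(v.size), (0.0, 1.0)))
        b = estimate_erev(IVCurve(v, 3.7 * i, np.zeros(v.size), (0.0, 1.0)))
        assert a.erev_mV == pytest.approx(b.erev_mV, rel=1e-12)

    def test_flagged_when_fewer_points_than_requested(self):
        iv = IVCurve(np.array([-5.0, 0.0, 5.0, 10.0]),
                     np.array([-1.0, 2.0, 4.0, 6.0]),
                     np.zeros(4), (0.0, 1.0))
        fit = estimate_erev(iv, n_below=2, n_above=2)
        assert fit.flagged


class TestPermeabilityRatio:
    def test_zero_reversal_gives_12p5(self):
        assert permeability_ratio(0.0, 100.0, 4.0, C) == pytest.approx(12.5)

    def test_thermal_voltage_reversal(self):
        """At Erev = RT/F the ratio is 6.25 e (e+1), by direct evaluation."""
        got = permeability_ratio(C.thermal_voltage_mV, 100.0, 4.0, C)
        assert got == pytest.approx(6.25 * math.e * (math.e + 1.0), rel=1e-12)

    @pytest.mark.parametrize("r", [0.1, 1.0, 12.5, 60.0])
    def test_round_trip_with_closed_form_inverse(self, r):
        erev = erev_from_permeability_ratio(r, 100.0, 4.0, C)
        assert permeability_ratio(erev, 100.0, 4.0, C) == pytest.approx(r, rel=1e-9)

    def test_rejects_nonpositive_concentrations(self):
        with pytest.raises(ValueError):
            permeability_ratio(0.0, 0.0, 4.0, C)
        with pytest.raises(ValueError):
            permeability_ratio(0.0, 100.0, -1.0, C)

    @settings(derandomize=True, max_examples=50)
    @given(e1=st.floats(-80.0, 80.0), e2=st.floats(-80.0, 80.0))
    def test_strictly_monotone_in_erev(self, e1, e2):
        lo, hi = sorted((e1, e2))
        if hi - lo < 1e-9:  # indistinguishable at float precision
            return
        assert permeability_ratio(lo, 100.0, 4.0, C) < permeability_ratio(hi, 100.0, 4.0, C)

    def test_scales_linearly_in_internal_and_inversely_in_calcium(self):
        base = permeability_ratio(10.0, 100.0, 4.0, C)
        assert permeability_ratio(10.0, 200.0, 4.0, C) == pytest.approx(2 * base)
        assert permeability_ratio(10.0, 100.0, 8.0, C) == pytest.approx(base / 2)


class TestFoldChange:
    def test_identical_peaks_give_unit_ratio(self):
        res = fold_change([(-50.0, -50.0), (-80.0, -80.0)], -40.0)
        assert res.mean == 1.0
        assert res.sem == 0.0
        assert res.n == 2

    def test_single_cell_arithmetic(self):
        res = fold_change([(-450.0, -30.0)], -40.0)
        assert res.per_cell_ratios == [15.0]

    def test_zero_nmdg_peak_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            res = fold_change([(-450.0, -30.0), (-100.0, 0.0)], -40.0)
        assert res.n == 1
        assert res.n_excluded == 1

    def test_opposite_polarity_rejected(self):
        with pytest.raises(ValueError):
            fold_change([(50.0, -30.0)], -40.0)

    def test_invariant_to_common_rescaling(self):
        cells = [(-450.0, -30.0), (-120.0, -40.0)]
        scaled = [(a * 2.5, b * 2.5) for a, b in cells]
        assert fold_change(cells, -40.0).mean == pytest.approx(
            fold_change(scaled, -40.0).mean
        )
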