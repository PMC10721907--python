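"""Stimulus waveforms, membrane integration and threshold search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import retfield as rf
from retfield.cable import bisect_threshold, make_pulse_train


class TestPulseTrain:
    def test_five_pulse_train_duration(self):
        w = make_pulse_train(100.0, pulse_width_ms=0.45, frequency_hz=20.0,
                             n_pulses=5)
        assert np.isclose(w.duration_ms, 250.0)

    @given(pw=st.floats(0.05, 1.0), gap=st.floats(0.0, 0.5),
           n=st.integers(1, 5))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_charge_balance_and_polarity(self, pw, gap, n):
        w = make_pulse_train(50.0, pulse_width_ms=pw, frequency_hz=20.0,
                             n_pulses=n, interphase_gap_ms=gap)
        assert abs(w.samples.sum()) < 1e-12          # charge balanced
        assert w.samples[np.flatnonzero(w.samples)[0]] == -1.0  # cathodic first

    def test_overlapping_phases_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            make_pulse_train(10.0, pulse_width_ms=30.0, frequency_hz=20.0,
                             n_pulses=2)


class TestSimulate:
    def test_zero_amplitude_rests(self, reference_neuron):
        _, cable, unit = reference_neuron
        w = make_pulse_train(0.0, n_pulses=1)
        res = rf.simulate(cable, unit, w, duration_ms=200.0, record=True)
        assert not res.spiked
        assert np.abs(res.vm - cable.params.v_rest).max() < 1.0

    def test_suprathreshold_spikes(self, reference_neuron, found_threshold):
        _, cable, unit = reference_neuron
        w = make_pulse_train(10.0 * found_threshold, n_pulses=1)
        assert rf.simulate(cable, unit, w, duration_ms=6.0).spiked

    def test_spike_initiates_in_sodium_band_near_threshold(
            self, reference_neuron, found_threshold):
        neuron, cable, unit = reference_neuron
        w = make_pulse_train(1.05 * found_threshold, n_pulses=1)
        res = rf.simulate(cable, unit, w, duration_ms=6.0, record=True)
        assert res.spiked
        sec = neuron.section[res.spike_compartment]
        from retfield.population import SECTION_CODES
        assert sec in (SECTION_CODES["sodium_band"], SECTION_CODES["hillock"],
                       SECTION_CODES["axon"])

    def test_field_scaling_equivalence(self, reference_neuron, found_threshold):
        _, cable, unit = reference_neuron
        for mult in (0.5, 1.2):
            a = rf.simulate(cable, unit * 2.0,
                            make_pulse_train(mult * found_threshold / 2.0,
                                             n_pulses=1), duration_ms=6.0)
            b = rf.simulate(cable, unit,
                            make_pulse_train(mult * found_threshold,
                                             n_pulses=1), duration_ms=6.0)
            assert a.spiked == b.spiked

    def test_dt_validation(self, reference_neuron):
        _, cable, unit = reference_neuron
        with pytest.raises(ValueError):
            rf.simulate(cable, unit, make_pulse_train(1.0, n_pulses=1),
                        dt_ms=0.05)


@pytest.fixture(scope="session")
def found_threshold(reference_neuron):
    _, cable, unit = reference_neuron
    return rf.find_threshold(cable, unit, make_pulse_train(1.0, n_pulses=1),
                             duration_ms=6.0)


class TestThresholdSearch:
    def test_bisection_matches_brute_force_scan(self, reference_neuron,
                                                found_threshold):
        _, cable, unit = reference_neuron
        w = make_pulse_train(1.0, n_pulses=1)
        amps = np.arange(max(found_threshold - 0.4, 0.05),
                         found_threshold + 0.4, 0.02)
        spiked = [rf.simulate(cable, unit, w.with_amplitude(a),
                              duration_ms=6.0).spiked for a in amps]
        first = amps[int(np.argmax(spiked))]
        assert abs(first - found_threshold) <= 0.1

    def test_indicator_neuron_bisection(self):
        """Pure bisection against a known activation boundary."""
        true = 123.45
        scan = np.arange(0.01, 1000, 0.01)
        brute = scan[int(np.argmax(scan >= true))]
        thr = bisect_threshold(lambda a: a >= true)
        assert abs(thr - brute) <= 0.1

    def test_bracket_width_and_evaluation_count(self):
        calls = []
        def spikes(a):
            calls.append(a)
            return a >= 123.45
        thr = bisect_threshold(spikes, lo_uA=0.0, hi_uA=1000.0, tol_uA=0.1)
        # ceil(log2(1000/0.1)) = 14 halvings plus the upper bracket check
        assert len(calls) == 15
        assert abs(thr - 123.45) <= 0.05   # midpoint of the final bracket

    def test_inexcitable_sentinel(self):
        thr = bisect_threshold(lambda a: False, hi_uA=1000.0, cap_factor=4.0)
        assert np.isnan(thr)

    def test_threshold_monotone_with_distance(self, reference_neuron):
        """Farther electrodes need more current (homogeneous half-space)."""
        neuron, cable, _ = reference_neuron
        w = make_pulse_train(1.0, n_pulses=1)
        prev = 0.0
        soma_xy = neuron.centers_mm[neuron.mask("soma")][0, :2]
        z_surf = neuron.centers_mm[neuron.mask("axon"), 2].max() + 0.015
        for d_um in (50.0, 100.0, 200.0, 300.0):
            el = np.array([soma_xy[0], soma_xy[1], z_surf + d_um / 1000.0])
            r_um = np.linalg.norm(neuron.centers_mm - el, axis=1) * 1000.0
            unit = rf.analytic_disc_potential(100.0, 0.1, 1.0, r_um)
            thr = rf.find_threshold(cable, unit, w, duration_ms=6.0)
            assert thr > prev
            prev = thr

    def test_strength_duration_monotone(self, reference_neuron):
        _, cable, unit = reference_neuron
        prev = np.inf
        for pw in (0.1, 0.2, 0.45, 0.7, 1.0):
            w = make_pulse_train(1.0, pulse_width_ms=pw, n_pulses=1)
            thr = rf.find_threshold(cable, unit, w, duration_ms=6.0)
            assert thr <= prev + 0.1
            prev = thr

    def test_dt_halving_convergence(self, reference_neuron, found_threshold):
        _, cable, unit = reference_neuron
        w = make_pulse_train(1.0, n_pulses=1)
        thr5 = rf.find_threshold(cable, unit, w, duration_ms=6.0, dt_ms=0.005)
        assert abs(thr5 - found_threshold) / found_threshold < 0.02
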