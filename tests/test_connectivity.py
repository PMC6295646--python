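import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from graphimg.connectivity import (ConnectivityGraph, PhaseMatrix, Recording,
                                   band_filter, connectivity_matrix,
                                   instantaneous_phase, pli_pair, wrap_phase)


def _sine_recording(freq, fs=250.0, seconds=4.0, n_channels=2):
    t = np.arange(int(fs * seconds)) / fs
    samples = np.tile(np.sin(2 * np.pi * freq * t), (n_channels, 1))
    return Recording([f"ch{i}" for i in range(n_channels)], samples, fs)


class TestBandFilter:
    def test_in_band_amplitude_preserved(self):
        rec = band_filter(_sine_recording(10.0), 8.0, 12.0)
        mid = rec.samples[0, 200:-200]
        ref = _sine_recording(10.0).samples[0, 200:-200]
        assert np.sqrt(np.mean(mid**2)) == pytest.approx(np.sqrt(np.mean(ref**2)), rel=0.05)

    def test_out_of_band_attenuated(self):
        rec = band_filter(_sine_recording(40.0), 8.0, 12.0)
        rms_out = np.sqrt(np.mean(rec.samples[0, 200:-200] ** 2))
        rms_in = np.sqrt(0.5)
        assert rms_out <= 0.1 * rms_in

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError):
            band_filter(_sine_recording(10.0), 12.0, 8.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_filter(_sine_recording(10.0), 8.0, 200.0)


class TestInstantaneousPhase:
    def test_phase_advances_at_signal_frequency(self):
        fs, f = 100.0, 5.0
        t = np.arange(400) / fs
        rec = Recording(["a", "b"], np.tile(np.cos(2 * np.pi * f * t), (2, 1)), fs)
        ph = instantaneous_phase(rec).phases[0]
        steps = wrap_phase(np.diff(ph))[50:-50]
        assert np.allclose(steps, 2 * np.pi * f / fs, atol=1e-3)

    def test_identical_channels_identical_phases(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=500)
        rec = Recording(["a", "b"], np.vstack([row, row]), 100.0)
        ph = instantaneous_phase(rec)
        assert np.array_equal(ph.phases[0], ph.phases[1])

    def test_sin_vs_cos_quarter_cycle_lag(self):
        fs, f = 100.0, 5.0
        t = np.arange(1000) / fs
        rec = Recording(["cos", "sin"],
                        np.vstack([np.cos(2 * np.pi * f * t), np.sin(2 * np.pi * f * t)]), fs)
        ph = instantaneous_phase(rec)
        delta = wrap_phase(ph.phases[0] - ph.phases[1])[100:-100]
        assert np.allclose(delta, np.pi / 2, atol=0.02)

    def test_constant_channel_warns(self):
        samples = np.vstack([np.ones(100), np.random.default_rng(1).normal(size=100)])
        with pytest.warns(UserWarning, match="constant"):
            instantaneous_phase(Recording(["flat", "b"], samples, 100.0))


class TestPliPair:
    @pytest.mark.parametrize(
        "delta, expected",
        [
            (np.zeros(10), 0.0),                          # no lag at all
            (np.full(7, np.pi / 3), 1.0),                 # constant positive lag
            (np.array([0.2, 0.3, -0.1]), 1.0 / 3.0),      # |(+1+1-1)/3|
            (np.array([0.2, -0.2, 0.2, -0.2]), 0.0),      # signs cancel
        ],
    )
    def test_closed_form_cases(self, delta, expected):
        base = np.linspace(-1.0, 1.0, delta.size)
        assert pli_pair(base + delta, base) == pytest.approx(expected, abs=1e-12)

    def test_wrapping_three_half_pi_behaves_as_minus_half_pi(self):
        # a lead of 3pi/2 is the same angle as a lag of pi/2
        a = np.full(5, 3 * np.pi / 2)
        b = np.zeros(5)
        assert pli_pair(a, b) == pli_pair(np.zeros(5), np.full(5, np.pi / 2))
        assert np.sign(wrap_phase(3 * np.pi / 2)) == -1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pli_pair(np.zeros(3), np.zeros(4))

    @given(st.integers(1, 32), st.integers(0, 10_000))
    @settings(deadline=None, max_examples=50)
    def test_brute_force_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-np.pi, np.pi, n)
        b = rng.uniform(-np.pi, np.pi, n)
        total = 0.0
        for x, y in zip(a, b):
            d = x - y
            while d <= -np.pi:
                d += 2 * np.pi
            while d > np.pi:
                d -= 2 * np.pi
            total += np.sign(d)
        assert pli_pair(a, b) == pytest.approx(abs(total) / n, abs=1e-12)

    @given(st.integers(0, 10_000), st.floats(-10, 10))
    @settings(deadline=None, max_examples=30)
    def test_symmetry_and_common_offset_invariance(self, seed, offset):
        rng = np.random.default_rng(seed)
        a = rng.uniform(-np.pi, np.pi, 20)
        b = rng.uniform(-np.pi, np.pi, 20)
        assert pli_pair(a, b) == pytest.approx(pli_pair(b, a), abs=1e-12)
        assert pli_pair(a + offset, b + offset) == pytest.approx(pli_pair(a, b), abs=1e-9)


class TestConnectivityMatrix:
    def test_montage_shape(self):
        rng = np.random.default_rng(3)
        ph = PhaseMatrix([f"s{i}" for i in range(273)],
                         rng.uniform(-np.pi, np.pi, (273, 50)))
        graph = connectivity_matrix(ph)
        assert graph.weights.shape == (273, 273)

    def test_identical_channels_zero_weight(self):
        row = np.random.default_rng(4).uniform(-np.pi, np.pi, 200)
        graph = connectivity_matrix(PhaseMatrix(["a", "b"], np.vstack([row, row])))
        assert graph.weights[0, 1] == 0.0

    def test_independent_phases_near_zero(self):
        rng = np.random.default_rng(5)
        ph = PhaseMatrix(["a", "b", "c"], rng.uniform(-np.pi, np.pi, (3, 10_000)))
        graph = connectivity_matrix(ph)
        off = graph.weights[~np.eye(3, dtype=bool)]
        assert np.all(off < 0.05)

    @given(st.integers(0, 1000))
    @settings(deadline=None, max_examples=20)
    def test_symmetric_zero_diagonal_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 8)
        ph = PhaseMatrix([f"c{i}" for i in range(n)],
                         rng.uniform(-np.pi, np.pi, (n, 64)))
        graph = connectivity_matrix(ph)
        w = graph.weights
        assert np.array_equal(w, w.T)
        assert np.all(np.diagonal(w) == 0)
        assert w.min() >= 0 and w.max() <= 1

    def test_epoch_averaging_matches_manual_mean(self):
        rng = np.random.default_rng(6)
        phases = rng.uniform(-np.pi, np.pi, (3, 300))
        ph = PhaseMatrix(["a", "b", "c"], phases)
        averaged = connectivity_matrix(ph, epoch_samples=100).weights
        manual = np.mean([
            connectivity_matrix(PhaseMatrix(["a", "b", "c"],
                                            phases[:, i * 100:(i + 1) * 100])).weights
            for i in range(3)
        ], axis=0)
        assert np.allclose(averaged, manual, atol=1e-12)


class TestGraphInvariants:
    def test_asymmetric_matrix_rejected(self):
        w = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ValueError):
            ConnectivityGraph(["a", "b"], w)

    def test_nonzero_diagonal_rejected(self):
        w = np.array([[0.1, 0.5], [0.5, 0.0]])
        with pytest.raises(ValueError):
            ConnectivityGraph(["a", "b"], w)

    def test_out_of_range_weight_rejected(self):
        w = np.array([[0.0, 1.5], [1.5, 0.0]])
        with pytest.raises(ValueError):
            ConnectivityGraph(["a", "b"], w)
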