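import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasestim.controller import (ControllerConfig, ControllerState,
                                  controller_step, design_phase_shift_fir,
                                  frequency_response, make_state)
from phasestim.errors import ConfigError

FS = 500.0
F0 = 10.0


def oracle_response(taps, f, fs):
    """Independent brute-force DTFT at one frequency (plain Python loop)."""
    re = im = 0.0
    for k, h in enumerate(taps):
        ang = -2.0 * np.pi * f * k / fs
        re += h * np.cos(ang)
        im += h * np.sin(ang)
    return complex(re, im)


class TestKernelDesign:
    def test_phase_180_is_negated_phase_0(self):
        k0 = design_phase_shift_fir(F0, 0.0, FS)
        k180 = design_phase_shift_fir(F0, 180.0, FS)
        np.testing.assert_allclose(k180.taps, -k0.taps, atol=1e-12)

    @pytest.mark.parametrize("n_taps", [51, 151])
    @pytest.mark.parametrize("phase", list(range(0, 360, 45)))
    def test_commanded_phase_realized_at_f0(self, phase, n_taps):
        """Response phase at f0, after removing the group-delay term,
        matches the command within 1 degree (brute-force oracle)."""
        kern = design_phase_shift_fir(F0, phase, FS, n_taps=n_taps)
        h = oracle_response(kern.taps, F0, FS)
        measured = np.rad2deg(np.angle(
            h * np.exp(2j * np.pi * F0 * kern.group_delay_samples / FS)))
        err = (measured - phase + 180.0) % 360.0 - 180.0
        assert abs(err) < 1.0

    def test_band_pass_shape(self):
        kern = design_phase_shift_fir(F0, 0.0, FS)
        assert abs(oracle_response(kern.taps, F0, FS)) == pytest.approx(1.0, abs=1e-6)
        assert abs(oracle_response(kern.taps, F0 / 4, FS)) < 0.1
        assert abs(oracle_response(kern.taps, 4 * F0, FS)) < 0.1

    def test_dc_rejection(self):
        for phase in (0.0, 90.0, 200.0):
            kern = design_phase_shift_fir(F0, phase, FS, n_taps=51)
            assert abs(frequency_response(kern, [0.0])[0]) < 1e-9

    def test_real_taps_conjugate_symmetry(self):
        kern = design_phase_shift_fir(F0, 45.0, FS)
        freqs = np.array([3.0, 10.0, 42.0])
        h_pos = frequency_response(kern, freqs)
        h_neg = frequency_response(kern, -freqs)
        np.testing.assert_allclose(h_neg, np.conj(h_pos), atol=1e-12)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ConfigError):
            design_phase_shift_fir(300.0, 0.0, FS)
        with pytest.raises(ConfigError):
            design_phase_shift_fir(F0, 0.0, FS, n_taps=50)


def _config(phase=0.0, gain=1.0, output_max=1.0, n_taps=51):
    kern = design_phase_shift_fir(F0, phase, FS, n_taps=n_taps)
    return ControllerConfig(kernel=kern, gain=gain, output_max=output_max)


class TestControllerStep:
    def test_zero_history_zero_sample(self):
        cfg = _config()
        stim, _, algo = controller_step(make_state(cfg), 0.0, cfg)
        assert algo == 0.0
        assert stim.intensity == 0.0

    def test_zero_gain_never_stimulates(self):
        cfg = _config(gain=0.0)
        state = make_state(cfg)
        rng = np.random.default_rng(0)
        for x in rng.standard_normal(200):
            stim, state, _ = controller_step(state, float(x), cfg)
            assert stim.intensity == 0.0

    def test_sine_steady_state_is_delayed_unit_sine(self):
        """Unit 10 Hz sine in -> unit 10 Hz sine out, delayed by the group
        delay (closed-form FIR sinusoidal steady state)."""
        cfg = _config(phase=0.0)
        state = make_state(cfg)
        n = int(4 * FS)
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * F0 * t)
        out = np.empty(n)
        for i, xi in enumerate(x):
            _, state, out[i] = controller_step(state, float(xi), cfg)
        tail = out[n // 2:]
        assert np.max(np.abs(tail)) == pytest.approx(1.0, rel=0.02)
        delay = cfg.kernel.group_delay_samples
        np.testing.assert_allclose(out[n // 2: n - delay],
                                   x[n // 2 - delay: n - 2 * delay], atol=0.02)

    def test_streaming_equals_batch_convolution(self):
        cfg = _config(phase=135.0)
        state = make_state(cfg)
        rng = np.random.default_rng(11)
        x = rng.standard_normal(400)
        streamed = np.empty(len(x))
        for i, xi in enumerate(x):
            _, state, streamed[i] = controller_step(state, float(xi), cfg)
        batch = np.convolve(x, cfg.kernel.taps)[: len(x)]
        np.testing.assert_allclose(streamed, batch, atol=1e-9)

    @given(seed=st.integers(0, 10_000), gain=st.floats(0.0, 10.0))
    @settings(max_examples=30, derandomize=True)
    def test_rectified_output_bounds(self, seed, gain):
        """Light intensity is never negative and never exceeds the ceiling."""
        cfg = _config(phase=90.0, gain=gain, output_max=0.8)
        state = make_state(cfg)
        for x in np.random.default_rng(seed).standard_normal(120) * 5:
            stim, state, _ = controller_step(state, float(x), cfg)
            assert 0.0 <= stim.intensity <= 0.8

    def test_linearity_below_saturation(self):
        cfg = _config(gain=0.1, output_max=1e9)
        s1, s2 = make_state(cfg), make_state(cfg)
        rng = np.random.default_rng(5)
        for x in rng.standard_normal(150):
            stim1, s1, a1 = controller_step(s1, float(x), cfg)
            stim2, s2, a2 = controller_step(s2, float(2 * x), cfg)
            assert a2 == pytest.approx(2 * a1, abs=1e-12)
            if stim1.intensity > 0:
                assert stim2.intensity == pytest.approx(2 * stim1.intensity, rel=1e-9)

    def test_state_reset_clears_history(self):
        cfg = _config()
        state = make_state(cfg)
        controller_step(state, 5.0, cfg)
        state.reset()
        _, _, algo = controller_step(state, 0.0, cfg)
        assert algo == 0.0
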