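"""The closed-loop algorithm: FIR band-pass/phase-shift of the LFP.

The control law is a single FIR convolution whose kernel is a windowed
cosine (Gabor-type) atom

    h[k] = w[k] * cos(2*pi*f0*(k - c)/fs + phi),   c = (n_taps - 1)/2,

normalized to unit magnitude response at the centre frequency ``f0``.  The
window ``w`` (Hann by default) sets the band-pass width; the commanded
phase ``phi`` rotates the response at ``f0``, so the filtered oscillation
is fed back with a chosen phase lead/lag.  The causal kernel delays the
signal by the group delay ``c`` samples; commanded phase is defined
relative to that delayed signal.

The filter output is converted to a light-intensity command by a scalar
gain, hard-rectified at zero (an LED cannot emit negative light) and
saturated at a configurable ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = [
    "FirKernel",
    "ControllerConfig",
    "ControllerState",
    "StimCommand",
    "design_phase_shift_fir",
    "frequency_response",
    "controller_step",
    "make_state",
]

#: -3 dB main-lobe width of a length-L Hann window, in bins of fs/L
_HANN_3DB_BINS = 1.44


@dataclass(frozen=True)
class FirKernel:
    """FIR tap weights plus the design metadata they were built from."""

    taps: np.ndarray
    sample_rate_hz: float
    centre_freq_hz: float
    phase_shift_deg: float
    bandwidth_hz: float
    window: str = "hann"

    @property
    def n_taps(self) -> int:
        return len(self.taps)

    @property
    def group_delay_samples(self) -> int:
        return (self.n_taps - 1) // 2


def frequency_response(kernel, freqs, sample_rate_hz: float | None = None) -> np.ndarray:
    """Exact discrete-time frequency response H(f) = sum_k h[k] e^{-2pi i f k / fs}
    by direct summation over taps.

    ``kernel`` may be a :class:`FirKernel` or a bare tap array (then
    ``sample_rate_hz`` is required).
    """
    if isinstance(kernel, FirKernel):
        taps = kernel.taps
        fs = kernel.sample_rate_hz
    else:
        taps = np.asarray(kernel, dtype=float)
        if sample_rate_hz is None:
            raise ConfigError("sample_rate_hz required when passing bare taps")
        fs = sample_rate_hz
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    k = np.arange(len(taps))
    # (n_freq, n_taps) phase matrix; fine for the kernel lengths in use
    return np.exp(-2j * np.pi * np.outer(freqs, k) / fs) @ taps


def design_phase_shift_fir(
    f0: float,
    phase_deg: float,
    fs: float,
    n_taps: int = 151,
    bandwidth_hz: float | None = None,
    window: str = "hann",
) -> FirKernel:
    """Design the band-pass/phase-shift kernel.

    Parameters
    ----------
    f0 : centre frequency in Hz; must be below Nyquist.
    phase_deg : commanded phase shift at ``f0``, degrees in [0, 360).
    fs : sample rate of the controller channel in Hz.
    n_taps : odd kernel length; default 151 (~0.3 s support at 500 Hz, three
        periods of a 10 Hz oscillation — enough for useful stop-band
        rejection an octave either side of f0).
    bandwidth_hz : approximate -3 dB width of the pass band.  The window
        support is chosen as ``L ~ 1.44 * fs / bandwidth`` samples (Hann
        main-lobe relation), clipped to ``n_taps``.  Default: the widest
        window the kernel supports, i.e. ``1.44 * fs / n_taps``.
    window : "hann" or "hamming".

    The kernel is made exactly zero-mean (no DC leakage) by subtracting a
    scaled copy of the window, then normalized to unit magnitude at ``f0``.
    """
    if not 0 < f0 < fs / 2:
        raise ConfigError(f"centre frequency {f0} Hz must lie strictly below Nyquist ({fs / 2} Hz)")
    if n_taps < 3 or n_taps % 2 == 0:
        raise ConfigError(f"n_taps must be odd and >= 3, got {n_taps}")
    if bandwidth_hz is None:
        bandwidth_hz = _HANN_3DB_BINS * fs / n_taps
    if bandwidth_hz <= 0:
        raise ConfigError(f"bandwidth_hz must be positive, got {bandwidth_hz}")

    support = int(round(_HANN_3DB_BINS * fs / bandwidth_hz))
    support = min(support | 1, n_taps)  # odd, no wider than the kernel
    if window == "hann":
        w_core = np.hanning(support + 2)[1:-1]  # nonzero interior
    elif window == "hamming":
        w_core = np.hamming(support)
    else:
        raise ConfigError(f"unknown window {window!r}")
    w = np.zeros(n_taps)
    c = (n_taps - 1) // 2
    half = (support - 1) // 2
    w[c - half: c + half + 1] = w_core

    k = np.arange(n_taps)
    target = np.deg2rad(phase_deg)
    phi = target
    # For short kernels the negative-frequency image of the cosine atom leaks
    # into the pass band and skews the realized phase, so iterate the
    # construction phase until the response phase at f0 hits the command.
    for _ in range(8):
        taps = w * np.cos(2 * np.pi * f0 * (k - c) / fs + phi)
        # null the DC response exactly without leaving the window support
        taps = taps - (taps.sum() / w.sum()) * w
        h0 = frequency_response(taps, [f0], sample_rate_hz=fs)[0]
        realized = np.angle(h0 * np.exp(2j * np.pi * f0 * c / fs))
        err = (realized - target + np.pi) % (2 * np.pi) - np.pi
        if abs(err) < np.deg2rad(1e-3):
            break
        phi -= err
    # unit magnitude at the centre frequency
    taps = taps / abs(h0)
    return FirKernel(
        taps=taps,
        sample_rate_hz=float(fs),
        centre_freq_hz=float(f0),
        phase_shift_deg=float(phase_deg % 360.0),
        bandwidth_hz=float(bandwidth_hz),
        window=window,
    )


@dataclass(frozen=True)
class StimCommand:
    """One stimulation command: non-negative light intensity, replicated to
    ``n_leds`` driven LEDs (5 in the chronic fork-optrode configuration)."""

    intensity: float
    n_leds: int = 1

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ConfigError("stimulation intensity cannot be negative")


@dataclass(frozen=True)
class ControllerConfig:
    """Kernel plus LFP-to-light conversion parameters."""

    kernel: FirKernel
    gain: float = 1.0  # light-units per volt
    output_max: float = 1.0  # saturation ceiling, normalized light-units
    n_leds: int = 1

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ConfigError(f"gain must be >= 0, got {self.gain}")
        if self.output_max <= 0:
            raise ConfigError(f"output_max must be > 0, got {self.output_max}")


@dataclass
class ControllerState:
    """History buffer of the most recent ``n_taps`` input samples,
    newest first (index 0 multiplies tap 0)."""

    history: np.ndarray
    enabled: bool = True

    @staticmethod
    def for_kernel(kernel: FirKernel) -> "ControllerState":
        return ControllerState(history=np.zeros(kernel.n_taps))

    def reset(self) -> None:
        self.history[:] = 0.0


def make_state(config: ControllerConfig) -> ControllerState:
    return ControllerState.for_kernel(config.kernel)


def controller_step(
    state: ControllerState, sample: float, config: ControllerConfig
) -> tuple[StimCommand, ControllerState, float]:
    """One controller tick: push ``sample``, convolve, rectify, saturate.

    Returns ``(stim, state, algo_out)``.  ``state`` is updated in place and
    returned for convenience; cost is constant per call.
    """
    buf = state.history
    if len(buf) != config.kernel.n_taps:
        raise ConfigError("controller state buffer does not match kernel length")
    buf[1:] = buf[:-1]
    buf[0] = sample
    algo_out = float(np.dot(config.kernel.taps, buf))
    intensity = config.gain * algo_out if state.enabled else 0.0
    if intensity < 0.0:
        intensity = 0.0
    elif intensity > config.output_max:
        intensity = config.output_max
    return StimCommand(intensity=intensity, n_leds=config.n_leds), state, algo_out


def kernel_to_rows(kernel: FirKernel) -> list[tuple[int, float]]:
    """Kernel as (tap index, weight) rows for columnar text export."""
    return [(int(i), float(v)) for i, v in enumerate(kernel.taps)]
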