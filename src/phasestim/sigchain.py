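"""Models of the analog front end between neural tissue and the controller.

Two signal paths are modelled, mirroring the control-system hardware:

* the *analog-input* path used when an external voltage source (bench signal
  generator or commercial acquisition system) feeds the controller board:
  a level shifter re-scaling a bipolar +/-10 V signal into the 0-3.3 V ADC
  range, a 2nd-order anti-aliasing lowpass at 250 Hz, and uniform ADC
  quantization;
* the *tissue* path through the recording headstage: a band-pass amplifier
  cascade modelled as a 2nd-order highpass plus 1st-order lowpass.

All recursive filters are Butterworth designs; "cutoff" means the -3 dB
point.  Filters run at the loop tick rate (the front end is analog, i.e.
fast relative to the per-channel sampling), and the per-channel decimation
happens downstream in the loop engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sig

from .errors import ConfigError

__all__ = [
    "LevelShifterSpec",
    "RecursiveFilterSpec",
    "AdcSpec",
    "ChainConfig",
    "level_shift",
    "design_recursive_filter",
    "apply_filter",
    "quantize",
    "SignalChain",
]


@dataclass(frozen=True)
class LevelShifterSpec:
    """Affine voltage re-scaler with saturating rails.

    Defaults map a +/-10 V peak-to-peak bipolar input onto the 0-3.3 V
    single-supply ADC input range.
    """

    in_min: float = -10.0
    in_max: float = 10.0
    out_min: float = 0.0
    out_max: float = 3.3

    def __post_init__(self) -> None:
        if not self.in_min < self.in_max:
            raise ConfigError(
                f"level shifter: in_min ({self.in_min}) must be < in_max ({self.in_max})"
            )
        if not self.out_min < self.out_max:
            raise ConfigError(
                f"level shifter: out_min ({self.out_min}) must be < out_max ({self.out_max})"
            )

    @property
    def slope(self) -> float:
        return (self.out_max - self.out_min) / (self.in_max - self.in_min)

    @property
    def offset(self) -> float:
        return self.out_min - self.slope * self.in_min


def level_shift(x, spec: LevelShifterSpec = LevelShifterSpec()):
    """Affine map of ``x`` from the input range onto the output range.

    Inputs outside ``[in_min, in_max]`` saturate at the output rails, as a
    physical single-supply circuit would.  Accepts scalars or arrays.
    """
    y = spec.slope * np.asarray(x, dtype=float) + spec.offset
    y = np.clip(y, spec.out_min, spec.out_max)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(y)
    return y


@dataclass(frozen=True)
class RecursiveFilterSpec:
    """Specification of a Butterworth IIR filter stage.

    ``cutoff_hz`` is the -3 dB frequency (magnitude 1/sqrt(2) of the
    passband value).
    """

    kind: str  # "lowpass" | "highpass"
    order: int
    cutoff_hz: float
    sample_rate_hz: float

    def __post_init__(self) -> None:
        if self.kind not in ("lowpass", "highpass"):
            raise ConfigError(f"filter kind must be 'lowpass' or 'highpass', got {self.kind!r}")
        if self.order < 1:
            raise ConfigError(f"filter order must be >= 1, got {self.order}")
        if self.sample_rate_hz <= 0:
            raise ConfigError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        if not 0 < self.cutoff_hz < self.sample_rate_hz / 2:
            raise ConfigError(
                f"cutoff_hz ({self.cutoff_hz}) must lie strictly between 0 and "
                f"Nyquist ({self.sample_rate_hz / 2})"
            )


def design_recursive_filter(spec: RecursiveFilterSpec) -> np.ndarray:
    """Design the Butterworth filter for ``spec``; returns second-order
    sections (shape ``(n_sections, 6)``) for numerically stable streaming."""
    btype = "low" if spec.kind == "lowpass" else "high"
    return _sig.butter(spec.order, spec.cutoff_hz, btype=btype,
                       fs=spec.sample_rate_hz, output="sos")


def apply_filter(x, sos: np.ndarray) -> np.ndarray:
    """Causal batch application of a second-order-section filter, starting
    from zero internal state (identical to sample-by-sample streaming)."""
    return _sig.sosfilt(sos, np.asarray(x, dtype=float))


@dataclass(frozen=True)
class AdcSpec:
    """Uniform mid-rise analog-to-digital converter over ``[v_min, v_max]``."""

    n_bits: int = 12
    v_min: float = 0.0
    v_max: float = 3.3

    def __post_init__(self) -> None:
        if self.n_bits < 1:
            raise ConfigError(f"ADC n_bits must be >= 1, got {self.n_bits}")
        if not self.v_min < self.v_max:
            raise ConfigError(f"ADC range invalid: v_min {self.v_min} >= v_max {self.v_max}")

    @property
    def step(self) -> float:
        return (self.v_max - self.v_min) / 2**self.n_bits


def quantize(x: float, spec: AdcSpec = AdcSpec()) -> tuple[int, float]:
    """Quantize voltage ``x`` to an integer code and its reconstruction.

    Mid-rise convention: code = floor((x - v_min)/step), clamped to
    [0, 2^n - 1]; reconstruction at the cell centre so the error for any
    in-range input is at most half a step.
    """
    n_codes = 2**spec.n_bits
    code = int(np.floor((x - spec.v_min) / spec.step))
    code = min(max(code, 0), n_codes - 1)
    volts = spec.v_min + (code + 0.5) * spec.step
    return code, volts


_STAGE_NAMES = ("level_shifter", "aaf", "amp_highpass", "amp_lowpass", "adc")
# physical signal order: headstage amplifiers sit tissue-side; the level
# shifter, AAF and ADC sit at the controller-board analog input
_CHAIN_ORDER = ("amp_highpass", "amp_lowpass", "level_shifter", "aaf", "adc")


@dataclass(frozen=True)
class ChainConfig:
    """Configuration of the full front-end chain.

    ``enabled_stages`` selects which stages are active, in the fixed
    physical order: amplifier band-pass (tissue side) -> level shifter ->
    anti-aliasing filter -> ADC.  All filter stages must share one sample
    rate (the loop tick rate).
    """

    level_shifter: LevelShifterSpec = field(default_factory=LevelShifterSpec)
    aaf: RecursiveFilterSpec = field(
        default_factory=lambda: RecursiveFilterSpec("lowpass", 2, 250.0, 1000.0))
    amp_highpass: RecursiveFilterSpec = field(
        default_factory=lambda: RecursiveFilterSpec("highpass", 2, 1.0, 1000.0))
    amp_lowpass: RecursiveFilterSpec = field(
        default_factory=lambda: RecursiveFilterSpec("lowpass", 1, 200.0, 1000.0))
    adc: AdcSpec = field(default_factory=AdcSpec)
    enabled_stages: tuple[str, ...] = ("amp_highpass", "amp_lowpass")

    def __post_init__(self) -> None:
        unknown = set(self.enabled_stages) - set(_STAGE_NAMES)
        if unknown:
            raise ConfigError(f"unknown chain stage(s): {sorted(unknown)}")
        rates = {
            self.aaf.sample_rate_hz,
            self.amp_highpass.sample_rate_hz,
            self.amp_lowpass.sample_rate_hz,
        }
        if len(rates) != 1:
            raise ConfigError(f"all chain filter stages must share one sample rate, got {sorted(rates)}")

    @property
    def sample_rate_hz(self) -> float:
        return self.aaf.sample_rate_hz

    @staticmethod
    def tissue_default(sample_rate_hz: float = 1000.0) -> "ChainConfig":
        """Recording-amplifier band-pass path (headstage front end)."""
        return ChainConfig(
            aaf=RecursiveFilterSpec("lowpass", 2, 250.0, sample_rate_hz),
            amp_highpass=RecursiveFilterSpec("highpass", 2, 1.0, sample_rate_hz),
            amp_lowpass=RecursiveFilterSpec("lowpass", 1, 200.0, sample_rate_hz),
            enabled_stages=("amp_highpass", "amp_lowpass"),
        )

    @staticmethod
    def analog_input_default(sample_rate_hz: float = 1000.0) -> "ChainConfig":
        """Bench/analog-input path: level shifter -> AAF -> ADC."""
        return ChainConfig(
            aaf=RecursiveFilterSpec("lowpass", 2, 250.0, sample_rate_hz),
            amp_highpass=RecursiveFilterSpec("highpass", 2, 1.0, sample_rate_hz),
            amp_lowpass=RecursiveFilterSpec("lowpass", 1, 200.0, sample_rate_hz),
            enabled_stages=("level_shifter", "aaf", "adc"),
        )


class SignalChain:
    """Stateful streaming evaluator of a :class:`ChainConfig`.

    ``step`` processes one sample; ``process`` a whole array with identical
    results.  Stage order is fixed (see :class:`ChainConfig`) regardless of
    the order stages are named in ``enabled_stages``.
    """

    def __init__(self, config: ChainConfig):
        self.config = config
        self._stages: list[tuple] = []
        for name in _CHAIN_ORDER:
            if name not in config.enabled_stages:
                continue
            if name == "level_shifter":
                s = config.level_shifter
                self._stages.append(("affine", s.slope, s.offset, s.out_min, s.out_max))
            elif name == "adc":
                self._stages.append(("adc", config.adc))
            else:
                spec = getattr(config, name)
                sos = design_recursive_filter(spec)
                # per-section direct-form-II-transposed state [z1, z2]
                state = [[0.0, 0.0] for _ in range(sos.shape[0])]
                self._stages.append(("sos", [tuple(sec) for sec in sos], state))

    # stage order follows the physical chain: amp band-pass sits tissue-side,
    # shifter/AAF/ADC sit on the controller board input
    def reset(self) -> None:
        for stage in self._stages:
            if stage[0] == "sos":
                for z in stage[2]:
                    z[0] = z[1] = 0.0

    def step(self, x: float) -> float:
        for stage in self._stages:
            tag = stage[0]
            if tag == "sos":
                for sec, z in zip(stage[1], stage[2]):
                    b0, b1, b2, _a0, a1, a2 = sec
                    y = b0 * x + z[0]
                    z[0] = b1 * x - a1 * y + z[1]
                    z[1] = b2 * x - a2 * y
                    x = y
            elif tag == "affine":
                _, slope, offset, lo, hi = stage
                x = slope * x + offset
                if x < lo:
                    x = lo
                elif x > hi:
                    x = hi
            else:  # adc
                _, volts = quantize(x, stage[1])
                x = volts
        return x

    def process(self, x) -> np.ndarray:
        return np.array([self.step(float(v)) for v in np.asarray(x, dtype=float)])
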