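"""Synthetic neural tissue: a stochastic damped oscillator driven by light.

The in-silico stand-in for the brain slice / anesthetized preparation is the
minimal model that exhibits the phenomenon of interest — a noisy narrow-band
LFP oscillation whose power can be raised or lowered by appropriately timed
feedback.  It is a linear second-order stochastic differential equation

    x'' = -w0^2 x - 2 zeta w0 x' + k * light(t) + sigma xi(t)

with w0 = 2 pi f0 (f0 ~ 10 Hz), damping ratio zeta, white acceleration
noise xi, and a non-negative light drive coupling additively into the
acceleration (a depolarizing input increases excitability).  Because the
LED drive is rectified (light >= 0), phase-dependence of the closed loop
arises from the timing of the rectified half-waves relative to the
oscillation: feedback in phase with velocity pumps energy in (less
effective damping, more power), anti-phase feedback damps it.

Integration is fixed-step Euler-Maruyama at the loop tick, keeping the
plant sample-synchronous with the firmware emulator.  The measured LFP is
x plus white measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

__all__ = [
    "PlantConfig",
    "PlantState",
    "make_plant_state",
    "plant_step",
    "stationary_std",
    "make_burst_signal",
]


@dataclass(frozen=True)
class PlantConfig:
    """Parameters of the stochastic oscillator.

    Defaults produce an LFP-like trace: a ~0.1 V RMS narrow-band 10 Hz
    oscillation whose phase stays coherent for ~0.4 s (damping ratio 0.04),
    i.e. long against the closed loop's ~50 ms feedback latency, and a
    light coupling strong enough that rectified feedback at full gain
    can shift the effective damping by a multiple of its open-loop value — the
    regime where phase-locked stimulation visibly enhances or suppresses
    the rhythm.
    """

    natural_freq_hz: float = 10.0
    damping_ratio: float = 0.04
    noise_sd: float = 20.0  # acceleration noise intensity, V/s^2 per sqrt(Hz)
    light_coupling: float = 2000.0  # V/s^2 per light-unit
    dt_s: float = 0.001
    measurement_noise_sd: float = 0.005  # V
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.damping_ratio < 1:
            raise ConfigError(f"damping_ratio must be in (0,1), got {self.damping_ratio}")
        if self.natural_freq_hz <= 0 or self.dt_s <= 0:
            raise ConfigError("natural_freq_hz and dt_s must be positive")
        if self.dt_s * self.natural_freq_hz > 0.05:
            raise ConfigError(
                f"dt_s * natural_freq_hz = {self.dt_s * self.natural_freq_hz:.3f}; "
                "the tick must resolve the oscillation (product must be <= 0.05)")
        if self.noise_sd < 0 or self.measurement_noise_sd < 0 or self.light_coupling < 0:
            raise ConfigError("noise_sd, measurement_noise_sd and light_coupling must be >= 0")


@dataclass
class PlantState:
    x: float  # oscillation amplitude, volts
    v: float  # velocity, volts/s
    rng: np.random.Generator


def make_plant_state(config: PlantConfig, x0: float = 0.0, v0: float = 0.0) -> PlantState:
    return PlantState(x=x0, v=v0, rng=np.random.Generator(np.random.PCG64(config.rng_seed)))


def plant_step(
    state: PlantState, light: float, config: PlantConfig
) -> tuple[float, PlantState]:
    """Advance the oscillator one Euler-Maruyama step under drive ``light``.

    Returns ``(lfp_sample, state)``; the state is updated in place.  The
    sample is the post-step position plus measurement noise.
    """
    if light < 0:
        raise ConfigError(f"light drive must be non-negative, got {light}")
    dt = config.dt_s
    w0 = 2.0 * np.pi * config.natural_freq_hz
    acc = (-w0 * w0 * state.x
           - 2.0 * config.damping_ratio * w0 * state.v
           + config.light_coupling * light)
    noise = config.noise_sd * np.sqrt(dt) * state.rng.standard_normal() if config.noise_sd > 0 else 0.0
    state.v += dt * acc + noise
    state.x += dt * state.v
    lfp = state.x
    if config.measurement_noise_sd > 0:
        lfp += config.measurement_noise_sd * state.rng.standard_normal()
    return float(lfp), state


def stationary_std(config: PlantConfig) -> float:
    """Closed-form stationary standard deviation of x for the undriven
    linear stochastic oscillator: sigma / sqrt(4 zeta w0^3)."""
    w0 = 2.0 * np.pi * config.natural_freq_hz
    return config.noise_sd / np.sqrt(4.0 * config.damping_ratio * w0**3)


def make_burst_signal(
    duration_s: float,
    burst_rate_hz: float = 0.05,
    burst_freq_hz: float = 10.0,
    rng_seed: int = 0,
    fs: float = 500.0,
    background_sd: float = 0.02,
    burst_amplitude: float = 0.5,
    burst_duration_s: float = 2.0,
) -> np.ndarray:
    """Noise background with randomly timed high-amplitude oscillatory bursts.

    A coarse emulation of paroxysmal (seizure-like) activity for exercising
    the recording path: Gaussian background plus Poisson-timed, Hann-
    enveloped oscillation packets at ``burst_freq_hz``.  Deterministic for a
    fixed ``rng_seed``.
    """
    if duration_s <= 0:
        raise ConfigError(f"duration_s must be positive, got {duration_s}")
    rng = np.random.Generator(np.random.PCG64(rng_seed))
    n = int(round(duration_s * fs))
    sig = background_sd * rng.standard_normal(n)
    n_bursts = rng.poisson(burst_rate_hz * duration_s) if burst_rate_hz > 0 else 0
    burst_len = int(round(burst_duration_s * fs))
    t = np.arange(burst_len) / fs
    envelope = np.hanning(burst_len)
    for _ in range(n_bursts):
        start = int(rng.integers(0, max(n - burst_len, 1)))
        phase = rng.uniform(0, 2 * np.pi)
        sig[start:start + burst_len] += (
            burst_amplitude * envelope * np.sin(2 * np.pi * burst_freq_hz * t + phase)
        )[: n - start]
    return sig
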