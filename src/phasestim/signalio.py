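"""Plain-text columnar signal files and deterministic test fixtures.

The canonical signal format is auditable text: comment header lines with
the sample rate, units and seed provenance, then ``time_s value`` rows.
Round-trips are exact to full float precision (values written with
``repr``).
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigError, DataError

__all__ = ["write_signal", "read_signal", "make_fixture"]

_FORMAT_LINE = "# phasestim-signal v1"


def write_signal(path, samples: np.ndarray, fs: float, units: str = "V",
                 seed: int | None = None) -> None:
    """Write a uniformly sampled signal as columnar text."""
    if fs <= 0:
        raise ConfigError(f"sample rate must be positive, got {fs}")
    samples = np.asarray(samples, dtype=float)
    with open(path, "w") as fh:
        fh.write(_FORMAT_LINE + "\n")
        fh.write(f"# sample_rate_hz = {fs!r}\n")
        fh.write(f"# units = {units}\n")
        if seed is not None:
            fh.write(f"# seed = {seed}\n")
        fh.write("# columns: time_s value\n")
        for i, v in enumerate(samples):
            fh.write(f"{i / fs!r} {float(v)!r}\n")


def read_signal(path) -> tuple[np.ndarray, float]:
    """Read a columnar signal file; returns ``(samples, sample_rate_hz)``.

    The sample-rate header is mandatory; the time column must advance at
    the declared fixed step.
    """
    fs = None
    times = []
    values = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "sample_rate_hz" in line and "=" in line:
                    fs = float(line.split("=", 1)[1])
                continue
            parts = line.split()
            if len(parts) != 2:
                raise DataError(f"{path}: malformed row {line!r}")
            try:
                times.append(float(parts[0]))
                values.append(float(parts[1]))
            except ValueError as exc:
                raise DataError(f"{path}: non-numeric row {line!r}") from exc
    if fs is None:
        raise DataError(f"{path}: missing 'sample_rate_hz' header")
    if not values:
        raise DataError(f"{path}: no samples")
    t = np.asarray(times)
    expected = np.arange(len(t)) / fs
    if len(t) > 1 and np.max(np.abs(t - expected)) > 1e-9 * max(1.0, t[-1]):
        raise DataError(f"{path}: time column is not uniform at {fs} Hz")
    return np.asarray(values), fs


def make_fixture(kind: str, duration_s: float = 60.0, fs: float = 1000.0,
                 seed: int = 0, **params) -> np.ndarray:
    """Deterministic test signals.

    kinds: ``sine`` (default amplitude 0.5 V — a 1 Vpp bench input — at
    10 Hz), ``white_noise`` (sd, default 0.1), ``bursts`` (noise background
    with oscillatory bursts), ``chirp`` (linear sweep f0->f1).
    """
    if duration_s <= 0 or fs <= 0:
        raise ConfigError("duration_s and fs must be positive")
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    if kind == "sine":
        amp = float(params.pop("amplitude", 0.5))
        freq = float(params.pop("freq_hz", 10.0))
        out = amp * np.sin(2 * np.pi * freq * t)
    elif kind == "white_noise":
        sd = float(params.pop("sd", 0.1))
        rng = np.random.Generator(np.random.PCG64(seed))
        out = sd * rng.standard_normal(n)
    elif kind == "bursts":
        from .plant import make_burst_signal
        out = make_burst_signal(
            duration_s,
            burst_rate_hz=float(params.pop("burst_rate_hz", 0.05)),
            burst_freq_hz=float(params.pop("burst_freq_hz", 10.0)),
            rng_seed=seed, fs=fs)
    elif kind == "chirp":
        from scipy.signal import chirp as _chirp
        f0 = float(params.pop("f0_hz", 5.0))
        f1 = float(params.pop("f1_hz", 15.0))
        amp = float(params.pop("amplitude", 0.5))
        out = amp * _chirp(t, f0=f0, t1=duration_s, f1=f1)
    else:
        raise ConfigError(f"unknown fixture kind {kind!r}")
    if params:
        raise ConfigError(f"unknown fixture parameter(s): {sorted(params)}")
    return out
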