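"""Phase-resolved spectral analysis of closed-loop sessions.

Three analyses, mirroring how closed-loop phase-shift experiments are
reported:

* Welch power spectra per condition (Hann window, 2 s segments, 50%
  overlap at 500 Hz -> 0.5 Hz resolution, enough to resolve structure
  around a 10 Hz oscillation);
* dominant-frequency detection over a band (the bench stability check:
  a 10 Hz sine at the input must dominate the recorded spectrum at 10 Hz);
* the frequency x phase *modulation map*: per-condition power relative to
  the pooled no-stimulation epochs, in dB, optionally tiled over two phase
  cycles (0-720 deg) so the enhancement/suppression band is visually
  continuous.

Epoch heads are trimmed (default 1 s) to drop filter and loop transients;
PSDs are estimated per epoch and averaged, never across epoch
discontinuities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .errors import DataError
from .loop_engine import CONTROL_ID, SessionLog

__all__ = [
    "SpectralEstimate",
    "ModulationMap",
    "estimate_psd",
    "dominant_frequency",
    "epoch_slices",
    "modulation_map",
    "band_modulation",
    "tile_two_cycles",
    "save_modulation_map",
    "plot_modulation_map",
]


@dataclass(frozen=True)
class SpectralEstimate:
    freqs: np.ndarray  # Hz, ascending
    power: np.ndarray  # power density, units^2 / Hz
    n_segments: int
    params: dict


@dataclass(frozen=True)
class ModulationMap:
    freqs: np.ndarray  # Hz
    phases_deg: np.ndarray  # commanded phase per column; may span 0-720
    modulation: np.ndarray  # dB, shape (n_freqs, n_phases)

    def __post_init__(self) -> None:
        if self.modulation.shape != (len(self.freqs), len(self.phases_deg)):
            raise DataError("modulation matrix shape does not match its axes")


def estimate_psd(
    signal: np.ndarray,
    fs: float,
    segment_len: int | None = None,
    overlap_frac: float = 0.5,
    window: str = "hann",
) -> SpectralEstimate:
    """Welch-averaged periodogram (density scaling, no detrending).

    ``segment_len`` defaults to 2 s of samples.  Satisfies the discrete
    Parseval identity: sum(power) * df equals the mean square of the signal
    up to edge effects of the tapered segments.
    """
    x = np.asarray(signal, dtype=float)
    if segment_len is None:
        segment_len = int(round(2.0 * fs))
    if len(x) < segment_len:
        raise DataError(
            f"signal ({len(x)} samples) shorter than one segment ({segment_len})")
    noverlap = int(round(overlap_frac * segment_len))
    freqs, power = _sig.welch(x, fs=fs, window=window, nperseg=segment_len,
                              noverlap=noverlap, detrend=False)
    step = segment_len - noverlap
    n_segments = (len(x) - segment_len) // step + 1
    return SpectralEstimate(
        freqs=freqs, power=power, n_segments=n_segments,
        params={"segment_len": segment_len, "overlap_frac": overlap_frac,
                "window": window, "fs": fs})


def dominant_frequency(est: SpectralEstimate, f_min: float, f_max: float) -> float:
    """Frequency of maximum power within [f_min, f_max]; ties resolve to the
    lower frequency (argmax returns the first index)."""
    mask = (est.freqs >= f_min) & (est.freqs <= f_max)
    if not mask.any():
        raise DataError(f"band [{f_min}, {f_max}] Hz contains no spectral bins")
    band_f = est.freqs[mask]
    band_p = est.power[mask]
    return float(band_f[np.argmax(band_p)])


@dataclass(frozen=True)
class EpochSlice:
    epoch_index: int
    condition_id: int  # CONTROL_ID for control epochs
    phase_deg: float | None
    start: int  # control-channel sample index, head-trim applied
    stop: int
    raw_start: int  # untrimmed start, for partition checks


def epoch_slices(log: SessionLog, trim_s: float = 1.0) -> list[EpochSlice]:
    """Contiguous per-epoch index ranges on the control channel.

    Indices address the channel-0 sample series (``log.channel_series(0)``).
    Each epoch's head is trimmed by ``trim_s`` to discard loop transients.
    """
    cfg = log.header["config"]
    n_ch = cfg["n_channels"]
    fs_ch = 1.0 / (cfg["tick_period_s"] * n_ch)
    trim = int(round(trim_s * fs_ch))
    phase_by_id = {c["condition_id"]: c["phase_shift_deg"] for c in cfg["conditions"]}

    ticks = log.packets["tick"].to_numpy()
    epoch_idx = log.packets["epoch_index"].to_numpy()
    cond_id = log.packets["condition_id"].to_numpy()
    # epoch boundaries in tick space
    change = np.flatnonzero(np.diff(epoch_idx)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(ticks)]])
    out: list[EpochSlice] = []
    for s, e in zip(starts, stops):
        t0, t1 = int(ticks[s]), int(ticks[e - 1]) + 1
        # channel-0 samples fall on ticks divisible by n_ch
        i0 = (t0 + n_ch - 1) // n_ch
        i1 = (t1 + n_ch - 1) // n_ch
        cid = int(cond_id[s])
        out.append(EpochSlice(
            epoch_index=int(epoch_idx[s]),
            condition_id=cid,
            phase_deg=phase_by_id.get(cid),
            start=min(i0 + trim, i1),
            stop=i1,
            raw_start=i0,
        ))
    return out


def _mean_psd_over_epochs(
    series: np.ndarray, fs: float, slices: list[EpochSlice],
    segment_len: int, overlap_frac: float, window: str,
) -> tuple[np.ndarray, np.ndarray, int]:
    psds = []
    n_seg = 0
    for sl in slices:
        chunk = series[sl.start: sl.stop]
        if len(chunk) < segment_len:
            continue
        est = estimate_psd(chunk, fs, segment_len, overlap_frac, window)
        psds.append(est.power)
        n_seg += est.n_segments
    if not psds:
        raise DataError("no epoch long enough for one spectral segment")
    est_freqs = estimate_psd(series[slices[0].start: slices[0].stop], fs,
                             segment_len, overlap_frac, window).freqs
    return est_freqs, np.mean(psds, axis=0), n_seg


def modulation_map(
    log: SessionLog,
    f_max: float | None = 50.0,
    trim_s: float = 1.0,
    segment_s: float = 2.0,
    overlap_frac: float = 0.5,
    window: str = "hann",
    tile: bool = False,
) -> ModulationMap:
    """Per-phase power modulation relative to pooled control epochs, in dB.

    For each stimulation condition, PSDs are estimated per epoch (never
    across discontinuities) and averaged; all control epochs pool into one
    reference spectrum.  M(f, phi) = 10 log10(P_phi(f) / P_control(f)).
    ``tile=True`` duplicates the phase axis over a second cycle (0-720 deg).
    """
    series, fs = log.channel_series(0)
    slices = epoch_slices(log, trim_s=trim_s)
    seg = int(round(segment_s * fs))
    ctrl = [sl for sl in slices if sl.condition_id == CONTROL_ID]
    if not ctrl:
        raise DataError("session log contains no control epochs")
    by_cond: dict[int, list[EpochSlice]] = {}
    for sl in slices:
        if sl.condition_id != CONTROL_ID:
            by_cond.setdefault(sl.condition_id, []).append(sl)
    if not by_cond:
        raise DataError("session log contains no stimulation epochs")

    freqs, p_ctrl, _ = _mean_psd_over_epochs(series, fs, ctrl, seg, overlap_frac, window)
    keep = freqs <= f_max if f_max is not None else slice(None)
    freqs_out = freqs[keep]
    # guard the DC bin (highpass chain nulls it in both numerator and denominator)
    floor = np.finfo(float).tiny

    cond_meta = {c["condition_id"]: c["phase_shift_deg"]
                 for c in log.header["config"]["conditions"]}
    order = sorted(by_cond, key=lambda cid: cond_meta[cid])
    cols = []
    phases = []
    for cid in order:
        _, p_cond, _ = _mean_psd_over_epochs(series, fs, by_cond[cid], seg,
                                             overlap_frac, window)
        m = 10.0 * np.log10(np.maximum(p_cond[keep], floor)
                            / np.maximum(p_ctrl[keep], floor))
        cols.append(m)
        phases.append(cond_meta[cid])
    mm = ModulationMap(freqs=freqs_out, phases_deg=np.array(phases, float),
                       modulation=np.column_stack(cols))
    return tile_two_cycles(mm) if tile else mm


def tile_two_cycles(mm: ModulationMap) -> ModulationMap:
    """Duplicate the phase axis over a second cycle so the unwrapped map
    spans 0-720 deg with M(f, phi) = M(f, phi + 360) exactly."""
    if mm.phases_deg.max() >= 360.0:
        return mm
    return ModulationMap(
        freqs=mm.freqs,
        phases_deg=np.concatenate([mm.phases_deg, mm.phases_deg + 360.0]),
        modulation=np.concatenate([mm.modulation, mm.modulation], axis=1),
    )


def band_modulation(mm: ModulationMap, f_lo: float, f_hi: float) -> np.ndarray:
    """Mean modulation over a frequency band, one value per phase column.

    Averages are taken on the power ratio (linear scale), then re-expressed
    in dB, so the result is the modulation of band power."""
    mask = (mm.freqs >= f_lo) & (mm.freqs <= f_hi)
    if not mask.any():
        raise DataError(f"band [{f_lo}, {f_hi}] Hz contains no spectral bins")
    lin = 10.0 ** (mm.modulation[mask] / 10.0)
    return 10.0 * np.log10(lin.mean(axis=0))


def save_modulation_map(mm: ModulationMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("# phasestim-modulation-map v1\n")
        fh.write("freq_hz,phase_deg,modulation_db\n")
        for j, ph in enumerate(mm.phases_deg):
            for i, f in enumerate(mm.freqs):
                fh.write(f"{float(f)!r},{float(ph)!r},{float(mm.modulation[i, j])!r}\n")


def plot_modulation_map(mm: ModulationMap, path, f_lo: float = 1.0,
                        f_hi: float = 30.0) -> None:
    """Render the map as a diverging heat map (red = enhancement,
    blue = suppression)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mask = (mm.freqs >= f_lo) & (mm.freqs <= f_hi)
    data = mm.modulation[mask]
    vmax = max(abs(data).max(), 1e-3)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.pcolormesh(mm.phases_deg, mm.freqs[mask], data, cmap="RdBu_r",
                       vmin=-vmax, vmax=vmax, shading="nearest")
    ax.set_xlabel("commanded phase shift (deg)")
    ax.set_ylabel("frequency (Hz)")
    fig.colorbar(im, ax=ax, label="power vs control (dB)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
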