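"""Discrete-time emulator of the firmware control loop.

One interrupt tick (default 1 ms) performs, in order: (1) advance the
plant by one step using the stimulation command issued ``loop_delay_ticks``
earlier; (2) push the measured LFP through the analog front-end chain and
sample the channel scheduled for this tick (channels are sampled in an
alternating manner, so each channel's effective rate is
``1/(tick_period * n_channels)`` — 500 Hz for the 1 ms / 2-channel
default); (3) if the sampled channel is the control channel (channel 0),
run one FIR controller step; (4) gate the command by the epoch plan —
control epochs force stimulation off; (5) append one packet to the session
log.  Between controller updates the command is held (zero-order hold).

Everything is deterministic given the session seed: the plant process and
measurement noise streams are spawned from a single ``SeedSequence`` and
the epoch plan from its own planner seed, so a session can be re-run
bit-identically from its logged header.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .controller import design_phase_shift_fir
from .errors import ConfigError, DataError
from .plant import PlantConfig
from .scheduler import (Condition, EpochPlan, PlannerConfig, build_plan,
                        default_phase_grid)
from .sigchain import ChainConfig, SignalChain

__all__ = [
    "ControllerParams",
    "LoopConfig",
    "SessionLog",
    "effective_channel_rate",
    "default_loop_config",
    "run_session",
    "replay_session",
    "stability_test_session",
    "rerun_from_header",
    "save_log",
    "load_log",
    "loop_config_to_dict",
    "loop_config_from_dict",
]

CONTROL_ID = -1  # condition_id used in logs for control periods


def effective_channel_rate(tick_period_s: float, n_channels: int) -> float:
    """Per-channel sampling rate when channels are read out alternately:
    1 / (tick_period_s * n_channels).  1 ms tick, 2 channels -> 500 Hz."""
    if tick_period_s <= 0 or n_channels < 1:
        raise ConfigError("tick_period_s must be > 0 and n_channels >= 1")
    return 1.0 / (tick_period_s * n_channels)


@dataclass(frozen=True)
class ControllerParams:
    """Shared controller settings; per-condition f0/phase/gain come from the
    epoch plan's conditions.

    The closed-loop kernel default is short (51 taps -> 50 ms group delay
    at 500 Hz): feedback latency must stay well inside the target rhythm's
    phase-coherence time or the commanded phase smears.  Offline spectral
    characterization favours longer kernels (the design function's own
    default); both are configurable.
    """

    n_taps: int = 51
    bandwidth_hz: float | None = None
    window: str = "hann"
    output_max: float = 1.0
    n_leds: int = 1


@dataclass(frozen=True)
class LoopConfig:
    tick_period_s: float = 0.001
    n_channels: int = 2
    loop_delay_ticks: int = 1
    seed: int = 0
    input_source: str = "plant"  # or "external"
    chain: ChainConfig = field(default_factory=lambda: ChainConfig.tissue_default())
    controller: ControllerParams = field(default_factory=ControllerParams)
    planner: PlannerConfig = field(default_factory=PlannerConfig)
    conditions: tuple[Condition, ...] = field(
        default_factory=lambda: tuple(default_phase_grid()))
    plant: PlantConfig = field(default_factory=PlantConfig)

    def __post_init__(self) -> None:
        if self.tick_period_s <= 0:
            raise ConfigError(f"tick_period_s must be > 0, got {self.tick_period_s}")
        if self.n_channels < 1:
            raise ConfigError(f"n_channels must be >= 1, got {self.n_channels}")
        if self.loop_delay_ticks < 1:
            raise ConfigError(f"loop_delay_ticks must be >= 1, got {self.loop_delay_ticks}")
        if self.input_source not in ("plant", "external"):
            raise ConfigError(f"input_source must be 'plant' or 'external', got {self.input_source!r}")
        tick_hz = 1.0 / self.tick_period_s
        if abs(self.chain.sample_rate_hz - tick_hz) > 1e-6 * tick_hz:
            raise ConfigError(
                f"chain sample rate ({self.chain.sample_rate_hz} Hz) must equal the "
                f"loop tick rate ({tick_hz} Hz)")
        fs_ctrl = effective_channel_rate(self.tick_period_s, self.n_channels)
        for c in self.conditions:
            if not 0 < c.centre_freq_hz < fs_ctrl / 2:
                raise ConfigError(
                    f"condition {c.condition_id}: centre frequency {c.centre_freq_hz} Hz "
                    f"violates Nyquist for the {fs_ctrl} Hz control channel")
        if abs(self.plant.dt_s - self.tick_period_s) > 1e-12:
            raise ConfigError("plant dt_s must equal tick_period_s (sample-synchronous loop)")

    @property
    def tick_hz(self) -> float:
        return 1.0 / self.tick_period_s

    @property
    def control_rate_hz(self) -> float:
        return effective_channel_rate(self.tick_period_s, self.n_channels)


def default_loop_config(seed: int = 0, gain: float = 1.0,
                        on_duration_s: float = 10.0,
                        off_duration_s: float = 10.0,
                        order: str = "pseudorandom") -> LoopConfig:
    """The standard 8-phase closed-loop session configuration."""
    return LoopConfig(
        seed=seed,
        planner=PlannerConfig(on_duration_s=on_duration_s,
                              off_duration_s=off_duration_s,
                              order=order, rng_seed=seed),
        conditions=tuple(default_phase_grid(gain=gain)),
        plant=dataclasses.replace(PlantConfig(), rng_seed=seed),
    )


# ---------------------------------------------------------------------------
# config (de)serialization — the session-log header must reproduce a session


def loop_config_to_dict(cfg: LoopConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["chain"]["enabled_stages"] = list(cfg.chain.enabled_stages)
    d["conditions"] = [dataclasses.asdict(c) for c in cfg.conditions]
    return d


def loop_config_from_dict(d: dict) -> LoopConfig:
    d = dict(d)
    chain = dict(d.pop("chain"))
    from .sigchain import AdcSpec, LevelShifterSpec, RecursiveFilterSpec
    chain_obj = ChainConfig(
        level_shifter=LevelShifterSpec(**chain["level_shifter"]),
        aaf=RecursiveFilterSpec(**chain["aaf"]),
        amp_highpass=RecursiveFilterSpec(**chain["amp_highpass"]),
        amp_lowpass=RecursiveFilterSpec(**chain["amp_lowpass"]),
        adc=AdcSpec(**chain["adc"]),
        enabled_stages=tuple(chain["enabled_stages"]),
    )
    return LoopConfig(
        tick_period_s=d["tick_period_s"],
        n_channels=d["n_channels"],
        loop_delay_ticks=d["loop_delay_ticks"],
        seed=d["seed"],
        input_source=d["input_source"],
        chain=chain_obj,
        controller=ControllerParams(**d["controller"]),
        planner=PlannerConfig(**d["planner"]),
        conditions=tuple(Condition(**c) for c in d["conditions"]),
        plant=PlantConfig(**d["plant"]),
    )


# ---------------------------------------------------------------------------
# session log


_PACKET_COLUMNS = ("tick", "time_s", "channel", "raw_lfp", "algo_out",
                   "stim_intensity", "condition_id", "epoch_index")


@dataclass
class SessionLog:
    """Header (full configuration + seeds + version) and per-tick packets."""

    header: dict
    packets: pd.DataFrame

    @property
    def config(self) -> LoopConfig:
        return loop_config_from_dict(self.header["config"])

    @property
    def n_ticks(self) -> int:
        return len(self.packets)

    def channel_series(self, channel: int = 0) -> tuple[np.ndarray, float]:
        """Recorded samples of one channel and their sample rate."""
        cfg = self.header["config"]
        mask = self.packets["channel"].to_numpy() == channel
        fs = effective_channel_rate(cfg["tick_period_s"], cfg["n_channels"])
        return self.packets["raw_lfp"].to_numpy()[mask], fs


def _design_condition_kernels(cfg: LoopConfig) -> dict[int, tuple[np.ndarray, float]]:
    fs_ctrl = cfg.control_rate_hz
    out: dict[int, tuple[np.ndarray, float]] = {}
    for c in cfg.conditions:
        kern = design_phase_shift_fir(
            c.centre_freq_hz, c.phase_shift_deg, fs_ctrl,
            n_taps=cfg.controller.n_taps,
            bandwidth_hz=cfg.controller.bandwidth_hz,
            window=cfg.controller.window)
        out[c.condition_id] = (kern.taps, c.gain)
    return out


def run_session(cfg: LoopConfig, duration_s: float | None = None,
                external: np.ndarray | None = None) -> SessionLog:
    """Run a closed-loop (or externally driven) session and return its log.

    ``duration_s`` defaults to the full epoch-plan duration and may not
    exceed it.  In ``input_source='external'`` mode, ``external`` supplies
    one raw sample per tick (open actuation — commands are logged but drive
    nothing).
    """
    plan = build_plan(list(cfg.conditions), cfg.planner, cfg.tick_hz)
    if duration_s is None:
        n = plan.total_ticks
    else:
        n = int(round(duration_s * cfg.tick_hz))
        if n > plan.total_ticks:
            raise ConfigError(
                f"duration {duration_s} s exceeds the epoch plan ({plan.total_ticks / cfg.tick_hz} s)")
    if cfg.input_source == "external":
        if external is None:
            raise ConfigError("input_source='external' requires an external sample array")
        if len(external) < n:
            raise DataError(f"external input has {len(external)} samples, need {n}")
    header = {
        "format": "phasestim-session-log",
        "version": 1,
        "software_version": _pkg_version,
        "duration_s": n * cfg.tick_period_s,
        "config": loop_config_to_dict(cfg),
    }
    packets = _run_ticks(cfg, plan, n, external)
    return SessionLog(header=header, packets=packets)


def _run_ticks(cfg: LoopConfig, plan: EpochPlan, n: int,
               external: np.ndarray | None) -> pd.DataFrame:
    dt = cfg.tick_period_s
    n_ch = cfg.n_channels
    delay = cfg.loop_delay_ticks
    plant_mode = cfg.input_source == "plant"

    # noise streams: one SeedSequence child per stream, independent of loop
    # structure so an identical header reproduces identical draws
    ss = np.random.SeedSequence(cfg.seed)
    ss_proc, ss_meas = ss.spawn(2)
    if plant_mode:
        p = cfg.plant
        proc = (np.random.Generator(np.random.PCG64(ss_proc)).standard_normal(n)
                * (p.noise_sd * np.sqrt(dt)))
        meas = (np.random.Generator(np.random.PCG64(ss_meas)).standard_normal(n)
                * p.measurement_noise_sd)
        w2 = (2.0 * np.pi * p.natural_freq_hz) ** 2
        two_zw = 2.0 * p.damping_ratio * 2.0 * np.pi * p.natural_freq_hz
        coupling = p.light_coupling
    else:
        ext = np.asarray(external, dtype=float)

    chain = SignalChain(cfg.chain)
    stages = chain._stages  # inlined below for per-tick speed
    kernels = _design_condition_kernels(cfg)
    out_max = cfg.controller.output_max

    # per-cycle lookups
    cyc = plan.cycle_ticks
    on_ticks = plan.on_ticks
    off_ticks = plan.off_ticks
    seq_taps = [kernels[c.condition_id][0] for c in plan.sequence]
    seq_gain = [kernels[c.condition_id][1] for c in plan.sequence]
    seq_id = [c.condition_id for c in plan.sequence]

    raw = np.empty(n)
    algo = np.empty(n)
    stim = np.empty(n)
    cond_col = np.empty(n, dtype=np.int64)
    epoch_col = np.empty(n, dtype=np.int64)
    applied = np.zeros(n + delay)  # applied[t] drives the plant at tick t

    x = 0.0
    v = 0.0
    buf = np.zeros(cfg.controller.n_taps)
    a_out = 0.0
    hold = 0.0
    prev_epoch = -1
    taps = seq_taps[0]
    gain = seq_gain[0]
    dot = np.dot

    for t in range(n):
        # (1) actuate + advance plant with the delayed command
        if plant_mode:
            acc = -w2 * x - two_zw * v + coupling * applied[t]
            v += dt * acc + proc[t]
            x += dt * v
            y = x + meas[t]
        else:
            y = ext[t]
        # (2) front-end chain (streaming, at the tick rate)
        for stage in stages:
            tag = stage[0]
            if tag == "sos":
                for sec, z in zip(stage[1], stage[2]):
                    b0, b1, b2, _a0, a1, a2 = sec
                    yy = b0 * y + z[0]
                    z[0] = b1 * y - a1 * yy + z[1]
                    z[1] = b2 * y - a2 * yy
                    y = yy
            elif tag == "affine":
                _, slope, offset, lo, hi = stage
                y = slope * y + offset
                if y < lo:
                    y = lo
                elif y > hi:
                    y = hi
            else:  # adc (mid-rise)
                spec = stage[1]
                code = int((y - spec.v_min) / spec.step)
                if code < 0:
                    code = 0
                elif code >= 2 ** spec.n_bits:
                    code = 2 ** spec.n_bits - 1
                y = spec.v_min + (code + 0.5) * spec.step
        # scheduler state for this tick
        cycle, within = divmod(t, cyc)
        is_stim = within < on_ticks
        e_idx = (2 * cycle + (0 if is_stim else 1)) if off_ticks > 0 else cycle
        if e_idx != prev_epoch:
            prev_epoch = e_idx
            taps = seq_taps[cycle]
            gain = seq_gain[cycle]
            if is_stim:
                buf[:] = 0.0  # conditions start from a cleared history
        # (3) controller on the control channel only (channel 0)
        if t % n_ch == 0:
            buf[1:] = buf[:-1]
            buf[0] = y
            a_out = float(dot(taps, buf))
            val = gain * a_out
            if val < 0.0:
                val = 0.0
            elif val > out_max:
                val = out_max
            hold = val
        # (4) epoch gate: control periods force stimulation off
        s = hold if is_stim else 0.0
        applied[t + delay] = s
        # (5) packet
        raw[t] = y
        algo[t] = a_out
        stim[t] = s
        cond_col[t] = seq_id[cycle] if is_stim else CONTROL_ID
        epoch_col[t] = e_idx

    ticks = np.arange(n, dtype=np.int64)
    return pd.DataFrame({
        "tick": ticks,
        "time_s": ticks * dt,
        "channel": (ticks % n_ch).astype(np.int64),
        "raw_lfp": raw,
        "algo_out": algo,
        "stim_intensity": stim,
        "condition_id": cond_col,
        "epoch_index": epoch_col,
    })


def replay_session(samples: np.ndarray, fs: float, cfg: LoopConfig) -> SessionLog:
    """Offline replay: run chain + controller + scheduler over a recorded
    single-channel LFP, producing the stimulation trace the hardware would
    have emitted.  No plant: the loop is open.

    ``fs`` must equal the configured controller rate (the kernel sample
    rate): a file recorded at 1000 Hz cannot drive a controller designed
    for 500 Hz.
    """
    expected_fs = cfg.control_rate_hz
    if abs(fs - expected_fs) > 1e-6 * expected_fs:
        raise ConfigError(
            f"replay file at {fs:g} Hz does not match the configured controller "
            f"rate of {expected_fs:g} Hz")
    replay_cfg = dataclasses.replace(
        cfg,
        n_channels=1,
        tick_period_s=1.0 / fs,
        input_source="external",
        chain=_rerate_chain(cfg.chain, fs),
        plant=dataclasses.replace(cfg.plant, dt_s=1.0 / fs),
    )
    fs_ctrl = replay_cfg.control_rate_hz
    if abs(fs_ctrl - fs) > 1e-6 * fs:
        raise ConfigError(f"replay sample rate {fs} Hz does not match controller rate {fs_ctrl} Hz")
    n_avail = len(samples)
    plan = build_plan(list(replay_cfg.conditions), replay_cfg.planner, fs)
    duration = min(n_avail, plan.total_ticks) / fs
    return run_session(replay_cfg, duration_s=duration, external=np.asarray(samples, float))


def _rerate_chain(chain: ChainConfig, fs: float) -> ChainConfig:
    """Re-declare the filter stages of ``chain`` at sample rate ``fs``.

    Enabled stages keep their corner frequencies (a corner at or above the
    new Nyquist raises).  Disabled stages are inert, so their corners are
    clamped below Nyquist instead of blocking the replay."""
    def rerate(spec, name):
        cutoff = spec.cutoff_hz
        if name not in chain.enabled_stages and cutoff >= fs / 2:
            cutoff = fs / 4
        return dataclasses.replace(spec, cutoff_hz=cutoff, sample_rate_hz=fs)

    return ChainConfig(
        level_shifter=chain.level_shifter,
        aaf=rerate(chain.aaf, "aaf"),
        amp_highpass=rerate(chain.amp_highpass, "amp_highpass"),
        amp_lowpass=rerate(chain.amp_lowpass, "amp_lowpass"),
        adc=chain.adc,
        enabled_stages=chain.enabled_stages,
    )


def stability_test_session(duration_s: float = 60.0, seed: int = 0,
                           freq_hz: float = 10.0,
                           amplitude_v: float = 0.5) -> SessionLog:
    """Bench stability check, emulated end-to-end.

    A 1 Vpp (0.5 V amplitude) sine at ``freq_hz`` is fed through the
    analog-input path — level shifter, anti-aliasing filter, ADC — and the
    loop engine runs the closed-loop algorithm over it.  The recorded
    channel's spectrum should be dominated by ``freq_hz``.
    """
    base = default_loop_config(seed=seed, on_duration_s=duration_s,
                               off_duration_s=0.0, order="sequential")
    cfg = dataclasses.replace(
        base,
        input_source="external",
        chain=ChainConfig.analog_input_default(base.tick_hz),
        conditions=base.conditions[:1],
    )
    n = int(round(duration_s * cfg.tick_hz))
    t = np.arange(n) * cfg.tick_period_s
    sine = amplitude_v * np.sin(2 * np.pi * freq_hz * t)
    return run_session(cfg, duration_s=duration_s, external=sine)


def rerun_from_header(header: dict) -> SessionLog:
    """Re-run a session from its logged header; bit-identical for plant
    sessions (external-input sessions need the original input file)."""
    cfg = loop_config_from_dict(header["config"])
    if cfg.input_source != "plant":
        raise DataError("cannot re-run an external-input session from its header alone")
    return run_session(cfg, duration_s=header["duration_s"])


# ---------------------------------------------------------------------------
# text persistence (canonical form: header block + columnar packet table)


def save_log(log: SessionLog, path) -> None:
    with open(path, "w") as fh:
        fh.write("# phasestim-session-log v1\n")
        fh.write("# header: " + json.dumps(log.header) + "\n")
        log.packets.to_csv(fh, index=False)


def load_log(path) -> SessionLog:
    header = None
    skip = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
                if line.startswith("# header:"):
                    header = json.loads(line[len("# header:"):])
            else:
                break
    if header is None:
        raise DataError(f"{path}: missing '# header:' line — not a session log")
    # round_trip parsing: the text log is the canonical store and must
    # reproduce the in-memory packet stream bit-for-bit
    packets = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    missing = set(_PACKET_COLUMNS) - set(packets.columns)
    if missing:
        raise DataError(f"{path}: packet table missing columns {sorted(missing)}")
    return SessionLog(header=header, packets=packets)
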