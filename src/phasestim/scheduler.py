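"""Experiment plan: timed stimulation epochs interleaved with controls.

A session cycles through the requested conditions (each fixing the FIR
centre frequency, phase shift and LFP-to-light gain), in sequential or
seeded pseudorandom order, with every ON epoch immediately followed by a
no-stimulation control epoch.  Pseudorandom order permutes conditions
independently within each repetition block, using numpy's PCG64 generator
so plans are bit-reproducible for a fixed seed.

Control epochs keep a reference to the preceding condition (useful for
paired analyses), but the default spectral analysis pools all controls into
a single reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError

__all__ = [
    "CONTROL",
    "Condition",
    "PlannerConfig",
    "Epoch",
    "EpochPlan",
    "build_plan",
    "condition_at",
    "default_phase_grid",
]


class _Control:
    """Singleton marker for no-stimulation control periods."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "CONTROL"


CONTROL = _Control()


@dataclass(frozen=True)
class Condition:
    """One closed-loop stimulation condition."""

    condition_id: int
    centre_freq_hz: float
    phase_shift_deg: float
    gain: float

    def __post_init__(self) -> None:
        if not 0 <= self.phase_shift_deg < 360:
            raise ConfigError(
                f"phase_shift_deg must be in [0, 360), got {self.phase_shift_deg}")


@dataclass(frozen=True)
class PlannerConfig:
    on_duration_s: float = 10.0
    off_duration_s: float = 10.0
    order: str = "pseudorandom"  # or "sequential"
    repetitions: int = 1
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.on_duration_s <= 0:
            raise ConfigError(f"on_duration_s must be > 0, got {self.on_duration_s}")
        if self.off_duration_s < 0:
            raise ConfigError(f"off_duration_s must be >= 0, got {self.off_duration_s}")
        if self.order not in ("sequential", "pseudorandom"):
            raise ConfigError(f"order must be 'sequential' or 'pseudorandom', got {self.order!r}")
        if self.repetitions < 1:
            raise ConfigError(f"repetitions must be >= 1, got {self.repetitions}")


@dataclass(frozen=True)
class Epoch:
    """Half-open tick interval [start_tick, end_tick)."""

    index: int
    start_tick: int
    end_tick: int
    condition: Condition | _Control
    ref_condition: Condition  # for controls: the condition that preceded

    @property
    def is_control(self) -> bool:
        return self.condition is CONTROL


@dataclass(frozen=True)
class EpochPlan:
    epochs: tuple[Epoch, ...]
    tick_hz: float
    on_ticks: int
    off_ticks: int
    sequence: tuple[Condition, ...] = field(repr=False)  # one entry per ON/OFF cycle

    @property
    def total_ticks(self) -> int:
        return self.epochs[-1].end_tick

    @property
    def cycle_ticks(self) -> int:
        return self.on_ticks + self.off_ticks

    def lookup(self, tick: int) -> tuple[int, Condition, bool]:
        """Constant-time lookup: (epoch_index, condition, is_stimulation).

        During control epochs the returned condition is the preceding one
        (its kernel stays loaded; stimulation is gated off).
        """
        if not 0 <= tick < self.total_ticks:
            raise IndexError(f"tick {tick} outside plan [0, {self.total_ticks})")
        cycle, within = divmod(tick, self.cycle_ticks)
        is_stim = within < self.on_ticks
        cond = self.sequence[cycle]
        if self.off_ticks > 0:
            epoch_index = 2 * cycle + (0 if is_stim else 1)
        else:
            epoch_index = cycle
        return epoch_index, cond, is_stim


def default_phase_grid(
    centre_freq_hz: float = 10.0, gain: float = 1.0
) -> list[Condition]:
    """The standard 8-condition grid: phase shifts 0-315 deg in 45 deg steps,
    shared centre frequency and gain."""
    return [
        Condition(condition_id=i, centre_freq_hz=centre_freq_hz,
                  phase_shift_deg=45.0 * i, gain=gain)
        for i in range(8)
    ]


def build_plan(
    conditions: list[Condition], config: PlannerConfig, tick_hz: float
) -> EpochPlan:
    """Lay the conditions out as contiguous ON/OFF cycles.

    Deterministic given ``config.rng_seed``: pseudorandom mode draws one
    independent permutation per repetition block from PCG64.
    """
    if not conditions:
        raise ConfigError("condition list must not be empty")
    if tick_hz <= 0:
        raise ConfigError(f"tick_hz must be positive, got {tick_hz}")
    ids = [c.condition_id for c in conditions]
    if len(set(ids)) != len(ids):
        raise ConfigError("condition_id values must be unique")

    on_ticks = int(round(config.on_duration_s * tick_hz))
    off_ticks = int(round(config.off_duration_s * tick_hz))
    if on_ticks < 1:
        raise ConfigError("on_duration_s shorter than one tick")

    rng = np.random.Generator(np.random.PCG64(config.rng_seed))
    sequence: list[Condition] = []
    for _ in range(config.repetitions):
        block = list(conditions)
        if config.order == "pseudorandom":
            block = [block[i] for i in rng.permutation(len(block))]
        sequence.extend(block)

    epochs: list[Epoch] = []
    t = 0
    for cond in sequence:
        epochs.append(Epoch(len(epochs), t, t + on_ticks, cond, cond))
        t += on_ticks
        if off_ticks > 0:
            epochs.append(Epoch(len(epochs), t, t + off_ticks, CONTROL, cond))
            t += off_ticks
    return EpochPlan(
        epochs=tuple(epochs),
        tick_hz=float(tick_hz),
        on_ticks=on_ticks,
        off_ticks=off_ticks,
        sequence=tuple(sequence),
    )


def condition_at(plan: EpochPlan, tick: int):
    """Condition active at ``tick``; CONTROL if in a no-stimulation period."""
    _, cond, is_stim = plan.lookup(tick)
    return cond if is_stim else CONTROL


def plan_to_rows(plan: EpochPlan) -> list[tuple]:
    """Plan as audit rows: (epoch, start_s, end_s, label, f0, phase, gain)."""
    rows = []
    for ep in plan.epochs:
        if ep.is_control:
            rows.append((ep.index, ep.start_tick / plan.tick_hz,
                         ep.end_tick / plan.tick_hz, "CONTROL", "", "", ""))
        else:
            c = ep.condition
            rows.append((ep.index, ep.start_tick / plan.tick_hz,
                         ep.end_tick / plan.tick_hz, c.condition_id,
                         c.centre_freq_hz, c.phase_shift_deg, c.gain))
    return rows
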