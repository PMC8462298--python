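"""Structured run configuration: YAML loading, validation, defaults.

A run file has nested sections (``loop``, ``sigchain``, ``controller``,
``scheduler``, ``plant``, ``analysis``) plus a global ``seed``.  Every key
is optional — defaults are the standard 8-phase closed-loop session — but
unknown keys are rejected by name, and derived quantities (filter sample
rates, plant integration step, planner seed) are filled in from the loop
section so a config cannot be internally inconsistent.  The fully resolved
configuration, defaults included, is what run headers and manifests echo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ConfigError
from .loop_engine import ControllerParams, LoopConfig, loop_config_to_dict
from .plant import PlantConfig
from .scheduler import Condition, PlannerConfig, default_phase_grid
from .sigchain import AdcSpec, ChainConfig, LevelShifterSpec, RecursiveFilterSpec

__all__ = ["AnalysisParams", "RunConfig", "load_config", "build_run_config"]


@dataclass(frozen=True)
class AnalysisParams:
    segment_s: float = 2.0
    overlap_frac: float = 0.5
    window: str = "hann"
    trim_s: float = 1.0
    f_max: float = 50.0

    def __post_init__(self) -> None:
        if self.segment_s <= 0:
            raise ConfigError(f"analysis segment_s must be > 0, got {self.segment_s}")
        if not 0 <= self.overlap_frac < 1:
            raise ConfigError(f"analysis overlap_frac must be in [0,1), got {self.overlap_frac}")
        if self.trim_s < 0:
            raise ConfigError(f"analysis trim_s must be >= 0, got {self.trim_s}")


@dataclass(frozen=True)
class RunConfig:
    seed: int
    loop: LoopConfig
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "loop": loop_config_to_dict(self.loop),
            "analysis": dataclasses_asdict(self.analysis),
        }


def dataclasses_asdict(obj) -> dict:
    import dataclasses
    return dataclasses.asdict(obj)


def _take(section: dict, path: str, known: set[str]) -> None:
    unknown = set(section) - known
    if unknown:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown key {key!r} in section {path!r}")


def _filter_spec(d: dict, path: str, default_kind: str, default_order: int,
                 default_cutoff: float, fs: float) -> RecursiveFilterSpec:
    _take(d, path, {"kind", "order", "cutoff_hz"})
    return RecursiveFilterSpec(
        kind=d.get("kind", default_kind),
        order=int(d.get("order", default_order)),
        cutoff_hz=float(d.get("cutoff_hz", default_cutoff)),
        sample_rate_hz=fs,
    )


def build_run_config(raw: dict | None, seed: int | None = None) -> RunConfig:
    """Build a fully validated :class:`RunConfig` from a nested dict.

    ``seed`` overrides the file's global seed (the CLI ``--seed`` flag).
    """
    raw = dict(raw or {})
    _take(raw, "<root>", {"seed", "loop", "sigchain", "controller",
                          "scheduler", "plant", "analysis"})
    g_seed = int(raw.get("seed", 0)) if seed is None else int(seed)

    loop_d = dict(raw.get("loop") or {})
    _take(loop_d, "loop", {"tick_period_s", "n_channels", "loop_delay_ticks",
                           "input_source"})
    tick = float(loop_d.get("tick_period_s", 0.001))
    n_ch = int(loop_d.get("n_channels", 2))
    if tick <= 0:
        raise ConfigError(f"loop.tick_period_s must be > 0, got {tick}")
    fs_tick = 1.0 / tick

    sc = dict(raw.get("sigchain") or {})
    _take(sc, "sigchain", {"enabled_stages", "level_shifter", "aaf",
                           "amp_highpass", "amp_lowpass", "adc"})
    ls_d = dict(sc.get("level_shifter") or {})
    _take(ls_d, "sigchain.level_shifter", {"in_min", "in_max", "out_min", "out_max"})
    adc_d = dict(sc.get("adc") or {})
    _take(adc_d, "sigchain.adc", {"n_bits", "v_min", "v_max"})
    chain = ChainConfig(
        level_shifter=LevelShifterSpec(**{k: float(v) for k, v in ls_d.items()}),
        aaf=_filter_spec(dict(sc.get("aaf") or {}), "sigchain.aaf",
                         "lowpass", 2, 250.0, fs_tick),
        amp_highpass=_filter_spec(dict(sc.get("amp_highpass") or {}),
                                  "sigchain.amp_highpass", "highpass", 2, 1.0, fs_tick),
        amp_lowpass=_filter_spec(dict(sc.get("amp_lowpass") or {}),
                                 "sigchain.amp_lowpass", "lowpass", 1, 200.0, fs_tick),
        adc=AdcSpec(n_bits=int(adc_d.get("n_bits", 12)),
                    v_min=float(adc_d.get("v_min", 0.0)),
                    v_max=float(adc_d.get("v_max", 3.3))),
        enabled_stages=tuple(sc.get("enabled_stages",
                                    ("amp_highpass", "amp_lowpass"))),
    )

    ctl_d = dict(raw.get("controller") or {})
    _take(ctl_d, "controller", {"n_taps", "bandwidth_hz", "window",
                                "output_max", "n_leds"})
    bw = ctl_d.get("bandwidth_hz")
    controller = ControllerParams(
        n_taps=int(ctl_d.get("n_taps", 51)),
        bandwidth_hz=None if bw is None else float(bw),
        window=ctl_d.get("window", "hann"),
        output_max=float(ctl_d.get("output_max", 1.0)),
        n_leds=int(ctl_d.get("n_leds", 1)),
    )

    sch_d = dict(raw.get("scheduler") or {})
    _take(sch_d, "scheduler", {"on_duration_s", "off_duration_s", "order",
                               "repetitions", "rng_seed", "conditions",
                               "centre_freq_hz", "gain"})
    planner = PlannerConfig(
        on_duration_s=float(sch_d.get("on_duration_s", 10.0)),
        off_duration_s=float(sch_d.get("off_duration_s", 10.0)),
        order=sch_d.get("order", "pseudorandom"),
        repetitions=int(sch_d.get("repetitions", 1)),
        rng_seed=int(sch_d.get("rng_seed", g_seed) or g_seed),
    )
    conds_raw = sch_d.get("conditions", "phase_grid")
    if conds_raw == "phase_grid":
        conditions = tuple(default_phase_grid(
            centre_freq_hz=float(sch_d.get("centre_freq_hz", 10.0)),
            gain=float(sch_d.get("gain", 1.0))))
    elif isinstance(conds_raw, list):
        conditions = []
        for i, cd in enumerate(conds_raw):
            cd = dict(cd)
            _take(cd, f"scheduler.conditions[{i}]",
                  {"condition_id", "centre_freq_hz", "phase_shift_deg", "gain"})
            conditions.append(Condition(
                condition_id=int(cd.get("condition_id", i)),
                centre_freq_hz=float(cd.get("centre_freq_hz", 10.0)),
                phase_shift_deg=float(cd.get("phase_shift_deg", 0.0)),
                gain=float(cd.get("gain", 1.0))))
        conditions = tuple(conditions)
    else:
        raise ConfigError(
            "scheduler.conditions must be 'phase_grid' or a list of condition maps")

    pl_d = dict(raw.get("plant") or {})
    _take(pl_d, "plant", {"natural_freq_hz", "damping_ratio", "noise_sd",
                          "light_coupling", "measurement_noise_sd", "rng_seed"})
    plant = PlantConfig(
        natural_freq_hz=float(pl_d.get("natural_freq_hz", 10.0)),
        damping_ratio=float(pl_d.get("damping_ratio", 0.04)),
        noise_sd=float(pl_d.get("noise_sd", 20.0)),
        light_coupling=float(pl_d.get("light_coupling", 1000.0)),
        dt_s=tick,
        measurement_noise_sd=float(pl_d.get("measurement_noise_sd", 0.005)),
        rng_seed=int(pl_d.get("rng_seed", g_seed) or g_seed),
    )

    an_d = dict(raw.get("analysis") or {})
    _take(an_d, "analysis", {"segment_s", "overlap_frac", "window", "trim_s", "f_max"})
    analysis = AnalysisParams(
        segment_s=float(an_d.get("segment_s", 2.0)),
        overlap_frac=float(an_d.get("overlap_frac", 0.5)),
        window=an_d.get("window", "hann"),
        trim_s=float(an_d.get("trim_s", 1.0)),
        f_max=float(an_d.get("f_max", 50.0)),
    )

    loop = LoopConfig(
        tick_period_s=tick,
        n_channels=n_ch,
        loop_delay_ticks=int(loop_d.get("loop_delay_ticks", 1)),
        seed=g_seed,
        input_source=loop_d.get("input_source", "plant"),
        chain=chain,
        controller=controller,
        planner=planner,
        conditions=conditions,
        plant=plant,
    )
    return RunConfig(seed=g_seed, loop=loop, analysis=analysis)


def load_config(path, seed: int | None = None) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return build_run_config(raw, seed=seed)
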