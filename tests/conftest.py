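import dataclasses

import pytest

from phasestim.loop_engine import LoopConfig, run_session
from phasestim.plant import PlantConfig
from phasestim.scheduler import Condition, PlannerConfig


def small_session_config(seed: int = 7, gain: float = 1.0,
                         on_s: float = 4.0, off_s: float = 4.0) -> LoopConfig:
    """Two-condition sequential session, short enough for unit tests."""
    conditions = (
        Condition(condition_id=0, centre_freq_hz=10.0, phase_shift_deg=0.0, gain=gain),
        Condition(condition_id=1, centre_freq_hz=10.0, phase_shift_deg=180.0, gain=gain),
    )
    return LoopConfig(
        seed=seed,
        planner=PlannerConfig(on_duration_s=on_s, off_duration_s=off_s,
                              order="sequential", rng_seed=seed),
        conditions=conditions,
        plant=dataclasses.replace(PlantConfig(), rng_seed=seed),
    )


@pytest.fixture(scope="session")
def short_log():
    """A 16 s two-condition closed-loop session log, shared across tests."""
    return run_session(small_session_config())
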