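"""Configuration objects for the UAV-refuelling task, the operator agent, and
the generative workload model.

Three frozen dataclasses describe a simulated study:

* :class:`TaskConfig` -- the rules and timing of the refuelling game and of the
  detection response task (DRT) schedule.  Defaults follow the task as run with
  human operators: fuel drains at 5% of the tank per second, refuelling succeeds
  only below 25% of the gauge, fresh UAVs spawn with 70-100% fuel, a successful
  refuel adds 50-100% of a full tank (capped), UAVs fly at 75 px/s on a
  1920x1080 screen, blocks last 120 s and sessions have 21 of them, and DRT
  prompts arrive with inter-stimulus intervals drawn uniformly from [3, 5] s.

* :class:`OperatorPolicy` -- a noisy-memory heuristic agent that stands in for a
  human operator.  The agent keeps drifting internal estimates of each UAV's
  fuel, periodically checks (hovers over) the UAV it believes is lowest, and
  clicks to refuel when the revealed fuel is below its trigger.  Any policy with
  this interface is acceptable; downstream analysis never depends on its
  internals.

* :class:`WorkloadModel` -- the ground-truth generative model for DRT outcomes:
  a logistic sub-model for omissions and a log-normal sub-model for reaction
  times, both driven by difficulty, block, and the refined task predictors
  (WeightFuel, #HHO3s, #FAR3s), each with a participant random intercept.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

#: The five scored task events: False-Alarm Hover Over, False-Alarm Refuel,
#: Hit Hover Over, Hit Refuel, Miss Refuel (crash).
EVENT_TYPES = ("FAHO", "FAR", "HHO", "HR", "MR")

#: Difficulty levels = number of UAVs on screen.
DIFFICULTIES = (3, 5, 7)

DEFAULT_PAYOFFS = {"FAHO": -50, "FAR": -500, "HHO": 50, "HR": 2000, "MR": -1000}


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 < value <= 1.0:
        raise ValueError(f"{name} must be in (0, 1], got {value!r}")


@dataclass(frozen=True)
class TaskConfig:
    """Rules and timing of the UAV-refuelling task and the DRT schedule."""

    n_uavs: int = 5
    fuel_drain_rate: float = 0.05
    refuel_threshold: float = 0.25
    spawn_fuel_range: tuple[float, float] = (0.70, 1.00)
    refuel_gain_range: tuple[float, float] = (0.50, 1.00)
    uav_speed: float = 75.0
    screen: tuple[int, int] = (1920, 1080)
    hover_min: float = 0.3
    block_duration: float = 120.0
    n_blocks: int = 21
    payoffs: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_PAYOFFS))
    isi_range: tuple[float, float] = (3.0, 5.0)
    stimulus_duration: float = 1.0
    response_window: float = 2.5

    def __post_init__(self) -> None:
        if self.n_uavs < 1:
            raise ValueError("n_uavs must be >= 1")
        _check_fraction("fuel_drain_rate", self.fuel_drain_rate)
        _check_fraction("refuel_threshold", self.refuel_threshold)
        for name in ("spawn_fuel_range", "refuel_gain_range"):
            lo, hi = getattr(self, name)
            _check_fraction(f"{name} lower bound", lo)
            _check_fraction(f"{name} upper bound", hi)
            if lo > hi:
                raise ValueError(f"{name} must be ordered, got ({lo}, {hi})")
        if self.isi_range[0] > self.isi_range[1]:
            raise ValueError("isi_range must be ordered")
        if self.isi_range[0] < self.stimulus_duration:
            raise ValueError("isi_range minimum must be >= stimulus_duration")
        if set(self.payoffs) != set(EVENT_TYPES):
            raise ValueError(
                f"payoffs must contain exactly the event types {EVENT_TYPES}"
            )
        for name in ("uav_speed", "hover_min", "block_duration", "response_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")


@dataclass(frozen=True)
class OperatorPolicy:
    """Parametric noisy-memory agent standing in for a human operator.

    The agent initiates fuel checks as a Poisson process with rate
    ``check_rate`` per second, targeting the UAV with the lowest perceived
    fuel.  Perception error for a UAV grows with the time since it was last
    observed: sd = ``memory_noise`` * sqrt(staleness) * ``load_scaling``**(K-3)
    for K UAVs on screen.  After a hover reveals the true fuel, the agent
    clicks to refuel when the revealed level is below ``refuel_trigger``;
    a trigger above the 25% task threshold produces occasional false-alarm
    refuels, as human operators do.  At each check every UAV whose perceived
    fuel is critical is independently neglected with probability
    ``lapse_prob`` (a per-opportunity lapse).
    """

    check_rate: float = 0.8
    memory_noise: float = 0.02
    load_scaling: float = 1.2
    refuel_trigger: float = 0.30
    lapse_prob: float = 0.05

    def __post_init__(self) -> None:
        for name in ("check_rate", "memory_noise", "load_scaling", "refuel_trigger"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.lapse_prob <= 1.0:
            raise ValueError("lapse_prob must be in [0, 1]")

    def perception_sd(self, n_uavs: int) -> float:
        """Effective fuel-estimate noise (per sqrt-second of staleness)."""
        return self.memory_noise * self.load_scaling ** max(n_uavs - 3, 0)


@dataclass(frozen=True)
class WorkloadModel:
    """Ground-truth generative model for DRT reaction times and omissions.

    The reaction-time sub-model is log-normal: log RT (ms) has mean
    ``rt_intercept`` plus a participant intercept (sd ``subject_sd``), effects
    of difficulty (dummy-coded +2UAVs / +4UAVs against the 3-UAV reference),
    block number, and the per-SD effects of the standardized predictors
    WeightFuel, #HHO3s, and #FAR3s, with residual sd ``residual_sd``.  The
    omission sub-model applies coefficients ``gamma_*`` to the same predictors
    on the logit scale, plus ``gamma_missprev`` for an omission on the previous
    trial, with its own participant intercept (sd ``omission_subject_sd``).

    Default magnitudes are chosen to mimic plausible human DRT effects: a
    ~450 ms baseline, roughly +45/+65 ms for 5/7 UAVs, tens of ms per SD of the
    fuel-awareness predictors (negative for WeightFuel: fuller fleets mean less
    workload), and a mild time-on-task drift.
    """

    rt_intercept: float = 6.109  # log-ms; exp() ~ 450 ms
    subject_sd: float = 0.15
    beta_difficulty: tuple[float, float] = (0.10, 0.14)  # (+2UAVs, +4UAVs)
    beta_block: float = 0.004
    beta_weightfuel: float = -0.09
    beta_hho3s: float = 0.09
    beta_far3s: float = 0.09
    residual_sd: float = 0.35
    gamma_intercept: float = -2.0
    gamma_difficulty: tuple[float, float] = (0.5, 0.9)
    gamma_block: float = 0.015
    gamma_weightfuel: float = -0.30
    gamma_hho3s: float = 0.12
    gamma_far3s: float = 0.12
    gamma_missprev: float = 1.0
    omission_subject_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.subject_sd < 0 or self.omission_subject_sd < 0:
            raise ValueError("random-intercept sds must be >= 0")

    def null_effects(self) -> "WorkloadModel":
        """A copy with every event/refined predictor effect set to zero.

        Difficulty, block, and random-intercept structure are retained; used
        for null-calibration studies where no windowed predictor carries
        signal.
        """
        return dataclasses.replace(
            self,
            beta_weightfuel=0.0,
            beta_hho3s=0.0,
            beta_far3s=0.0,
            gamma_weightfuel=0.0,
            gamma_hho3s=0.0,
            gamma_far3s=0.0,
            gamma_missprev=0.0,
        )


# ---------------------------------------------------------------------------
# Serialization


_SECTIONS = {"task": TaskConfig, "policy": OperatorPolicy, "workload": WorkloadModel}


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def save_config(
    path: str | Path,
    task: TaskConfig | None = None,
    policy: OperatorPolicy | None = None,
    workload: WorkloadModel | None = None,
) -> None:
    """Write a YAML (or JSON, by extension) file mirroring the config objects."""
    payload = {}
    for key, obj in (("task", task), ("policy", policy), ("workload", workload)):
        if obj is not None:
            payload[key] = _to_plain(obj)
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(payload, indent=2))
    else:
        path.write_text(yaml.safe_dump(payload, sort_keys=False))


def _from_plain(cls, data: dict):
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def load_config(path: str | Path) -> dict:
    """Read a config file written by :func:`save_config`.

    Returns a dict with any of the keys ``task``, ``policy``, ``workload``
    mapped to reconstructed dataclass instances.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    out = {}
    for key, cls in _SECTIONS.items():
        if key in (data or {}):
            out[key] = _from_plain(cls, data[key])
    return out
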