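"""Headless simulator of the UAV-refuelling task with a DRT workload probe.

The simulator has three layers:

1. Task dynamics (:func:`step_dynamics`, :func:`classify_interaction`,
   :func:`draw_block_schedule`): UAVs fly at constant speed reflecting at
   screen edges, fuel drains at a constant rate, empty UAVs crash (a Miss
   Refuel) and are immediately replaced, and hover/click interactions are
   scored into the five event types.

2. A noisy-memory operator agent (:class:`~workloadcv.config.OperatorPolicy`)
   that checks the UAV it believes has the lowest fuel and refuels when the
   revealed level is below its trigger.

3. A generative DRT model (:func:`generate_drt_stream`,
   :func:`simulate_study`): prompts arrive with uniform [3, 5] s
   inter-stimulus intervals; omissions follow a logistic sub-model and
   reaction times a log-normal sub-model, both driven by ground-truth task
   predictors so that the full analysis pipeline can be validated by
   parameter recovery.

The study driver is event-driven: between agent actions and crashes all
dynamics are closed-form, so blocks are simulated exactly without a tick
loop.  Event timestamps are reported on a 0.1 s grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import DIFFICULTIES, OperatorPolicy, TaskConfig, WorkloadModel
from .features import weight_fuel

__all__ = [
    "SimState",
    "StudyData",
    "draw_block_schedule",
    "step_dynamics",
    "classify_interaction",
    "schedule_prompts",
    "generate_drt_stream",
    "simulate_study",
]

MS_PER_S = 1000.0


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_block_schedule(n_blocks: int, seed) -> list[int]:
    """Pseudo-random difficulty schedule in balanced triples.

    Every consecutive non-overlapping triple of blocks is an independent
    random permutation of the three difficulty levels (3, 5, 7 UAVs), so each
    third of the session samples every difficulty once.

    Parameters
    ----------
    n_blocks : int
        Number of blocks; must be divisible by 3.
    seed : int or numpy Generator
        Randomness source; the same seed yields the same schedule.
    """
    if n_blocks % 3 != 0:
        raise ValueError(f"n_blocks must be divisible by 3, got {n_blocks}")
    rng = _as_rng(seed)
    schedule: list[int] = []
    for _ in range(n_blocks // 3):
        schedule.extend(rng.permutation(DIFFICULTIES).tolist())
    return schedule


# ---------------------------------------------------------------------------
# Tick-level kinematics (public API; the study driver uses the event-driven
# path below, which needs no positions)


@dataclass
class SimState:
    """Kinematic task state: one row per on-screen UAV."""

    clock: float
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray  # radians
    fuel: np.ndarray
    hovered_before: np.ndarray
    uav_id: np.ndarray
    next_id: int
    score: int = 0

    @classmethod
    def fresh(cls, config: TaskConfig, rng) -> "SimState":
        rng = _as_rng(rng)
        k = config.n_uavs
        w, h = config.screen
        return cls(
            clock=0.0,
            x=rng.uniform(0, w, k),
            y=rng.uniform(0, h, k),
            heading=rng.uniform(0, 2 * np.pi, k),
            fuel=rng.uniform(*config.spawn_fuel_range, k),
            hovered_before=np.zeros(k, dtype=bool),
            uav_id=np.arange(k),
            next_id=k,
            score=0,
        )


def _reflect(pos: np.ndarray, heading_component: np.ndarray, limit: float):
    """Fold positions into [0, limit], flipping the motion component."""
    period = 2 * limit
    pos = np.mod(pos, period)
    over = pos > limit
    pos[over] = period - pos[over]
    heading_component = heading_component.copy()
    heading_component[over] *= -1
    return pos, heading_component


def step_dynamics(
    state: SimState, dt: float, config: TaskConfig, rng=None
) -> tuple[SimState, list[dict]]:
    """Advance the kinematic state by ``dt`` seconds.

    UAVs move ``uav_speed * dt`` pixels along their heading, reflecting at
    screen boundaries; fuel drops by ``fuel_drain_rate * dt``.  Any UAV whose
    fuel reaches zero emits a Miss Refuel (MR) event and is replaced on the
    spot by a fresh UAV entering from a screen edge with spawn-range fuel and
    a random heading, so the fleet size never changes.

    Returns the updated state and the list of MR events emitted during the
    step (dicts with ``t``, ``event_type``, ``uav_id``, ``fuel_at_event``,
    ``points``).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rng = _as_rng(rng)
    w, h = config.screen
    vx = np.cos(state.heading) * config.uav_speed
    vy = np.sin(state.heading) * config.uav_speed
    x, vx = _reflect(state.x + vx * dt, vx, w)
    y, vy = _reflect(state.y + vy * dt, vy, h)
    heading = np.arctan2(vy, vx)
    fuel = state.fuel - config.fuel_drain_rate * dt
    state = dataclasses.replace(
        state, clock=state.clock + dt, x=x, y=y, heading=heading, fuel=fuel
    )
    events: list[dict] = []
    crashed = np.flatnonzero(state.fuel <= 1e-12)
    for slot in crashed:
        events.append(
            {
                "t": state.clock,
                "event_type": "MR",
                "uav_id": int(state.uav_id[slot]),
                "fuel_at_event": 0.0,
                "points": config.payoffs["MR"],
            }
        )
        state.score += config.payoffs["MR"]
        # replacement enters from a random screen edge
        edge = rng.integers(4)
        state.x[slot] = 0.0 if edge == 0 else (w if edge == 1 else rng.uniform(0, w))
        state.y[slot] = 0.0 if edge == 2 else (h if edge == 3 else rng.uniform(0, h))
        state.heading[slot] = rng.uniform(0, 2 * np.pi)
        state.fuel[slot] = rng.uniform(*config.spawn_fuel_range)
        state.hovered_before[slot] = False
        state.uav_id[slot] = state.next_id
        state.next_id += 1
    state.fuel = np.clip(state.fuel, 0.0, 1.0)
    return state, events


def classify_interaction(
    kind: str, fuel: float, first_hover: bool, config: TaskConfig
) -> str | None:
    """Score a hover or click against the current fuel level.

    Clicking below the refuel threshold is a Hit Refuel (HR), above it a
    False-Alarm Refuel (FAR).  A sustained non-first hover is a Hit Hover
    Over (HHO) below the threshold, otherwise a False-Alarm Hover Over
    (FAHO).  The single allowed first hover per UAV is unscored (returns
    ``None``).  "Below" is strict: a fuel level exactly at the threshold
    counts as above.
    """
    if not 0.0 <= fuel <= 1.0:
        raise ValueError(f"fuel must be in [0, 1], got {fuel!r}")
    if kind not in ("hover", "click"):
        raise ValueError(f"kind must be 'hover' or 'click', got {kind!r}")
    hit = fuel < config.refuel_threshold
    if kind == "click":
        return "HR" if hit else "FAR"
    if first_hover:
        return None
    return "HHO" if hit else "FAHO"


# ---------------------------------------------------------------------------
# Event-driven block simulation (fuel and interactions only)


@dataclass
class _BlockTrace:
    """Everything a block simulation produced, in analysis-ready arrays."""

    events: list[dict]
    # checkpoints: piecewise-linear fuel reconstruction anchors
    ck_times: np.ndarray
    ck_fuels: np.ndarray  # (n_ck, K)
    # hover observations
    hover_times: np.ndarray
    hover_slots: np.ndarray
    hover_fuels: np.ndarray  # (n_hover, K) fuel vector at hover instant
    score: int
    n_uavs: int
    drain: float

    def fuel_at(self, t: np.ndarray) -> np.ndarray:
        """Fuel vector (len K) at each query time; shape (len(t), K)."""
        idx = np.searchsorted(self.ck_times, t, side="right") - 1
        return np.clip(
            self.ck_fuels[idx] - self.drain * (t - self.ck_times[idx])[:, None],
            0.0,
            1.0,
        )


def _simulate_block(
    rng: np.random.Generator, config: TaskConfig, policy: OperatorPolicy
) -> _BlockTrace:
    k = config.n_uavs
    drain = config.fuel_drain_rate
    t_end = config.block_duration
    fuel = rng.uniform(*config.spawn_fuel_range, k)
    uav_id = np.arange(k)
    next_id = k
    last_obs = np.zeros(k)  # agent saw spawn levels (initial free gauge)
    sd = policy.perception_sd(k)

    t = 0.0
    score = 0
    events: list[dict] = []
    ck_times = [0.0]
    ck_fuels = [fuel.copy()]
    hov_t: list[float] = []
    hov_slot: list[int] = []
    hov_fuel: list[np.ndarray] = []

    inf = np.inf
    next_check = (
        t + rng.exponential(1.0 / policy.check_rate) if policy.check_rate > 0 else inf
    )
    pending_t, pending_slot = inf, -1

    def emit(ev_type: str, slot: int, f: float, when: float) -> None:
        nonlocal score
        pts = config.payoffs[ev_type]
        score += pts
        events.append(
            {
                "t": round(when, 1),
                "event_type": ev_type,
                "uav_id": int(uav_id[slot]),
                "fuel_at_event": float(f),
                "points": pts,
            }
        )

    def checkpoint(when: float) -> None:
        ck_times.append(when)
        ck_fuels.append(fuel.copy())

    while True:
        t_crash = t + fuel.min() / drain
        t_next = min(t_crash, pending_t, next_check)
        if t_next >= t_end:
            break
        fuel -= drain * (t_next - t)
        t = t_next
        if t == t_crash and fuel.min() <= 1e-12:
            slot = int(np.argmin(fuel))
            emit("MR", slot, 0.0, t)
            fuel[slot] = rng.uniform(*config.spawn_fuel_range)
            uav_id[slot] = next_id
            next_id += 1
            last_obs[slot] = t  # replacement arrival is salient
            checkpoint(t)
            if pending_slot == slot:
                pending_t, pending_slot = inf, -1
                next_check = t + rng.exponential(1.0 / policy.check_rate)
        elif t == pending_t:
            slot = pending_slot
            f = float(fuel[slot])
            hov_t.append(t)
            hov_slot.append(slot)
            hov_fuel.append(fuel.copy())
            emit(classify_interaction("hover", f, False, config), slot, f, t)
            last_obs[slot] = t
            if f < policy.refuel_trigger:
                emit(classify_interaction("click", f, False, config), slot, f, t)
                if f < config.refuel_threshold:  # successful refuel
                    fuel[slot] = min(1.0, f + rng.uniform(*config.refuel_gain_range))
                    checkpoint(t)
            pending_t, pending_slot = inf, -1
            next_check = t + rng.exponential(1.0 / policy.check_rate)
        else:  # initiate a check
            staleness = np.maximum(t - last_obs, 0.0)
            perceived = fuel + rng.standard_normal(k) * sd * np.sqrt(staleness)
            cost = perceived.copy()
            critical = perceived < policy.refuel_trigger
            lapsed = critical & (rng.random(k) < policy.lapse_prob)
            cost[lapsed] = inf
            if np.isinf(cost).all():
                cost = perceived
            pending_slot = int(np.argmin(cost))
            pending_t = t + config.hover_min
            next_check = inf  # busy until the hover resolves

    return _BlockTrace(
        events=events,
        ck_times=np.asarray(ck_times),
        ck_fuels=np.asarray(ck_fuels),
        hover_times=np.asarray(hov_t),
        hover_slots=np.asarray(hov_slot, dtype=int),
        hover_fuels=(
            np.asarray(hov_fuel) if hov_fuel else np.empty((0, k))
        ),
        score=score,
        n_uavs=k,
        drain=drain,
    )


# ---------------------------------------------------------------------------
# DRT generation


def schedule_prompts(duration: float, isi_range: tuple[float, float], rng) -> np.ndarray:
    """Prompt onsets with independent uniform inter-stimulus intervals.

    The first onset is itself one ISI after the block starts; onsets beyond
    ``duration`` are not emitted.
    """
    rng = _as_rng(rng)
    lo, hi = isi_range
    onsets = []
    t = rng.uniform(lo, hi)
    while t < duration:
        onsets.append(t)
        t += rng.uniform(lo, hi)
    return np.asarray(onsets)


_RT_COVARIATES = ("diff5", "diff7", "block", "weightfuel", "hho3s", "far3s")


def _linear_predictors(model: WorkloadModel, cov: dict) -> tuple[float, float]:
    """(log-RT mean, omission logit) at one covariate profile, excluding
    intercepts/random effects/missprev."""
    b2, b4 = model.beta_difficulty
    g2, g4 = model.gamma_difficulty
    eta_rt = (
        b2 * cov.get("diff5", 0.0)
        + b4 * cov.get("diff7", 0.0)
        + model.beta_block * cov.get("block", 0.0)
        + model.beta_weightfuel * cov.get("weightfuel", 0.0)
        + model.beta_hho3s * cov.get("hho3s", 0.0)
        + model.beta_far3s * cov.get("far3s", 0.0)
    )
    eta_om = (
        g2 * cov.get("diff5", 0.0)
        + g4 * cov.get("diff7", 0.0)
        + model.gamma_block * cov.get("block", 0.0)
        + model.gamma_weightfuel * cov.get("weightfuel", 0.0)
        + model.gamma_hho3s * cov.get("hho3s", 0.0)
        + model.gamma_far3s * cov.get("far3s", 0.0)
    )
    return eta_rt, eta_om


def generate_drt_stream(
    session_length: float,
    workload_trace,
    model: WorkloadModel,
    seed,
    config: TaskConfig | None = None,
) -> pd.DataFrame:
    """Generate one continuous stream of DRT prompts with RT or omission.

    Parameters
    ----------
    session_length : float
        Length of the stream in seconds; must exceed the maximum ISI.
    workload_trace : callable or None
        ``trace(t)`` returns a mapping of covariate values at time ``t``
        (keys among ``diff5, diff7, block, weightfuel, hho3s, far3s``, on the
        scale the model coefficients expect).  ``None`` means all covariates
        are zero, reducing RT to log-normal(rt_intercept + subject intercept,
        residual_sd).
    model : WorkloadModel
        Generative coefficients; one subject intercept per sub-model is drawn
        for the whole stream.
    seed : int or Generator
        Randomness source.
    config : TaskConfig, optional
        Supplies the ISI range and response window.
    """
    config = config or TaskConfig()
    if session_length <= config.isi_range[1]:
        raise ValueError("session_length must exceed the maximum ISI")
    rng = _as_rng(seed)
    onsets = schedule_prompts(session_length, config.isi_range, rng)
    b_rt = rng.normal(0.0, model.subject_sd)
    b_om = rng.normal(0.0, model.omission_subject_sd)
    rows = []
    prev_omit = 0.0
    window_ms = config.response_window * MS_PER_S
    for t in onsets:
        cov = workload_trace(t) if workload_trace is not None else {}
        eta_rt, eta_om = _linear_predictors(model, cov)
        logit = model.gamma_intercept + eta_om + model.gamma_missprev * prev_omit + b_om
        omitted = rng.random() < expit(logit)
        rt = np.nan
        if not omitted:
            rt = float(
                np.exp(model.rt_intercept + eta_rt + b_rt + rng.normal(0.0, model.residual_sd))
            )
            if rt > window_ms:  # no response inside the window counts as omission
                rt, omitted = np.nan, True
        rows.append({"prompt_t": float(t), "rt_ms": rt, "omission": int(omitted)})
        prev_omit = float(omitted)
    return pd.DataFrame(rows, columns=["prompt_t", "rt_ms", "omission"])


# ---------------------------------------------------------------------------
# Full study


@dataclass
class StudyData:
    """Simulated study: event, DRT, and state-snapshot logs plus ground truth."""

    events: pd.DataFrame
    drt: pd.DataFrame
    snapshots: pd.DataFrame
    truth: WorkloadModel
    config: TaskConfig
    policy: OperatorPolicy
    seed: int | None = None
    block_scores: pd.DataFrame | None = None


def _window_counts(event_times: np.ndarray, prompts: np.ndarray, w: float) -> np.ndarray:
    """Events with t in (p - w, p] for each prompt p (both arrays sorted)."""
    hi = np.searchsorted(event_times, prompts, side="right")
    lo = np.searchsorted(event_times, prompts - w, side="right")
    return hi - lo


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = np.std(x, ddof=1) if len(x) > 1 else 0.0
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - np.mean(x)) / sd


def simulate_study(
    n_participants: int,
    config: TaskConfig | None = None,
    policy: OperatorPolicy | None = None,
    model: WorkloadModel | None = None,
    seed: int = 0,
    n_days: int = 2,
    feature_window: float = 3.0,
    weightfuel_exponent: float = 0.25,
) -> StudyData:
    """Simulate a full study: participants x days x blocks.

    For each participant-day, a balanced difficulty schedule is drawn, every
    block is simulated with the operator agent, and DRT outcomes are generated
    from the workload model evaluated at ground-truth predictor values
    (WeightFuel at the prompt, HHO/FAR counts in the preceding
    ``feature_window`` seconds, block number, difficulty dummies, previous
    omission).  WeightFuel and the counts are standardized within the
    participant-day before the per-SD coefficients are applied, matching the
    scale on which effect sizes are defined.

    Randomness is keyed per participant (and per day) from the study seed, so
    adding participants never perturbs the data of earlier ones.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    config = config or TaskConfig()
    policy = policy or OperatorPolicy()
    model = model or WorkloadModel()
    k_max = max(DIFFICULTIES)

    ev_frames, drt_frames, snap_frames, score_rows = [], [], [], []
    window_ms = config.response_window * MS_PER_S

    for pid_idx in range(n_participants):
        pid = f"p{pid_idx + 1:02d}"
        rng_p = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(pid_idx,))
        )
        b_rt = rng_p.normal(0.0, model.subject_sd)
        b_om = rng_p.normal(0.0, model.omission_subject_sd)
        for day in range(1, n_days + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(pid_idx, day))
            )
            schedule = draw_block_schedule(config.n_blocks, rng)
            day_trials = []  # accumulated across blocks before standardization
            for block, diff in enumerate(schedule, start=1):
                cfg_b = dataclasses.replace(config, n_uavs=diff)
                trace = _simulate_block(rng, cfg_b, policy)
                prompts = schedule_prompts(config.block_duration, config.isi_range, rng)

                for ev in trace.events:
                    ev_frames.append(
                        {
                            "participant_id": pid,
                            "day": day,
                            "block": block,
                            "difficulty": diff,
                            **ev,
                        }
                    )
                score_rows.append(
                    {
                        "participant_id": pid,
                        "day": day,
                        "block": block,
                        "difficulty": diff,
                        "score": trace.score,
                    }
                )

                fuels = trace.fuel_at(prompts)  # (n_prompts, diff)
                # vectorized power mean, same semantics as features.weight_fuel
                wf = np.mean(fuels**weightfuel_exponent, axis=1) ** (
                    1.0 / weightfuel_exponent
                )
                ev_t = {
                    typ: np.sort(
                        [e["t"] for e in trace.events if e["event_type"] == typ]
                    )
                    for typ in ("HHO", "FAR")
                }
                n_hho = _window_counts(np.asarray(ev_t["HHO"]), prompts, feature_window)
                n_far = _window_counts(np.asarray(ev_t["FAR"]), prompts, feature_window)

                # most recent hover before each prompt, for OrdFuel downstream
                h_idx = np.searchsorted(trace.hover_times, prompts, side="right") - 1
                for j, p in enumerate(prompts):
                    row = {
                        "participant_id": pid,
                        "day": day,
                        "block": block,
                        "difficulty": diff,
                        "prompt_t": float(p),
                    }
                    for u in range(k_max):
                        row[f"fuel_{u + 1}"] = (
                            float(fuels[j, u]) if u < diff else np.nan
                        )
                    if h_idx[j] >= 0:
                        row["hover_t"] = float(trace.hover_times[h_idx[j]])
                        row["hover_slot"] = int(trace.hover_slots[h_idx[j]]) + 1
                        hv = trace.hover_fuels[h_idx[j]]
                        for u in range(k_max):
                            row[f"hfuel_{u + 1}"] = (
                                float(hv[u]) if u < diff else np.nan
                            )
                    else:
                        row["hover_t"] = np.nan
                        row["hover_slot"] = np.nan
                        for u in range(k_max):
                            row[f"hfuel_{u + 1}"] = np.nan
                    snap_frames.append(row)

                day_trials.append(
                    {
                        "block": block,
                        "difficulty": diff,
                        "prompts": prompts,
                        "wf": wf,
                        "n_hho": n_hho.astype(float),
                        "n_far": n_far.astype(float),
                    }
                )

            # standardize realized predictors within the participant-day
            wf_all = np.concatenate([d["wf"] for d in day_trials])
            hho_all = np.concatenate([d["n_hho"] for d in day_trials])
            far_all = np.concatenate([d["n_far"] for d in day_trials])
            wf_z = _zscore(wf_all)
            hho_z = _zscore(hho_all)
            far_z = _zscore(far_all)
            pos = 0
            for d in day_trials:
                n = len(d["prompts"])
                prev_omit = 0.0
                for j in range(n):
                    cov = {
                        "diff5": 1.0 if d["difficulty"] == 5 else 0.0,
                        "diff7": 1.0 if d["difficulty"] == 7 else 0.0,
                        "block": float(d["block"]),
                        "weightfuel": wf_z[pos + j],
                        "hho3s": hho_z[pos + j],
                        "far3s": far_z[pos + j],
                    }
                    eta_rt, eta_om = _linear_predictors(model, cov)
                    logit = (
                        model.gamma_intercept
                        + eta_om
                        + model.gamma_missprev * prev_omit
                        + b_om
                    )
                    omitted = rng.random() < expit(logit)
                    rt = np.nan
                    if not omitted:
                        rt = float(
                            np.exp(
                                model.rt_intercept
                                + eta_rt
                                + b_rt
                                + rng.normal(0.0, model.residual_sd)
                            )
                        )
                        if rt > window_ms:
                            rt, omitted = np.nan, True
                    drt_frames.append(
                        {
                            "participant_id": pid,
                            "day": day,
                            "block": d["block"],
                            "difficulty": d["difficulty"],
                            "prompt_t": float(d["prompts"][j]),
                            "rt_ms": rt,
                            "omission": int(omitted),
                        }
                    )
                    prev_omit = float(omitted)
                pos += n

    snap_cols = (
        ["participant_id", "day", "block", "difficulty", "prompt_t"]
        + [f"fuel_{u + 1}" for u in range(k_max)]
        + ["hover_t", "hover_slot"]
        + [f"hfuel_{u + 1}" for u in range(k_max)]
    )
    events = pd.DataFrame(
        ev_frames,
        columns=[
            "participant_id",
            "day",
            "block",
            "difficulty",
            "t",
            "event_type",
            "uav_id",
            "fuel_at_event",
            "points",
        ],
    )
    drt = pd.DataFrame(
        drt_frames,
        columns=[
            "participant_id",
            "day",
            "block",
            "difficulty",
            "prompt_t",
            "rt_ms",
            "omission",
        ],
    )
    snapshots = pd.DataFrame(snap_frames, columns=snap_cols)
    return StudyData(
        events=events,
        drt=drt,
        snapshots=snapshots,
        truth=model,
        config=config,
        policy=policy,
        seed=seed,
        block_scores=pd.DataFrame(score_rows),
    )
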