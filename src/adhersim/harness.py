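"""Experiment harness: single sessions and full multi-arm runs.

Seeding is counter-based: the master seed plus (arm index, participant index)
feed a :class:`numpy.random.SeedSequence`, so each participant owns an
isolated substream and changing one arm's size never reshuffles another
participant's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from adhersim.agents import AgentParams, AgentContext, accrue_score, decide_dose
from adhersim.env import (
    DoseEvent,
    DoseOutcome,
    EnvState,
    SessionConfig,
    apply_earnings,
    classify_entry,
    close_dose_window,
    schedule_doses,
)
from adhersim.interventions import CONDITION_NAMES, ConditionSpec, apply_condition, make_condition

#: default per-arm sample sizes (control, incentive, reminder, commitment, elongated)
DEFAULT_ARM_SIZES = {
    "control": 104,
    "incentive": 106,
    "reminder": 97,
    "commitment": 102,
    "elongated": 100,
}

WRONG_CODE_SENTINEL = "????"


@dataclass(frozen=True)
class ExperimentPlan:
    arm_sizes: dict = field(default_factory=lambda: dict(DEFAULT_ARM_SIZES))
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name, n in self.arm_sizes.items():
            if name not in CONDITION_NAMES:
                raise ValueError(f"unknown condition {name!r} in plan")
            if n < 0:
                raise ValueError("arm sizes must be >= 0")


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's summary row."""

    participant_id: str
    condition: str
    seed: int
    adherence_rate: float  # percent of scheduled doses correct and on time
    n_on_time: int
    n_off_time: int
    n_wrong_code: int
    n_missed: int
    relapse_round: Optional[int]
    final_score: int
    earnings: float


@dataclass(frozen=True)
class ScoreEvent:
    """Game-score accrual over one inter-window segment."""

    t_start: int
    t_end: int
    blur: float
    points: int


def participant_seed(master_seed: int, arm_index: int, participant_index: int) -> int:
    """Stable 64-bit per-participant seed from the (master, arm, index) counter."""
    words = np.random.SeedSequence(
        entropy=[master_seed, arm_index, participant_index]
    ).generate_state(2)
    return int(words[0]) << 32 | int(words[1])


def run_session(
    config: SessionConfig,
    condition: Union[str, ConditionSpec],
    agent_params: AgentParams,
    seed: int,
    participant_id: str = "p0",
) -> tuple[ParticipantRecord, list]:
    """Simulate one 870 s session and return (record, event trace).

    The trace interleaves one :class:`ScoreEvent` per inter-window segment with
    one :class:`DoseEvent` per window, in time order.  Identical (config,
    condition, agent_params, seed) reproduce the trace bit for bit.
    """
    spec = make_condition(condition) if isinstance(condition, str) else condition
    cfg = apply_condition(spec, config)
    rng = np.random.default_rng(seed)
    state = EnvState.initial(cfg)
    events: list = []

    flags = spec.agent_context_flags
    half = cfg.dose_interval_s // 2
    max_offset = half - 1
    prev_close = 0

    for dose_index, scheduled_t in enumerate(schedule_doses(cfg), start=1):
        close_t = scheduled_t + half
        if dose_index == cfg.n_doses:
            close_t = cfg.session_duration_s  # last window absorbs the tail

        context = AgentContext(
            symptoms_cleared=state.symptoms_cleared,
            reminder_shown="reminder_shown" in flags,
            incentive_active="incentive_active" in flags,
            commitment_signed="commitment_signed" in flags,
        )
        action = decide_dose(agent_params, context, rng)

        entry_t: Optional[int] = None
        entered_code: Optional[str] = None
        if action.attempt:
            # jitter truncated to the window's open interval; entries pushed to
            # the edge remain off time
            offset = max(-max_offset, min(max_offset, action.entry_offset_s))
            entry_t = scheduled_t + offset
            entered_code = cfg.code if action.code_correct else WRONG_CODE_SENTINEL
        outcome = classify_entry(cfg, dose_index, entry_t, entered_code)

        # score accrues at the blur level holding over the segment
        dt = close_t - prev_close
        points = accrue_score(agent_params, state.blur, dt, rng)
        events.append(ScoreEvent(t_start=prev_close, t_end=close_t, blur=state.blur, points=points))
        state.cumulative_game_score += points
        prev_close = close_t

        close_dose_window(state, cfg, dose_index, outcome, rng)
        apply_earnings(state, cfg)
        state.t = close_t
        events.append(
            DoseEvent(
                dose_index=dose_index,
                scheduled_t=scheduled_t,
                entry_t=entry_t,
                entered_code=entered_code,
                outcome=outcome,
                blur_after=state.blur,
                relapse_triggered=state.last_relapse_triggered,
            )
        )

    dose_events = [e for e in events if isinstance(e, DoseEvent)]
    counts = {o: sum(1 for e in dose_events if e.outcome == o) for o in DoseOutcome}
    record = ParticipantRecord(
        participant_id=participant_id,
        condition=spec.name,
        seed=seed,
        adherence_rate=100.0 * counts[DoseOutcome.CORRECT_ON_TIME] / cfg.n_doses,
        n_on_time=counts[DoseOutcome.CORRECT_ON_TIME],
        n_off_time=counts[DoseOutcome.CORRECT_OFF_TIME],
        n_wrong_code=counts[DoseOutcome.WRONG_CODE],
        n_missed=counts[DoseOutcome.MISSED],
        relapse_round=state.relapse_round,
        final_score=state.cumulative_game_score,
        earnings=state.earnings,
    )
    return record, events


def run_experiment(
    plan: ExperimentPlan,
    config: SessionConfig | None = None,
    agent_params: AgentParams | None = None,
    collect_events: bool = False,
    heterogeneity: dict | None = None,
) -> tuple[list[ParticipantRecord], dict, dict]:
    """Run every arm at its planned size.

    Returns (records, consort, events_by_participant).  ``consort`` maps each
    arm to ``{"assigned": n, "analyzed": n}``; with no exclusions modelled the
    two are always equal.  Events are collected only when requested (they are
    bulky).  ``heterogeneity`` optionally draws per-participant agent
    parameters from hyperpriors (see :func:`adhersim.agents.sample_agent_params`),
    using a substream derived from the participant's seed.
    """
    from adhersim.agents import sample_agent_params

    config = config or SessionConfig()
    agent_params = agent_params or AgentParams()
    records: list[ParticipantRecord] = []
    events_by_participant: dict[str, list] = {}
    consort: dict[str, dict] = {}

    for arm_index, name in enumerate(CONDITION_NAMES):
        n = plan.arm_sizes.get(name, 0)
        spec = make_condition(name)
        for i in range(n):
            pid = f"{name}-{i:03d}"
            seed = participant_seed(plan.master_seed, arm_index, i)
            params = sample_agent_params(
                agent_params, heterogeneity, np.random.default_rng(seed ^ 0x9E3779B97F4A7C15)
            )
            record, events = run_session(config, spec, params, seed, participant_id=pid)
            records.append(record)
            if collect_events:
                events_by_participant[pid] = events
        consort[name] = {"assigned": n, "analyzed": n}
    return records, consort, events_by_participant


def records_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    """Participant table with one row per record (column dictionary in README)."""
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "condition": [r.condition for r in records],
            "seed": [r.seed for r in records],
            "adherence_rate": [r.adherence_rate for r in records],
            "n_on_time": [r.n_on_time for r in records],
            "n_off_time": [r.n_off_time for r in records],
            "n_wrong_code": [r.n_wrong_code for r in records],
            "n_missed": [r.n_missed for r in records],
            "relapse_round": [r.relapse_round for r in records],
            "final_score": [r.final_score for r in records],
            "earnings": [r.earnings for r in records],
        }
    )
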