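"""Illness/treatment overlay: dose schedule, blur, code entry, relapse, earnings.

The session is an 870 s clock with 14 one-per-minute code-entry windows.  The
screen starts fully blurred ("illness onset"); each correct code entry clears
a fixed fraction; once enough correct entries accumulate the screen stays
clear ("symptoms cleared").  After clearance, every window not answered with a
correct on-time code carries a relapse hazard that starts at 2% and doubles
per consecutive miss; a relapse re-blurs the screen by 25%.

Time is modelled in whole seconds.  Window ``i`` spans
``(scheduled_t - dose_interval_s/2, scheduled_t + dose_interval_s/2]`` so the
14 windows partition the session; an entry counts as on time when its offset
from the scheduled second is within ``on_time_window_s``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional

import numpy as np


class DoseOutcome(str, Enum):
    CORRECT_ON_TIME = "CORRECT_ON_TIME"
    CORRECT_OFF_TIME = "CORRECT_OFF_TIME"
    WRONG_CODE = "WRONG_CODE"
    MISSED = "MISSED"


@dataclass(frozen=True)
class SessionConfig:
    """All fixed parameters of one session."""

    session_duration_s: int = 870
    dose_interval_s: int = 60
    n_doses: int = 14
    on_time_window_s: int = 15
    initial_blur: float = 1.0
    clear_after_doses: int = 7
    relapse_base_p: float = 0.02
    relapse_multiplier: float = 2.0
    relapse_blur_increment: float = 0.25
    max_relapses: int = 1
    show_up_fee: float = 80.0
    earnings_cap: float = 500.0
    incentive_bonus: float = 5.0
    # linear game-score payout: rupees per point (420 Rs per 20,000 points)
    rupees_per_point: float = 420.0 / 20000.0
    code: str = "1234"
    condition: str = "control"

    def __post_init__(self) -> None:
        if self.n_doses * self.dose_interval_s > self.session_duration_s:
            raise ValueError("n_doses * dose_interval_s must fit in session_duration_s")
        if not (0.0 <= self.relapse_base_p <= 1.0):
            raise ValueError("relapse_base_p must be in [0, 1]")
        if self.relapse_multiplier < 1.0:
            raise ValueError("relapse_multiplier must be >= 1")
        if not (0.0 <= self.initial_blur <= 1.0):
            raise ValueError("initial_blur must be in [0, 1]")
        if self.show_up_fee > self.earnings_cap:
            raise ValueError("show_up_fee must not exceed earnings_cap")
        if not (0 < self.on_time_window_s < self.dose_interval_s / 2):
            raise ValueError("on_time_window_s must be in (0, dose_interval_s/2)")
        if self.clear_after_doses < 1 or self.max_relapses < 0:
            raise ValueError("clear_after_doses >= 1 and max_relapses >= 0 required")


@dataclass
class EnvState:
    """Evolving session state."""

    t: int = 0
    blur: float = 1.0
    doses_taken: int = 0
    correct_entries: int = 0
    consecutive_misses: int = 0
    relapses: int = 0
    relapsed: bool = False
    relapse_round: Optional[int] = None
    symptoms_cleared: bool = False
    codes_effective: bool = True
    earnings: float = 80.0
    cumulative_game_score: int = 0
    on_time_entries: int = 0
    windows_closed: int = 0
    last_relapse_triggered: bool = False

    @classmethod
    def initial(cls, config: SessionConfig) -> "EnvState":
        return cls(blur=config.initial_blur, earnings=config.show_up_fee)


@dataclass(frozen=True)
class DoseEvent:
    """Event-log row for one dose window."""

    dose_index: int
    scheduled_t: int
    entry_t: Optional[int]
    entered_code: Optional[str]
    outcome: DoseOutcome
    blur_after: float
    relapse_triggered: bool


def schedule_doses(config: SessionConfig) -> list[int]:
    """Scheduled entry times: one per ``dose_interval_s`` for ``n_doses``."""
    times = [config.dose_interval_s * i for i in range(1, config.n_doses + 1)]
    if times and times[-1] > config.session_duration_s:
        raise ValueError("last scheduled dose exceeds session duration")
    return times


def classify_entry(
    config: SessionConfig,
    dose_index: int,
    entry_t: Optional[int],
    entered_code: Optional[str],
) -> DoseOutcome:
    """Classify what happened in one dose window.

    An absent entry is MISSED; a wrong code is WRONG_CODE; a correct code is
    on time iff ``|entry_t - scheduled_t| <= on_time_window_s``.
    """
    if not (1 <= dose_index <= config.n_doses):
        raise ValueError(f"dose_index must be in 1..{config.n_doses}")
    if entry_t is None:
        return DoseOutcome.MISSED
    if entered_code != config.code:
        return DoseOutcome.WRONG_CODE
    scheduled_t = config.dose_interval_s * dose_index
    if abs(entry_t - scheduled_t) <= config.on_time_window_s:
        return DoseOutcome.CORRECT_ON_TIME
    return DoseOutcome.CORRECT_OFF_TIME


def relapse_hazard(config: SessionConfig, m: int) -> float:
    """Relapse probability after the ``m``-th consecutive post-clearance miss.

    ``min(1, relapse_base_p * relapse_multiplier**(m-1))``: 0.02, 0.04,
    0.08, ... capped at 1.
    """
    if m < 1:
        raise ValueError("hazard is defined only for m >= 1 misses")
    return min(1.0, config.relapse_base_p * config.relapse_multiplier ** (m - 1))


def update_blur(state: EnvState, config: SessionConfig) -> float:
    """Blur after one more correct entry.

    Each correct entry removes ``initial_blur / clear_after_doses`` of blur;
    before any relapse this equals
    ``max(0, initial_blur * (1 - correct_entries / clear_after_doses))``.
    Once ``correct_entries >= clear_after_doses`` the screen is clear and
    clearance is permanent apart from relapse increments, which subsequent
    correct entries wash out at the same per-dose rate.
    """
    decrement = config.initial_blur / config.clear_after_doses
    return max(0.0, state.blur - decrement)


def apply_earnings(state: EnvState, config: SessionConfig) -> EnvState:
    """Recompute earnings: show-up fee + linear game-score payout
    (+ Rs ``incentive_bonus`` per on-time entry on the incentive arm), capped.
    """
    total = config.show_up_fee + config.rupees_per_point * state.cumulative_game_score
    if config.condition == "incentive":
        total += config.incentive_bonus * state.on_time_entries
    state.earnings = min(config.earnings_cap, total)
    return state


def close_dose_window(
    state: EnvState,
    config: SessionConfig,
    dose_index: int,
    outcome: DoseOutcome,
    rng: np.random.Generator,
) -> EnvState:
    """Apply the outcome of one dose window to the session state.

    CORRECT_ON_TIME resets the consecutive-miss counter, counts a taken dose
    and clears blur one step.  CORRECT_OFF_TIME also counts as taken and
    clears blur, but — like MISSED and WRONG_CODE — increments the
    consecutive-miss counter once symptoms have cleared and draws the relapse
    hazard.  Hazard is inactive before clearance.  A relapse adds
    ``relapse_blur_increment`` of blur (clamped to 1) and records the round;
    at most ``max_relapses`` relapses fire per session.  After ``n_doses``
    windows the codes become ineffective.
    """
    if dose_index != state.windows_closed + 1:
        raise ValueError(
            f"window {dose_index} closed out of order (expected {state.windows_closed + 1})"
        )
    if dose_index > config.n_doses:
        raise ValueError(f"windows capped at {config.n_doses}")

    if outcome in (DoseOutcome.CORRECT_ON_TIME, DoseOutcome.CORRECT_OFF_TIME):
        state.doses_taken += 1
        state.correct_entries += 1
        state.blur = update_blur(state, config)
        if state.correct_entries >= config.clear_after_doses:
            state.symptoms_cleared = True
        if outcome == DoseOutcome.CORRECT_ON_TIME:
            state.on_time_entries += 1
            state.consecutive_misses = 0

    relapse_triggered = False
    if outcome != DoseOutcome.CORRECT_ON_TIME and state.symptoms_cleared:
        state.consecutive_misses += 1
        if state.relapses < config.max_relapses:
            p = relapse_hazard(config, state.consecutive_misses)
            if rng.random() < p:
                relapse_triggered = True
                state.blur = min(1.0, state.blur + config.relapse_blur_increment)
                state.relapses += 1
                state.relapsed = True
                state.relapse_round = dose_index

    state.windows_closed += 1
    if state.windows_closed >= config.n_doses:
        state.codes_effective = False
    state.last_relapse_triggered = relapse_triggered
    return state


def relapse_round_pmf(config: SessionConfig, clearance_round: int) -> dict[int, float]:
    """Analytic distribution of the relapse round for an agent that enters
    correct on-time codes until clearance and never afterwards.

    With clearance reached at window ``clearance_round``, miss ``k`` happens at
    window ``clearance_round + k`` with hazard ``h_k = min(1, base * mult**(k-1))``
    and ``P(round = clearance_round + k) = h_k * prod_{i<k} (1 - h_i)``.
    Returns a map from round to probability (rounds beyond ``n_doses`` omitted).
    """
    pmf: dict[int, float] = {}
    surv = 1.0
    for k in range(1, config.n_doses - clearance_round + 1):
        h = relapse_hazard(config, k)
        pmf[clearance_round + k] = surv * h
        surv *= 1.0 - h
    return pmf
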