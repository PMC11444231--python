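"""Condition plugins for the five arms.

Only the elongated arm changes illness mechanics (symptoms take twice as many
correct entries to clear).  Incentive adds a per-on-time-entry bonus to
earnings, reminder pops a message at every scheduled dose time, and the
commitment arm is environmentally identical to control — its signed sticker
is purely an agent-side context flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from adhersim.env import SessionConfig, schedule_doses

CONDITION_NAMES = ("control", "incentive", "reminder", "commitment", "elongated")


@dataclass(frozen=True)
class ConditionSpec:
    name: str
    env_overrides: dict = field(default_factory=dict)
    reminder_duration_s: int = 3
    agent_context_flags: frozenset = frozenset()


def make_condition(name: str, reminder_duration_s: int = 3) -> ConditionSpec:
    """Build the spec for a named arm; unknown names fail fast."""
    if name not in CONDITION_NAMES:
        raise ValueError(f"unknown condition {name!r}; valid: {', '.join(CONDITION_NAMES)}")
    if name == "control":
        return ConditionSpec(name=name)
    if name == "incentive":
        return ConditionSpec(name=name, agent_context_flags=frozenset({"incentive_active"}))
    if name == "reminder":
        return ConditionSpec(
            name=name,
            reminder_duration_s=reminder_duration_s,
            agent_context_flags=frozenset({"reminder_shown"}),
        )
    if name == "commitment":
        return ConditionSpec(name=name, agent_context_flags=frozenset({"commitment_signed"}))
    # elongated: symptoms take twice as long to disappear
    return ConditionSpec(name=name, env_overrides={"clear_after_doses_factor": 2})


def apply_condition(spec: ConditionSpec, config: SessionConfig) -> SessionConfig:
    """Session config for this arm derived from the control config."""
    updates: dict = {"condition": spec.name}
    factor = spec.env_overrides.get("clear_after_doses_factor")
    if factor:
        updates["clear_after_doses"] = config.clear_after_doses * factor
    for key, value in spec.env_overrides.items():
        if key != "clear_after_doses_factor":
            updates[key] = value
    return replace(config, **updates)


def reminder_schedule(spec: ConditionSpec, config: SessionConfig) -> list[tuple[int, int]]:
    """Reminder intervals ``[scheduled_t, scheduled_t + reminder_duration_s]``,
    one per dose; empty for non-reminder arms."""
    if spec.name != "reminder":
        return []
    return [(t, t + spec.reminder_duration_s) for t in schedule_doses(config)]
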