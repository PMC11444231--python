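"""Synthetic participants: a minimal stochastic stand-in for the human sample.

Each dose window is an independent Bernoulli decision to attempt the code
entry.  The base attempt probability is reduced once symptoms have cleared
(symptom-free lapses) and boosted toward 1 by reminders, incentives, or a
signed commitment.  Attempted entries carry Gaussian timing jitter and a
small wrong-code probability.  Game score accrues at a skill rate impaired
linearly by blur.

Defaults are calibrated so the control arm's mean adherence lands near 44%
and the reminder arm near 67%, with off-time and wrong-code entry proportions
roughly matching the published 63/21/7 split of code entries.  They are
documentation of the published pattern, not claims of behavioural truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats

from adhersim.env import SessionConfig


@dataclass(frozen=True)
class AgentParams:
    """Behavioural parameters of one synthetic participant."""

    p_attend: float = 0.664
    symptom_free_mult: float = 0.70
    reminder_compliance: float = 0.90
    incentive_sensitivity: float = 0.30
    commitment_boost: float = 0.0
    timing_sd_s: float = 13.0
    p_wrong_code: float = 0.077
    skill: float = 12.0
    blur_impairment: float = 0.9

    def __post_init__(self) -> None:
        for name in (
            "p_attend",
            "symptom_free_mult",
            "reminder_compliance",
            "incentive_sensitivity",
            "commitment_boost",
            "p_wrong_code",
            "blur_impairment",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.timing_sd_s < 0 or self.skill < 0:
            raise ValueError("timing_sd_s and skill must be >= 0")


@dataclass(frozen=True)
class AgentContext:
    """Per-window context the environment hands to the agent."""

    symptoms_cleared: bool = False
    reminder_shown: bool = False
    incentive_active: bool = False
    commitment_signed: bool = False


@dataclass(frozen=True)
class DoseAction:
    attempt: bool
    entry_offset_s: Optional[int] = None
    code_correct: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.attempt and self.entry_offset_s is None:
            raise ValueError("attempting action needs an entry offset")
        if not self.attempt and self.entry_offset_s is not None:
            raise ValueError("non-attempt carries no entry offset")


def attend_probability(params: AgentParams, context: AgentContext) -> float:
    """Probability of attempting this window's code entry.

    Base ``p_attend`` is multiplied by ``symptom_free_mult`` once symptoms
    have cleared, then each active support pulls the probability toward 1:
    ``p <- p + x * (1 - p)`` for reminder compliance, incentive sensitivity
    and commitment boost in turn.
    """
    p = params.p_attend * (params.symptom_free_mult if context.symptoms_cleared else 1.0)
    if context.reminder_shown:
        p += params.reminder_compliance * (1.0 - p)
    if context.incentive_active:
        p += params.incentive_sensitivity * (1.0 - p)
    if context.commitment_signed:
        p += params.commitment_boost * (1.0 - p)
    return min(1.0, max(0.0, p))


def decide_dose(
    params: AgentParams, context: AgentContext, rng: np.random.Generator
) -> DoseAction:
    """Draw one dose decision: attempt, timing offset (whole seconds), code."""
    if rng.random() >= attend_probability(params, context):
        return DoseAction(attempt=False)
    offset = int(round(rng.normal(0.0, params.timing_sd_s))) if params.timing_sd_s > 0 else 0
    correct = rng.random() >= params.p_wrong_code
    return DoseAction(attempt=True, entry_offset_s=offset, code_correct=correct)


def expected_on_time_probability(
    params: AgentParams, context: AgentContext, config: SessionConfig
) -> float:
    """Closed-form per-dose probability of a correct on-time entry:
    attend × P(|offset| <= window) × (1 − wrong-code)."""
    if params.timing_sd_s > 0:
        # offsets are rounded to whole seconds, so |offset| <= w iff the
        # continuous draw lies in (-(w+0.5), w+0.5)
        w = config.on_time_window_s + 0.5
        p_window = 2.0 * stats.norm.cdf(w / params.timing_sd_s) - 1.0
    else:
        p_window = 1.0
    return attend_probability(params, context) * p_window * (1.0 - params.p_wrong_code)


def accrue_score(
    params: AgentParams, blur: float, dt: int, rng: np.random.Generator
) -> int:
    """Game points over ``dt`` seconds at the given blur level.

    Per-second rate is ``skill * (1 - blur_impairment * blur)``, floored at 0,
    with stochastic rounding of the fractional part each second (so the total
    is ``dt*floor(rate) + Binomial(dt, frac(rate))``, expectation exactly
    ``rate * dt``).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    rate = max(0.0, params.skill * (1.0 - params.blur_impairment * blur))
    whole = math.floor(rate)
    frac = rate - whole
    extra = int(rng.binomial(dt, frac)) if frac > 0 else 0
    return whole * dt + extra


_UNIT_FIELDS = {
    "p_attend",
    "symptom_free_mult",
    "reminder_compliance",
    "incentive_sensitivity",
    "commitment_boost",
    "p_wrong_code",
    "blur_impairment",
}


def sample_agent_params(
    base: AgentParams,
    heterogeneity: dict[str, dict] | None,
    rng: np.random.Generator,
) -> AgentParams:
    """Draw one participant's parameters from optional per-field hyperpriors.

    ``heterogeneity`` maps a field name to either
    ``{"dist": "beta", "a": ..., "b": ...}`` (unit-interval fields) or
    ``{"dist": "normal", "sd": ...}`` (centred on the base value, clipped to
    the field's valid range).  Fields without an entry keep their base value.
    """
    if not heterogeneity:
        return base
    updates: dict[str, float] = {}
    for name, spec in heterogeneity.items():
        if not hasattr(base, name):
            raise ValueError(f"unknown agent parameter {name!r}")
        dist = spec.get("dist")
        if dist == "beta":
            if name not in _UNIT_FIELDS:
                raise ValueError(f"beta hyperprior only valid for unit-interval fields, not {name}")
            updates[name] = float(rng.beta(spec["a"], spec["b"]))
        elif dist == "normal":
            value = getattr(base, name) + rng.normal(0.0, spec["sd"])
            if name in _UNIT_FIELDS:
                value = min(1.0, max(0.0, value))
            else:
                value = max(0.0, value)
            updates[name] = float(value)
        else:
            raise ValueError(f"unknown hyperprior dist {dist!r} for {name}")
    return replace(base, **updates)


def calibrate(
    target_mean_adherence: float,
    n_sims: int,
    rng: np.random.Generator,
    base_params: AgentParams | None = None,
    config: SessionConfig | None = None,
    tol: float = 0.5,
    max_iter: int = 30,
) -> tuple[AgentParams, float, float]:
    """Bisection search over ``p_attend`` so the simulated control-arm mean
    adherence hits ``target_mean_adherence`` (percent).

    All other parameters are held at ``base_params``.  Returns the calibrated
    params, the achieved mean, and its Monte-Carlo standard error.  Raises if
    the target exceeds what ``p_attend = 1`` can achieve (e.g. because of
    wrong-code and timing noise).
    """
    from adhersim.harness import run_session  # local import: avoids cycle

    if not (0.0 <= target_mean_adherence < 100.0 or target_mean_adherence == 100.0):
        raise ValueError("target must be in [0, 100]")
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    base_params = base_params or AgentParams()
    config = config or SessionConfig()

    seeds = rng.integers(0, 2**63, size=n_sims)

    def mean_adherence(p: float) -> tuple[float, float]:
        params = replace(base_params, p_attend=p)
        rates = np.empty(n_sims)
        for i, s in enumerate(seeds):
            record, _ = run_session(config, "control", params, int(s))
            rates[i] = record.adherence_rate
        return float(rates.mean()), float(rates.std(ddof=1) / math.sqrt(n_sims))

    if target_mean_adherence == 0.0:
        return replace(base_params, p_attend=0.0), 0.0, 0.0

    hi_mean, hi_se = mean_adherence(1.0)
    if target_mean_adherence > hi_mean + 3 * hi_se:
        raise ValueError(
            f"target {target_mean_adherence}% unattainable: p_attend=1 "
            f"achieves only {hi_mean:.1f}% (SE {hi_se:.2f}) given timing/wrong-code noise"
        )

    lo, hi = 0.0, 1.0
    achieved, se = hi_mean, hi_se
    best = 1.0
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        achieved, se = mean_adherence(mid)
        best = mid
        if abs(achieved - target_mean_adherence) <= tol:
            break
        if achieved < target_mean_adherence:
            lo = mid
        else:
            hi = mid
    return replace(base_params, p_attend=best), achieved, se
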