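import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adhersim.env import (
    DoseOutcome,
    EnvState,
    SessionConfig,
    apply_earnings,
    classify_entry,
    close_dose_window,
    relapse_hazard,
    relapse_round_pmf,
    schedule_doses,
    update_blur,
)


class TestSessionConfig:
    def test_defaults_valid(self):
        cfg = SessionConfig()
        assert cfg.session_duration_s == 870
        assert cfg.n_doses == 14

    def test_rejects_overlong_schedule(self):
        with pytest.raises(ValueError):
            SessionConfig(n_doses=15)

    def test_rejects_bad_probability(self):
        with pytest.raises(ValueError):
            SessionConfig(relapse_base_p=1.5)

    def test_rejects_fee_above_cap(self):
        with pytest.raises(ValueError):
            SessionConfig(show_up_fee=600.0)


class TestSchedule:
    def test_defaults_fourteen_per_minute(self, config):
        times = schedule_doses(config)
        assert times == [60 * i for i in range(1, 15)]
        assert len(times) == 14

    def test_single_dose(self):
        assert schedule_doses(SessionConfig(n_doses=1)) == [60]

    def test_last_within_session(self, config):
        assert schedule_doses(config)[-1] <= config.session_duration_s


class TestClassifyEntry:
    def test_on_time_at_scheduled(self, config):
        assert classify_entry(config, 3, 180, config.code) == DoseOutcome.CORRECT_ON_TIME

    def test_off_time_outside_window(self, config):
        assert classify_entry(config, 1, 60 + 45, config.code) == DoseOutcome.CORRECT_OFF_TIME

    def test_wrong_code(self, config):
        assert classify_entry(config, 1, 60, "nope") == DoseOutcome.WRONG_CODE

    def test_missed(self, config):
        assert classify_entry(config, 1, None, None) == DoseOutcome.MISSED

    @pytest.mark.parametrize("window", [1, 5, 14, 29])
    def test_window_boundary_any_width(self, window):
        cfg = SessionConfig(on_time_window_s=window)
        assert classify_entry(cfg, 1, 60 + window, cfg.code) == DoseOutcome.CORRECT_ON_TIME
        assert classify_entry(cfg, 1, 60 + window + 1, cfg.code) == DoseOutcome.CORRECT_OFF_TIME
        assert classify_entry(cfg, 1, 60 - window - 1, cfg.code) == DoseOutcome.CORRECT_OFF_TIME

    def test_bad_dose_index(self, config):
        with pytest.raises(ValueError):
            classify_entry(config, 15, 900, config.code)


class TestRelapseHazard:
    def test_first_miss_two_percent(self, config):
        assert relapse_hazard(config, 1) == pytest.approx(0.02)

    @pytest.mark.parametrize("m,expected", [(2, 0.04), (3, 0.08), (4, 0.16)])
    def test_doubling(self, config, m, expected):
        assert relapse_hazard(config, m) == pytest.approx(expected)

    def test_cap_at_one(self, config):
        # 0.02 * 2**6 = 1.28 -> capped
        assert relapse_hazard(config, 7) == 1.0

    def test_zero_misses_rejected(self, config):
        with pytest.raises(ValueError):
            relapse_hazard(config, 0)

    def test_six_miss_cumulative_probability(self, config):
        # closed form: 1 - prod(1 - 0.02 * 2**i) for i in 0..5
        p = 1.0 - math.prod(1.0 - 0.02 * 2**i for i in range(6))
        assert p == pytest.approx(0.822, abs=5e-4)
        # Monte-Carlo cross-check of the same quantity
        rng = np.random.default_rng(5)
        n = 100_000
        relapsed = 0
        for _ in range(n):
            for m in range(1, 7):
                if rng.random() < relapse_hazard(config, m):
                    relapsed += 1
                    break
        mc = relapsed / n
        se = math.sqrt(p * (1 - p) / n)
        assert abs(mc - p) < 4 * se


class TestUpdateBlur:
    def test_linear_clearance(self, config):
        state = EnvState.initial(config)
        for _ in range(3):
            state.blur = update_blur(state, config)
            state.correct_entries += 1
        assert state.blur == pytest.approx(1 - 3 / 7)

    def test_full_clearance_at_seven(self, config, rng):
        state = EnvState.initial(config)
        for i in range(1, 8):
            close_dose_window(state, config, i, DoseOutcome.CORRECT_ON_TIME, rng)
        assert state.blur == pytest.approx(0.0)
        assert state.symptoms_cleared

    def test_elongated_half_clear_at_seven(self, rng):
        cfg = SessionConfig(clear_after_doses=14)
        state = EnvState.initial(cfg)
        for i in range(1, 8):
            close_dose_window(state, cfg, i, DoseOutcome.CORRECT_ON_TIME, rng)
        assert state.blur == pytest.approx(0.5)
        assert not state.symptoms_cleared


class TestCloseDoseWindow:
    def _cleared_state(self, config, rng):
        state = EnvState.initial(config)
        for i in range(1, config.clear_after_doses + 1):
            close_dose_window(state, config, i, DoseOutcome.CORRECT_ON_TIME, rng)
        assert state.symptoms_cleared
        return state

    def test_pre_clearance_miss_has_no_hazard(self, config):
        class ExplodingRng:
            def random(self):  # pragma: no cover - should never run
                raise AssertionError("hazard drawn before clearance")

        state = EnvState.initial(config)
        close_dose_window(state, config, 1, DoseOutcome.MISSED, ExplodingRng())
        assert state.consecutive_misses == 0
        assert not state.relapsed

    def test_relapse_adds_quarter_blur(self, config, rng):
        state = self._cleared_state(config, rng)

        class AlwaysHit:
            def random(self):
                return 0.0

        blur_before = state.blur
        close_dose_window(state, config, config.clear_after_doses + 1, DoseOutcome.MISSED, AlwaysHit())
        assert state.blur == pytest.approx(blur_before + 0.25)
        assert state.relapsed
        assert state.relapse_round == config.clear_after_doses + 1

    def test_max_relapses_suppresses_second(self, config, rng):
        state = self._cleared_state(config, rng)

        class AlwaysHit:
            def random(self):
                return 0.0

        hit = AlwaysHit()
        close_dose_window(state, config, 8, DoseOutcome.MISSED, hit)
        first_round = state.relapse_round
        close_dose_window(state, config, 9, DoseOutcome.MISSED, hit)
        assert state.relapses == 1
        assert state.relapse_round == first_round

    def test_on_time_resets_miss_counter(self, config, rng):
        state = self._cleared_state(config, rng)

        class NeverHit:
            def random(self):
                return 1.0

        close_dose_window(state, config, 8, DoseOutcome.MISSED, NeverHit())
        assert state.consecutive_misses == 1
        close_dose_window(state, config, 9, DoseOutcome.CORRECT_ON_TIME, rng)
        assert state.consecutive_misses == 0

    def test_out_of_order_rejected(self, config, rng):
        state = EnvState.initial(config)
        close_dose_window(state, config, 1, DoseOutcome.MISSED, rng)
        with pytest.raises(ValueError):
            close_dose_window(state, config, 1, DoseOutcome.MISSED, rng)

    def test_window_15_rejected_and_codes_expire(self, config, rng):
        state = EnvState.initial(config)
        for i in range(1, 15):
            close_dose_window(state, config, i, DoseOutcome.CORRECT_ON_TIME, rng)
        assert not state.codes_effective
        with pytest.raises(ValueError):
            close_dose_window(state, config, 15, DoseOutcome.MISSED, rng)

    @settings(max_examples=40, deadline=None)
    @given(
        outcomes=st.lists(st.sampled_from(list(DoseOutcome)), min_size=14, max_size=14),
        seed=st.integers(0, 2**31),
    )
    def test_blur_stays_in_unit_interval(self, outcomes, seed):
        cfg = SessionConfig(max_relapses=14)  # stress clamping with many relapses
        rng = np.random.default_rng(seed)
        state = EnvState.initial(cfg)
        for i, outcome in enumerate(outcomes, start=1):
            close_dose_window(state, cfg, i, outcome, rng)
            assert 0.0 <= state.blur <= 1.0
        assert state.windows_closed == 14


class TestEarnings:
    def test_session_start_is_show_up_fee(self, config):
        state = EnvState.initial(config)
        apply_earnings(state, config)
        assert state.earnings == pytest.approx(80.0)

    def test_incentive_adds_five_per_on_time(self):
        cfg = SessionConfig(condition="incentive")
        state = EnvState.initial(cfg)
        state.on_time_entries = 1
        apply_earnings(state, cfg)
        assert state.earnings == pytest.approx(85.0)

    def test_control_ignores_on_time_bonus(self, config):
        state = EnvState.initial(config)
        state.on_time_entries = 10
        apply_earnings(state, config)
        assert state.earnings == pytest.approx(80.0)

    def test_cap_at_500(self, config):
        state = EnvState.initial(config)
        state.cumulative_game_score = 10_000_000
        apply_earnings(state, config)
        assert state.earnings == pytest.approx(500.0)

    def test_linear_score_payout(self, config):
        state = EnvState.initial(config)
        state.cumulative_game_score = 20_000
        apply_earnings(state, config)
        assert state.earnings == pytest.approx(80.0 + 420.0)


class TestRelapseRoundPmf:
    def test_pmf_is_probability(self, config):
        pmf = relapse_round_pmf(config, clearance_round=7)
        assert set(pmf) == set(range(8, 15))
        # hazard is capped at 1 by the 7th consecutive miss, so relapse is
        # certain within the default session and the pmf sums to exactly 1
        assert sum(pmf.values()) == pytest.approx(1.0)

    def test_pmf_subprobability_with_late_clearance(self, config):
        pmf = relapse_round_pmf(config, clearance_round=11)
        assert set(pmf) == {12, 13, 14}
        assert 0 < sum(pmf.values()) < 1

    def test_first_round_mass_is_base_hazard(self, config):
        pmf = relapse_round_pmf(config, clearance_round=7)
        assert pmf[8] == pytest.approx(0.02)
        assert pmf[9] == pytest.approx(0.98 * 0.04)
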