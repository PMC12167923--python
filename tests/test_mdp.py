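"""MDP: discretization bins, 487-state coding, action masks, cycle stepping."""

import numpy as np
import pytest

from pvdose.mdp import (
    ACTIONS,
    ALL_STATES,
    DOSE_LEVELS,
    INITIAL_PREV_DOSE,
    N_STATES,
    PREV_DOSE_CODES,
    ClinicalState,
    DoseTitrationEnv,
    discretize_observation,
    legal_actions,
    random_rollout,
    state_from_index,
    state_index,
)


class TestDiscretization:
    @pytest.mark.parametrize(
        "obs,expected",
        [
            ((100, 3.5, 44), (2, 2, 1)),  # moderate thrombocytopenia / neutropenia
            ((500, 12, 46), (4, 4, 2)),  # everything above range
            ((150, 4, 45), (3, 3, 2)),  # boundaries: efficacy floors, HCT >= 45
            ((74.99, 2.99, 44.99), (1, 1, 1)),  # just below severe thresholds
            ((400, 10, 0.1), (3, 3, 1)),  # efficacy ceilings are inclusive
            ((400.01, 10.01, 45.0), (4, 4, 2)),
        ],
    )
    def test_bins(self, obs, expected):
        assert discretize_observation(*obs) == expected

    def test_invalid_observations_rejected(self):
        with pytest.raises(ValueError):
            discretize_observation(float("nan"), 5, 40)
        with pytest.raises(ValueError):
            discretize_observation(100, -1, 40)


class TestStateSpace:
    def test_counts_480_plus_7_initial(self):
        assert N_STATES == 487
        non_initial = [s for s in ALL_STATES if s.prev_dose != INITIAL_PREV_DOSE]
        initial = [s for s in ALL_STATES if s.prev_dose == INITIAL_PREV_DOSE]
        assert len(non_initial) == 480
        # 8 initial-candidate tuples minus the discarded all-normal one
        assert len(initial) == 7

    def test_index_round_trip_all_states(self):
        seen = set()
        for s in ALL_STATES:
            i = state_index(s)
            assert 0 <= i < 487
            assert state_from_index(i) == s
            seen.add(i)
        assert len(seen) == 487

    def test_all_normal_initial_tuple_invalid(self):
        with pytest.raises(ValueError):
            ClinicalState(3, 3, 1, -1)

    def test_toxic_initial_tuples_invalid(self):
        with pytest.raises(ValueError):
            ClinicalState(2, 3, 1, -1)
        with pytest.raises(ValueError):
            ClinicalState(3, 1, 2, -1)

    def test_bad_codes_rejected(self):
        with pytest.raises(ValueError):
            ClinicalState(5, 3, 1, 50)
        with pytest.raises(ValueError):
            ClinicalState(3, 3, 1, 60)
        with pytest.raises(ValueError):
            state_from_index(487)


def expected_actions(state: ClinicalState) -> tuple[int, ...]:
    """Literal transcription of the published action table, row by row.

    Kept deliberately independent of the package's mask generator: every
    row is written out explicitly so the two implementations can only
    agree by encoding the same clinical rules.
    """
    plt_cat, wbc_cat, prev = state.plt_cat, state.wbc_cat, state.prev_dose
    step_up = {50: (50, 75), 75: (50, 75, 100), 100: (75, 100, 125),
               125: (100, 125, 150), 150: (125, 150, 175), 175: (150, 175, 200),
               200: (175, 200)}
    if prev == -1:
        return (50, 75, 100, 125, 150, 175, 200)
    if plt_cat == 1 or wbc_cat == 1:  # severe: forced interruption, any prev
        return (0,)
    if prev > 0:
        if plt_cat >= 3 and wbc_cat >= 3:  # no toxicity
            return step_up[prev]
        # moderate toxicity (plt 2 and/or wbc 2)
        if prev == 50:
            return (0,)
        return step_up[prev]
    if prev == 0:  # interrupted for moderate toxicity
        if plt_cat == 3 and wbc_cat == 3:
            return (0, 50)
        return (0,)
    # prev < 0: interrupted for severe toxicity; both lineages now >= 2
    resume = {-50: (0, 50), -75: (0, 50, 75), -100: (0, 50, 75, 100),
              -125: (0, 50, 75, 100, 125), -150: (0, 50, 75, 100, 125, 150),
              -175: (0, 50, 75, 100, 125, 150, 175),
              -200: (0, 50, 75, 100, 125, 150, 175, 200)}
    return resume[prev]


class TestLegalActions:
    def test_matches_published_table_on_all_487_states(self):
        for s in ALL_STATES:
            assert legal_actions(s) == expected_actions(s), s.as_tuple()

    def test_never_empty_and_on_grid(self):
        for s in ALL_STATES:
            menu = legal_actions(s)
            assert menu
            assert all(a in ACTIONS for a in menu)

    @pytest.mark.parametrize(
        "state,expected",
        [
            ((3, 3, 1, 50), (50, 75)),
            ((2, 2, 1, -100), (0, 50, 75, 100)),
            ((1, 3, 1, 125), (0,)),
            ((3, 3, 2, -1), (50, 75, 100, 125, 150, 175, 200)),
            ((2, 3, 1, 50), (0,)),  # moderate at the floor dose
            ((4, 2, 2, 200), (175, 200)),  # moderate at the ceiling
            ((3, 3, 1, 0), (0, 50)),  # resumption after moderate interruption
            ((2, 3, 1, 0), (0,)),  # not yet recovered: keep holding
        ],
    )
    def test_specific_rows(self, state, expected):
        assert legal_actions(ClinicalState(*state)) == expected


class TestAdvanceCycle:
    def test_positive_dose_updates_prev_dose_28_days(self, typical_patient):
        env = DoseTitrationEnv(typical_patient)
        s0 = env.reset()
        assert s0.prev_dose == -1
        s1, outcome, done = env.step(100)
        assert outcome.cycle_length == 28
        assert s1.prev_dose == 100
        assert env.day == 28
        assert not done

    def test_severe_interruption_codes_negative_trigger(self):
        # a drug-sensitive patient driven with maximal dosing must reach
        # observed severe toxicity, forcing a coded 14-day interruption
        from pvdose.twin import HctPD, LineagePD, PatientParameters

        sensitive = PatientParameters(
            ka=2.0, cl=110.0, v=50.0, ke0=0.15,
            plt=LineagePD(620.0, 10.0, 0.3, 0.8),
            wbc=LineagePD(12.0, 5.0, 0.25, 0.2),
            hct=HctPD(42.0, 0.05, 0.25),
        )
        env = DoseTitrationEnv(sensitive)
        s = env.reset()
        trigger = None
        while not env.done:
            a = max(env.legal_actions())
            s, outcome, _ = env.step(a)
            if s.plt_cat == 1 or s.wbc_cat == 1:
                trigger = a
                break
        assert trigger is not None and trigger > 0
        s_next, outcome, _ = env.step(0)
        assert outcome.cycle_length == 14
        assert s_next.prev_dose == -trigger

    def test_moderate_interruption_at_50_codes_zero(self, typical_patient):
        env = DoseTitrationEnv(typical_patient)
        state = ClinicalState(2, 3, 1, 50)
        env.reset()
        env._state = state  # place the env in the moderate-toxicity state
        s_next, outcome, _ = env.step(0)
        assert outcome.cycle_length == 14
        assert s_next.prev_dose in (0, -50)  # -50 if the hold itself went severe
        if s_next.plt_cat >= 2 and s_next.wbc_cat >= 2:
            assert s_next.prev_dose == 0

    def test_illegal_action_rejected(self, typical_patient):
        env = DoseTitrationEnv(typical_patient)
        env.reset()
        with pytest.raises(ValueError):
            env.step(0)  # interruption is not a legal initial action

    def test_episode_clock_exact(self, typical_patient):
        rng = np.random.default_rng(0)
        for _ in range(5):
            env = DoseTitrationEnv(typical_patient)
            env.reset()
            total = 0
            while not env.done:
                menu = env.legal_actions()
                _, outcome, _ = env.step(menu[rng.integers(len(menu))])
                total += outcome.cycle_length
            assert total == 224
            assert env.day == 224

    def test_step_after_horizon_rejected(self, typical_patient):
        env = DoseTitrationEnv(typical_patient)
        env.reset()
        while not env.done:
            env.step(min(env.legal_actions(), key=lambda a: (a == 0, a)))
        with pytest.raises(RuntimeError):
            env.step(50)


class TestRandomRollouts:
    def test_visited_states_always_valid(self, small_population):
        rng = np.random.default_rng(7)
        for patient in small_population[:3]:
            env = DoseTitrationEnv(patient.params)
            visited = random_rollout(env, rng, n_episodes=40)
            assert all(0 <= i < N_STATES for i in visited)

    def test_in_range_counts_bounded(self, typical_patient):
        env = DoseTitrationEnv(typical_patient)
        env.reset()
        rng = np.random.default_rng(1)
        while not env.done:
            menu = env.legal_actions()
            _, o, _ = env.step(menu[rng.integers(len(menu))])
            for n in (o.plt_in_range, o.wbc_in_range, o.hct_in_range):
                assert 0 <= n <= o.cycle_length
            assert np.isfinite([o.plt_deriv, o.wbc_deriv, o.hct_deriv]).all()
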