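"""Tabular Q-learning: update rule, exploration, convergence, determinism."""

import numpy as np
import pytest

from pvdose.mdp import ClinicalState, DoseTitrationEnv, legal_actions
from pvdose.population import VirtualPatient
from pvdose.qlearning import (
    QTable,
    TrainingConfig,
    greedy_policy_rollout,
    q_update,
    select_action,
    train_individual_agent,
    train_population_agent,
)
from pvdose.reward import SMOOTHED, STRICT, cycle_reward
from pvdose.twin import HctPD, LineagePD, PatientParameters


def toy_patient(pid=0) -> VirtualPatient:
    """Deterministic patient with elevated PLT, stable WBC/HCT."""
    params = PatientParameters(
        ka=2.0,
        cl=150.0,
        v=50.0,
        ke0=0.1,
        plt=LineagePD(baseline=650.0, mtt=10.0, gamma=0.3, slope=0.34),
        wbc=LineagePD(baseline=8.0, mtt=5.0, gamma=0.25, slope=0.1),
        hct=HctPD(baseline=42.0, kout=0.05, slope=0.2),
    )
    return VirtualPatient(id=pid, params=params, pattern=("plt",), sensitivity="typical")


class TestQUpdate:
    def test_zero_reward_zero_table_unchanged(self):
        table = QTable()
        s = ClinicalState(3, 3, 1, 100)
        q_update(table, s, 100, 0.0, ClinicalState(3, 3, 1, 100), False, 0.5, 0.9)
        assert np.all(table.values == 0.0)

    def test_terminal_update_moves_half_way(self):
        table = QTable()
        s = ClinicalState(3, 3, 1, 100)
        q_update(table, s, 100, 10.0, None, True, 0.5, 0.9)
        assert table.value(s, 100) == pytest.approx(5.0)

    def test_only_target_entry_changes(self):
        table = QTable()
        s = ClinicalState(3, 3, 1, 100)
        q_update(table, s, 100, 4.0, None, True, 1.0, 0.9)
        assert np.count_nonzero(table.values) == 1

    def test_illegal_pair_rejected(self):
        table = QTable()
        with pytest.raises(ValueError):
            q_update(table, ClinicalState(1, 3, 1, 100), 100, 1.0, None, True, 0.5, 0.9)

    def test_chain_converges_to_discounted_sum(self):
        """A 3-step forced chain with constant reward r reaches
        r * (1 - gamma^3) / (1 - gamma) at the head state."""
        table = QTable()
        r, gamma = 2.0, 0.9
        chain = [
            ClinicalState(1, 3, 1, 100),
            ClinicalState(1, 3, 1, 125),
            ClinicalState(1, 3, 1, 150),
        ]
        for _ in range(200):
            for i, s in enumerate(chain):
                terminal = i == len(chain) - 1
                nxt = None if terminal else chain[i + 1]
                q_update(table, s, 0, r, nxt, terminal, 0.5, gamma)
        expected = r * (1 - gamma**3) / (1 - gamma)
        assert table.value(chain[0], 0) == pytest.approx(expected, abs=1e-6)


class TestSelectAction:
    def test_greedy_picks_argmax(self):
        table = QTable()
        s = ClinicalState(3, 3, 1, 100)
        table.values[:] = 0.0
        from pvdose.qlearning import _ACTION_INDEX
        from pvdose.mdp import state_index

        table.values[state_index(s), _ACTION_INDEX[125]] = 3.0
        rng = np.random.default_rng(0)
        assert select_action(table, s, 0.0, rng) == 125

    def test_tie_breaks_to_lowest_dose(self):
        table = QTable()
        s = ClinicalState(3, 3, 1, 100)  # menu {75, 100, 125}, all zeros
        rng = np.random.default_rng(0)
        assert select_action(table, s, 0.0, rng) == 75

    def test_full_exploration_uniform(self):
        table = QTable()
        s = ClinicalState(3, 3, 1, 100)
        rng = np.random.default_rng(42)
        n = 10_000
        draws = [select_action(table, s, 1.0, rng) for _ in range(n)]
        counts = {a: draws.count(a) for a in (75, 100, 125)}
        p = 1.0 / 3.0
        sigma = (n * p * (1 - p)) ** 0.5
        for a, c in counts.items():
            assert abs(c - n * p) < 3 * sigma, counts


def brute_force_best_return(patient, horizon, allowed, reward_cfg):
    """Exhaustive enumeration over all legal dose sequences."""

    def recurse(prefix):
        env = DoseTitrationEnv(patient.params, horizon_days=horizon, allowed_doses=allowed)
        state = env.reset()
        total = 0.0
        for a in prefix:
            state, outcome, done = env.step(a)
            total += cycle_reward(outcome, reward_cfg)
        if env.done:
            return total
        best = -np.inf
        for a in env.legal_actions(state):
            best = max(best, recurse(prefix + (a,)))
        return best

    return recurse(())


class TestOracleEquivalence:
    def test_two_cycle_toy_matches_exhaustive_search(self):
        """Greedy return after training equals the exhaustive optimum.

        Two 28-day cycles and three dose levels: the initial state is only
        visited at the first decision and every later state only at the
        second, so a stationary table can represent the optimal policy
        exactly; undiscounted alpha=1 training on the deterministic twin
        then reduces to exact dynamic programming.
        """
        patient = toy_patient()
        allowed = (50, 100, 150)
        horizon = 56
        best = brute_force_best_return(patient, horizon, allowed, STRICT)

        env = DoseTitrationEnv(patient.params, horizon_days=horizon, allowed_doses=allowed)
        config = TrainingConfig(
            alpha=1.0, gamma=1.0, epsilon_init=1.0, epsilon_floor=1.0,
            episodes=400, seed=3, reward=STRICT,
        )
        table = train_individual_agent(patient, config, env=env, return_rollout=False)
        log = greedy_policy_rollout(table, patient, env=env, reward_cfg=STRICT)
        assert log.total_reward == pytest.approx(best, abs=1e-6)

    def test_same_seed_identical_tables(self):
        patient = toy_patient()
        cfg = TrainingConfig(episodes=50, seed=11)
        t1 = train_individual_agent(patient, cfg, return_rollout=False)
        t2 = train_individual_agent(patient, cfg, return_rollout=False)
        assert np.array_equal(t1.values, t2.values)


class TestGreedyRollout:
    def test_rollout_deterministic_and_legal(self):
        patient = toy_patient()
        table, _ = train_individual_agent(patient, TrainingConfig(episodes=200, seed=0))
        log1 = greedy_policy_rollout(table, patient)
        log2 = greedy_policy_rollout(table, patient)
        assert [d.action for d in log1.decisions] == [d.action for d in log2.decisions]
        assert np.array_equal(log1.plt, log2.plt)
        for d in log1.decisions:
            assert d.action in legal_actions(d.state)

    def test_rollout_covers_full_horizon(self):
        patient = toy_patient()
        table, log = train_individual_agent(patient, TrainingConfig(episodes=200, seed=0))
        assert log.horizon == 224
        assert len(log.day) == 225
        assert sum(d.cycle_length for d in log.decisions) == 224


class TestPopulationTraining:
    def test_single_patient_equals_individual(self):
        """With one patient, population training is individual training."""
        patient = toy_patient()
        cfg = TrainingConfig(episodes=300, sweeps=300, seed=9, reward=SMOOTHED)
        t_pop = train_population_agent([patient], cfg)
        t_ind = train_individual_agent(patient, cfg, return_rollout=False)
        assert np.array_equal(t_pop.values, t_ind.values)

    def test_identical_patients_policy_matches_individual(self):
        """A population of clones learns the same greedy behaviour."""
        clones = [toy_patient(pid=i) for i in range(3)]
        cfg = TrainingConfig(episodes=900, sweeps=300, seed=4, reward=SMOOTHED)
        t_pop = train_population_agent(clones, cfg)
        t_ind = train_individual_agent(clones[0], cfg, return_rollout=False)
        log_pop = greedy_policy_rollout(t_pop, clones[0], reward_cfg=SMOOTHED)
        log_ind = greedy_policy_rollout(t_ind, clones[0], reward_cfg=SMOOTHED)
        assert [d.action for d in log_pop.decisions] == [d.action for d in log_ind.decisions]

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            train_population_agent([], TrainingConfig())

    def test_maintain_dose_in_efficacy_states(self, small_population):
        """The learned population policy mostly confirms the dose when all
        endpoints are in range (the clinical protocol's own efficacy rule)."""
        cfg = TrainingConfig(episodes=2000, sweeps=150, seed=21, reward=SMOOTHED)
        table = train_population_agent(small_population, cfg)
        visited = []
        for patient in small_population:
            log = greedy_policy_rollout(table, patient, reward_cfg=SMOOTHED)
            for d in log.decisions:
                s = d.state
                if (s.plt_cat, s.wbc_cat, s.hct_cat) == (3, 3, 1) and s.prev_dose > 0:
                    visited.append(d.action == s.prev_dose)
        assert visited, "no efficacy states visited by the greedy policy"
        assert sum(visited) / len(visited) > 0.5


class TestPersistence:
    def test_qtable_json_round_trip(self, tmp_path):
        patient = toy_patient()
        table, _ = train_individual_agent(patient, TrainingConfig(episodes=100, seed=2))
        path = tmp_path / "q.json"
        table.to_json(path)
        back = QTable.from_json(path)
        assert np.allclose(table.values[table.mask], back.values[back.mask])

    def test_policy_table_covers_all_states(self):
        table = QTable()
        df = table.policy_table()
        assert len(df) == 487
        assert set(df.columns) == {"plt_cat", "wbc_cat", "hct_cat", "prev_dose", "greedy_dose"}
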