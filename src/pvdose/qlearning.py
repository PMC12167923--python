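"""Tabular Q-learning for the dosing MDP.

One-step Q-learning with an epsilon-greedy behaviour policy is run on
whole treatment episodes simulated by a patient's digital twin:

``Q(s,a) <- Q(s,a) + alpha * (r + gamma * max_a' Q(s',a') - Q(s,a))``

with a zero bootstrap at the episode horizon (finite 8-month treatment).
Forced actions (interruptions) are the single legal action of their state
and are updated like any other, which keeps the Bellman backup
well-defined through interruption chains.  Greedy ties break toward the
lowest dose, a conservative clinical default.

Two training regimes are provided:

* ``train_individual_agent`` -- one agent per patient, trained on the
  patient's own twin with the strict reward (hard zero on severe
  toxicity);
* ``train_population_agent`` -- one shared table updated across episodes
  that sweep round-robin through a heterogeneous population, with the
  smoothed reward.

Because the twin is deterministic, the haematological outcome of a cycle
depends only on the dose sequence administered so far; trainers therefore
memoise cycle outcomes keyed by the dose prefix, which makes the late
(mostly greedy) episodes nearly free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mdp import (
    ACTIONS,
    LEGAL_MASK,
    N_STATES,
    ClinicalState,
    DoseTitrationEnv,
    state_from_index,
    state_index,
)
from .population import VirtualPatient
from .reward import STRICT, SMOOTHED, RewardConfig, cycle_reward

_ACTION_INDEX = {a: i for i, a in enumerate(ACTIONS)}


class QTable:
    """Action-value store over the 487 valid states and 8 actions.

    Entries exist (are finite) only for legal (state, action) pairs;
    illegal pairs are masked to -inf for the argmax/max operations and
    rejected by :meth:`update`.
    """

    def __init__(self) -> None:
        self.values = np.zeros((N_STATES, len(ACTIONS)))
        self.mask = LEGAL_MASK

    def value(self, state: ClinicalState, action: int) -> float:
        si, ai = state_index(state), _ACTION_INDEX[action]
        if not self.mask[si, ai]:
            raise ValueError(f"action {action} illegal in state {state.as_tuple()}")
        return float(self.values[si, ai])

    def max_value(self, state: ClinicalState, menu: tuple[int, ...] | None = None) -> float:
        si = state_index(state)
        if menu is None:
            return float(self.values[si][self.mask[si]].max())
        return max(float(self.values[si, _ACTION_INDEX[a]]) for a in menu)

    def greedy_action(self, state: ClinicalState, menu: tuple[int, ...] | None = None) -> int:
        """Argmax over the legal menu; ties break toward the lowest dose."""
        si = state_index(state)
        if menu is None:
            menu = tuple(a for a in ACTIONS if self.mask[si, _ACTION_INDEX[a]])
        best, best_v = menu[0], -np.inf
        for a in menu:  # ascending dose order; strict > keeps the lowest tie
            v = float(self.values[si, _ACTION_INDEX[a]])
            if v > best_v:
                best, best_v = a, v
        return best

    def update(
        self,
        state: ClinicalState,
        action: int,
        reward: float,
        next_state: ClinicalState | None,
        terminal: bool,
        alpha: float,
        gamma: float,
        next_menu: tuple[int, ...] | None = None,
    ) -> float:
        """One Q-learning backup; returns the new Q(s, a)."""
        if not np.isfinite(reward):
            raise ValueError("reward must be finite")
        si, ai = state_index(state), _ACTION_INDEX[action]
        if not self.mask[si, ai]:
            raise ValueError(f"action {action} illegal in state {state.as_tuple()}")
        target = reward if terminal else reward + gamma * self.max_value(next_state, next_menu)
        self.values[si, ai] += alpha * (target - self.values[si, ai])
        return float(self.values[si, ai])

    # ------------------------------------------------------------ persistence
    def to_json(self, path) -> None:
        payload = {}
        for si in range(N_STATES):
            state = state_from_index(si)
            entry = {
                str(a): self.values[si, _ACTION_INDEX[a]]
                for a in ACTIONS
                if self.mask[si, _ACTION_INDEX[a]]
            }
            payload[",".join(map(str, state.as_tuple()))] = entry
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "QTable":
        table = cls()
        with open(path) as fh:
            payload = json.load(fh)
        for key, entry in payload.items():
            tup = tuple(int(x) for x in key.split(","))
            si = state_index(ClinicalState(*tup))
            for a, v in entry.items():
                table.values[si, _ACTION_INDEX[int(a)]] = v
        return table

    def policy_table(self) -> pd.DataFrame:
        """Human-readable greedy decision table (state tuple -> dose)."""
        rows = []
        for si in range(N_STATES):
            state = state_from_index(si)
            rows.append(
                {
                    "plt_cat": state.plt_cat,
                    "wbc_cat": state.wbc_cat,
                    "hct_cat": state.hct_cat,
                    "prev_dose": state.prev_dose,
                    "greedy_dose": self.greedy_action(state),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of the tabular trainer (all overridable)."""

    alpha: float = 0.1
    gamma: float = 0.3
    epsilon_init: float = 1.0
    epsilon_floor: float = 0.02
    episodes: int = 10000
    sweeps: int = 200  # population training: sweeps over the whole population
    seed: int = 0
    reward: RewardConfig = STRICT

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if not 0 <= self.epsilon_floor <= self.epsilon_init <= 1:
            raise ValueError("need 0 <= epsilon_floor <= epsilon_init <= 1")
        if self.episodes < 1 or self.sweeps < 1:
            raise ValueError("episodes and sweeps must be >= 1")

    def epsilon_schedule(self, n_episodes: int) -> np.ndarray:
        """Geometric decay from epsilon_init to epsilon_floor over n episodes."""
        if n_episodes == 1 or self.epsilon_init == 0:
            return np.full(n_episodes, self.epsilon_init)
        if self.epsilon_floor == 0:
            eps = np.geomspace(self.epsilon_init, 1e-4, n_episodes)
            eps[-1] = 0.0
            return eps
        return np.geomspace(self.epsilon_init, self.epsilon_floor, n_episodes)


def q_update(
    qtable: QTable,
    state: ClinicalState,
    action: int,
    reward: float,
    next_state: ClinicalState | None,
    terminal: bool,
    alpha: float,
    gamma: float,
) -> QTable:
    """Functional wrapper over :meth:`QTable.update` (mutates and returns)."""
    qtable.update(state, action, reward, next_state, terminal, alpha, gamma)
    return qtable


def select_action(
    qtable: QTable,
    state: ClinicalState,
    epsilon: float,
    rng: np.random.Generator,
    menu: tuple[int, ...] | None = None,
) -> int:
    """Epsilon-greedy action: explore uniformly, otherwise greedy."""
    if menu is None:
        from .mdp import legal_actions

        menu = legal_actions(state)
    if epsilon > 0 and rng.random() < epsilon:
        return int(menu[rng.integers(len(menu))])
    return qtable.greedy_action(state, menu)


# --------------------------------------------------------------------- cache
class _CycleCache:
    """Memoised cycle outcomes of one deterministic twin.

    Keyed by the dose sequence administered so far: the twin has no
    stochastic component, so a dose prefix fully determines the internal
    state at the next decision point.
    """

    def __init__(self, env: DoseTitrationEnv):
        self.env = env
        # key: dose prefix -> (internal twin state, day, clinical state,
        # outcome of the last cycle, done flag)
        self._store: dict[tuple[int, ...], tuple] = {}

    def episode_start(self):
        return self.env.reset()

    def step(self, prefix: tuple[int, ...], action: int):
        """Outcome of appending ``action`` to the dose prefix.

        Returns ``(next_state, outcome, done)``.  Prefixes are visited
        incrementally within an episode, so on a cache miss the parent
        snapshot is always available (or is the baseline) and only the new
        cycle needs simulating.
        """
        key = prefix + (action,)
        hit = self._store.get(key)
        if hit is not None:
            return hit[2:]
        env = self.env
        if prefix:
            parent = self._store[prefix]
            env._internal, env.day, env._state = parent[0], parent[1], parent[2]
        else:
            env.reset()
        next_state, outcome, done = env.step(action)
        self._store[key] = (env._internal, env.day, next_state, outcome, done)
        return next_state, outcome, done


# ------------------------------------------------------------------ episodes
@dataclass
class Decision:
    index: int
    day: int
    state: ClinicalState
    action: int
    cycle_length: int
    reward: float
    plt_obs: float
    wbc_obs: float
    hct_obs: float


@dataclass
class EpisodeLog:
    """Full record of one treatment episode (decisions + daily trajectory)."""

    patient_id: int | None
    decisions: list[Decision]
    day: np.ndarray
    plt: np.ndarray
    wbc: np.ndarray
    hct: np.ndarray
    dose: np.ndarray
    total_reward: float

    @property
    def horizon(self) -> int:
        return int(self.day[-1])

    def decisions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "decision": [d.index for d in self.decisions],
                "day": [d.day for d in self.decisions],
                "state": [d.state.as_tuple() for d in self.decisions],
                "state_index": [state_index(d.state) for d in self.decisions],
                "action": [d.action for d in self.decisions],
                "cycle_length": [d.cycle_length for d in self.decisions],
                "plt_obs": [d.plt_obs for d in self.decisions],
                "wbc_obs": [d.wbc_obs for d in self.decisions],
                "hct_obs": [d.hct_obs for d in self.decisions],
                "reward": [d.reward for d in self.decisions],
            }
        )

    def trajectory_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day, "dose_mg": self.dose, "plt": self.plt, "wbc": self.wbc, "hct": self.hct}
        )


def _run_episode_logged(env: DoseTitrationEnv, choose, reward_cfg: RewardConfig,
                        patient_id: int | None = None) -> EpisodeLog:
    """Run one episode, recording decisions and the daily trajectory.

    ``choose(state, observations, menu) -> action``.
    """
    state = env.reset()
    base_obs = env.current_observations()
    days = [0]
    plt_v, wbc_v, hct_v, dose_v = [base_obs[0]], [base_obs[1]], [base_obs[2]], [0.0]
    decisions: list[Decision] = []
    total = 0.0
    idx = 0
    while not env.done:
        day = env.day
        menu = env.legal_actions()
        obs = env.current_observations()
        action = choose(state, obs, menu)
        next_state, outcome, done = env.step(action)
        r = cycle_reward(outcome, reward_cfg)
        total += r
        decisions.append(
            Decision(
                index=idx,
                day=day,
                state=state,
                action=action,
                cycle_length=outcome.cycle_length,
                reward=r,
                plt_obs=outcome.plt_obs,
                wbc_obs=outcome.wbc_obs,
                hct_obs=outcome.hct_obs,
            )
        )
        for offset, (p, w, h) in enumerate(outcome.daily, start=1):
            days.append(day + offset)
            plt_v.append(p)
            wbc_v.append(w)
            hct_v.append(h)
            dose_v.append(float(action))
        state = next_state
        idx += 1
    if reward_cfg.terminal_chr_bonus:
        if 150 <= plt_v[-1] <= 400 and 4 <= wbc_v[-1] <= 10 and hct_v[-1] < 45:
            total += reward_cfg.terminal_chr_bonus
    return EpisodeLog(
        patient_id=patient_id,
        decisions=decisions,
        day=np.asarray(days),
        plt=np.asarray(plt_v),
        wbc=np.asarray(wbc_v),
        hct=np.asarray(hct_v),
        dose=np.asarray(dose_v),
        total_reward=total,
    )


def rollout_with_policy(env: DoseTitrationEnv, policy,
                        reward_cfg: RewardConfig = STRICT,
                        patient_id: int | None = None) -> EpisodeLog:
    """Roll any :class:`~pvdose.protocols.Policy` through a full episode."""
    policy.reset()
    return _run_episode_logged(
        env, lambda s, obs, menu: policy.decide(s, obs), reward_cfg, patient_id
    )


def greedy_policy_rollout(
    qtable: QTable,
    patient: VirtualPatient | None = None,
    *,
    env: DoseTitrationEnv | None = None,
    reward_cfg: RewardConfig = STRICT,
) -> EpisodeLog:
    """Deterministic (epsilon = 0) rollout of a trained table on a twin."""
    if env is None:
        if patient is None:
            raise ValueError("provide a patient or an environment")
        env = DoseTitrationEnv(patient.params)
    pid = patient.id if patient is not None else None
    return _run_episode_logged(
        env, lambda s, obs, menu: qtable.greedy_action(s, menu), reward_cfg, pid
    )


# ------------------------------------------------------------------ training
def _train_episodes(
    qtable: QTable,
    caches: list[_CycleCache],
    order: np.ndarray,
    epsilons: np.ndarray,
    config: TrainingConfig,
    rng: np.random.Generator,
) -> None:
    """Shared training loop: one cached episode per entry of ``order``."""
    alpha, gamma = config.alpha, config.gamma
    reward_cfg = config.reward
    for episode, cache_i in enumerate(order):
        cache = caches[cache_i]
        eps = float(epsilons[episode])
        state = cache.episode_start()
        prefix: tuple[int, ...] = ()
        env = cache.env
        while True:
            menu = env.legal_actions(state)
            action = select_action(qtable, state, eps, rng, menu)
            next_state, outcome, done = cache.step(prefix, action)
            r = cycle_reward(outcome, reward_cfg)
            if done and reward_cfg.terminal_chr_bonus:
                if (
                    150 <= outcome.plt_obs <= 400
                    and 4 <= outcome.wbc_obs <= 10
                    and outcome.hct_obs < 45
                ):
                    r += reward_cfg.terminal_chr_bonus
            next_menu = None if done else env.legal_actions(next_state)
            qtable.update(state, action, r, None if done else next_state, done,
                          alpha, gamma, next_menu)
            if done:
                break
            prefix += (action,)
            state = next_state


def train_individual_agent(
    patient: VirtualPatient,
    config: TrainingConfig = TrainingConfig(),
    *,
    env: DoseTitrationEnv | None = None,
    return_rollout: bool = True,
):
    """Train a personal agent on the patient's own digital twin.

    Uses the strict reward by default (hard zero on severe end-of-cycle
    toxicity).  Returns ``(qtable, greedy EpisodeLog)`` -- the rollout is
    the personalised dosing policy evaluated on the same twin it was
    trained on -- or just the table when ``return_rollout`` is False.
    """
    if env is None:
        env = DoseTitrationEnv(patient.params)
    rng = np.random.default_rng(config.seed)
    qtable = QTable()
    cache = _CycleCache(env)
    order = np.zeros(config.episodes, dtype=int)
    epsilons = config.epsilon_schedule(config.episodes)
    _train_episodes(qtable, [cache], order, epsilons, config, rng)
    if not return_rollout:
        return qtable
    log = greedy_policy_rollout(qtable, patient, env=env, reward_cfg=config.reward)
    return qtable, log


def train_population_agent(
    patients: list[VirtualPatient],
    config: TrainingConfig = TrainingConfig(reward=SMOOTHED),
    *,
    envs: list[DoseTitrationEnv] | None = None,
) -> QTable:
    """Train one shared agent across a population (smoothed reward).

    Episodes sweep round-robin through the patients (``config.sweeps``
    passes), pooling every patient's rewards into a single table.
    """
    if not patients:
        raise ValueError("population must be non-empty")
    if envs is None:
        envs = [DoseTitrationEnv(p.params) for p in patients]
    rng = np.random.default_rng(config.seed)
    qtable = QTable()
    caches = [_CycleCache(env) for env in envs]
    order = np.tile(np.arange(len(patients)), config.sweeps)
    epsilons = config.epsilon_schedule(len(order))
    _train_episodes(qtable, caches, order, epsilons, config, rng)
    return qtable


class GreedyQPolicy:
    """Policy-interface adapter around a trained table."""

    def __init__(self, qtable: QTable):
        self.qtable = qtable

    def reset(self) -> None:
        pass

    def decide(self, state: ClinicalState, observations) -> int:
        return self.qtable.greedy_action(state)
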