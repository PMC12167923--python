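"""YAML configuration for the command-line workflows.

Sections (all optional; missing keys fall back to package defaults):

population:
  n_patients: 98
  seed: 1
  iiv_sd: {plt_slope: 0.25, ...}      # override individual IIV sds
  typicals: {plt_slope: 0.5, ...}     # override typical values
twin:
  substeps_per_day: 3
  horizon_days: 224
reward:
  variant: strict          # or smoothed
  terminal_chr_bonus: 0.0
training:
  alpha: 0.1
  gamma: 0.3
  epsilon_init: 1.0
  epsilon_floor: 0.02
  episodes: 10000
  sweeps: 200
  seed: 1
evaluation:
  n_test_sets: 10
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .population import DEFAULT_IIV_SD, DEFAULT_TYPICALS, PopulationSpec
from .reward import RewardConfig
from .qlearning import TrainingConfig


@dataclass
class RunConfig:
    population: PopulationSpec
    training: TrainingConfig
    reward: RewardConfig
    horizon_days: int = 224
    substeps_per_day: int = 3
    n_test_sets: int = 10
    raw: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.raw, sort_keys=True).encode()).hexdigest()[:12]


def load_config(path: str | None = None) -> RunConfig:
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}

    pop_raw = dict(raw.get("population", {}))
    typicals = dict(DEFAULT_TYPICALS)
    typicals.update(pop_raw.pop("typicals", {}))
    iiv = dict(DEFAULT_IIV_SD)
    iiv.update(pop_raw.pop("iiv_sd", {}))
    population = PopulationSpec(
        n_patients=int(pop_raw.get("n_patients", 98)),
        seed=int(pop_raw.get("seed", 0)),
        typicals=typicals,
        iiv_sd=iiv,
    )

    reward_raw = dict(raw.get("reward", {}))
    reward = RewardConfig(
        variant=reward_raw.get("variant", "strict"),
        terminal_chr_bonus=float(reward_raw.get("terminal_chr_bonus", 0.0)),
    )

    train_raw = dict(raw.get("training", {}))
    base = TrainingConfig()  # package defaults back any missing keys
    training = TrainingConfig(
        alpha=float(train_raw.get("alpha", base.alpha)),
        gamma=float(train_raw.get("gamma", base.gamma)),
        epsilon_init=float(train_raw.get("epsilon_init", base.epsilon_init)),
        epsilon_floor=float(train_raw.get("epsilon_floor", base.epsilon_floor)),
        episodes=int(train_raw.get("episodes", base.episodes)),
        sweeps=int(train_raw.get("sweeps", base.sweeps)),
        seed=int(train_raw.get("seed", base.seed)),
        reward=reward,
    )

    twin_raw = dict(raw.get("twin", {}))
    eval_raw = dict(raw.get("evaluation", {}))
    return RunConfig(
        population=population,
        training=training,
        reward=reward,
        horizon_days=int(twin_raw.get("horizon_days", 224)),
        substeps_per_day=int(twin_raw.get("substeps_per_day", 3)),
        n_test_sets=int(eval_raw.get("n_test_sets", 10)),
        raw=raw,
    )
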