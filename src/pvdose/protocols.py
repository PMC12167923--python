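"""Deterministic benchmark dosing policies.

The reference policy is the phase-III-style clinical titration protocol:
start at 100 mg/day (after the baseline phlebotomy check), then at the end
of every 28-day cycle confirm the dose when all three endpoints are in
range, step +25 mg on inefficacy, step -25 mg on moderate toxicity
(interrupting instead when already at the 50 mg floor), and interrupt for
14 days on severe toxicity.  After a moderate-toxicity interruption
treatment resumes at 50 mg once PLT and WBC are back in the efficacy
range; after a severe-toxicity interruption it resumes one level below the
triggering dose (floored at 50 mg) once both lineages have recovered above
the severe threshold.  The resumption-dose branch is a reconstruction of
the protocol's unprinted flow-chart internals, kept consistent with the
safety mask of the MDP so every emitted dose is a legal action.

Trivial baselines (fixed dose, uniform-random legal) share the same policy
interface, as do the greedy Q-table policies, which is what allows the
comparison harness to treat all strategies uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mdp import ClinicalState, DoseTitrationEnv, discretize_observation

START_DOSE = 100
DOSE_STEP = 25
MIN_DOSE, MAX_DOSE = 50, 200


@dataclass
class ProtocolMemory:
    """What the clinical protocol remembers between cycles."""

    last_dose: int | None = None
    interrupted: bool = False
    trigger_dose: int | None = None
    severe_trigger: bool = False

    def __post_init__(self) -> None:
        if self.interrupted != (self.trigger_dose is not None):
            raise ValueError("trigger dose must be recorded iff interrupted")


class Policy:
    """Interface shared by all dosing strategies."""

    def reset(self) -> None:  # pragma: no cover - trivial default
        pass

    def decide(self, state: ClinicalState, observations: tuple[float, float, float]) -> int:
        raise NotImplementedError


class ClinicalProtocol(Policy):
    """The rule-based givinostat titration protocol."""

    def __init__(self) -> None:
        self.memory = ProtocolMemory()

    def reset(self) -> None:
        self.memory = ProtocolMemory()

    def decide(self, state: ClinicalState, observations: tuple[float, float, float]) -> int:
        plt_cat, wbc_cat, hct_cat = discretize_observation(*observations)
        mem = self.memory

        if mem.last_dose is None and not mem.interrupted:  # treatment start
            mem.last_dose = START_DOSE
            return START_DOSE

        if mem.interrupted:
            if mem.severe_trigger:
                if plt_cat >= 2 and wbc_cat >= 2:  # both above the severe threshold
                    dose = max(mem.trigger_dose - DOSE_STEP, MIN_DOSE)
                    mem.interrupted = False
                    mem.trigger_dose = None
                    mem.severe_trigger = False
                    mem.last_dose = dose
                    return dose
                return 0
            if plt_cat == 3 and wbc_cat == 3:  # recovered from moderate toxicity
                mem.interrupted = False
                mem.trigger_dose = None
                mem.last_dose = MIN_DOSE
                return MIN_DOSE
            return 0

        if plt_cat == 1 or wbc_cat == 1:  # severe toxicity -> 14-day interruption
            mem.interrupted = True
            mem.severe_trigger = True
            mem.trigger_dose = mem.last_dose
            return 0
        if plt_cat == 2 or wbc_cat == 2:  # moderate toxicity
            if mem.last_dose == MIN_DOSE:
                mem.interrupted = True
                mem.severe_trigger = False
                mem.trigger_dose = mem.last_dose
                return 0
            mem.last_dose -= DOSE_STEP
            return mem.last_dose
        if plt_cat == 3 and wbc_cat == 3 and hct_cat == 1:  # efficacy -> confirm
            return mem.last_dose
        # inefficacy (any endpoint above range, incl. HCT >= 45 alone) -> +25
        mem.last_dose = min(mem.last_dose + DOSE_STEP, MAX_DOSE)
        return mem.last_dose


class FixedDosePolicy(Policy):
    """Administer a constant dose except where the safety mask forbids it.

    When the fixed dose is not legal (interruptions, resumption menus, or
    step constraints), the closest legal action is chosen, preferring the
    highest legal dose not exceeding the target.
    """

    def __init__(self, dose: int = START_DOSE):
        from .mdp import DOSE_LEVELS

        if dose not in DOSE_LEVELS:
            raise ValueError(f"dose {dose} not on the grid {DOSE_LEVELS}")
        self.dose = dose

    def decide(self, state: ClinicalState, observations) -> int:
        from .mdp import legal_actions

        menu = legal_actions(state)
        if self.dose in menu:
            return self.dose
        below = [d for d in menu if 0 < d <= self.dose]
        if below:
            return max(below)
        positive = [d for d in menu if d > 0]
        return min(positive) if positive else 0


class RandomLegalPolicy(Policy):
    """Uniform choice over the legal action menu (exploration baseline)."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng

    def decide(self, state: ClinicalState, observations) -> int:
        from .mdp import legal_actions

        menu = legal_actions(state)
        return int(menu[self.rng.integers(len(menu))])


def run_policy(env: DoseTitrationEnv, policy: Policy):
    """Roll a policy through one full episode.

    Returns an :class:`~pvdose.qlearning.EpisodeLog`; the import lives here
    to keep the module dependency one-way.
    """
    from .qlearning import rollout_with_policy

    return rollout_with_policy(env, policy)
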