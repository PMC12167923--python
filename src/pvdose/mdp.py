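"""The givinostat dosing Markov decision process.

State
-----
A clinical state is the 4-tuple ``(plt_cat, wbc_cat, hct_cat, prev_dose)``:

* ``plt_cat``: 1 severe thrombocytopenia (<75), 2 moderate ([75,150)),
  3 efficacy ([150,400]), 4 inefficacy (>400), in 10^9/L;
* ``wbc_cat``: 1 severe neutropenia (<3), 2 moderate ([3,4)), 3 efficacy
  ([4,10]), 4 inefficacy (>10), in 10^9/L;
* ``hct_cat``: 1 efficacy (<45%), 2 inefficacy (>=45%);
* ``prev_dose``: the last administered dose with a sign code -- positive
  while on treatment, negative while interrupted for severe toxicity
  (magnitude = triggering dose), 0 while interrupted for moderate toxicity
  (which can only be triggered at 50 mg/day), and -1 only at treatment
  start.

Boundary convention: severe bins are open above (value < threshold),
efficacy bins are closed on both ends, inefficacy is strictly above; a
boundary value therefore lands in the better category.

Enumerating the 32 category combinations with the 15 non-initial
``prev_dose`` codes gives 480 states; adding the 8 initial tuples with
``plt_cat >= 3`` and ``wbc_cat >= 3`` and discarding the all-normal
``(3, 3, 1, -1)`` (impossible at a PV baseline) yields 487 states in
total.

Actions
-------
An action is the daily dose for the next treatment cycle (28 days; 14 days
while interrupted), constrained by the safety mask of the clinical
protocol: stepwise +-25 mg changes outside toxicity, forced interruption
on severe toxicity (and on moderate toxicity at the lowest dose), and
restricted resumption menus after an interruption.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .twin import DigitalTwin, PatientParameters

#: Non-zero dose levels (mg/day).
DOSE_LEVELS = (50, 75, 100, 125, 150, 175, 200)
#: All actions, ordered ascending; index in this tuple is the action index.
ACTIONS = (0,) + DOSE_LEVELS
#: prev_dose codes excluding the initial-state flag -1.
PREV_DOSE_CODES = tuple(-d for d in reversed(DOSE_LEVELS)) + (0,) + DOSE_LEVELS

INITIAL_PREV_DOSE = -1
HORIZON_DAYS = 224  # 8 cycles x 28 days ("8 months")
CYCLE_DAYS = 28
INTERRUPTION_DAYS = 14


@dataclass(frozen=True)
class ClinicalState:
    plt_cat: int
    wbc_cat: int
    hct_cat: int
    prev_dose: int

    def __post_init__(self) -> None:
        if self.plt_cat not in (1, 2, 3, 4) or self.wbc_cat not in (1, 2, 3, 4):
            raise ValueError(f"invalid PLT/WBC category in {self}")
        if self.hct_cat not in (1, 2):
            raise ValueError(f"invalid HCT category in {self}")
        if self.prev_dose == INITIAL_PREV_DOSE:
            if self.plt_cat < 3 or self.wbc_cat < 3:
                raise ValueError(f"initial state must have plt_cat>=3 and wbc_cat>=3: {self}")
            if (self.plt_cat, self.wbc_cat, self.hct_cat) == (3, 3, 1):
                raise ValueError("the all-normal initial tuple (3,3,1,-1) is not a PV state")
        elif self.prev_dose not in PREV_DOSE_CODES:
            raise ValueError(f"invalid prev_dose code {self.prev_dose}")

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.plt_cat, self.wbc_cat, self.hct_cat, self.prev_dose)


def discretize_observation(plt: float, wbc: float, hct: float) -> tuple[int, int, int]:
    """Map raw (PLT, WBC, HCT) observations to the category triple."""
    for name, v in (("plt", plt), ("wbc", wbc), ("hct", hct)):
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{name} observation must be finite and non-negative, got {v}")
    if plt < 75:
        plt_cat = 1
    elif plt < 150:
        plt_cat = 2
    elif plt <= 400:
        plt_cat = 3
    else:
        plt_cat = 4
    if wbc < 3:
        wbc_cat = 1
    elif wbc < 4:
        wbc_cat = 2
    elif wbc <= 10:
        wbc_cat = 3
    else:
        wbc_cat = 4
    hct_cat = 1 if hct < 45 else 2
    return plt_cat, wbc_cat, hct_cat


def _enumerate_states() -> tuple[ClinicalState, ...]:
    states = []
    for plt_cat in (1, 2, 3, 4):
        for wbc_cat in (1, 2, 3, 4):
            for hct_cat in (1, 2):
                for prev in PREV_DOSE_CODES:
                    states.append(ClinicalState(plt_cat, wbc_cat, hct_cat, prev))
    for plt_cat in (3, 4):
        for wbc_cat in (3, 4):
            for hct_cat in (1, 2):
                if (plt_cat, wbc_cat, hct_cat) == (3, 3, 1):
                    continue
                states.append(ClinicalState(plt_cat, wbc_cat, hct_cat, INITIAL_PREV_DOSE))
    return tuple(states)


ALL_STATES: tuple[ClinicalState, ...] = _enumerate_states()
N_STATES = len(ALL_STATES)  # 487
_STATE_TO_INDEX = {s.as_tuple(): i for i, s in enumerate(ALL_STATES)}


def state_index(state: ClinicalState) -> int:
    """Bijective index in [0, 486] of a valid clinical state."""
    try:
        return _STATE_TO_INDEX[state.as_tuple()]
    except KeyError:  # pragma: no cover - ClinicalState validation already rejects
        raise ValueError(f"invalid state {state}")


def state_from_index(index: int) -> ClinicalState:
    """Inverse of :func:`state_index`."""
    if not 0 <= index < N_STATES:
        raise ValueError(f"state index {index} out of range [0, {N_STATES - 1}]")
    return ALL_STATES[index]


def _step_menu(dose: int) -> tuple[int, ...]:
    """Stay/+-25 menu around a positive dose, clipped at the grid edges."""
    i = DOSE_LEVELS.index(dose)
    lo = max(i - 1, 0)
    hi = min(i + 1, len(DOSE_LEVELS) - 1)
    return tuple(DOSE_LEVELS[lo : hi + 1])


def legal_actions(state: ClinicalState) -> tuple[int, ...]:
    """Admissible next-cycle doses for a state (ascending, never empty).

    Encodes the clinical-protocol safety mask: any severe toxicity forces a
    14-day interruption (dose 0); moderate toxicity at 50 mg forces an
    interruption, at higher doses allows stay/+-25; toxicity-free states
    allow stay/+-25 (edge-clipped); after a moderate-toxicity interruption
    the menu is {0, 50} once both PLT and WBC are back in the efficacy
    range; after a severe-toxicity interruption it is {0, 50, ...,
    |triggering dose|} once both are above the severe threshold.  States
    not meeting their resumption condition remain forced to 0.
    """
    plt_cat, wbc_cat, prev = state.plt_cat, state.wbc_cat, state.prev_dose
    if prev == INITIAL_PREV_DOSE:
        return DOSE_LEVELS
    if plt_cat == 1 or wbc_cat == 1:  # severe toxicity, any prev_dose
        return (0,)
    if prev == 0:  # interrupted for moderate toxicity (trigger was 50 mg)
        if plt_cat == 3 and wbc_cat == 3:
            return (0, 50)
        return (0,)
    if prev < 0:  # interrupted for severe toxicity
        # both lineages recovered above the severe threshold -> resumption
        # menu up to the triggering dose (full recovery also qualifies)
        return (0,) + tuple(d for d in DOSE_LEVELS if d <= -prev)
    # on treatment (prev > 0)
    if plt_cat == 2 or wbc_cat == 2:  # moderate toxicity
        if prev == 50:
            return (0,)
        menu = _step_menu(prev)
        return menu
    return _step_menu(prev)


#: Legality mask over (state index, action index); used by the Q-table.
LEGAL_MASK = np.zeros((N_STATES, len(ACTIONS)), dtype=bool)
for _i, _s in enumerate(ALL_STATES):
    for _a in legal_actions(_s):
        LEGAL_MASK[_i, ACTIONS.index(_a)] = True


@dataclass
class CycleOutcome:
    """Everything observed over one treatment cycle.

    ``daily`` holds the (PLT, WBC, HCT) values at the end of each of the
    cycle's days; observations and the difference-quotient derivatives
    ``y' = y(t_end) - y(t_end - 1)`` are taken from the last two daily
    values; in-range day counts use the target ranges PLT in [150,400],
    WBC in [4,10], HCT < 45.
    """

    dose: int
    cycle_length: int
    daily: np.ndarray  # shape (cycle_length, 3)
    plt_obs: float
    wbc_obs: float
    hct_obs: float
    plt_deriv: float
    wbc_deriv: float
    hct_deriv: float
    plt_in_range: int
    wbc_in_range: int
    hct_in_range: int

    @property
    def observations(self) -> tuple[float, float, float]:
        return (self.plt_obs, self.wbc_obs, self.hct_obs)


def _in_range_counts(daily: np.ndarray) -> tuple[int, int, int]:
    plt_n = int(np.sum((daily[:, 0] >= 150) & (daily[:, 0] <= 400)))
    wbc_n = int(np.sum((daily[:, 1] >= 4) & (daily[:, 1] <= 10)))
    hct_n = int(np.sum(daily[:, 2] < 45))
    return plt_n, wbc_n, hct_n


class DoseTitrationEnv:
    """One patient's treatment episode as an MDP environment.

    Wraps a :class:`~pvdose.twin.DigitalTwin` and exposes cycle-level
    ``reset`` / ``step`` semantics.  The episode clock starts at day 0
    (baseline, after the optional phlebotomy) and ends exactly at
    ``horizon_days``; a final cycle that would overrun is truncated.

    ``allowed_doses`` optionally restricts the positive dose menu (used by
    small exhaustive-search test problems); dose 0 stays available where
    the safety mask forces or offers it.
    """

    def __init__(
        self,
        patient: PatientParameters,
        horizon_days: int = HORIZON_DAYS,
        *,
        phlebotomy: bool = True,
        substeps_per_day: int = 3,
        allowed_doses: tuple[int, ...] | None = None,
    ):
        if horizon_days < INTERRUPTION_DAYS or horizon_days % INTERRUPTION_DAYS:
            raise ValueError("horizon_days must be a positive multiple of 14")
        self.twin = DigitalTwin(patient, substeps_per_day=substeps_per_day)
        self.horizon_days = int(horizon_days)
        self.phlebotomy = bool(phlebotomy)
        if allowed_doses is not None:
            allowed = tuple(sorted(set(allowed_doses)))
            if any(d not in DOSE_LEVELS for d in allowed) or not allowed:
                raise ValueError(f"allowed_doses must be a non-empty subset of {DOSE_LEVELS}")
            self.allowed_doses = allowed
        else:
            self.allowed_doses = DOSE_LEVELS
        self._state: ClinicalState | None = None
        self._internal = None
        self.day = 0

    # ------------------------------------------------------------------ api
    def reset(self) -> ClinicalState:
        # The initial clinical state reflects the *pre-phlebotomy* baseline
        # measurements (a patient whose only abnormality is HCT >= 45 is
        # still a valid PV presentation); the phlebotomy then normalises
        # the internal state before day 0 of the simulation.
        raw = self.twin.baseline_state(phlebotomy=False)
        cats = discretize_observation(*self.twin.observe(raw))
        if cats == (3, 3, 1):
            raise ValueError(
                "patient baseline is fully normal; not a valid PV initial state"
            )
        self._internal = self.twin.baseline_state(phlebotomy=self.phlebotomy)
        self.day = 0
        self._baseline_obs = self.twin.observe(self._internal)
        self._state = ClinicalState(*cats, INITIAL_PREV_DOSE)
        return self._state

    @property
    def state(self) -> ClinicalState:
        if self._state is None:
            raise RuntimeError("environment not reset")
        return self._state

    @property
    def done(self) -> bool:
        return self.day >= self.horizon_days

    def current_observations(self) -> tuple[float, float, float]:
        return self.twin.observe(self._internal)

    def legal_actions(self, state: ClinicalState | None = None) -> tuple[int, ...]:
        """Legal actions, intersected with any ``allowed_doses`` restriction."""
        s = self.state if state is None else state
        menu = legal_actions(s)
        if self.allowed_doses is DOSE_LEVELS:
            return menu
        kept = tuple(d for d in menu if d == 0 or d in self.allowed_doses)
        return kept if kept else (menu[0],)

    def step(self, action: int) -> tuple[ClinicalState, CycleOutcome, bool]:
        """Advance one treatment cycle at the chosen dose."""
        if self._state is None:
            raise RuntimeError("environment not reset")
        if self.done:
            raise RuntimeError("episode already at the horizon")
        state = self._state
        if action not in self.legal_actions(state):
            raise ValueError(f"action {action} illegal in state {state.as_tuple()}")

        nominal = INTERRUPTION_DAYS if action == 0 else CYCLE_DAYS
        cycle_len = min(nominal, self.horizon_days - self.day)
        prev_obs = self.twin.observe(self._internal)
        self._internal, daily = self.twin.step_days(self._internal, action, cycle_len)
        daily = np.asarray(daily)

        plt_obs, wbc_obs, hct_obs = daily[-1]
        if cycle_len >= 2:
            deriv = daily[-1] - daily[-2]
        else:
            deriv = daily[-1] - np.asarray(prev_obs)
        counts = _in_range_counts(daily)
        outcome = CycleOutcome(
            dose=int(action),
            cycle_length=int(cycle_len),
            daily=daily,
            plt_obs=float(plt_obs),
            wbc_obs=float(wbc_obs),
            hct_obs=float(hct_obs),
            plt_deriv=float(deriv[0]),
            wbc_deriv=float(deriv[1]),
            hct_deriv=float(deriv[2]),
            plt_in_range=counts[0],
            wbc_in_range=counts[1],
            hct_in_range=counts[2],
        )

        next_prev = self._next_prev_dose(state, int(action))
        cats = discretize_observation(float(plt_obs), float(wbc_obs), float(hct_obs))
        self.day += cycle_len
        self._state = ClinicalState(*cats, next_prev)
        return self._state, outcome, self.done

    # ----------------------------------------------------------------- rules
    @staticmethod
    def _next_prev_dose(state: ClinicalState, action: int) -> int:
        """prev_dose bookkeeping: sign codes interruption cause and trigger."""
        if action > 0:
            return action
        prev = state.prev_dose
        if state.plt_cat == 1 or state.wbc_cat == 1:
            # severe-toxicity interruption: record the triggering dose
            if prev > 0:
                return -prev
            if prev < 0 and prev != INITIAL_PREV_DOSE:
                return prev  # still interrupted, keep the trigger
            # severe toxicity emerging during a moderate interruption: the
            # moderate trigger can only have been 50 mg/day
            return -50
        if prev > 0:
            # moderate-toxicity interruption (only forced at 50 mg/day)
            return 0
        # dose 0 chosen at a resumption decision: stay interrupted, keep code
        return prev


def random_rollout(
    env: DoseTitrationEnv, rng: np.random.Generator, n_episodes: int = 1
) -> list[int]:
    """Uniform-random legal rollouts; returns every visited state index."""
    visited = []
    for _ in range(n_episodes):
        state = env.reset()
        visited.append(state_index(state))
        while not env.done:
            menu = env.legal_actions()
            action = menu[rng.integers(len(menu))]
            state, _, _ = env.step(action)
            visited.append(state_index(state))
    return visited
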