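"""Deterministic hematopoiesis digital twin.

A virtual polycythemia-vera patient is represented by a small mechanistic
PK-PD system that maps a daily oral dosing schedule onto daily platelet
(PLT, 10^9/L), white-blood-cell (WBC, 10^9/L) and haematocrit (HCT, %)
values over the treatment horizon:

* **PK** -- one-compartment disposition with first-order absorption.  Each
  treatment day deposits the daily dose as a bolus into the absorption
  depot; the plasma concentration ``C(t) = A_central / V`` equilibrates
  with a biophase (effect) compartment ``dCe/dt = ke0 * (C - Ce)`` whose
  concentration drives all three pharmacodynamic blocks.  The slow
  biophase (ke0 ~ 0.1/day) makes the myelosuppressive effect build over
  one to two weeks, so the marrow feedback keeps pace and the transient
  nadir stays close to the eventual steady state -- end-of-cycle
  monitoring is then an honest surrogate for the whole cycle.
* **PLT / WBC** -- Friberg-type transit-chain myelosuppression: a
  proliferative pool, three transit compartments and the circulating pool,
  all sharing the rate constant ``ktr = 4 / MTT``.  Drug linearly inhibits
  proliferation (``E = slope * C``, clipped at 1) and the feedback term
  ``(baseline / circulating)^gamma`` produces the rebound overshoot typical
  of marrow recovery.
* **HCT** -- indirect-response turnover ``dH/dt = kin * (1 - E) - kout * H``
  with ``kin = kout * baseline``, i.e. drug inhibits red-cell production.

The drug-free system is exactly at steady state when every compartment sits
at its baseline, so an untreated twin stays flat -- a property the test
suite relies on.  No residual unexplained variability is simulated: a
patient's response is fully determined by their parameters, which is what
makes the twin usable as the environment of a deterministic Markov decision
process.

Integration uses a fixed daily grid (matching the daily in-range
bookkeeping of the reward) with classical 4th-order Runge-Kutta substeps
inside each day.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Clinically available daily doses (mg/day); 0 codes an interruption/hold.
DOSE_GRID = (0, 50, 75, 100, 125, 150, 175, 200)

#: Baseline HCT at or above this (%) triggers a preliminary phlebotomy.
PHLEBOTOMY_THRESHOLD = 45.0
#: HCT (%) restored by the day-0 phlebotomy.
PHLEBOTOMY_TARGET = 43.0

_CYCLE_LENGTHS = (14, 28)


def _require_positive(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be a strictly positive finite number, got {value!r}")


@dataclass(frozen=True)
class LineagePD:
    """Friberg-chain block for one cell lineage (PLT or WBC).

    baseline : circulating level at drug-free equilibrium (10^9/L)
    mtt      : mean transit time through the maturation chain (day)
    gamma    : rebound feedback exponent (dimensionless)
    slope    : linear drug-effect coefficient on proliferation (1/(mg/L))
    """

    baseline: float
    mtt: float
    gamma: float
    slope: float

    def __post_init__(self) -> None:
        for name in ("baseline", "mtt", "gamma", "slope"):
            _require_positive(name, getattr(self, name))


@dataclass(frozen=True)
class HctPD:
    """Indirect-response block for haematocrit.

    baseline : HCT at drug-free equilibrium (%)
    kout     : first-order turnover rate (1/day)
    slope    : linear drug-effect coefficient on production (1/(mg/L))
    """

    baseline: float
    kout: float
    slope: float

    def __post_init__(self) -> None:
        for name in ("baseline", "kout", "slope"):
            _require_positive(name, getattr(self, name))


@dataclass(frozen=True)
class PatientParameters:
    """Full parameter set of one virtual patient.

    ka : first-order absorption rate (1/day)
    cl : apparent clearance (L/day)
    v  : apparent volume of distribution (L)
    ke0 : biophase equilibration rate (1/day); small values delay the
        onset of myelosuppression relative to plasma exposure
    plt, wbc : per-lineage myelosuppression blocks
    hct : haematocrit turnover block
    """

    ka: float
    cl: float
    v: float
    plt: LineagePD
    wbc: LineagePD
    hct: HctPD
    ke0: float = 0.1

    def __post_init__(self) -> None:
        for name in ("ka", "cl", "v", "ke0"):
            _require_positive(name, getattr(self, name))
        if not 50.0 <= self.plt.baseline <= 1500.0:
            raise ValueError(f"PLT baseline {self.plt.baseline} outside physiologic [50, 1500]")
        if not 1.0 <= self.wbc.baseline <= 50.0:
            raise ValueError(f"WBC baseline {self.wbc.baseline} outside physiologic [1, 50]")
        if not 20.0 <= self.hct.baseline <= 70.0:
            raise ValueError(f"HCT baseline {self.hct.baseline} outside physiologic [20, 70]")


@dataclass(frozen=True)
class ScheduleSegment:
    start_day: int
    length_days: int
    daily_dose: int


@dataclass(frozen=True)
class DosingSchedule:
    """Ordered, contiguous dosing segments on the clinical dose grid.

    Days not covered by any segment (after the last one) are drug-free;
    gaps *between* segments are rejected -- an explicit 0 mg/day segment
    must be used for planned interruptions.
    """

    segments: tuple[ScheduleSegment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule must contain at least one segment")
        prev_end = None
        for seg in self.segments:
            if seg.start_day < 0:
                raise ValueError("segment start_day must be >= 0")
            if seg.length_days not in _CYCLE_LENGTHS:
                raise ValueError(f"segment length must be in {_CYCLE_LENGTHS}, got {seg.length_days}")
            if seg.daily_dose not in DOSE_GRID:
                raise ValueError(f"dose {seg.daily_dose} not on the allowed grid {DOSE_GRID}")
            if prev_end is not None and seg.start_day != prev_end:
                raise ValueError("segments must be contiguous and non-overlapping")
            prev_end = seg.start_day + seg.length_days
        if self.segments[0].start_day != 0:
            raise ValueError("first segment must start at day 0")

    @property
    def end_day(self) -> int:
        last = self.segments[-1]
        return last.start_day + last.length_days

    @classmethod
    def constant(cls, dose: int, n_days: int) -> "DosingSchedule":
        """Constant-dose schedule built from 28-day blocks (+ a 14-day tail)."""
        if n_days % 14 != 0 or n_days <= 0:
            raise ValueError("constant schedule length must be a positive multiple of 14")
        segments, day = [], 0
        while n_days - day >= 28:
            segments.append(ScheduleSegment(day, 28, dose))
            day += 28
        if n_days - day == 14:
            segments.append(ScheduleSegment(day, 14, dose))
        return cls(tuple(segments))

    def dose_by_day(self, horizon_days: int) -> np.ndarray:
        """Daily dose vector for days 0 .. horizon-1 (0 after the last segment)."""
        if self.end_day > horizon_days:
            raise ValueError("schedule extends beyond the horizon")
        doses = np.zeros(horizon_days, dtype=float)
        for seg in self.segments:
            doses[seg.start_day : seg.start_day + seg.length_days] = seg.daily_dose
        return doses


@dataclass
class HematologyTrajectory:
    """Daily PLT/WBC/HCT values over days 0..H; day 0 is the (post-phlebotomy) baseline."""

    day: np.ndarray
    plt: np.ndarray
    wbc: np.ndarray
    hct: np.ndarray
    dose: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.day)
        for name in ("plt", "wbc", "hct", "dose"):
            if len(getattr(self, name)) != n:
                raise ValueError("trajectory columns must have equal length")

    @property
    def horizon(self) -> int:
        return int(self.day[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"day": self.day, "dose_mg": self.dose, "plt": self.plt, "wbc": self.wbc, "hct": self.hct}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# Internal continuous state layout (14 floats):
#   0 depot, 1 central,
#   2-6  PLT prol, t1, t2, t3, circ,
#   7-11 WBC prol, t1, t2, t3, circ,
#   12 HCT, 13 biophase concentration.
_STATE_SIZE = 14


def apply_phlebotomy(state: tuple, target_hct: float = PHLEBOTOMY_TARGET) -> tuple:
    """Instantaneous day-0 phlebotomy: reset HCT to ``target_hct``.

    Applied only when the current HCT is at or above the 45% threshold;
    otherwise a no-op with a warning.  PLT and WBC are untouched.
    """
    state = tuple(state)
    if state[12] < PHLEBOTOMY_THRESHOLD:
        warnings.warn(
            "phlebotomy requested with HCT < 45%; no-op", RuntimeWarning, stacklevel=2
        )
        return state
    return state[:12] + (float(target_hct),) + state[13:]


class DigitalTwin:
    """Deterministic simulator for one patient's haematological response.

    Parameters
    ----------
    params : PatientParameters
        The patient's digital-twin parameter set.
    substeps_per_day : int
        Runge-Kutta substeps inside each daily step.  The default (3) keeps
        the fastest rate constants (ka ~ 2/day, CL/V ~ 3/day) well inside
        the RK4 stability region while keeping training loops cheap.
    """

    def __init__(self, params: PatientParameters, substeps_per_day: int = 3):
        if substeps_per_day < 1:
            raise ValueError("substeps_per_day must be >= 1")
        self.params = params
        self.substeps_per_day = int(substeps_per_day)

    # ------------------------------------------------------------------ state
    def baseline_state(self, phlebotomy: bool = True) -> tuple:
        """Drug-free equilibrium state (the fixed point of the system).

        With ``phlebotomy`` (the clinical default), a baseline HCT >= 45%
        is reset to the 43% target before treatment starts.
        """
        p, w, h = self.params.plt, self.params.wbc, self.params.hct
        state = (0.0, 0.0) + (p.baseline,) * 5 + (w.baseline,) * 5 + (h.baseline, 0.0)
        if phlebotomy and h.baseline >= PHLEBOTOMY_THRESHOLD:
            state = apply_phlebotomy(state)
        return state

    @staticmethod
    def observe(state: tuple) -> tuple[float, float, float]:
        """(PLT, WBC, HCT) read-out of an internal state."""
        return (state[6], state[11], state[12])

    # ------------------------------------------------------------- integration
    def step_days(self, state: tuple, dose: float, n_days: int):
        """Advance ``n_days`` at a constant daily dose.

        The dose is deposited as a bolus into the absorption depot at the
        start of each day.  Returns ``(final_state, daily)`` where ``daily``
        is a list of (PLT, WBC, HCT) tuples observed at the *end* of each
        simulated day.

        This is the hot path of agent training, so it is written with plain
        floats and local variables rather than array operations.
        """
        if dose not in DOSE_GRID:
            raise ValueError(f"dose {dose} not on the allowed grid {DOSE_GRID}")
        if n_days < 0:
            raise ValueError("n_days must be >= 0")
        prm = self.params
        ka = prm.ka
        kel = prm.cl / prm.v
        inv_v = 1.0 / prm.v
        pb, pg, ps = prm.plt.baseline, prm.plt.gamma, prm.plt.slope
        wb, wg, ws = prm.wbc.baseline, prm.wbc.gamma, prm.wbc.slope
        ktp = 4.0 / prm.plt.mtt
        ktw = 4.0 / prm.wbc.mtt
        hk, hb, hs = prm.hct.kout, prm.hct.baseline, prm.hct.slope
        hkin = hk * hb
        ke0 = prm.ke0

        nsub = self.substeps_per_day
        h_step = 1.0 / nsub
        dose_f = float(dose)

        def rhs(s):
            depot, central = s[0], s[1]
            p0, p1, p2, p3, p4 = s[2], s[3], s[4], s[5], s[6]
            w0, w1, w2, w3, w4 = s[7], s[8], s[9], s[10], s[11]
            hh, ce = s[12], s[13]
            conc = central * inv_v
            ep = ps * ce
            if ep > 1.0:
                ep = 1.0
            ew = ws * ce
            if ew > 1.0:
                ew = 1.0
            eh = hs * ce
            if eh > 1.0:
                eh = 1.0
            fbp = (pb / p4) ** pg if p4 > 1e-9 else (pb / 1e-9) ** pg
            fbw = (wb / w4) ** wg if w4 > 1e-9 else (wb / 1e-9) ** wg
            return (
                -ka * depot,
                ka * depot - kel * central,
                ktp * p0 * ((1.0 - ep) * fbp - 1.0),
                ktp * (p0 - p1),
                ktp * (p1 - p2),
                ktp * (p2 - p3),
                ktp * (p3 - p4),
                ktw * w0 * ((1.0 - ew) * fbw - 1.0),
                ktw * (w0 - w1),
                ktw * (w1 - w2),
                ktw * (w2 - w3),
                ktw * (w3 - w4),
                hkin * (1.0 - eh) - hk * hh,
                ke0 * (conc - ce),
            )

        s = tuple(float(x) for x in state)
        if len(s) != _STATE_SIZE:
            raise ValueError(f"internal state must have {_STATE_SIZE} components")
        daily = []
        half = 0.5 * h_step
        sixth = h_step / 6.0
        for _ in range(n_days):
            s = (s[0] + dose_f,) + s[1:]
            for _ in range(nsub):
                k1 = rhs(s)
                s2 = tuple(s[i] + half * k1[i] for i in range(14))
                k2 = rhs(s2)
                s3 = tuple(s[i] + half * k2[i] for i in range(14))
                k3 = rhs(s3)
                s4 = tuple(s[i] + h_step * k3[i] for i in range(14))
                k4 = rhs(s4)
                s = tuple(
                    s[i] + sixth * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i]) for i in range(14)
                )
            # guard against pathological parameter draws driving counts negative
            if s[6] <= 1e-9 or s[11] <= 1e-9 or s[12] <= 1e-9:
                s = tuple(x if x > 1e-9 else 1e-9 for x in s)
            daily.append((s[6], s[11], s[12]))
        return s, daily


def steady_state_baseline(params: PatientParameters) -> tuple:
    """Internal state at drug-free equilibrium (no phlebotomy applied).

    The returned state reproduces the configured baselines exactly under a
    zero-dose simulation of any length.
    """
    return DigitalTwin(params).baseline_state(phlebotomy=False)


def simulate_schedule(
    patient: PatientParameters,
    schedule: DosingSchedule,
    horizon_days: int,
    *,
    phlebotomy: bool = True,
    substeps_per_day: int = 3,
) -> HematologyTrajectory:
    """Simulate a full dosing schedule and return the daily trajectory.

    Days beyond the schedule's last segment are drug-free (dose 0), which
    makes post-treatment recovery directly observable.
    """
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    doses = schedule.dose_by_day(horizon_days)
    twin = DigitalTwin(patient, substeps_per_day=substeps_per_day)
    state = twin.baseline_state(phlebotomy=phlebotomy)
    plt0, wbc0, hct0 = twin.observe(state)
    plt_v, wbc_v, hct_v = [plt0], [wbc0], [hct0]
    day = 0
    while day < horizon_days:
        dose = doses[day]
        run = 1
        while day + run < horizon_days and doses[day + run] == dose:
            run += 1
        state, daily = twin.step_days(state, int(dose), run)
        for p, w, h in daily:
            plt_v.append(p)
            wbc_v.append(w)
            hct_v.append(h)
        day += run
    dose_col = np.concatenate([[doses[0]], doses])  # dose "administered on" each day; day 0 shows day-0 dose
    return HematologyTrajectory(
        day=np.arange(horizon_days + 1),
        plt=np.asarray(plt_v),
        wbc=np.asarray(wbc_v),
        hct=np.asarray(hct_v),
        dose=dose_col,
    )
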