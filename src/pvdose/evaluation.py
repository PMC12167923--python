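"""Treatment-outcome metrics and strategy comparison harness.

Per-patient metrics are computed at daily resolution from a full
treatment trajectory (day 0 = baseline, excluded from all day-count
denominators, so an 8-month episode has 224 scored days):

* complete hematological response (CHR) on a day means PLT in [150,400]
  x10^9/L, WBC in [4,10] x10^9/L and HCT < 45% simultaneously;
* "days until stable CHR" is the first (1-based) day from which CHR holds
  on every remaining day of the episode -- the strictest reading of a
  stable response;
* a severe-toxicity day has PLT < 75 or WBC < 3; a moderate day has
  PLT < 150 or WBC < 4 without being severe; contiguous runs of a grade
  count as one episode of that grade.

Population summaries report the median and the empirical 2.5th / 97.5th
percentiles (numpy's linear interpolation between order statistics).
Two comparison modes mirror the two evaluation frameworks:

* **panel A** -- one shared population-trained table benchmarked against
  the clinical protocol on k independent test populations, rolled up
  across sets as the median of the k medians and the 2.5th / 97.5th
  percentile of the k per-set percentiles;
* **panel B** -- per-patient agents, the population agent and the
  clinical protocol compared on a single population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mdp import DoseTitrationEnv
from .protocols import ClinicalProtocol, Policy
from .qlearning import EpisodeLog, GreedyQPolicy, QTable, rollout_with_policy
from .population import VirtualPatient
from .reward import STRICT, RewardConfig

SEVERE_PLT, SEVERE_WBC = 75.0, 3.0


@dataclass
class PatientMetrics:
    """Daily-resolution treatment outcomes for one patient."""

    patient_id: int | None
    chr_at_end: bool
    days_until_stable_chr: float  # NaN when never stably in CHR
    pct_days_plt: float
    pct_days_wbc: float
    pct_days_hct: float
    pct_days_chr: float
    any_severe: bool
    pct_days_severe: float
    n_severe_episodes: int
    n_moderate_episodes: int
    n_dose_adjustments: int
    n_interruptions: int


_PCT_FIELDS = ("pct_days_plt", "pct_days_wbc", "pct_days_hct", "pct_days_chr", "pct_days_severe")


def compute_patient_metrics(log: EpisodeLog, horizon: int = 224) -> PatientMetrics:
    """Compute all metrics from a complete episode log."""
    if log.horizon != horizon or len(log.day) != horizon + 1:
        raise ValueError(
            f"trajectory must cover days 0..{horizon}, got 0..{log.horizon} "
            f"({len(log.day)} rows)"
        )
    # day 0 is the pre-treatment baseline; score days 1..horizon
    plt, wbc, hct = log.plt[1:], log.wbc[1:], log.hct[1:]
    n = horizon

    plt_in = (plt >= 150) & (plt <= 400)
    wbc_in = (wbc >= 4) & (wbc <= 10)
    hct_in = hct < 45
    chr_day = plt_in & wbc_in & hct_in
    severe = (plt < SEVERE_PLT) | (wbc < SEVERE_WBC)
    moderate = ((plt < 150) | (wbc < 4)) & ~severe

    # first 1-based day from which CHR persists to the horizon
    if chr_day[-1]:
        d = n - 1
        while d > 0 and chr_day[d - 1]:
            d -= 1
        stable = float(d + 1)
    else:
        stable = float("nan")

    def runs(flags: np.ndarray) -> int:
        return int(np.sum(flags & ~np.concatenate([[False], flags[:-1]])))

    actions = [d.action for d in log.decisions]
    adjustments = sum(1 for i in range(1, len(actions)) if actions[i] != actions[i - 1])
    interruptions = sum(1 for a in actions if a == 0)

    return PatientMetrics(
        patient_id=log.patient_id,
        chr_at_end=bool(chr_day[-1]),
        days_until_stable_chr=stable,
        pct_days_plt=100.0 * plt_in.mean(),
        pct_days_wbc=100.0 * wbc_in.mean(),
        pct_days_hct=100.0 * hct_in.mean(),
        pct_days_chr=100.0 * chr_day.mean(),
        any_severe=bool(severe.any()),
        pct_days_severe=100.0 * severe.mean(),
        n_severe_episodes=runs(severe),
        n_moderate_episodes=runs(moderate),
        n_dose_adjustments=adjustments,
        n_interruptions=interruptions,
    )


_SUMMARY_METRICS = (
    "days_until_stable_chr",
    "pct_days_severe",
    "pct_days_plt",
    "pct_days_wbc",
    "pct_days_hct",
    "pct_days_chr",
    "n_dose_adjustments",
    "n_interruptions",
)


def summarize_population(metrics: list[PatientMetrics]) -> pd.DataFrame:
    """Median and 95% empirical interval per metric, plus response rates.

    ``days_until_stable_chr`` is summarised over the patients that reach a
    stable CHR (NaN-aware percentiles); the CHR and severe-toxicity rates
    are reported as percentages of patients.
    """
    if not metrics:
        raise ValueError("cannot summarise an empty population")
    rows = []
    for name in _SUMMARY_METRICS:
        values = np.asarray([getattr(m, name) for m in metrics], dtype=float)
        if np.all(np.isnan(values)):
            med = lo = hi = float("nan")
        else:
            med = float(np.nanmedian(values))
            lo = float(np.nanpercentile(values, 2.5))
            hi = float(np.nanpercentile(values, 97.5))
        rows.append({"metric": name, "median": med, "p2.5": lo, "p97.5": hi})
    out = pd.DataFrame(rows).set_index("metric")
    n = len(metrics)
    out.loc["pct_patients_chr_at_end"] = [
        100.0 * sum(m.chr_at_end for m in metrics) / n, np.nan, np.nan]
    out.loc["pct_patients_any_severe"] = [
        100.0 * sum(m.any_severe for m in metrics) / n, np.nan, np.nan]
    return out


# ------------------------------------------------------------------ strategies
class Strategy:
    """A named way of producing a dosing policy for a given patient."""

    name: str = "strategy"

    def policy_for(self, patient: VirtualPatient) -> Policy:
        raise NotImplementedError


class ClinicalProtocolStrategy(Strategy):
    name = "clinical_protocol"

    def policy_for(self, patient: VirtualPatient) -> Policy:
        return ClinicalProtocol()


class SharedQTableStrategy(Strategy):
    """One table (e.g. the population agent) applied to every patient."""

    def __init__(self, qtable: QTable, name: str = "ql_pop"):
        if qtable is None:
            raise ValueError(f"strategy {name!r} has no trained table")
        self.qtable = qtable
        self.name = name

    def policy_for(self, patient: VirtualPatient) -> Policy:
        return GreedyQPolicy(self.qtable)


class PerPatientQTableStrategy(Strategy):
    """One trained table per patient id (the individual agents)."""

    def __init__(self, tables: dict[int, QTable], name: str = "ql_ind"):
        self.tables = dict(tables)
        self.name = name

    def policy_for(self, patient: VirtualPatient) -> Policy:
        try:
            table = self.tables[patient.id]
        except KeyError:
            raise ValueError(f"no trained table for patient {patient.id}") from None
        return GreedyQPolicy(table)


class FixedDoseStrategy(Strategy):
    def __init__(self, dose: int = 100):
        from .protocols import FixedDosePolicy

        self._dose = dose
        FixedDosePolicy(dose)  # validate
        self.name = f"fixed_{dose}mg"

    def policy_for(self, patient: VirtualPatient) -> Policy:
        from .protocols import FixedDosePolicy

        return FixedDosePolicy(self._dose)


def evaluate_strategy(
    strategy: Strategy,
    patients: list[VirtualPatient],
    *,
    horizon_days: int = 224,
    reward_cfg: RewardConfig = STRICT,
    substeps_per_day: int = 3,
) -> tuple[list[PatientMetrics], list[EpisodeLog]]:
    """Roll a strategy over a population; metrics + logs per patient."""
    metrics, logs = [], []
    for patient in patients:
        env = DoseTitrationEnv(
            patient.params, horizon_days=horizon_days, substeps_per_day=substeps_per_day
        )
        log = rollout_with_policy(env, strategy.policy_for(patient), reward_cfg, patient.id)
        logs.append(log)
        metrics.append(compute_patient_metrics(log, horizon=horizon_days))
    return metrics, logs


@dataclass
class ComparisonReport:
    """Per-strategy population summaries (+ per-set detail in panel A)."""

    mode: str
    summaries: dict[str, pd.DataFrame]
    per_set: dict[str, list[pd.DataFrame]] | None = None
    metrics: dict[str, list[PatientMetrics]] | None = None

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for name, summary in self.summaries.items():
            part = summary.copy()
            part.insert(0, "strategy", name)
            parts.append(part.reset_index())
        return pd.concat(parts, ignore_index=True)


def _roll_up(per_set: list[pd.DataFrame]) -> pd.DataFrame:
    """Across-set roll-up: median of medians, 2.5th pct of 2.5th pcts, etc."""
    import warnings

    stacked = {col: np.stack([s[col].to_numpy() for s in per_set]) for col in ("median", "p2.5", "p97.5")}
    out = per_set[0].copy()
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="All-NaN slice")
        out["median"] = np.nanmedian(stacked["median"], axis=0)
        out["p2.5"] = np.nanpercentile(stacked["p2.5"], 2.5, axis=0)
        out["p97.5"] = np.nanpercentile(stacked["p97.5"], 97.5, axis=0)
    return out


def run_comparison(
    populations: list[list[VirtualPatient]],
    strategies: list[Strategy],
    *,
    mode: str = "panel_b",
    horizon_days: int = 224,
    substeps_per_day: int = 3,
) -> ComparisonReport:
    """Compare dosing strategies.

    mode="panel_a": every strategy is evaluated on each of the k test
    populations and summaries are rolled up across sets.
    mode="panel_b": all strategies are evaluated on a single population
    (``populations`` must contain exactly one).
    """
    if mode not in ("panel_a", "panel_b"):
        raise ValueError(f"unknown comparison mode {mode!r}")
    if mode == "panel_b" and len(populations) != 1:
        raise ValueError("panel_b mode expects exactly one population")
    if not populations or not strategies:
        raise ValueError("need at least one population and one strategy")

    summaries: dict[str, pd.DataFrame] = {}
    per_set: dict[str, list[pd.DataFrame]] = {}
    all_metrics: dict[str, list[PatientMetrics]] = {}
    for strategy in strategies:
        set_summaries = []
        strat_metrics: list[PatientMetrics] = []
        for pop in populations:
            metrics, _ = evaluate_strategy(
                strategy, pop, horizon_days=horizon_days, substeps_per_day=substeps_per_day
            )
            strat_metrics.extend(metrics)
            set_summaries.append(summarize_population(metrics))
        per_set[strategy.name] = set_summaries
        all_metrics[strategy.name] = strat_metrics
        if mode == "panel_a":
            summaries[strategy.name] = _roll_up(set_summaries)
        else:
            summaries[strategy.name] = set_summaries[0]
    return ComparisonReport(
        mode=mode,
        summaries=summaries,
        per_set=per_set if mode == "panel_a" else None,
        metrics=all_metrics,
    )
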