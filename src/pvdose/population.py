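"""Stratified virtual-population generator.

Virtual polycythemia-vera patients are sampled around typical twin
parameters with log-normal interindividual variability (IIV).  Two axes of
heterogeneity are controlled:

* **baseline-elevation pattern** -- which of PLT / WBC / HCT start above
  their target range.  Every PV patient has at least one elevated endpoint
  at baseline, so the seven non-empty subsets of {PLT, WBC, HCT} form the
  default (equiprobable) strata.  Rejection sampling enforces the pattern
  exactly: elevated endpoints are drawn above their range, the others
  inside it.
* **drug-effect sensitivity** -- a low / typical / high band multiplying
  all three drug-effect slopes, so that the optimal dose genuinely differs
  between patients.

Each patient id owns an independent random sub-stream derived from the
population seed, so a population can be extended without reshuffling
earlier draws.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .twin import HctPD, LineagePD, PatientParameters

ENDPOINTS = ("plt", "wbc", "hct")

#: All seven admissible baseline-elevation patterns (at least one elevated).
BASELINE_PATTERNS = (
    ("plt",),
    ("wbc",),
    ("hct",),
    ("plt", "wbc"),
    ("plt", "hct"),
    ("wbc", "hct"),
    ("plt", "wbc", "hct"),
)

SENSITIVITY_BANDS = ("low", "typical", "high")
_SENSITIVITY_MULTIPLIER = {"low": 0.6, "typical": 1.0, "high": 1.5}

_MAX_REJECTIONS = 1000

# Typical twin parameter values.  Chosen once so that the 100 mg/day
# starting dose is neither universally toxic nor universally ineffective
# across the sampled population (see docs/methods.md).
DEFAULT_TYPICALS: dict[str, float] = {
    "ka": 2.0,
    "cl": 150.0,
    "v": 50.0,
    "ke0": 0.1,
    "plt_baseline_elevated": 650.0,
    "plt_baseline_normal": 275.0,
    "plt_mtt": 10.0,
    "plt_gamma": 0.3,
    "plt_slope": 0.34,
    "wbc_baseline_elevated": 13.0,
    "wbc_baseline_normal": 7.0,
    "wbc_mtt": 5.0,
    "wbc_gamma": 0.25,
    "wbc_slope": 0.20,
    "hct_baseline_elevated": 47.0,
    "hct_baseline_normal": 42.0,
    "hct_kout": 0.05,
    "hct_slope": 0.25,
}

# Log-normal IIV standard deviations (on the log scale).
DEFAULT_IIV_SD: dict[str, float] = {
    "ka": 0.2,
    "cl": 0.15,
    "v": 0.2,
    "ke0": 0.15,
    "plt_baseline_elevated": 0.15,
    "plt_baseline_normal": 0.1,
    "plt_mtt": 0.15,
    "plt_gamma": 0.1,
    "plt_slope": 0.15,
    "wbc_baseline_elevated": 0.12,
    "wbc_baseline_normal": 0.1,
    "wbc_mtt": 0.15,
    "wbc_gamma": 0.1,
    "wbc_slope": 0.15,
    "hct_baseline_elevated": 0.03,
    "hct_baseline_normal": 0.03,
    "hct_kout": 0.15,
    "hct_slope": 0.15,
}

# Baseline acceptance windows: elevated endpoints must exceed the range
# ceiling, normal ones must lie inside the target range (physiologic caps).
_BASELINE_WINDOWS = {
    ("plt", True): (400.0, 1500.0),
    ("plt", False): (150.0, 400.0),
    ("wbc", True): (10.0, 50.0),
    ("wbc", False): (4.0, 10.0),
    ("hct", True): (45.0, 70.0),
    ("hct", False): (20.0, 45.0),
}


@dataclass(frozen=True)
class Stratum:
    """One sampling stratum: baseline pattern x sensitivity band."""

    pattern: tuple[str, ...]
    proportion: float
    sensitivity: str = "any"  # "low" | "typical" | "high" | "any"

    def __post_init__(self) -> None:
        if not self.pattern or any(e not in ENDPOINTS for e in self.pattern):
            raise ValueError(f"invalid baseline pattern {self.pattern!r}")
        if self.sensitivity not in SENSITIVITY_BANDS + ("any",):
            raise ValueError(f"unknown sensitivity band {self.sensitivity!r}")
        if self.proportion < 0:
            raise ValueError("stratum proportion must be >= 0")


def default_strata() -> tuple[Stratum, ...]:
    """Seven equiprobable baseline-pattern strata, sensitivity drawn per patient."""
    return tuple(Stratum(pattern=p, proportion=1.0 / 7.0) for p in BASELINE_PATTERNS)


@dataclass
class PopulationSpec:
    """Configuration of the virtual-population sampler."""

    n_patients: int = 98
    seed: int = 0
    typicals: dict = field(default_factory=lambda: dict(DEFAULT_TYPICALS))
    iiv_sd: dict = field(default_factory=lambda: dict(DEFAULT_IIV_SD))
    strata: tuple = field(default_factory=default_strata)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not self.strata:
            raise ValueError("strata specification must not be empty")
        total = sum(s.proportion for s in self.strata)
        if not np.isclose(total, 1.0):
            raise ValueError(f"strata proportions must sum to 1, got {total}")
        for key, sd in self.iiv_sd.items():
            if sd < 0:
                raise ValueError(f"IIV sd for {key!r} must be >= 0")


@dataclass(frozen=True)
class VirtualPatient:
    """A sampled patient: id, twin parameters and stratum labels."""

    id: int
    params: PatientParameters
    pattern: tuple[str, ...]
    sensitivity: str

    def to_dict(self) -> dict:
        return {
            "id": self.id,
            "pattern": list(self.pattern),
            "sensitivity": self.sensitivity,
            "params": asdict(self.params),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VirtualPatient":
        pp = d["params"]
        params = PatientParameters(
            ka=pp["ka"],
            cl=pp["cl"],
            v=pp["v"],
            ke0=pp.get("ke0", 0.1),
            plt=LineagePD(**pp["plt"]),
            wbc=LineagePD(**pp["wbc"]),
            hct=HctPD(**pp["hct"]),
        )
        return cls(
            id=int(d["id"]),
            params=params,
            pattern=tuple(d["pattern"]),
            sensitivity=d["sensitivity"],
        )


def _lognormal(rng: np.random.Generator, typical: float, sd: float) -> float:
    if sd == 0.0:
        return typical
    return float(typical * np.exp(rng.normal(0.0, sd)))


def _sample_baseline(
    rng: np.random.Generator, spec: PopulationSpec, endpoint: str, elevated: bool
) -> float:
    key = f"{endpoint}_baseline_{'elevated' if elevated else 'normal'}"
    lo, hi = _BASELINE_WINDOWS[(endpoint, elevated)]
    typical = spec.typicals[key]
    sd = spec.iiv_sd.get(key, 0.0)
    for _ in range(_MAX_REJECTIONS):
        value = _lognormal(rng, typical, sd)
        # "elevated" means strictly above the range ceiling for PLT/WBC and
        # at/above 45% for HCT (matching the >= 45 phlebotomy threshold).
        if endpoint == "hct":
            ok = (lo <= value <= hi) if elevated else (lo <= value < hi)
        else:
            ok = (lo < value <= hi) if elevated else (lo <= value <= hi)
        if ok:
            return value
    raise RuntimeError(
        f"could not sample a {'elevated' if elevated else 'normal'} {endpoint} baseline "
        f"after {_MAX_REJECTIONS} rejections; spec inconsistent with the PV constraint"
    )


def _cap_slope(slope: float, baseline: float, gamma: float, cl: float, floor: float) -> float:
    """Bound a lineage's drug-effect slope by minimum-dose tolerability.

    The twin's steady state under a constant daily dose D is
    ``baseline * (1 - slope * D / CL)^(1/gamma)``.  The population is
    calibrated so that the lowest clinical dose (50 mg/day) is tolerable
    for every patient: the slope is capped (with a 10% margin) so the
    50 mg steady state stays at or above ``floor``, a level whose
    transient nadir still clears the severe-toxicity threshold.
    """
    c50 = 50.0 / cl
    e_max = 1.0 - (floor / baseline) ** gamma if baseline > floor else 0.0
    if e_max <= 0:
        # baseline already at/below the floor cannot occur with the
        # default windows; keep a minimal positive effect if it does
        return min(slope, 0.05 / c50)
    return min(slope, 0.9 * e_max / c50)


def _has_feasible_dose(params: PatientParameters) -> bool:
    """True if some grid dose's predicted steady state normalizes all endpoints.

    Uses the twin's closed-form steady states under a constant daily dose
    (average biophase concentration D / CL) with small safety margins
    inside the target ranges.  Together with the minimum-dose tolerability
    cap this calibrates the population so that an effective *and* safe
    titration target exists for every patient -- the 25 mg grid spacing
    can otherwise leave a patient whose per-endpoint dose windows do not
    overlap on any available dose.
    """
    for dose in (50, 75, 100, 125, 150, 175, 200):
        c = dose / params.cl
        e_p = min(params.plt.slope * c, 1.0)
        e_w = min(params.wbc.slope * c, 1.0)
        e_h = min(params.hct.slope * c, 1.0)
        plt_ss = params.plt.baseline * (1.0 - e_p) ** (1.0 / params.plt.gamma)
        wbc_ss = params.wbc.baseline * (1.0 - e_w) ** (1.0 / params.wbc.gamma)
        hct_ss = params.hct.baseline * (1.0 - e_h)
        if 160.0 <= plt_ss <= 390.0 and 4.3 <= wbc_ss <= 9.7 and hct_ss <= 44.5:
            return True
    return False


def patient_rng(seed: int, patient_id: int) -> np.random.Generator:
    """Independent random sub-stream for one patient id."""
    return np.random.default_rng([int(seed), int(patient_id)])


def sample_patient(
    spec: PopulationSpec, stratum: Stratum, patient_id: int, rng: np.random.Generator | None = None
) -> VirtualPatient:
    """Draw one virtual patient from a stratum.

    Parameters are log-normal around the typical values; baselines are
    rejection-sampled so the stratum's elevation pattern holds exactly
    (listed endpoints above range, the others inside it), which guarantees
    the PV invariant that at least one endpoint starts out of range.  A
    whole draw is rejected and repeated when no grid dose can normalize
    all three endpoints at steady state (see :func:`_has_feasible_dose`).
    """
    if rng is None:
        rng = patient_rng(spec.seed, patient_id)
    sens = stratum.sensitivity
    if sens == "any":
        sens = SENSITIVITY_BANDS[rng.integers(len(SENSITIVITY_BANDS))]
    mult = _SENSITIVITY_MULTIPLIER[sens]
    t, sd = spec.typicals, spec.iiv_sd

    def draw(key: str) -> float:
        return _lognormal(rng, t[key], sd.get(key, 0.0))

    elev = {e: e in stratum.pattern for e in ENDPOINTS}
    for _ in range(_MAX_REJECTIONS):
        cl = draw("cl")
        plt_baseline = _sample_baseline(rng, spec, "plt", elev["plt"])
        wbc_baseline = _sample_baseline(rng, spec, "wbc", elev["wbc"])
        plt_gamma = draw("plt_gamma")
        wbc_gamma = draw("wbc_gamma")
        params = PatientParameters(
            ka=draw("ka"),
            cl=cl,
            v=draw("v"),
            ke0=draw("ke0"),
            plt=LineagePD(
                baseline=plt_baseline,
                mtt=draw("plt_mtt"),
                gamma=plt_gamma,
                slope=_cap_slope(
                    mult * draw("plt_slope"), plt_baseline, plt_gamma, cl, floor=125.0
                ),
            ),
            wbc=LineagePD(
                baseline=wbc_baseline,
                mtt=draw("wbc_mtt"),
                gamma=wbc_gamma,
                slope=_cap_slope(
                    mult * draw("wbc_slope"), wbc_baseline, wbc_gamma, cl, floor=3.6
                ),
            ),
            hct=HctPD(
                baseline=_sample_baseline(rng, spec, "hct", elev["hct"]),
                kout=draw("hct_kout"),
                slope=mult * draw("hct_slope"),
            ),
        )
        if _has_feasible_dose(params):
            return VirtualPatient(
                id=patient_id, params=params, pattern=stratum.pattern, sensitivity=sens
            )
    raise RuntimeError(
        f"no dose-feasible parameter draw for stratum {stratum.pattern}/{sens} after "
        f"{_MAX_REJECTIONS} attempts; spec inconsistent with the calibration constraints"
    )


def _stratum_counts(spec: PopulationSpec) -> list[int]:
    """Largest-remainder allocation of n_patients across strata."""
    targets = [s.proportion * spec.n_patients for s in spec.strata]
    counts = [int(np.floor(x)) for x in targets]
    remainders = [x - c for x, c in zip(targets, counts)]
    short = spec.n_patients - sum(counts)
    for idx in sorted(range(len(counts)), key=lambda i: -remainders[i])[:short]:
        counts[idx] += 1
    return counts


def generate_stratified_population(spec: PopulationSpec) -> list[VirtualPatient]:
    """Sample the full stratified population (ids 0 .. n_patients-1)."""
    counts = _stratum_counts(spec)
    patients: list[VirtualPatient] = []
    pid = 0
    for stratum, count in zip(spec.strata, counts):
        for _ in range(count):
            patients.append(sample_patient(spec, stratum, pid))
            pid += 1
    return patients


def save_population(patients: list[VirtualPatient], path, *, seed: int | None = None) -> None:
    payload = {"seed": seed, "patients": [p.to_dict() for p in patients]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_population(path) -> list[VirtualPatient]:
    with open(path) as fh:
        payload = json.load(fh)
    return [VirtualPatient.from_dict(d) for d in payload["patients"]]
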