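"""Multiobjective piecewise reward for the dosing MDP.

Each treatment cycle is scored as the sum of three endpoint terms (PLT,
WBC, HCT), each in turn a weighted sum of three components in [0, 1]:

* ``reward_obs``  (weight 10) -- scores the end-of-cycle observation
  against the therapeutic window, peaking at the middle of the normal
  range;
* ``reward_range`` (weight 7)  -- the fraction of the cycle's days spent
  inside the target range;
* ``reward_der``   (weight 5)  -- scores the end-of-cycle trend ``y'``
  (difference quotient over the last two daily values): stability is
  rewarded inside the range, movement *toward* the range outside it.

The total therefore lies in [0, 66].  Two variants exist:

* **strict** -- any severe end-of-cycle toxicity (PLT < 75 or WBC < 3)
  zeroes the whole cycle reward;
* **smoothed** -- no hard zero; the sub-range observation branch extends
  below the severe threshold, so deep toxicity is merely scored very low.
  The two variants agree exactly whenever no severe toxicity is observed.

``reward_obs`` works on a transformed coordinate ``z`` so that all three
endpoints share one piecewise shape anchored at 150 (range floor), 275
(range middle) and 400 (range ceiling): PLT uses ``z = value``; WBC uses
``z = 37.5 * value`` below the mid-band and ``z = 40 * value`` above it
(placing 4 -> 150 and 10 -> 400); HCT uses ``z = 8.89 * value`` (placing
45% at the 400 ceiling).  Distances from anchors are taken in absolute
value so the score always decays away from the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .mdp import CycleOutcome

LN5 = math.log(5.0)

ENDPOINTS = ("plt", "wbc", "hct")


@dataclass(frozen=True)
class RewardConfig:
    """Weights, shape constants and variant selection for the reward."""

    beta_obs: float = 10.0
    beta_range: float = 7.0
    beta_der: float = 5.0
    #: sub-range branch constants; a + c = 0.5 makes the score continuous
    #: at the efficacy floor (z = 150).
    a: float = 0.643
    c: float = -0.143
    rate_sub: float = 0.01
    rate_eff: float = 0.06
    wbc_scale_low: float = 37.5
    wbc_scale_high: float = 40.0
    hct_scale: float = 8.89
    variant: str = "strict"  # "strict" | "smoothed"
    #: optional terminal bonus added once at episode end if the patient is
    #: in complete hematological response on the final day (default off).
    terminal_chr_bonus: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in ("strict", "smoothed"):
            raise ValueError(f"unknown reward variant {self.variant!r}")
        for name in ("beta_obs", "beta_range", "beta_der"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.a + self.c - 0.5) > 1e-12:
            raise ValueError("continuity requires a + c = 0.5")


STRICT = RewardConfig(variant="strict")
SMOOTHED = RewardConfig(variant="smoothed")


def _exp(x: float) -> float:
    # exp with clipped argument; the reward only ever needs decaying tails
    return math.exp(x) if x > -60.0 else 0.0


def _shape(z: float, cfg: RewardConfig) -> float:
    """Common piecewise shape on the transformed coordinate z (PLT scale)."""
    if z < 150.0:
        return cfg.a * _exp(-cfg.rate_sub * abs(z - 150.0)) + cfg.c
    if z < 275.0:
        return 0.5 * (1.0 - _exp(-cfg.rate_eff * abs(z - 150.0))) + 0.5
    if z <= 400.0:
        return 0.5 * (1.0 - _exp(-cfg.rate_eff * abs(z - 400.0))) + 0.5
    return 0.5 * _exp(-cfg.rate_sub * abs(z - 400.0))


def reward_obs(endpoint: str, value: float, config: RewardConfig = STRICT) -> float:
    """Observation score in [0, 1] for an end-of-cycle value.

    The strict and smoothed variants only differ below the severe
    threshold, where the strict total is zeroed anyway; here both evaluate
    the same sub-range branch, keeping the function total on positive
    inputs.
    """
    if value <= 0 or not math.isfinite(value):
        raise ValueError(f"observation must be positive and finite, got {value}")
    if endpoint == "plt":
        z = value
    elif endpoint == "wbc":
        # 37.5 maps the moderate band and lower efficacy half onto the PLT
        # scale (4 -> 150); 40 maps the upper half (10 -> 400).
        z = config.wbc_scale_low * value if value < 7.0 else config.wbc_scale_high * value
    elif endpoint == "hct":
        z = config.hct_scale * value
        # HCT has no toxicity floor: below the 22.5% pivot the lower-half
        # efficacy branch applies, never the sub-range branch.
        if value < 22.5:
            return 0.5 * (1.0 - _exp(-config.rate_eff * abs(z - 150.0))) + 0.5
        if value < 45.0:
            return 0.5 * (1.0 - _exp(-config.rate_eff * abs(z - 400.0))) + 0.5
        return 0.5 * _exp(-config.rate_sub * abs(z - 400.0))
    else:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    return _shape(z, config)


def reward_range(in_range_days: int, cycle_length: int) -> float:
    """Fraction of the cycle's days with the endpoint inside its range."""
    if cycle_length <= 0:
        raise ValueError("cycle_length must be positive")
    if not 0 <= in_range_days <= cycle_length:
        raise ValueError(f"in_range_days {in_range_days} outside [0, {cycle_length}]")
    return in_range_days / cycle_length


def reward_der(
    endpoint: str, y_prime: float, category: str, config: RewardConfig = STRICT
) -> float:
    """Trend score in [0, 1] given the end-of-cycle range position.

    ``category`` is "below", "in" or "above" (the endpoint's target
    range); HCT has no "below" arm -- sub-45% haematocrit is scored with
    the in-range stability formula.
    """
    if not math.isfinite(y_prime):
        raise ValueError("y' must be finite")
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if endpoint == "hct" and category == "below":
        category = "in"
    y = max(-50.0, min(50.0, y_prime))
    if category == "in":
        return _exp(-y_prime * y_prime * LN5) if abs(y_prime) < 10 else 0.0
    if category == "below":
        if y <= 0:
            return 0.2 / (1.0 + math.exp(-y))
        return 1.0 / (1.0 + math.exp(-y))
    if category == "above":
        if y < 0:
            return 1.0 / (1.0 + math.exp(-abs(y)))
        return 0.2 / (1.0 + math.exp(-y))
    raise ValueError(f"unknown category {category!r}")


def _range_category(endpoint: str, value: float) -> str:
    if endpoint == "plt":
        return "below" if value < 150 else ("in" if value <= 400 else "above")
    if endpoint == "wbc":
        return "below" if value < 4 else ("in" if value <= 10 else "above")
    return "in" if value < 45 else "above"


def endpoint_reward(
    endpoint: str, value: float, y_prime: float, in_range_days: int, cycle_length: int,
    config: RewardConfig = STRICT,
) -> float:
    """Weighted endpoint term: beta1*obs + beta2*range + beta3*der."""
    return (
        config.beta_obs * reward_obs(endpoint, value, config)
        + config.beta_range * reward_range(in_range_days, cycle_length)
        + config.beta_der * reward_der(endpoint, y_prime, _range_category(endpoint, value), config)
    )


def cycle_reward(outcome: CycleOutcome, config: RewardConfig = STRICT) -> float:
    """Scalar reward of one treatment cycle (in [0, 66]).

    Strict variant: returns 0 outright when the end-of-cycle observation
    shows severe toxicity (PLT < 75 or WBC < 3); intra-cycle dips do not
    trigger the zero, only the observed values at the monitoring day.
    """
    if config.variant == "strict" and (outcome.plt_obs < 75.0 or outcome.wbc_obs < 3.0):
        return 0.0
    total = 0.0
    for endpoint, value, deriv, days in (
        ("plt", outcome.plt_obs, outcome.plt_deriv, outcome.plt_in_range),
        ("wbc", outcome.wbc_obs, outcome.wbc_deriv, outcome.wbc_in_range),
        ("hct", outcome.hct_obs, outcome.hct_deriv, outcome.hct_in_range),
    ):
        total += endpoint_reward(endpoint, value, deriv, days, outcome.cycle_length, config)
    return total


def plot_reward_curves(outdir, config: RewardConfig = SMOOTHED) -> list[str]:
    """Dump the three observation-score curves and the trend-score arms as PNGs."""
    import os

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    os.makedirs(outdir, exist_ok=True)
    written = []

    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    grids = {
        "plt": np.linspace(1, 700, 1200),
        "wbc": np.linspace(0.2, 18, 1200),
        "hct": np.linspace(20, 60, 1200),
    }
    for ax, (endpoint, grid) in zip(axes, grids.items()):
        ax.plot(grid, [reward_obs(endpoint, v, config) for v in grid])
        ax.set_title(f"reward_obs ({endpoint.upper()})")
        ax.set_xlabel({"plt": "PLT (10^9/L)", "wbc": "WBC (10^9/L)", "hct": "HCT (%)"}[endpoint])
        ax.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    path = os.path.join(outdir, "reward_obs.png")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)

    fig, ax = plt.subplots(figsize=(5.5, 3.8))
    ys = np.linspace(-4, 4, 801)
    for cat in ("below", "in", "above"):
        ax.plot(ys, [reward_der("plt", y, cat, config) for y in ys], label=cat)
    ax.set_xlabel("y' (units/day)")
    ax.set_ylabel("reward_der")
    ax.legend()
    fig.tight_layout()
    path = os.path.join(outdir, "reward_der.png")
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
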