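# Methods

`pvdose` simulates adaptive givinostat-style dose titration in polycythemia
vera (PV) and studies it with tabular reinforcement learning.  This note
documents the models, the parameters that matter, the design choices made
where the design was genuinely open, and what the synthetic setting does and
does not show about real treatment.

## The clinical problem

PV overproduces platelets (PLT), white blood cells (WBC) and red cells
(hematocrit, HCT).  Therapy aims at a complete hematological response
(CHR): PLT ∈ [150, 400]×10⁹/L, WBC ∈ [4, 10]×10⁹/L and HCT < 45%
simultaneously.  The same three endpoints bound safety from below: grade-1
(moderate) toxicity is PLT ∈ [75, 150) or WBC ∈ [3, 4); grade-2 (severe)
toxicity is PLT < 75 or WBC < 3.  Doses come from a fixed grid
{50, 75, …, 200} mg/day, adjusted at the end of each 28-day cycle by at
most one 25 mg step; severe toxicity forces a 14-day interruption.
Patients presenting with HCT ≥ 45% receive a phlebotomy that resets HCT to
43% before treatment starts.  The treatment horizon is 8 cycles × 28 days
= 224 days.

## The digital twin

Each virtual patient is a deterministic PK-PD system (no residual
unexplained variability), so a patient's response is fully determined by
their parameters and the dose sequence — this is what lets a patient serve
as the training environment of a Markov decision process.

* **PK**: one-compartment disposition with first-order absorption (`ka`,
  `CL`, `V`); each treatment day deposits the daily dose into the depot.
* **Biophase**: the plasma concentration equilibrates into an effect
  compartment, `dCe/dt = ke0 (C − Ce)` with `ke0 ≈ 0.1/day`, so the
  myelosuppressive effect builds over one to two weeks.  This delayed
  drive keeps the marrow feedback in step with the insult: the transient
  nadir then lies close to the eventual steady state, and end-of-cycle
  monitoring (which both the clinical protocol and the reward key on) is
  an honest surrogate for the whole cycle.
* **PLT and WBC**: Friberg-type transit chains — proliferative pool, three
  transit compartments, circulating pool, all with `ktr = 4/MTT`; drug
  inhibits proliferation linearly (`E = slope · Ce`, clipped at 1) and the
  feedback `(baseline/circulating)^γ` drives recovery.  The steady state
  under a constant dose D is `baseline · (1 − slope·D/CL)^(1/γ)`.
* **HCT**: indirect-response turnover with production inhibition,
  `dH/dt = kout·baseline·(1 − E) − kout·H`.

The feedback exponents are deliberately small (γ ≈ 0.3 for PLT, 0.25 for
WBC).  Large exponents turn the transit chain into a delayed-feedback
oscillator (limit cycles, rebound overshoot); small exponents give damped,
slowly-rebounding responses, which has a second consequence we rely on:
when an excursion below the severe threshold does occur it persists to the
next monitoring day instead of being masked by a fast rebound, so a
monitoring-based penalty can see it.

Integration is classical RK4 with 3 substeps per day on a daily grid (the
daily grid matches the daily in-range bookkeeping of the reward).  The
drug-free system is exactly at its fixed point, so untreated trajectories
are flat to machine precision.

## The virtual population

Patients are sampled log-normally around typical values.  Two axes of
heterogeneity are stratified:

* **baseline-elevation pattern** — which endpoints start above range.  All
  PV patients have at least one endpoint out of range at baseline; the 7
  non-empty subsets of {PLT, WBC, HCT} form the default equiprobable
  strata (98 patients split 14 per stratum), enforced exactly by rejection
  sampling (elevated endpoints above range, the others inside it).
* **drug-effect sensitivity** — a low/typical/high band (×0.6/×1.0/×1.5 on
  all three slopes) recorded as a patient label, drawn per patient unless
  a stratum pins it.

Typical values (ka 2/day, CL 150 L/day, V 50 L, ke0 0.1/day; PLT baseline
650 elevated / 275 normal, MTT 10 d, γ 0.3, slope 0.34 L/mg; WBC 13 / 7,
MTT 5 d, γ 0.25, slope 0.20; HCT 47 / 42 %, kout 0.05/day, slope 0.25)
were chosen once so that the clinical 100 mg/day starting dose is neither
universally toxic nor universally ineffective: across the default
population the per-patient optimal dose genuinely spans the grid.

Two calibration constraints shape the sampled parameters:

1. **Minimum-dose tolerability.**  Each lineage's slope is capped (10%
   margin) so the predicted steady state at 50 mg/day stays above a floor
   (PLT 125, WBC 3.6) whose transient nadir still clears the severe
   threshold.  Without it, a rare patient with a strong slope on a
   *normal* baseline has no tolerable dose at all, and no dosing policy —
   learned or clinical — can avoid severe toxicity.
2. **Dose feasibility.**  A whole parameter draw is rejected unless some
   grid dose's predicted steady state normalizes all three endpoints
   (PLT ∈ [160, 390], WBC ∈ [4.3, 9.7], HCT ≤ 44.5).  The 25 mg grid
   spacing can otherwise leave a patient whose PLT and WBC dose windows
   fail to overlap on any available dose; the best achievable policy for
   such a patient oscillates through the moderate band and grazes severe
   toxicity.

Both constraints use the twin's closed-form steady states, are part of the
generator's fixed definition, and mildly truncate the marginals of the
parameters they involve (CL, slopes, γ); parameters outside the
calibration (ka, V, ke0, MTT, kout) keep exact log-normal marginals.
Each patient id owns an independent random sub-stream, so populations are
extensible without reshuffling.

## The MDP

States are 4-tuples (PLT category 1–4, WBC category 1–4, HCT category 1–2,
previous-dose code).  The previous-dose code stores the last administered
dose with a sign convention that compactly encodes interruption history:
positive while on treatment, negative (−trigger) while interrupted for
severe toxicity, 0 while interrupted for moderate toxicity (only possible
at the 50 mg floor) and −1 only at treatment start.  32 category
combinations × 15 codes give 480 states; 8 initial-candidate tuples
(no-toxicity categories with code −1) minus the discarded all-normal tuple
add 7 more, for 487 total.  The initial state is discretized from the
*pre-phlebotomy* baseline (initial states with elevated HCT exist only
then); the simulation itself starts from the post-phlebotomy state.

Boundary conventions make the bins a partition that favors the better
category: severe bins are open above (value < threshold), efficacy bins
closed on both ends, inefficacy strictly above.

Action menus follow the clinical safety mask: all 7 doses at treatment
start; stay/±25 (edge-clipped) without toxicity; stay/±25 under moderate
toxicity except a forced interruption at the 50 mg floor; a forced
interruption under any severe toxicity; menu {0, 50} to resume after a
moderate interruption once both lineages are back in the efficacy range;
menu {0, 50, …, trigger} after a severe interruption once both are above
the severe threshold.  States not meeting their resumption condition stay
forced to 0 for another 14 days with an unchanged code (the published rule
table does not enumerate these states; holding is the minimal consistent
completion).  Choosing 0 at a resumption decision re-enters a 14-day hold.
Cycles last 28 days (14 during interruptions); a final cycle that would
overrun day 224 is truncated so the episode clock is exact.

## The reward

Each cycle scores as Σ over endpoints of 10·obs + 7·range + 5·trend, total
in [0, 66]:

* **obs** scores the end-of-cycle value on a shared piecewise shape over a
  transformed coordinate z anchored at 150/275/400 (PLT: z = value; WBC:
  z = 37.5·value below the mid-band, 40·value above, placing 4→150 and
  10→400; HCT: z = 8.89·value, placing 45%→400).  Below range:
  0.643·e^(−0.01|z−150|) − 0.143 (the constants sum to 0.5, making the
  score continuous at the range floor); lower efficacy half:
  1 − 0.5·e^(−0.06|z−150|); upper half: 1 − 0.5·e^(−0.06|z−400|); above
  range: 0.5·e^(−0.01|z−400|).  Distances are absolute values — without
  them the sub-range branch would reward deeper toxicity.  The upper
  efficacy half is anchored at 400 (mirror of the lower half), which gives
  the intended peak at mid-range and continuity at the ceiling.
* **range** is the fraction of the cycle's days with the endpoint inside
  its target range.
* **trend** scores y′ = y(t_end) − y(t_end−1) in raw units/day: inside the
  range 5^(−y′²) (maximum 1 at stability, 0.2 at |y′| = 1, matching the
  0.2-scaled logistic arms); below range 0.2/(1+e^(−y′)) for y′ ≤ 0 and
  1/(1+e^(−y′)) for y′ > 0 (movement toward range is rewarded); mirrored
  above range.  HCT has no below-range arm.

The **strict** variant returns 0 outright when the end-of-cycle
observation shows severe toxicity; the **smoothed** variant extends the
sub-range obs branch below the severe threshold instead of zeroing.  The
two agree exactly whenever PLT ≥ 75 and WBC ≥ 3.  Severe zeroing keys off
end-of-cycle observations only — intra-cycle dips are penalized solely
through lost in-range days — mirroring monthly clinical monitoring.
Interruption cycles are scored like any 14-day cycle.  An optional
terminal CHR bonus (constant added when CHR holds on the final day) is
available but off by default.

## Q-learning

One-step tabular Q-learning with ε-greedy exploration runs on whole
224-day episodes; the episode terminates at the horizon with a zero
bootstrap.  Forced actions (interruptions) are the single legal action of
their state and update normally, keeping backups well defined through
interruption chains.  Greedy ties break toward the lowest dose.

Defaults: α = 0.1, γ = 0.3, ε decaying geometrically 1.0 → 0.02 over
10000 episodes per patient (individual) and 200 round-robin sweeps
through the population (population agent).  Two defaults deserve
justification:

* **γ = 0.3.**  The 487-state coding carries no episode clock, so a state
  revisited within an episode closes a bootstrap loop whose fixed point
  approaches r/(1−γ).  Near γ = 1 this inflates the value of policies that
  revisit states (e.g. dose oscillations) by up to two orders of
  magnitude over any realizable 8-cycle return, and training reliably
  converges to such policies.  A short effective horizon (γ ≈ 0.3, look-
  ahead of a few cycles) removes the pathology while preserving enough
  foresight for titration, because the twin responds to a dose change
  within one cycle.
* **Small α, long schedule.**  All stochasticity in a backup comes from
  downstream policy churn under the ε floor.  Choosing the starting dose
  requires comparing 7 initial actions whose subtrees are explored
  unevenly and whose true values can differ by well under 1%; large step
  sizes (α ≥ 0.3) leave value noise above that margin and occasionally
  flip the greedy start toward a slightly worse, more aggressive dose.
  α = 0.1 with a long, mostly-greedy tail (ε floor 0.02 over 10000
  episodes) averages the churn away; with cycle outcomes memoised per
  dose prefix the long schedule still trains in seconds per patient.

The individual trainer uses the strict reward, the population trainer the
smoothed one (with a hard zero, a population agent is pushed toward
uniformly low doses by its most sensitive patients; smoothing restores the
efficacy gradient).  Because the twin is deterministic, cycle outcomes are
memoised per dose-sequence prefix, which makes late (mostly greedy)
episodes nearly free; a 4000-episode training runs in a few seconds.

The exhaustive-search oracle test uses a two-cycle horizon, where the
stationary table is exact (initial states occur only at the first decision
and every later state only at the second), α = 1 and γ = 1, under which
Q-learning on a deterministic MDP reduces to exact dynamic programming.

## The clinical benchmark

The rule-based protocol starts at 100 mg/day, confirms the dose when all
three endpoints are in range, steps +25 on inefficacy (including HCT ≥ 45%
alone), steps −25 on moderate toxicity (interrupting at the 50 mg floor)
and interrupts on severe toxicity.  Resumption — at 50 mg after a moderate
interruption once both lineages are back in range; one level below the
trigger (floored at 50) after a severe interruption once both are above
the severe threshold — reconstructs flow-chart internals that are not
printed in full; the reconstruction is constrained to emit only doses the
MDP's safety mask allows, which the test suite asserts on every cycle.

## Evaluation

Metrics are computed at daily resolution over days 1–224 (day 0 is the
baseline): %-days with each endpoint in range and with CHR; CHR at day
224; days until stable CHR (first 1-based day from which CHR holds to the
horizon — the strictest reading of "stable"; NaN when never reached);
any-severe flag and %-severe days; counts of contiguous moderate/severe
runs, dose changes between consecutive decisions, and interruption cycles.
Population summaries report medians with empirical 2.5/97.5 percentiles
(numpy linear interpolation).  Two comparison modes exist: a shared
population table against the protocol on k independent test sets with an
across-set roll-up (median of the k medians, 2.5th percentile of the k
2.5th percentiles, …), and a three-way comparison of individual agents,
the population agent and the protocol on one population — intentionally
the population the shared agent was trained on, its most favorable
conditions.

## Problem sizes

The package's own experiments run at desk scale: cohorts of 12–14 patients
(at least one per baseline stratum), 4000 training episodes per individual
agent and 150–200 population sweeps.  Typical observed outcomes at this
scale: individually-trained agents reach median %-days-in-CHR around
85–90% with zero severe-toxicity days, population agents and the clinical
protocol 5–15 percentage points lower, with the protocol showing severe
toxicity in roughly one patient in ten — the same qualitative ordering as
the full-scale clinical-simulation study this framework models, whose
original PK-PD model and 98-patient × 10-set design are not reproduced
here.

## Limitations

* The twin is a generic myelosuppression surrogate, not an estimated
  givinostat model: no covariates, inter-occasion variability or residual
  error; absolute outcome numbers are properties of this surrogate, not of
  the drug.
* The two calibration constraints guarantee that a safe and an effective
  dose exist for every sampled patient.  Passing safety and dominance
  checks therefore demonstrate that the learner *finds* such policies, not
  that they exist for arbitrary real patients.
* The discretized state is not strictly Markov with respect to the twin's
  continuous state (the same tuple can hide different transient phases);
  tabular Q-learning treats this as noise, and the small γ bounds the
  damage, but policies remain mildly sub-optimal in principle.
* Measurement error, mid-treatment phlebotomy and continuous dosing are
  out of scope.
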