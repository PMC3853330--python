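# Model and methods

## The model

`msabm` simulates a small patch of central-nervous-system white matter as a
toroidal square lattice (default 51 x 51 patches), each patch endowed with
`init_mye` = 100 units of myelin.  Three kinds of mobile agents live on the
lattice:

* **effector T cells (Teff)** — autoreactive cells that, once activated,
  attack the myelin of the patch they stand on;
* **regulatory T cells (Treg)** — cells that, once activated, hunt and
  suppress active Teff within a visibility radius;
* **viruses** — the environmental trigger (EBV-like): contact with a
  resting T cell activates it through molecular mimicry and consumes the
  virus.

The Teff/Treg pair forms a predator-prey loop: activated Teff grow by
duplication fueled by myelin (the prey's "food"), activated Treg grow by
duplicating after each successful suppression (the predator's positive
feedback).  A time step is 2.4 simulated hours (3650 steps/year); the
standard experiment runs 5 years = 18250 steps.

### Per-step schedule

1. **Pulse trains.**  Per species, a Bernoulli trial with probability
   `pulse_prob` = 100/365 introduces one agent on a uniformly random patch
   (resting state, life drawn uniformly on [1, 2*hlife]).  In the default
   `per_step` mode the trial runs every step; `per_day` mode (one trial per
   simulated day, i.e. every 10 steps) is selectable and yields on average
   100 impulses per species per year.
2. **Agent turns**, in a freshly shuffled order (randomized NetLogo-style
   `ask`).  Each agent acts on its state as of its turn and then steps to a
   uniformly random Von Neumann neighbor:
   * a resting T cell activates on the nearest virus within
     `virus_radius` (consuming it);
   * an active Teff attacks its patch's myelin (removing `eat_mye` = 5
     units, floored at 0) and, if the patch held any myelin, attempts
     duplication with probability

     p_e = eff_dup * (myelin / init_mye)^2 * mean_Tregs / (Treg_here + mean_Tregs)

     evaluated on the post-attack patch, where `Treg_here` counts active
     Tregs within `treg_radius`;
   * an active Treg suppresses the nearest active Teff within
     `treg_radius` (moving onto its patch) and, on success, attempts
     duplication with constant probability `p_t`.
   * Duplication is gated by patch crowding: if the parent's patch already
     holds `patch_density` = 3 agents, the parent relocates one patch and
     retries exactly once (fresh probability, fresh Bernoulli).  A newborn
     is active, placed on a random neighboring patch, and draws a fresh
     life counter; the parent's life counter is halved (floored, min 1).
3. **Myelin recovery.**  Every patch with 0 < myelin < init_mye regains
   `rec_mye` units (clamped at `init_mye`).  A patch at exactly 0 never
   recovers: its damage is permanent (a lesion).
4. **Aging.**  Every life counter decrements; agents at 0 are removed.

Damage is measured in myelin units: `recoverable` is the summed deficit of
patches that still hold myelin, `unrecoverable` is `init_mye` per bare
patch, `total` their sum (ceiling: 51^2 x 100 = 260 100).

### Scenarios and virtual patients

A *healthy* individual has matched maximum duplication rates
(`eff_dup` = `p_t` = 0.1 per step); a *hill* individual has impaired Treg
duplication (`p_t` = 0.025).  A virtual patient is a random seed: one seed
fully determines a trajectory, and a cohort is a list of seeds.  Cohorts
are compared by the median final total damage and a two-sample
Kolmogorov-Smirnov test (scipy's implementation; an independent
brute-force ECDF oracle backs it in the test suite).

Relapses are operationalized as episodes of new permanent damage: steps on
which unrecoverable damage strictly increases, merged when separated by at
most `merge_gap` = 10 steps (1 simulated day).

## Two engines, one model

The schedule and rules are implemented twice:

* a **reference engine** in transparent pure Python
  (`msabm.engine.step` and the rule functions in `msabm.dynamics`), which
  every rule-level unit test exercises directly; and
* a **fast engine** (`msabm.engine_fast`, numba-compiled flat-array
  state with per-patch doubly-linked agent buckets), the default for
  `run_simulation` and hence for cohort experiments, roughly 10x faster
  at full scale.

The two consume different random streams, so individual trajectories
differ; the test suite checks them against each other statistically (a
closed-form immigration-death steady state with duplication disabled, and
a KS comparison of final-damage distributions) and checks the shared
invariants (monotone permanent damage, myelin bounds, no damage without
the viral trigger, bit-reproducibility per engine) on both.

## Determinism

Within either engine a run is a pure function of (parameters, seed).  The
reference engine draws rule decisions from one `random.Random` stream in
schedule order, with a same-seeded numpy generator supplying turn
permutations and movement directions; the fast engine uses a single
seeded Mersenne-Twister stream.  Searches for the nearest virus or prey
scan the neighborhood in rings of increasing distance and break exact
ties uniformly at random.

## Parameters without published values (calibration)

Four constants are required by the rules but have no published value.
They were fixed once, before the cohort experiments, as follows, and are
all exposed in the configuration file:

* **`rec_mye` = 13 units/step.**  The recovery rate has a sharp regime
  structure relative to the attack rate: at most `patch_density` = 3 Teff
  can occupy a patch, so the maximal drain is 15 units/step.  For
  `rec_mye` <= 10 even two co-located attackers make net progress and
  lesions spread almost unconditionally; for `rec_mye` >= 15 no siege can
  ever bare a patch and permanent damage is structurally impossible.  The
  interesting regime is 10 < rec_mye < 15, where only a maximal, sustained
  siege (three attackers for tens of steps) produces a lesion — this is
  what lets healthy individuals absorb flares with little or no permanent
  damage while runaway flares in hill individuals still scar.  Within that
  regime the value 13 was chosen because the simulated hill-cohort median
  best approximates the reported one.
* **`mean_Tregs` = 1 cell.**  The half-saturation of the Treg-mediated
  suppression of Teff duplication.  Cross-balance requires that a
  realistic local Treg presence can drive net Teff growth negative: with
  net growth eff_dup * K/(T+K) - 1/hlife, suppression to below the death
  rate needs T > 5K active Tregs within the 29-patch visibility disk.
  The patch-crowding cap makes T ~ 50 (needed for K = 10) unreachable in
  practice, whereas T ~ 5 (K = 1) is routinely achieved around a flare, so
  K = 1 is the value at which the advertised regulation mechanism can
  actually operate.
* **`virus_radius` = 3 patches**, mirroring the published Treg visibility
  radius: activation and suppression are both short-range contact
  processes.
* **`agents_per_pulse` = 1**: a pulse is the escape of a single
  self-reactive clone from thymic selection, the smallest biologically
  meaningful amplitude.

**Pulse mode.**  The source description of the pulse trains is internally
inconsistent: the stated mechanism (a Bernoulli trial with p = 100/365 at
*every* 2.4-hour step) yields ~1000 impulses per species-year, while the
stated rate is 100 per year.  The default here follows the mechanism
(`per_step`), because the resulting standing populations of resting cells
and viruses (~16 each) are what make continuous immune surveillance — and
with it the healthy/hill contrast — possible at all; with day-level trials
(~1.6 standing agents per species) activated Tregs are almost never
present, flares burn unopposed, and both scenarios collapse onto
near-total tissue destruction.  `per_day` mode preserves the
100-impulses-per-year reading and remains selectable.

## What the defaults reproduce, and what they do not

With these defaults the model reproduces the qualitative phenotype
contrast: hill cohorts accumulate large permanent damage concentrated in
the first half of the horizon (declining relapse rate), healthy cohorts
usually end with zero or near-zero permanent damage, and the two arms are
cleanly separable (large KS distance).  Because four constants are free,
the *absolute* cohort medians are calibration-dependent; the hill median
lands near the reported value by construction of the `rec_mye` choice,
while the healthy median here is lower than the reported one (our healthy
runs recover almost completely; reproducing a healthy median of several
thousand units while simultaneously keeping permanent damage at zero is
not achievable under any single calibration of this rule set, since
standing recoverable damage of that size requires slow recovery, which in
turn produces lesions).  The arms separate more sharply here (KS D near 1
at 20 + 20 patients) than reported (D = 0.75 at 100 + 100), which would
require substantial between-arm overlap — i.e. frequent catastrophic
healthy patients and mild hill patients — that this calibration does not
produce.

## Numerical choices and edge cases

* Attack clamps myelin at 0 and still grants duplication eligibility (the
  eligibility test is the *pre*-attack myelin; p_e then uses the
  post-attack value, which may be 0).
* The duplication Bernoulli is evaluated before the crowding gate; exactly
  one relocate-and-retry per attempt guarantees termination.
* `Treg_here` counts active Tregs only (resting cells release no
  inhibitory signal), inclusively within Euclidean distance
  `treg_radius` on the torus.
* The fast path of the Teff turn draws the uniform deviate first and
  counts neighborhood Tregs only when the deviate clears the myelin-only
  upper bound on p_e; the realized law is exactly Bernoulli(p_e).
* Damage medians use the midpoint convention for even cohort sizes.
* With `grid_size` < 2*radius + 1 the neighborhood tables deduplicate
  wrapped offsets, so tiny test lattices behave correctly.

## Problem sizes

The cohort experiment uses 20 virtual patients per arm at the full 5-year
horizon (18250 steps, 51 x 51 lattice); the published experiment used 100
per arm.  Property checks in the test suite use shorter horizons (hundreds
of steps) and smaller lattices (15-21 patches across), which are large
enough to exercise every rule including torus wrap-around.

## Known limitations

* No explicit antigen-presenting cells, cytokine fields, lymphoid
  compartments, or blood-brain barrier: activation is collapsed into
  direct virus contact, inhibition into a saturating count of nearby
  active Tregs.
* Viruses neither replicate nor persist latently; they are consumed on
  contact.
* The lattice is a closed torus: flares cannot drain into surrounding
  tissue, which likely sharpens the all-or-nothing character of runs.
* Clinical mapping (EDSS, MRI lesion counts) is out of scope; "relapse"
  here means new permanent damage only.
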