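"""State-transition rules of the model, one function per rule.

The model couples three agent populations on a myelinated lattice:

* resting effector and regulatory T cells enter via stochastic pulse
  trains and are activated by contact with a virus (molecular mimicry);
* active effector T cells (Teff) attack the myelin of their patch and,
  on a successful attack, may duplicate with a probability that grows with
  local myelin and is suppressed by nearby active regulatory T cells;
* active regulatory T cells (Treg) hunt active Teff within a visibility
  radius, suppress them, and may duplicate on success (positive feedback);
* myelin regrows at a fixed rate on damaged patches unless the patch was
  stripped bare, in which case the damage is permanent.

Every function mutates the World in place and consumes random numbers
exclusively from ``world.rng``, so the engine's fixed schedule makes runs
reproducible from the seed alone.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .geometry import Position
from .params import Params
from .world import Agent, CellState, Species, World, draw_initial_life


@dataclass(frozen=True)
class PulseEvent:
    """One successful pulse-train impulse for one species."""

    species: Species
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("pulse count must be >= 1")


def pulse_events(step: int, params: Params, rng: random.Random) -> list[PulseEvent]:
    """Bernoulli pulse-train trials for Teff, Treg and virus at this step.

    In ``per_day`` mode the three trials are performed only on steps that
    start a new simulated day (every ``params.steps_per_day`` steps), each
    with success probability ``pulse_prob``; at the default probability of
    100/365 per day this yields on average 100 impulses per species per
    year.  In ``per_step`` mode the trials run on every step.  Each success
    contributes one event of ``agents_per_pulse`` agents.
    """
    if step < 0:
        raise ValueError("step must be >= 0")
    if params.pulse_mode == "per_day" and step % params.steps_per_day != 0:
        return []
    events = []
    for species in (Species.TEFF, Species.TREG, Species.VIRUS):
        p = (
            params.effective_virus_pulse_prob
            if species is Species.VIRUS
            else params.pulse_prob
        )
        if p > 0.0 and rng.random() < p:
            events.append(PulseEvent(species, params.agents_per_pulse))
    return events


def introduce_agents(world: World, events: list[PulseEvent]) -> list[Agent]:
    """Place pulse-train arrivals on uniformly random patches.

    T cells enter resting; viruses carry no state.  Every arrival gets a
    fresh life draw from the uniform [1, 2*hlife] distribution.
    """
    born = []
    for ev in events:
        state = None if ev.species is Species.VIRUS else CellState.RESTING
        for _ in range(ev.count):
            pos = world.random_position()
            life = draw_initial_life(world.params.hlife, world.rng)
            born.append(world.spawn(ev.species, state, pos, life))
    return born


def move_agent(world: World, agent: Agent) -> Position:
    """Relocate an agent to one of its 4 Von Neumann neighbors, uniformly."""
    return world.move_random(agent)


def activate_by_virus(world: World, tcell: Agent) -> bool:
    """Resting T cell + virus contact: viral trigger via molecular mimicry.

    If at least one virus lies within ``virus_radius`` of the resting cell,
    the nearest one (ties broken uniformly at random) is consumed and the
    cell switches to the active state.  Returns True iff activation fired.
    """
    if tcell.species is Species.VIRUS or tcell.state is not CellState.RESTING:
        raise ValueError("activate_by_virus requires a resting T cell")
    virus = world.nearest_in_class("virus", tcell.pos, world.params.virus_radius)
    if virus is None:
        return False
    world.remove(virus)
    world.set_state(tcell, CellState.ACTIVE)
    return True


def teff_attack(world: World, teff: Agent) -> bool:
    """Active Teff attacks the myelin of its patch.

    Removes ``eat_mye`` units (floored at 0).  Returns True iff the patch
    held any myelin before the attack — the condition for the Teff to be
    eligible to duplicate this step.  A bare (zero-myelin) patch yields no
    attack and no duplication eligibility.
    """
    if teff.species is not Species.TEFF or teff.state is not CellState.ACTIVE:
        raise ValueError("teff_attack requires an active Teff")
    i, j = teff.pos
    m = world.myelin[i, j]
    if m <= 0.0:
        return False
    world.myelin[i, j] = max(0.0, m - world.params.eat_mye)
    return True


def teff_duplication_probability(
    myelin: float, params: Params, treg_here: int
) -> float:
    """Duplication probability of an attack-eligible active Teff.

    p_e = eff_dup * (myelin^2 / init_mye^2) * (mean_Tregs / (treg_here + mean_Tregs))

    The quadratic myelin term favors duplication on well-myelinated patches;
    the saturating Treg term models cytokine-mediated down-regulation by
    nearby active regulatory cells (half suppression at treg_here ==
    mean_Tregs).  Always in [0, eff_dup].
    """
    if not 0.0 <= myelin <= params.init_mye:
        raise ValueError(f"myelin must be in [0, {params.init_mye}], got {myelin}")
    if treg_here < 0:
        raise ValueError("treg_here must be >= 0")
    return (
        params.eff_dup
        * (myelin * myelin)
        / (params.init_mye * params.init_mye)
        * params.mean_Tregs
        / (treg_here + params.mean_Tregs)
    )


def count_tregs_in_radius(world: World, pos: Position, radius: float) -> int:
    """Number of *active* Tregs within `radius` (inclusive) of a position.

    Only active Tregs count: the inhibitory cytokines that down-regulate
    Teff duplication are released by activated regulatory cells.
    """
    return world.count_in_class("treg_active", pos, radius)


def attempt_duplication(
    world: World,
    parent: Agent,
    prob: float,
    recompute: Optional[Callable[[World, Agent], float]] = None,
) -> Optional[Agent]:
    """One duplication attempt for an eligible active cell.

    Bernoulli(prob) first; on success the patch crowding gate applies: the
    newborn is created only if the total number of agents on the parent's
    patch is below ``patch_density``.  If the patch is crowded the parent
    moves to a random Von Neumann neighbor and exactly one retry is made —
    fresh probability (via `recompute`, e.g. re-evaluating p_e on the new
    patch) and a fresh Bernoulli — after which the attempt ends for this
    step.  The newborn is born active on a random neighboring patch with a
    fresh life draw and is exempt from the crowding check at placement; the
    parent pays for duplication with its life counter halved (floored,
    minimum 1).
    """
    if parent.state is not CellState.ACTIVE:
        raise ValueError("only active cells may duplicate")
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"prob must be in [0, 1], got {prob}")
    rng = world.rng
    for retry in (False, True):
        if rng.random() >= prob:
            return None
        if world.patch_count(parent.pos) < world.params.patch_density:
            child_pos = world.random_neighbor(parent.pos)
            life = draw_initial_life(world.params.hlife, rng)
            child = world.spawn(parent.species, CellState.ACTIVE, child_pos, life)
            parent.life = max(1, parent.life // 2)
            return child
        if retry:
            return None
        world.relocate(parent, world.random_neighbor(parent.pos))
        if recompute is not None:
            prob = recompute(world, parent)
    return None


def teff_turn(world: World, teff: Agent) -> bool:
    """One active-Teff turn: myelin attack plus, if eligible, a duplication
    attempt at the probability law evaluated on the post-attack patch.

    Fused fast path equivalent to ``teff_attack`` followed by
    ``attempt_duplication`` at ``teff_duplication_probability``: the uniform
    deviate is drawn first and the neighborhood Treg count is evaluated only
    when the deviate already clears the myelin-only upper bound
    eff_dup * m^2 / init_mye^2 >= p_e, which leaves the Bernoulli(p_e) law
    exact while skipping most radius scans.  Returns True iff an attack
    occurred.
    """
    if teff.species is not Species.TEFF or teff.state is not CellState.ACTIVE:
        raise ValueError("teff_turn requires an active Teff")
    mye = world._mye_flat
    idx = teff._idx
    m = mye[idx].item()
    if m <= 0.0:
        return False
    m = m - world._eat
    if m < 0.0:
        m = 0.0
    mye[idx] = m

    rng = world.rng
    scale = world._dup_scale
    K = world._K
    for retry in (False, True):
        u = rng.random()
        bound = scale * m * m
        if u >= bound:
            return True
        treg_here = world.count_in_class("treg_active", teff.pos, world._treg_radius)
        if u >= bound * K / (treg_here + K):
            return True
        if world._patch_total[teff._idx] < world._density:
            child_pos = world.random_neighbor(teff.pos)
            life = draw_initial_life(world._hlife, rng)
            world.spawn(Species.TEFF, CellState.ACTIVE, child_pos, life)
            teff.life = max(1, teff.life // 2)
            return True
        if retry:
            return True
        world.relocate(teff, world.random_neighbor(teff.pos))
        m = mye[teff._idx].item()  # p_e is re-evaluated on the new patch
    return True


def treg_turn(world: World, treg: Agent) -> bool:
    """One active-Treg turn: hunt and suppress, then a duplication attempt
    at the constant rate p_t on success.  Returns True iff a suppression
    occurred."""
    if not treg_suppress(world, treg):
        return False
    attempt_duplication(world, treg, world.params.p_t)
    return True


def treg_suppress(world: World, treg: Agent) -> bool:
    """Active Treg hunts the nearest active Teff within its visibility radius.

    On success the Teff is removed, the Treg moves onto the Teff's patch,
    and the Treg becomes eligible to duplicate.  Ties at equal distance are
    broken uniformly at random.  Returns True iff a suppression occurred.
    """
    if treg.species is not Species.TREG or treg.state is not CellState.ACTIVE:
        raise ValueError("treg_suppress requires an active Treg")
    prey = world.nearest_in_class("teff_active", treg.pos, world.params.treg_radius)
    if prey is None:
        return False
    target = prey.pos
    world.remove(prey)
    world.relocate(treg, target)
    return True


def recover_myelin(world: World) -> float:
    """Regrow myelin on recoverably damaged patches; return total units restored.

    Every patch with 0 < myelin < init_mye gains min(rec_mye, deficit).
    Patches at exactly 0 are permanently demyelinated and never recover.
    """
    m = world.myelin
    init = world.params.init_mye
    mask = (m > 0.0) & (m < init)
    if not mask.any():
        return 0.0
    gain = np.minimum(world.params.rec_mye, init - m[mask])
    m[mask] += gain
    return float(gain.sum())


def decrement_life_and_reap(world: World) -> int:
    """Age every agent by one step and remove those whose life hits 0."""
    removed = 0
    for a in world.agents:
        if not a.alive:
            continue
        a.life -= 1
        if a.life <= 0:
            world.remove(a)
            removed += 1
    world.compact()
    return removed
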