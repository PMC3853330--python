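"""Simulation engine: canonical per-step schedule, full-run driver, recorders.

Each time step applies, in a fixed order:

1. stochastic pulse trains (new resting T cells and viruses);
2. one pass over all agents in a freshly shuffled order, in which each
   agent takes its turn — resting T cells try to activate on a nearby
   virus; active Teff attack myelin and, if the attack landed, attempt
   duplication; active Tregs hunt and suppress active Teff and, on
   success, attempt duplication — and then steps to a random Von Neumann
   neighbor;
3. myelin recovery on recoverably damaged patches;
4. life-counter decrement and removal of expired agents.

The shuffled turn order emulates NetLogo's randomized ``ask`` semantics
while keeping the consumption order of the single random stream
deterministic, so a run is a pure function of (params, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import (
    activate_by_virus,
    decrement_life_and_reap,
    introduce_agents,
    pulse_events,
    recover_myelin,
    teff_turn,
    treg_turn,
)
from .params import Params
from .world import World

logger = logging.getLogger(__name__)

TIMESERIES_COLUMNS = (
    "step",
    "teff_resting",
    "teff_active",
    "treg_resting",
    "treg_active",
    "virus",
    "recoverable",
    "unrecoverable",
    "total",
)

#: snapshot category codes
INTACT, RECOVERABLE, UNRECOVERABLE = 0, 1, 2


@dataclass(frozen=True)
class DamageRecord:
    """Tissue damage in myelin units at one instant.

    recoverable: summed myelin deficit of patches that still hold myelin;
    unrecoverable: init_mye per fully demyelinated patch (permanent lesion);
    total: their sum.
    """

    recoverable: float
    unrecoverable: float

    @property
    def total(self) -> float:
        return self.recoverable + self.unrecoverable


def compute_damage(world: World) -> DamageRecord:
    """Damage accounting in myelin units.

    A patch at zero myelin contributes its full initial endowment
    (init_mye) to the unrecoverable pool; any other patch contributes its
    current deficit to the recoverable pool.
    """
    m = world.myelin
    init = world.params.init_mye
    bare = m == 0.0
    unrec = float(init * bare.sum())
    rec = float((init - m[~bare]).sum())
    return DamageRecord(recoverable=rec, unrecoverable=unrec)


@dataclass
class Snapshot:
    """Final spatial state: raw myelin plus 3-level damage categories."""

    myelin: np.ndarray
    categories: np.ndarray  # INTACT / RECOVERABLE / UNRECOVERABLE per patch


def snapshot(world: World) -> Snapshot:
    m = world.myelin.copy()
    init = world.params.init_mye
    cats = np.full(m.shape, RECOVERABLE, dtype=np.int8)
    cats[m >= init] = INTACT
    cats[m == 0.0] = UNRECOVERABLE
    return Snapshot(myelin=m, categories=cats)


@dataclass
class TimeSeries:
    """Per-step population counts and damage levels, including step 0."""

    steps: list[int] = field(default_factory=list)
    teff_resting: list[int] = field(default_factory=list)
    teff_active: list[int] = field(default_factory=list)
    treg_resting: list[int] = field(default_factory=list)
    treg_active: list[int] = field(default_factory=list)
    virus: list[int] = field(default_factory=list)
    recoverable: list[float] = field(default_factory=list)
    unrecoverable: list[float] = field(default_factory=list)
    total: list[float] = field(default_factory=list)

    def record(self, world: World) -> None:
        counts = world.population_counts()
        damage = compute_damage(world)
        self.steps.append(world.step_count)
        self.teff_resting.append(counts["teff_resting"])
        self.teff_active.append(counts["teff_active"])
        self.treg_resting.append(counts["treg_resting"])
        self.treg_active.append(counts["treg_active"])
        self.virus.append(counts["virus"])
        self.recoverable.append(damage.recoverable)
        self.unrecoverable.append(damage.unrecoverable)
        self.total.append(damage.total)

    def __len__(self) -> int:
        return len(self.steps)

    def final_damage(self) -> DamageRecord:
        return DamageRecord(
            recoverable=self.recoverable[-1], unrecoverable=self.unrecoverable[-1]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": self.steps,
                "teff_resting": self.teff_resting,
                "teff_active": self.teff_active,
                "treg_resting": self.treg_resting,
                "treg_active": self.treg_active,
                "virus": self.virus,
                "recoverable": self.recoverable,
                "unrecoverable": self.unrecoverable,
                "total": self.total,
            }
        )


def step(world: World) -> World:
    """Advance the world by one time step under the canonical schedule."""
    from .world import TEFF_ACTIVE, TEFF_RESTING, TREG_ACTIVE, TREG_RESTING

    rng = world.rng

    # 1. pulse trains
    events = pulse_events(world.step_count, world.params, rng)
    introduce_agents(world, events)

    # 2. one pass over all agents in a freshly shuffled order; each agent
    #    acts on its state as of its turn and then moves (randomized
    #    NetLogo-style "ask" semantics).  Agents born during the pass act
    #    from the next step on.
    # the master list holds only living agents at phase start (the reap at
    # the end of the previous step compacted it)
    alive = world.agents
    order_rng = world._order_rng
    order = [alive[k] for k in order_rng.permutation(len(alive)).tolist()]
    directions = order_rng.integers(0, 4, size=len(order)).tolist()
    move = world.move_random
    for agent, direction in zip(order, directions):
        if not agent.alive:
            continue  # suppressed or consumed earlier this pass
        cls = agent._cls
        if cls == TEFF_ACTIVE:
            teff_turn(world, agent)
        elif cls == TREG_ACTIVE:
            treg_turn(world, agent)
        elif cls == TEFF_RESTING or cls == TREG_RESTING:
            activate_by_virus(world, agent)
        move(agent, direction)

    # 3. myelin recovery
    recover_myelin(world)

    # 4. aging and death
    decrement_life_and_reap(world)

    world.step_count += 1
    return world


def run_simulation(
    params: Params, seed: int, steps: int, engine: str = "fast"
) -> tuple[TimeSeries, World]:
    """Simulate one virtual patient for `steps` time steps.

    Returns the full per-step TimeSeries (length steps + 1, including the
    initial state) and the final World for spatial inspection.

    `engine` selects the implementation: ``"fast"`` (default) runs the
    compiled engine in :mod:`msabm.engine_fast`; ``"reference"`` runs the
    transparent pure-Python schedule below.  Both implement the identical
    rules; each is bit-reproducible from (params, seed).  The fast engine
    returns a World carrying the final lattice state and step counter but
    no materialized agent list.
    """
    if steps < 0:
        raise ValueError("steps must be >= 0")
    if engine == "fast":
        from .engine_fast import run_fast

        counts, damage, myelin = run_fast(params, seed, steps)
        ts = TimeSeries(
            steps=list(range(steps + 1)),
            teff_resting=counts[:, 0].tolist(),
            teff_active=counts[:, 1].tolist(),
            treg_resting=counts[:, 2].tolist(),
            treg_active=counts[:, 3].tolist(),
            virus=counts[:, 4].tolist(),
            recoverable=damage[:, 0].tolist(),
            unrecoverable=damage[:, 1].tolist(),
            total=damage[:, 2].tolist(),
        )
        world = World(params, seed)
        world.myelin[:, :] = myelin
        world.step_count = steps
        return ts, world
    if engine != "reference":
        raise ValueError(f"engine must be 'fast' or 'reference', got {engine!r}")
    world = World(params, seed)
    ts = TimeSeries()
    ts.record(world)
    log_every = params.steps_per_year
    for _ in range(steps):
        step(world)
        ts.record(world)
        if world.step_count % log_every == 0:
            counts = world.population_counts()
            dmg = ts.final_damage()
            logger.info(
                "seed=%d year=%.1f agents=%s damage=(rec=%.0f unrec=%.0f)",
                seed,
                world.step_count / params.steps_per_year,
                counts,
                dmg.recoverable,
                dmg.unrecoverable,
            )
    return ts, world
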