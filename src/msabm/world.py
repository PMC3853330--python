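"""The simulated world: lattice state, agent population, and the random stream.

A :class:`World` is fully determined by its :class:`~msabm.params.Params`
and an integer seed (the "virtual patient" identity): one pseudo-random
stream is seeded once and every stochastic rule consumes from it in the
canonical schedule order, so identical (params, seed) pairs reproduce
identical trajectories bit for bit.

Myelin is held in a dense grid_size x grid_size array.  Agents (effector T
cells, regulatory T cells, viruses) are indexed per (species, state) class
on flat per-patch lists with precomputed neighborhood tables, so nearest-
target searches and radius counts stay O(patches in radius) with small
constants even when flares push the population into the thousands.
"""

from __future__ import annotations

import random
from enum import Enum
from functools import lru_cache
from typing import Iterable, Optional

import numpy as np

from .geometry import Position, ring_offsets, von_neumann_neighbors
from .params import Params


class Species(Enum):
    TEFF = "teff"
    TREG = "treg"
    VIRUS = "virus"


class CellState(Enum):
    RESTING = "resting"
    ACTIVE = "active"


def draw_initial_life(hlife: int, rng: random.Random) -> int:
    """Draw an agent's initial life counter: uniform on [1, 2*hlife] steps.

    The expected value is hlife + 0.5 steps, so `hlife` plays the role of
    the mean half-life of the species.
    """
    if hlife < 1:
        raise ValueError(f"hlife must be >= 1, got {hlife}")
    return rng.randint(1, 2 * hlife)


# class indices for the per-class occupancy stores
TEFF_RESTING, TEFF_ACTIVE, TREG_RESTING, TREG_ACTIVE, VIRUS = range(5)

CLASS_KEYS = (
    "teff_resting",
    "teff_active",
    "treg_resting",
    "treg_active",
    "virus",
)

_CLASS_INDEX = {k: i for i, k in enumerate(CLASS_KEYS)}


@lru_cache(maxsize=None)
def _nbr4_table(n: int) -> tuple[tuple[tuple[int, Position], ...], ...]:
    """Per-patch Von Neumann neighbors as (flat index, position) pairs."""
    return tuple(
        tuple((q[0] * n + q[1], q) for q in von_neumann_neighbors((i, j), n))
        for i in range(n)
        for j in range(n)
    )


@lru_cache(maxsize=None)
def _ring_table(n: int, radius: float) -> tuple[tuple[tuple[int, ...], ...], ...]:
    """Per-patch groups of flat indices within `radius`, nearest first."""
    offsets = ring_offsets(n, radius)
    table = []
    for i in range(n):
        for j in range(n):
            table.append(
                tuple(
                    tuple(((i + di) % n) * n + (j + dj) % n for di, dj in group)
                    for _, group in offsets
                )
            )
    return tuple(table)


def _class_of(species: Species, state: Optional[CellState]) -> int:
    if species is Species.VIRUS:
        return VIRUS
    if species is Species.TEFF:
        return TEFF_RESTING if state is CellState.RESTING else TEFF_ACTIVE
    return TREG_RESTING if state is CellState.RESTING else TREG_ACTIVE


class Agent:
    """One mobile agent.  Viruses carry no activation state (state is None)."""

    __slots__ = ("species", "state", "life", "pos", "alive", "_idx", "_cls")

    def __init__(
        self,
        species: Species,
        state: Optional[CellState],
        life: int,
        pos: Position,
    ) -> None:
        if species is Species.VIRUS and state is not None:
            raise ValueError("viruses have no activation state")
        if species is not Species.VIRUS and state is None:
            raise ValueError("T cells must have an activation state")
        if life < 1:
            raise ValueError(f"life must be >= 1, got {life}")
        self.species = species
        self.state = state
        self.life = life
        self.pos = pos
        self.alive = True
        self._idx = -1
        self._cls = _class_of(species, state)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        st = self.state.value if self.state is not None else "-"
        return f"Agent({self.species.value}, {st}, life={self.life}, pos={self.pos})"


class World:
    """Toroidal lattice + agent population + step counter."""

    def __init__(self, params: Params, seed: int) -> None:
        self.params = params
        self.seed = seed
        self.rng = random.Random(seed)
        n = params.grid_size
        self._n = n
        self.myelin = np.full((n, n), float(params.init_mye))
        self._mye_flat = self.myelin.ravel()  # shared-memory view, hot path
        self.agents: list[Agent] = []
        self.step_count = 0
        # secondary stream for turn-order permutations (seed-determined)
        self._order_rng = np.random.default_rng(seed)
        # rule constants hoisted out of the per-agent hot path
        self._eat = float(params.eat_mye)
        self._dup_scale = params.eff_dup / (params.init_mye * params.init_mye)
        self._K = float(params.mean_Tregs)
        self._treg_radius = float(params.treg_radius)
        self._density = int(params.patch_density)
        self._hlife = int(params.hlife)
        n2 = n * n
        # per-class, per-patch agent lists, flat-indexed by row*n + col
        self._occ: list[list[list[Agent]]] = [
            [[] for _ in range(n2)] for _ in CLASS_KEYS
        ]
        self._patch_total: list[int] = [0] * n2
        self._counts: list[int] = [0] * len(CLASS_KEYS)
        # per-patch Von Neumann neighbors, shared across Worlds of this size
        self._nbr4 = _nbr4_table(n)

    def _rings_for(self, radius: float) -> tuple[tuple[tuple[int, ...], ...], ...]:
        return _ring_table(self._n, radius)

    # -- population bookkeeping -------------------------------------------

    def spawn(
        self,
        species: Species,
        state: Optional[CellState],
        pos: Position,
        life: int,
    ) -> Agent:
        agent = Agent(species, state, life, pos)
        agent._idx = pos[0] * self._n + pos[1]
        self.agents.append(agent)
        self._occ[agent._cls][agent._idx].append(agent)
        self._patch_total[agent._idx] += 1
        self._counts[agent._cls] += 1
        return agent

    def remove(self, agent: Agent) -> None:
        agent.alive = False
        self._occ[agent._cls][agent._idx].remove(agent)
        self._patch_total[agent._idx] -= 1
        self._counts[agent._cls] -= 1

    def relocate(self, agent: Agent, pos: Position) -> None:
        idx = pos[0] * self._n + pos[1]
        if idx == agent._idx:
            return
        cell_lists = self._occ[agent._cls]
        cell_lists[agent._idx].remove(agent)
        self._patch_total[agent._idx] -= 1
        agent._idx = idx
        agent.pos = pos
        cell_lists[idx].append(agent)
        self._patch_total[idx] += 1

    def move_random(self, agent: Agent, direction: Optional[int] = None) -> Position:
        """Step the agent to a uniformly chosen Von Neumann neighbor.

        `direction` (0-3) may be supplied by the caller (the engine batches
        the draws per step); otherwise it is drawn from the main stream.
        """
        if direction is None:
            direction = self.rng.getrandbits(2)
        idx, pos = self._nbr4[agent._idx][direction]
        cell_lists = self._occ[agent._cls]
        cell_lists[agent._idx].remove(agent)
        self._patch_total[agent._idx] -= 1
        agent._idx = idx
        agent.pos = pos
        cell_lists[idx].append(agent)
        self._patch_total[idx] += 1
        return pos

    def set_state(self, agent: Agent, state: CellState) -> None:
        """Switch a T cell's activation state, reindexing it."""
        if agent.species is Species.VIRUS:
            raise ValueError("viruses have no activation state")
        if agent.state is state:
            return
        self._occ[agent._cls][agent._idx].remove(agent)
        self._counts[agent._cls] -= 1
        agent.state = state
        agent._cls = _class_of(agent.species, state)
        self._occ[agent._cls][agent._idx].append(agent)
        self._counts[agent._cls] += 1

    def compact(self) -> None:
        """Drop dead agents from the master list."""
        self.agents = [a for a in self.agents if a.alive]

    # -- spatial queries ---------------------------------------------------

    def patch_count(self, pos: Position) -> int:
        """Number of agents (all species) currently on a patch."""
        return self._patch_total[pos[0] * self._n + pos[1]]

    def occupancy_at(self, pos: Position) -> list[Agent]:
        """All agents on one patch (across classes; order unspecified)."""
        idx = pos[0] * self._n + pos[1]
        out: list[Agent] = []
        for cls_lists in self._occ:
            out.extend(cls_lists[idx])
        return out

    def random_position(self) -> Position:
        n = self._n
        return (self.rng.randrange(n), self.rng.randrange(n))

    def random_neighbor(self, pos: Position) -> Position:
        return self._nbr4[pos[0] * self._n + pos[1]][self.rng.getrandbits(2)][1]

    def nearest_in_class(
        self, key: str, pos: Position, radius: float
    ) -> Optional[Agent]:
        """Nearest agent of a class within `radius` (torus Euclidean, inclusive).

        Ties at the minimal distance are broken uniformly at random.
        Returns None when the neighborhood holds no such agent.
        """
        cls = _CLASS_INDEX[key]
        if not self._counts[cls]:
            return None
        cell_lists = self._occ[cls]
        for group in self._rings_for(radius)[pos[0] * self._n + pos[1]]:
            candidates: list[Agent] = []
            for idx in group:
                cell = cell_lists[idx]
                if cell:
                    candidates.extend(cell)
            if candidates:
                if len(candidates) == 1:
                    return candidates[0]
                return self.rng.choice(candidates)
        return None

    def count_in_class(self, key: str, pos: Position, radius: float) -> int:
        """Number of agents of a class within `radius` of pos (inclusive)."""
        cls = _CLASS_INDEX[key]
        if not self._counts[cls]:
            return 0
        cell_lists = self._occ[cls]
        total = 0
        for group in self._rings_for(radius)[pos[0] * self._n + pos[1]]:
            for idx in group:
                cell = cell_lists[idx]
                if cell:
                    total += len(cell)
        return total

    # -- observables -------------------------------------------------------

    def population_counts(self) -> dict[str, int]:
        """Counts of each species/state class among living agents."""
        return dict(zip(CLASS_KEYS, self._counts))

    def living_agents(self) -> Iterable[Agent]:
        return (a for a in self.agents if a.alive)
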