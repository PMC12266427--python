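"""Discrete-time birth-death process with mutation accumulation.

At every step a uniformly chosen cell divides with probability beta or dies
with probability delta = 1 - beta.  On division the mother is replaced by
two daughters; each daughter inherits all of the mother's mutations and
independently acquires U ~ dist(mu) brand-new mutations under the
infinite-sites approximation (every mutation id is globally unique and
never reused).  The mutations one daughter gains in one division form a
"division block"; a block is recorded even when U = 0, so that a cell's
division count always equals the number of blocks along its lineage.

All expectations downstream are conditioned on survival of the whole
population, which the simulator realises by rejection: a run whose
population hits zero before the stopping rule fires is discarded and
restarted with fresh draws from the same seeded stream, so a whole
conditioned ensemble is reproducible from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .distributions import MutationDistribution, mutation_distribution

__all__ = [
    "SimulationConfig",
    "CellRecord",
    "PopulationState",
    "StepEvent",
    "RunResult",
    "draw_mutation_count",
    "step",
    "run",
    "run_trajectory_sizes",
]

DEFAULT_MAX_RESTARTS = 1_000_000


@dataclass(frozen=True)
class SimulationConfig:
    """All parameters of one birth-death-with-mutations run.

    ``stop`` is ``("size", N)`` — stop the first time the population
    reaches N cells — or ``("steps", i)`` — stop after exactly i Markov
    steps.  ``delta`` is always derived as 1 - beta.
    """

    beta: float = 1.0
    mu: float = 0.0
    n0: int = 1
    stop: tuple[Literal["size", "steps"], int] = ("size", 100)
    mutation_dist: str | MutationDistribution = "poisson"
    track_matrix: bool = False
    seed: int | None = None
    max_restarts: int = DEFAULT_MAX_RESTARTS

    def __post_init__(self) -> None:
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must be in (0, 1]")
        if self.beta <= self.delta:
            raise ValueError(
                "only the growing-population case beta > delta is supported"
            )
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.n0 < 1:
            raise ValueError("n0 must be >= 1")
        kind, target = self.stop
        if kind not in ("size", "steps"):
            raise ValueError(f"unknown stopping rule {kind!r}")
        if kind == "size" and target < self.n0:
            raise ValueError("size stop target must be >= n0")
        if kind == "steps" and target < 0:
            raise ValueError("step stop target must be >= 0")
        # materialise the distribution once so bad specs fail early
        object.__setattr__(self, "_dist", self.distribution())

    @property
    def delta(self) -> float:
        return 1.0 - self.beta

    @property
    def pure_birth(self) -> bool:
        return self.beta == 1.0

    def distribution(self) -> MutationDistribution:
        return mutation_distribution(self.mutation_dist, mean=self.mu)

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class CellRecord:
    """A living cell: its mutation ids, division-block ids and counters.

    ``burden`` == len(mutations) and ``divisions`` == len(blocks) whenever
    full tracking is on.
    """

    mutations: set[int] = field(default_factory=set)
    blocks: tuple[int, ...] = ()
    divisions: int = 0

    @property
    def burden(self) -> int:
        return len(self.mutations)


class PopulationState:
    """Living cells plus bookkeeping counters at Markov step ``i``.

    Two storage modes share one event interface so that both consume the
    random stream identically:

    * full mode (``track_ids=True``): per-cell mutation-id sets and block
      ids, a global abundance table (mutation id -> number of living
      carriers), and a block registry (block id -> tuple of mutation ids,
      empty for placeholder blocks);
    * compact mode: only per-cell (divisions, burden) counters, for large
      runs where the SFS and genotype matrix are not needed.
    """

    def __init__(self, n0: int = 1, track_ids: bool = True):
        if n0 < 1:
            raise ValueError("n0 must be >= 1")
        self.track_ids = track_ids
        self.step_count = 0
        self.next_mutation_id = 0
        self.next_block_id = 0
        if track_ids:
            self.cells: list[CellRecord] = [CellRecord() for _ in range(n0)]
            self.abundance: dict[int, int] = {}
            self.block_registry: dict[int, tuple[int, ...]] = {}
            # block id -> founding daughter's current existence is implicit:
            # membership is recorded per cell in CellRecord.blocks
        else:
            self.divisions: list[int] = [0] * n0
            self.burdens: list[int] = [0] * n0
            # M_i is only trackable compactly while no mutation is ever
            # lost, i.e. in the pure-birth case
            self._compact_m: int | None = 0

    # -- size and TMB -----------------------------------------------------

    @property
    def size(self) -> int:
        return len(self.cells) if self.track_ids else len(self.divisions)

    @property
    def unique_mutation_count(self) -> int | None:
        """M_i: number of distinct mutations carried by >= 1 living cell.

        None in compact mode once a death has occurred (lost ids unknown).
        """
        if self.track_ids:
            return len(self.abundance)
        return self._compact_m

    # -- event application ------------------------------------------------

    def apply_birth(self, idx: int, u1: int, u2: int) -> None:
        b1 = self.next_block_id
        b2 = b1 + 1
        self.next_block_id += 2
        m0 = self.next_mutation_id
        new1 = tuple(range(m0, m0 + u1))
        new2 = tuple(range(m0 + u1, m0 + u1 + u2))
        self.next_mutation_id = m0 + u1 + u2
        if self.track_ids:
            parent = self.cells[idx]
            # each parental mutation now has one extra living carrier
            for m in parent.mutations:
                self.abundance[m] += 1
            for m in new1 + new2:
                self.abundance[m] = 1
            self.block_registry[b1] = new1
            self.block_registry[b2] = new2
            d1 = CellRecord(
                mutations=parent.mutations | set(new1),
                blocks=parent.blocks + (b1,),
                divisions=parent.divisions + 1,
            )
            d2 = CellRecord(
                mutations=parent.mutations | set(new2),
                blocks=parent.blocks + (b2,),
                divisions=parent.divisions + 1,
            )
            self.cells[idx] = d1
            self.cells.append(d2)
        else:
            d = self.divisions[idx] + 1
            b = self.burdens[idx]
            self.divisions[idx] = d
            self.divisions.append(d)
            self.burdens.append(b + u2)
            self.burdens[idx] = b + u1
            if self._compact_m is not None:
                self._compact_m += u1 + u2
        self.step_count += 1

    def apply_death(self, idx: int) -> None:
        if self.track_ids:
            dying = self.cells[idx]
            for m in dying.mutations:
                n = self.abundance[m] - 1
                if n:
                    self.abundance[m] = n
                else:
                    del self.abundance[m]
            self.cells[idx] = self.cells[-1]
            self.cells.pop()
        else:
            self.divisions[idx] = self.divisions[-1]
            self.divisions.pop()
            self.burdens[idx] = self.burdens[-1]
            self.burdens.pop()
            self._compact_m = None
        self.step_count += 1

    # -- per-cell counter views -------------------------------------------

    def division_counts(self) -> list[int]:
        if self.track_ids:
            return [c.divisions for c in self.cells]
        return list(self.divisions)

    def burden_counts(self) -> list[int]:
        if self.track_ids:
            return [c.burden for c in self.cells]
        return list(self.burdens)


@dataclass(frozen=True)
class StepEvent:
    kind: Literal["birth", "death"]
    cell_index: int
    u1: int | None = None
    u2: int | None = None


def draw_mutation_count(
    dist: str | MutationDistribution,
    rng: np.random.Generator,
    mean: float | None = None,
) -> int:
    """One draw of the number of new mutations for one daughter cell."""
    d = mutation_distribution(dist, mean=mean)
    u = d.draw(rng)
    if u < 0:
        raise ValueError("mutation distribution produced a negative draw")
    return u


def step(
    state: PopulationState,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> StepEvent:
    """Advance the chain by one event; returns what happened.

    Random-stream consumption is identical in full and compact modes:
    one uniform for birth-vs-death, one integer for the cell choice and,
    on birth, one draw per daughter.
    """
    n = state.size
    if n == 0:
        raise RuntimeError("cannot step an extinct population")
    is_birth = config.beta >= 1.0 or rng.random() < config.beta
    idx = int(rng.integers(n))
    if is_birth:
        dist = config._dist
        u1 = dist.draw(rng)
        u2 = dist.draw(rng)
        state.apply_birth(idx, u1, u2)
        return StepEvent("birth", idx, u1, u2)
    state.apply_death(idx)
    return StepEvent("death", idx)


@dataclass
class RunResult:
    state: PopulationState
    discarded: int
    config: SimulationConfig
    trajectory: list[tuple[int, int, int | None]] | None = None

    @property
    def attempts(self) -> int:
        return self.discarded + 1


def _stopped(state: PopulationState, stop: tuple[str, int]) -> bool:
    kind, target = stop
    if kind == "size":
        return state.size >= target
    return state.step_count >= target


def run(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    record_trajectory: bool = False,
) -> RunResult:
    """Run until the stopping rule fires, conditioned on survival.

    A run whose population hits zero before the stop is discarded and
    restarted from the same stream (rejection conditioning); the number of
    discarded attempts is reported.  With a size stop the returned state is
    at the first step where N_i equals the target.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    kind, target = config.stop
    if kind == "size" and target == config.n0:
        state = PopulationState(config.n0, track_ids=config.track_matrix)
        traj = [(0, state.size, state.unique_mutation_count)] if record_trajectory else None
        return RunResult(state, 0, config, traj)

    discarded = 0
    while True:
        state = PopulationState(config.n0, track_ids=config.track_matrix)
        traj: list[tuple[int, int, int | None]] | None = None
        if record_trajectory:
            traj = [(0, state.size, state.unique_mutation_count)]
        extinct = False
        while not _stopped(state, config.stop):
            if state.size == 0:
                extinct = True
                break
            step(state, config, rng)
            if record_trajectory:
                traj.append(
                    (state.step_count, state.size, state.unique_mutation_count)
                )
        if not extinct and state.size > 0:
            return RunResult(state, discarded, config, traj)
        discarded += 1
        if discarded >= config.max_restarts:
            raise RuntimeError(
                f"stopping rule {config.stop} not reached within "
                f"{config.max_restarts} attempts (all extinct)"
            )


def run_trajectory_sizes(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> RunResult:
    """As ``run`` but records (i, N_i, M_i) at every step.

    M_i is None in compact mode once a death occurred (see
    PopulationState.unique_mutation_count).
    """
    return run(config, rng=rng, record_trajectory=True)


def write_trajectory_tsv(result: RunResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("step\tN\tM\n")
        for i, n, m in result.trajectory or []:
            fh.write(f"{i}\t{n}\t{'NA' if m is None else m}\n")
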