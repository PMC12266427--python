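"""Per-division mutation-count distributions.

Each daughter cell produced by a division acquires U new mutations, with U
drawn from one of the distributions here.  The default model is Poisson
with mean mu; the alternatives (fixed, geometric, user-supplied table)
exist to probe the claim that only the mean of the mutational distribution
matters for the expected burden distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .histograms import IntHistogram


class MutationDistribution:
    """Base class: a nonnegative-integer draw with a known mean."""

    mean: float

    def draw(self, rng: np.random.Generator) -> int:
        raise NotImplementedError

    def draw_many(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.array([self.draw(rng) for _ in range(size)], dtype=np.int64)


@dataclass
class PoissonMutations(MutationDistribution):
    mean: float

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("Poisson mean must be >= 0")

    def draw(self, rng: np.random.Generator) -> int:
        if self.mean == 0.0:
            return 0
        return int(rng.poisson(self.mean))

    def draw_many(self, rng, size):
        if self.mean == 0.0:
            return np.zeros(size, dtype=np.int64)
        return rng.poisson(self.mean, size=size).astype(np.int64)


@dataclass
class FixedMutations(MutationDistribution):
    """Degenerate distribution: exactly ``mean`` mutations per daughter."""

    mean: float

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("fixed mean must be >= 0")
        if self.mean != int(self.mean):
            raise ValueError("fixed mutation count must be an integer")

    def draw(self, rng: np.random.Generator) -> int:
        return int(self.mean)

    def draw_many(self, rng, size):
        return np.full(size, int(self.mean), dtype=np.int64)


@dataclass
class GeometricMutations(MutationDistribution):
    """Geometric on {0, 1, 2, ...} parameterised by its mean."""

    mean: float

    def __post_init__(self) -> None:
        if self.mean < 0:
            raise ValueError("geometric mean must be >= 0")

    @property
    def _p(self) -> float:
        return 1.0 / (1.0 + self.mean)

    def draw(self, rng: np.random.Generator) -> int:
        if self.mean == 0.0:
            return 0
        # numpy's geometric is supported on {1, 2, ...}
        return int(rng.geometric(self._p)) - 1

    def draw_many(self, rng, size):
        if self.mean == 0.0:
            return np.zeros(size, dtype=np.int64)
        return (rng.geometric(self._p, size=size) - 1).astype(np.int64)


class TableMutations(MutationDistribution):
    """Arbitrary distribution given as an integer histogram of weights."""

    def __init__(self, table: IntHistogram | dict[int, float]):
        if isinstance(table, IntHistogram):
            items = dict(table.counts)
        else:
            items = {int(k): float(v) for k, v in table.items()}
        if not items:
            raise ValueError("empty mutation table")
        if any(k < 0 for k in items):
            raise ValueError("mutation counts must be >= 0")
        if any(v < 0 for v in items.values()):
            raise ValueError("table weights must be >= 0")
        total = float(sum(items.values()))
        if total <= 0:
            raise ValueError("table has zero total weight")
        self.support = np.array(sorted(items), dtype=np.int64)
        self.probs = np.array([items[k] for k in sorted(items)], dtype=float) / total
        self.mean = float((self.support * self.probs).sum())

    def draw(self, rng: np.random.Generator) -> int:
        return int(rng.choice(self.support, p=self.probs))

    def draw_many(self, rng, size):
        return rng.choice(self.support, p=self.probs, size=size).astype(np.int64)


_NAMED = {
    "poisson": PoissonMutations,
    "fixed": FixedMutations,
    "geometric": GeometricMutations,
}


def mutation_distribution(
    spec: str | MutationDistribution,
    mean: float | None = None,
    table: IntHistogram | dict | None = None,
) -> MutationDistribution:
    """Build a mutation distribution from a name + mean, or pass one through."""
    if isinstance(spec, MutationDistribution):
        return spec
    name = str(spec).lower()
    if name == "table":
        if table is None:
            raise ValueError("table distribution requires a histogram")
        return TableMutations(table)
    if name not in _NAMED:
        raise ValueError(f"unknown mutation distribution {spec!r}")
    if mean is None:
        raise ValueError(f"{name} distribution requires a mean")
    return _NAMED[name](mean)
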