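"""Integer-indexed histograms and expected curves.

These are the concrete carriers of the three summary statistics of the
branching process: the site frequency spectrum (SFS, indexed by mutation
abundance j >= 1), the division distribution (DD, indexed by per-cell
division count l >= 0) and the single-cell mutational burden distribution
(MBD, indexed by per-cell mutation count k >= 0).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np

ROLES = ("sfs", "dd", "mbd")

# first admissible index per role: SFS counts abundances >= 1
_ROLE_START = {"sfs": 1, "dd": 0, "mbd": 0}


@dataclass
class IntHistogram:
    """Sparse histogram over nonnegative integers with a role tag."""

    counts: Counter = field(default_factory=Counter)
    role: str = "mbd"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown histogram role {self.role!r}")
        self.counts = Counter(self.counts)
        start = _ROLE_START[self.role]
        for idx, c in self.counts.items():
            if idx < start:
                raise ValueError(f"{self.role} index {idx} < {start}")
            if c < 0:
                raise ValueError(f"negative count at index {idx}")

    def __getitem__(self, idx: int) -> int:
        return self.counts.get(idx, 0)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(sorted(self.counts.items()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntHistogram):
            return NotImplemented
        return self.role == other.role and +self.counts == +other.counts

    @property
    def total(self) -> int:
        """Total mass (number of mutations for SFS, of cells for DD/MBD)."""
        return sum(self.counts.values())

    @property
    def weighted_total(self) -> int:
        """Sum of index*count; for SFS and MBD this is the number of
        mutational occurrences (total 1-entries of the genotype matrix)."""
        return sum(i * c for i, c in self.counts.items())

    def mean(self) -> float:
        if self.total == 0:
            raise ValueError("mean of empty histogram")
        return self.weighted_total / self.total

    def max_index(self) -> int:
        return max(self.counts) if self.counts else _ROLE_START[self.role]

    def to_array(self, length: int | None = None) -> np.ndarray:
        """Dense counts from index 0 (index j for SFS arrays too: entry 0
        is identically zero there)."""
        n = (self.max_index() + 1) if length is None else length
        arr = np.zeros(n, dtype=float)
        for i, c in self.counts.items():
            if i < n:
                arr[i] = c
        return arr

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# role={self.role}\n")
            fh.write("index\tcount\n")
            for i, c in self:
                fh.write(f"{i}\t{c}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "IntHistogram":
        path = Path(path)
        role = "mbd"
        counts: Counter = Counter()
        with path.open() as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if "role=" in line:
                        role = line.split("role=", 1)[1].strip()
                    continue
                if line.startswith("index"):
                    continue
                i, c = line.split("\t")
                counts[int(i)] = int(c)
        return cls(counts=counts, role=role)

    @classmethod
    def from_values(cls, values, role: str) -> "IntHistogram":
        return cls(counts=Counter(int(v) for v in values), role=role)


@dataclass
class ExpectedCurve:
    """Real-valued expected distribution over integer indices.

    ``values[t]`` is the expectation at index ``start + t``.  ``provenance``
    records how the curve was obtained (closed_form | recurrence |
    approximation | conversion) and ``params`` the process parameters it was
    computed for.
    """

    values: np.ndarray
    start: int = 0
    provenance: str = "closed_form"
    params: dict = field(default_factory=dict)
    role: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("expected curve has negative values")

    def __getitem__(self, idx: int) -> float:
        t = idx - self.start
        if t < 0 or t >= len(self.values):
            return 0.0
        return float(self.values[t])

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.start + len(self.values))

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def mean(self) -> float:
        return float((self.indices * self.values).sum() / self.values.sum())

    def to_array(self, length: int | None = None) -> np.ndarray:
        """Dense values from index 0."""
        n = (self.start + len(self.values)) if length is None else length
        arr = np.zeros(n, dtype=float)
        hi = min(n, self.start + len(self.values))
        if hi > self.start:
            arr[self.start:hi] = self.values[: hi - self.start]
        return arr

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            if self.role:
                fh.write(f"# role={self.role}\n")
            fh.write(f"# provenance={self.provenance}\n")
            if self.params:
                items = " ".join(f"{k}={v}" for k, v in sorted(self.params.items()))
                fh.write(f"# params {items}\n")
            fh.write("index\texpected\n")
            for i, v in zip(self.indices, self.values):
                fh.write(f"{i}\t{v:.12g}\n")


def as_weight_map(dist) -> dict[int, float]:
    """Normalise a histogram/curve/mapping to an index->weight dict."""
    if isinstance(dist, IntHistogram):
        return {int(i): float(c) for i, c in dist.counts.items() if c}
    if isinstance(dist, ExpectedCurve):
        return {
            int(i): float(v)
            for i, v in zip(dist.indices, dist.values)
            if v != 0.0
        }
    if isinstance(dist, Mapping):
        return {int(i): float(v) for i, v in dist.items() if v}
    raise TypeError(f"cannot interpret {type(dist).__name__} as a distribution")
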