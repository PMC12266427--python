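"""Genotype matrix and the three summary histograms (SFS, DD, MBD).

The genotype (SNP) matrix Y_i is a binary cell x mutation incidence
matrix: entry (n, m) is 1 iff living cell n carries mutation m.  Mutations
acquired by one daughter in one division form a "division block"; all
columns of a block share one incidence pattern, and a division that added
no mutations contributes a placeholder all-zero column so the block record
survives.  The three histograms are

* SFS  {S_j}: per-mutation abundance (number of carriers j >= 1),
* DD   {D_l}: per-cell division count (blocks along the lineage),
* MBD  {B_k}: per-cell mutational burden,

and they satisfy sum_k B_k = sum_l D_l = N_i, sum_j S_j = M_i, and the
mutational-occurrences identity sum_j j*S_j = sum_k k*B_k (the total
number of 1-entries of Y_i).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .histograms import IntHistogram
from .simulator import PopulationState

__all__ = [
    "GenotypeMatrix",
    "sfs_from_state",
    "dd_from_state",
    "mbd_from_state",
    "mutational_occurrences",
    "export_matrix",
    "read_matrix",
    "OccurrenceIdentityError",
]

PLACEHOLDER = -1  # mutation-id sentinel for all-zero placeholder columns


class OccurrenceIdentityError(AssertionError):
    """Raised when sum_j j*S_j != sum_k k*B_k on one realisation."""


@dataclass
class GenotypeMatrix:
    """Binary incidence of living cells (rows) x mutation columns.

    ``columns`` lists, per matrix column, ``(mutation_id, block_id)`` with
    ``mutation_id == PLACEHOLDER`` for all-zero placeholder columns.
    ``block_members`` maps block id -> sorted tuple of row indices of the
    cells whose lineage includes that block; for non-placeholder blocks
    this duplicates the incidence pattern, for placeholder blocks it is the
    only record of membership.
    """

    incidence: sp.csr_matrix
    columns: list[tuple[int, int]]
    block_members: dict[int, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.incidence = sp.csr_matrix(self.incidence, dtype=np.int8)
        if self.incidence.shape[1] != len(self.columns):
            raise ValueError("column annotation length mismatch")

    @property
    def n_cells(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_columns(self) -> int:
        return self.incidence.shape[1]

    @classmethod
    def from_state(cls, state: PopulationState) -> "GenotypeMatrix":
        if not state.track_ids:
            raise ValueError(
                "genotype matrix requires a full-tracking run "
                "(track_matrix=True)"
            )
        # column layout: blocks in creation order; one column per mutation,
        # one all-zero column per empty (placeholder) block
        columns: list[tuple[int, int]] = []
        col_of_mutation: dict[int, int] = {}
        for b in sorted(state.block_registry):
            muts = state.block_registry[b]
            if muts:
                for m in muts:
                    col_of_mutation[m] = len(columns)
                    columns.append((m, b))
            else:
                columns.append((PLACEHOLDER, b))
        rows: list[int] = []
        cols: list[int] = []
        members: dict[int, list[int]] = {b: [] for b in state.block_registry}
        for r, cell in enumerate(state.cells):
            for m in cell.mutations:
                rows.append(r)
                cols.append(col_of_mutation[m])
            for b in cell.blocks:
                members[b].append(r)
        inc = sp.coo_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)),
            shape=(len(state.cells), len(columns)),
        ).tocsr()
        block_members = {b: tuple(sorted(v)) for b, v in members.items()}
        return cls(inc, columns, block_members)

    # -- histograms from the matrix alone ---------------------------------

    def sfs(self) -> IntHistogram:
        """Histogram of per-mutation abundances (column sums >= 1).

        All-zero columns — placeholders, and mutations whose carriers all
        died — are excluded, so the total equals M_i.
        """
        sums = np.asarray(self.incidence.sum(axis=0)).ravel()
        return IntHistogram(Counter(int(s) for s in sums if s > 0), role="sfs")

    def mbd(self) -> IntHistogram:
        """Histogram of per-cell burdens (row sums)."""
        sums = np.asarray(self.incidence.sum(axis=1)).ravel()
        return IntHistogram(Counter(int(s) for s in sums), role="mbd")

    def dd(self) -> IntHistogram:
        """Histogram of per-cell division counts via block membership."""
        per_cell = Counter()
        for rows in self.block_members.values():
            for r in rows:
                per_cell[r] += 1
        counts = Counter(per_cell[r] for r in range(self.n_cells))
        return IntHistogram(counts, role="dd")

    def occurrences(self) -> int:
        """Total 1-entries of Y_i."""
        return int(self.incidence.sum())


def _require(state_or_matrix) -> tuple[PopulationState | None, GenotypeMatrix | None]:
    if isinstance(state_or_matrix, PopulationState):
        return state_or_matrix, None
    if isinstance(state_or_matrix, GenotypeMatrix):
        return None, state_or_matrix
    raise TypeError(
        f"expected PopulationState or GenotypeMatrix, got "
        f"{type(state_or_matrix).__name__}"
    )


def sfs_from_state(state_or_matrix) -> IntHistogram:
    """Site frequency spectrum: S_j = #mutations carried by exactly j cells."""
    state, matrix = _require(state_or_matrix)
    if matrix is not None:
        return matrix.sfs()
    if not state.track_ids:
        raise ValueError(
            "SFS requires mutation-id tracking; rerun with track_matrix=True"
        )
    return IntHistogram(Counter(state.abundance.values()), role="sfs")


def dd_from_state(state_or_matrix) -> IntHistogram:
    """Division distribution: D_l = #cells having undergone l divisions."""
    state, matrix = _require(state_or_matrix)
    if matrix is not None:
        return matrix.dd()
    return IntHistogram(Counter(state.division_counts()), role="dd")


def mbd_from_state(state_or_matrix) -> IntHistogram:
    """Mutational burden distribution: B_k = #cells carrying k mutations."""
    state, matrix = _require(state_or_matrix)
    if matrix is not None:
        return matrix.mbd()
    return IntHistogram(Counter(state.burden_counts()), role="mbd")


def mutational_occurrences(state_or_matrix) -> int:
    """Number of mutational occurrences: the sum of the entries of Y_i.

    Computes sum_j j*S_j and checks it equals sum_k k*B_k before
    returning; a mismatch means the infinite-sites bookkeeping is broken
    and raises OccurrenceIdentityError.
    """
    sfs = sfs_from_state(state_or_matrix)
    mbd = mbd_from_state(state_or_matrix)
    from_sfs = sfs.weighted_total
    from_mbd = mbd.weighted_total
    if from_sfs != from_mbd:
        raise OccurrenceIdentityError(
            f"occurrence identity violated: sum j*S_j = {from_sfs} but "
            f"sum k*B_k = {from_mbd}"
        )
    return from_sfs


# -- export / import ------------------------------------------------------


def export_matrix(matrix: GenotypeMatrix, path: str | Path) -> dict[str, Path]:
    """Write the incidence as MatrixMarket plus TSV annotations.

    ``path`` is a stem: writes ``<stem>.mtx`` (coordinate incidence),
    ``<stem>.columns.tsv`` (column -> mutation id, block id; placeholder
    columns carry mutation_id = -1) and ``<stem>.blocks.tsv`` (block id ->
    member cell rows).  Round-trip via ``read_matrix`` reproduces all three
    histograms exactly.
    """
    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": stem.with_suffix(".mtx"),
        "columns": Path(str(stem) + ".columns.tsv"),
        "blocks": Path(str(stem) + ".blocks.tsv"),
    }
    mmwrite(str(paths["matrix"]), matrix.incidence.tocoo(), field="integer")
    with paths["columns"].open("w") as fh:
        fh.write("column\tmutation_id\tblock_id\n")
        for c, (m, b) in enumerate(matrix.columns):
            fh.write(f"{c}\t{m}\t{b}\n")
    with paths["blocks"].open("w") as fh:
        fh.write("block_id\tcell_rows\n")
        for b in sorted(matrix.block_members):
            rows = ",".join(map(str, matrix.block_members[b]))
            fh.write(f"{b}\t{rows}\n")
    return paths


def read_matrix(path: str | Path) -> GenotypeMatrix:
    """Inverse of ``export_matrix`` (same stem convention)."""
    stem = Path(path)
    inc = sp.csr_matrix(mmread(str(stem.with_suffix(".mtx"))))
    columns: list[tuple[int, int]] = []
    with Path(str(stem) + ".columns.tsv").open() as fh:
        next(fh)
        for line in fh:
            _, m, b = line.split()
            columns.append((int(m), int(b)))
    block_members: dict[int, tuple[int, ...]] = {}
    with Path(str(stem) + ".blocks.tsv").open() as fh:
        next(fh)
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            b = int(parts[0])
            rows = tuple(int(x) for x in parts[1].split(",")) if parts[1] else ()
            block_members[b] = rows
    return GenotypeMatrix(inc, columns, block_members)
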