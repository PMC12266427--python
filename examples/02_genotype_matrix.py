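"""The dynamical genotype matrix and its three summary histograms.

A full-tracking run stores, per living cell, the set of mutation ids and
the division blocks they arrived in.  The binary cell x mutation matrix
then yields all three summaries: per-mutation abundances (SFS), per-cell
block counts (DD) and per-cell burdens (MBD).  The script verifies the
mutational-occurrences identity sum_j j S_j = sum_k k B_k — both sides
count the 1-entries of the matrix — and round-trips the matrix through
MatrixMarket + TSV export.
"""

import tempfile
from pathlib import Path

import numpy as np

from mutburden import (
    GenotypeMatrix, SimulationConfig, dd_from_state, export_matrix,
    mbd_from_state, mutational_occurrences, read_matrix, run, sfs_from_state,
)

config = SimulationConfig(beta=2 / 3, mu=2.0, stop=("size", 30),
                          track_matrix=True)
state = run(config, rng=np.random.default_rng(4)).state

sfs, dd, mbd = sfs_from_state(state), dd_from_state(state), mbd_from_state(state)
print(f"N = {state.size} cells, M = {state.unique_mutation_count} unique mutations")
print(f"SFS {dict(sfs.counts)}")
print(f"DD  {dict(sorted(dd.counts.items()))}")
print(f"MBD {dict(sorted(mbd.counts.items()))}")
occ = mutational_occurrences(state)
print(f"occurrences: sum_j j*S_j = sum_k k*B_k = {occ}")
print(f"mean abundance per mutation (SFS mean) {occ / sfs.total:.2f}; "
      f"mean burden per cell (MBD mean) {occ / state.size:.2f}")

matrix = GenotypeMatrix.from_state(state)
print(f"matrix: {matrix.n_cells} cells x {matrix.n_columns} columns "
      f"({sum(1 for m, _ in matrix.columns if m < 0)} placeholder columns)")
with tempfile.TemporaryDirectory() as tmp:
    export_matrix(matrix, Path(tmp) / "geno")
    back = read_matrix(Path(tmp) / "geno")
    print("round-trip preserves histograms:",
          back.sfs() == sfs and back.dd() == dd and back.mbd() == mbd)
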