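# mutburden

Discrete-time birth–death branching simulations with neutral mutation
accumulation, and the exact/approximate theory of the three summary
distributions they generate:

* the **site frequency spectrum** (SFS) `{S_j}` — how many mutations are
  carried by exactly *j* living cells;
* the **division distribution** (DD) `{D_l}` — how many cells have *l*
  divisions in their history (leaf depths of the lineage tree);
* the **single-cell mutational burden distribution** (MBD) `{B_k}` — how
  many cells carry exactly *k* mutations.

The package is aimed at people modelling clonal growth — tumour expansion
under neutral evolution, somatic mosaicism, clonal haematopoiesis — who
want to connect bulk-level spectra (SFS) with single-cell quantities (DD,
MBD) inside one stochastic process, and to check simulations against
closed-form expectations.

## Model

At each step a uniformly chosen cell divides with probability β or dies
with probability δ = 1 − β (growing case β > δ; single mutation-free
progenitor, N₀ = 1, unless stated). On division each daughter inherits all
parental mutations and gains `U ~ Poisson(μ)` new, globally unique ones
(infinite-sites; `fixed`, `geometric` or table-valued draws with the same
mean are also available). A realisation is a growing binary tree whose
bookkeeping lives in a binary **genotype matrix** (cells × mutations, with
"division blocks" marking mutations that arrived together, and placeholder
columns for mutation-free divisions). The matrix makes the three summaries
and the occurrences identity `Σ_j j·S_j = Σ_k k·B_k` mechanical.

Expectations (conditioned on survival, realised by discard-and-restart):

* pure birth (Yule, δ = 0), exact:
  `E[S_j,i] = 2μ(i+1)/(j(j+1))` for `j ≤ i`;
  `E[D_l,i] = [i l] 2^l / i!` with `[i l]` the unsigned Stirling numbers of
  the first kind;
  `E[B_k,i] = Σ_l E[D_l,i] e^{−lμ}(lμ)^k / k!`;
  mean burden `2μ(H_{i+1} − 1)` — a rescaled harmonic number;
* birth–death (0 < δ < β), first order in the low-death / large-population
  regime: the SFS gains a geometric series in δ/β, the DD becomes the
  normalised partition `f(i,l) = [i l] 2^l (1−δ/β)^{−l}` of `E[N_i]`, and
  `E[N_i | survival]` itself is computed exactly by propagating the finite
  Markov chain with absorbing 0.

## Worked example

```python
import numpy as np
from mutburden import (SimulationConfig, run, sfs_from_state,
                       mbd_from_state, mutational_occurrences)

cfg = SimulationConfig(beta=2/3, mu=2.0, stop=("size", 30), track_matrix=True)
state = run(cfg, rng=np.random.default_rng(4)).state
occ = mutational_occurrences(state)
print(state.size, state.unique_mutation_count, occ,
      occ / state.unique_mutation_count, occ / state.size)
```

prints `30 167 664 3.976 22.13`: the run stopped at N = 30 living cells
carrying M = 167 distinct mutations and 664 mutational occurrences
(1-entries of the genotype matrix), i.e. a mean abundance of ~3.98 cells
per mutation and a mean burden of ~22.1 mutations per cell. The
`examples/` directory has one narrative script per capability
(trajectories, the genotype matrix and its export, Yule DD vs the Stirling
law, DD→MBD conversion, birth–death conditioning); each prints the numbers
it computes and says what they mean. A thin CLI mirrors the library:
`mutburden simulate|expected|convert|compare|ensemble --help`.

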