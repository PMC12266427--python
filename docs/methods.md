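# Methods

## Model and assumptions

The process is a discrete-time Markov chain on population size with
per-cell genealogy. At each step one living cell is chosen uniformly; it
divides with probability β or dies with probability δ = 1 − β. Only the
growing case β > δ is supported — expectations are conditioned on survival
and the supercritical regime is what makes that conditioning
non-degenerate. Division replaces the mother by two daughters; each
daughter inherits every parental mutation and acquires an independent
number `U` of brand-new mutations. Mutations are never reused
(infinite-sites approximation) and never revert. Selection is absent: the
choice of the dividing/dying cell never depends on its mutations, which is
what lets every expectation close on the current summary statistics alone.

Time is a step counter, not physical time. The usual continuous-time
birth–death process maps onto this chain by conditioning on the embedded
jump sequence, so size-stopped quantities transfer directly; step-indexed
quantities (anything written at fixed `i`) do not have a continuous-time
analogue without a time-change.

`U` defaults to Poisson(μ). `fixed`, `geometric` and user-table
distributions with the same mean are provided to probe how much of the
burden distribution is driven by the division genealogy versus the
mutation-count noise (see Limitations).

## Parameters

| name | meaning | default / typical |
|---|---|---|
| β | per-step division probability (δ = 1 − β derived, never stored) | 1 (pure birth); 2/3 for death studies |
| μ | mean new mutations per daughter per division (dimensionless count) | 2 (SFS studies), 10 (burden studies) |
| N₀ | initial population, mutation-free progenitors | 1 (theory requires it; simulator allows more) |
| stop | `("size", N)` first step with N cells, or `("steps", i)` | N = 10²–10³ |
| R | surviving replicates per ensemble | 100–200 |
| seed | master seed; replicate r uses stream `[seed, r]` | — |

μ values of order 1–10 per division bracket what is reported for human
somatic tissues and tumours; final sizes of 10²–10³ cells keep a
200-replicate ensemble in seconds-to-tens-of-seconds on one core while
leaving ~15–20 populated histogram bins, which is what the bin-wise
z-comparisons need.

## Conditioning on survival

All expectations are conditioned on the population being alive at the
observation point. The simulator realises this by rejection: an attempt
whose population hits 0 before the stopping rule fires is discarded,
tallied, and restarted from the same random stream. For a step-count stop
this is exactly conditioning on `N_i > 0`; for a size stop it conditions
on ever reaching the target, which for this chain (state-independent jump
probabilities) has probability `1 − (δ/β − (δ/β)^N)/(1 − (δ/β)^N)` — the
tallied discard fraction therefore estimates δ/β up to an exponentially
small correction, and is itself a check of the conditioning.

The reference for `E[N_i | survival]` is not the linear rule
`(β−δ)i + 1` (a low-death approximation) but exact forward propagation of
the finite chain with absorbing 0, renormalised over surviving mass. The
state space is truncated at `20(β−δ)i_max + 50`; the propagator raises if
more than 1e-10 of probability ever sits at the cap. The linear curve is
returned alongside for comparison.

## Exact pure-birth theory and its numerics

Unsigned Stirling numbers of the first kind `[i l]` are built by the
triangular recurrence as exact big integers up to i = 300 and by the same
recurrence in log space (vectorised `logaddexp` row updates) beyond; the
assembled quantities `[i l] 2^l / i!` are always formed in log space and
exponentiated last, because numerator and denominator separately overflow
float64 near i ≳ 170. The log route is validated against the exact route
to 1e-12 relative, and the row identity `Σ_l [i l] 2^l = (i+1)!` — which
is precisely mass conservation of the expected division distribution — is
checked exactly for i ≤ 30 and in log space at i = 2000.

The recurrence iterators for the expected SFS and DD are kept as
first-class operations, not just tests: the SFS closed form
`2μ(i+1)/(j(j+1))` is exact only in the triangle `j ≤ i` (outside it the
true expectation is 0 while the closed form is positive), so the iterator
is the authority wherever the two disagree. The expected MBD is the
expected DD pushed through Poisson kernels; the mixture support is
truncated at `mean + 10·sd` of the widest component and the truncation
defect is required to stay below 1e-8 of the total mass.

First-order birth–death forms: the SFS series in powers of δ/β is
truncated when a term falls below 1e-12 of the running sum (geometric
convergence makes this safe); the DD partition `f(i,l)` is normalised by
log-sum-exp. Both reduce termwise to the pure-birth forms at δ = 0, which
is tested.

## DD ↔ MBD conversion

Forward: `B(k) = Σ_l D(l)·Pois(lμ)(k)`, linear in the DD and applicable to
a single realisation, an ensemble mean, or a theoretical curve; the mean
map `mean(B) = μ·mean(D)` is exact before truncation and is asserted to
machine precision. Only μ enters — deliberately no variance parameter.

Inverse: each burden k is assigned to division class `round(k/μ)`
(half-integer boundaries, ties to even). This is the maximum-likelihood
class assignment when the component means `lμ` are well separated
(component sd `√(lμ)` small against spacing μ, i.e. `l ≲ μ`); it conserves
mass exactly and is intentionally simple — no regularised deconvolution.
With μ = 10 and classes around l ≈ 12 the separation condition fails and
adjacent classes mix appreciably (Poisson(30) puts only ~59% of its mass
in its own class); the round-trip tests therefore assert the numerically
computed mass fractions rather than near-perfect recovery, and use μ = 100
to demonstrate the well-separated regime.

## What the simulations do and do not emulate

The generator produces the idealised object the theory describes: neutral
growth from one progenitor, complete single-cell genotypes, no sequencing
noise, no sampling, no subclonal selection, no back-mutation. Agreement of
simulation with theory here validates the mathematics, not the
applicability to any real dataset — real single-cell data add allelic
dropout, doublets, finite sampling of cells, and possible selection, none
of which are modelled. Two storage modes exist: full tracking (per-cell
mutation-id sets, division blocks, global abundance table — needed for the
SFS and the genotype matrix) and compact counters (divisions and burden
per cell — enough for DD/MBD at large N). Both consume the random stream
identically, so they produce identical histograms from the same seed;
compact mode cannot report the number of unique mutations once a death has
occurred, since the dying cell's identity set is unknown, and returns None
for it then.

## Design choices that were genuinely open

* **Blocks per division.** Each division creates two block records (one
  per daughter), including empty "placeholder" ones; a cell's division
  count is then always the number of blocks on its lineage, and the
  genotype matrix can carry an all-zero column per mutation-free daughter
  without losing the depth information. The alternative — one block per
  division — would have made the two daughters' independent draws share a
  record and broken the column-per-daughter layout of the matrix.
* **Lost mutations.** A mutation whose carriers all died stays in the
  matrix as an all-zero column (it is history) but is excluded from the
  SFS and from M_i, keeping `Σ_j S_j = M_i` an identity about the living
  population. The occurrences identity then holds exactly with death,
  because lost mutations leave both sides simultaneously.
* **Ensemble substreams.** Replicate r draws from `default_rng([seed, r])`
  rather than splitting one stream sequentially, so any replicate can be
  reproduced in isolation and the ensemble is order-independent.
* **E[N_i] inside the birth–death forms.** Defaults to the numerically
  conditioned chain; the linear `(β−δ)i + 1` is available as an option,
  and size-stopped comparisons pass the known final N directly.

## Problem sizes used in tests and the acceptance script

Identity and oracle checks run at i ≤ 6 (exhaustive enumeration of all i!
division choices, exact rationals) and i ≤ 200 (closed form vs
recurrence, 1e-10 relative). Ensemble comparisons use final size 10³ with
200 replicates (division distribution, burden conversion, birth–death
SFS) and 10⁴ attempts for the extinction fraction; these sizes put every
compared bin's Monte-Carlo error at the few-percent level, which is the
scale the 3-SE criteria need.

## Known limitations

* The birth–death SFS/DD expressions are first-order approximations; at
  δ/β = 1/2 they are accurate at the small-j / well-populated-bin level
  the tests probe, but are not exact, and no exact finite-i birth–death
  solution is provided.
* The MBD's insensitivity to the mutation-count distribution is a
  shape-level statement. Distributions with the same mean but different
  variance change the MBD variance by (mean divisions)·σ²; a degenerate
  (fixed-count) distribution puts all burden on a lattice and differs from
  the Poisson-mixture prediction bin-wise at any sample size, while
  agreeing to ~5% in total variation at μ = 10, N = 10³. Tests assert
  both facts rather than an unconditional equality.
* Step-indexed expectations assume N₀ = 1; the theory functions refuse
  other initial conditions rather than approximating them.
* No clonal competition / type-dependent rates, no coalescent machinery,
  no sequencing-noise or sampling model.
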