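"""One conditioned realisation of the birth-death process with mutations.

Runs the discrete-time chain (birth probability beta = 2/3, death
probability 1/3, Poisson(2) mutations per daughter per division) from a
single mutation-free progenitor until the population first reaches 100
cells, discarding and restarting any attempt that goes extinct.  Prints
the (step, population size N_i, unique mutations M_i) trajectory every 25
steps: N_i performs a +1/-1 random walk biased upward, while the tumour
mutational burden M_i grows roughly linearly but dips when dying cells
take private mutations with them.
"""

import numpy as np

from mutburden import SimulationConfig, run_trajectory_sizes

config = SimulationConfig(
    beta=2 / 3, mu=2.0, stop=("size", 100), track_matrix=True,
)
result = run_trajectory_sizes(config, rng=np.random.default_rng(1))

print(f"discarded (extinct) attempts before this survivor: {result.discarded}")
print("step\tN\tM")
for i, n, m in result.trajectory[::25]:
    print(f"{i}\t{n}\t{m}")
i, n, m = result.trajectory[-1]
print(f"{i}\t{n}\t{m}   <- stop fired: first step with N = 100")
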