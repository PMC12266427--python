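"""Birth-death (beta = 2/3) conditioning and first-order approximations.

Three checks with death present: (i) the discarded-attempt fraction under
rejection conditioning estimates the extinction probability delta/beta;
(ii) the mean population of step-stopped surviving runs follows the
exactly-propagated conditioned chain E[N_i | N_i > 0], which the linear
rule (beta - delta) i + 1 only approximates; (iii) the ensemble-mean SFS
at small abundances follows the geometric-series correction of the
1/(j(j+1)) law.
"""

import numpy as np

from mutburden import SimulationConfig, run, run_ensemble, theory

beta = 2 / 3

# (i) extinction probability via restart bookkeeping
cfg = SimulationConfig(beta=beta, mu=0.0, stop=("size", 100),
                       track_matrix=False)
rng = np.random.default_rng(2)
attempts = discarded = 0
while attempts < 4000:
    res = run(cfg, rng)
    discarded += res.discarded
    attempts += res.discarded + 1
print(f"discarded fraction {discarded / attempts:.3f} "
      f"(extinction probability delta/beta = {(1 - beta) / beta:.3f})")

# (ii) conditioned population size at a fixed step count
i_stop = 60
ens = run_ensemble(cfg.with_(stop=("steps", i_stop)), R=300, master_seed=8,
                   stats=("dd",))
sizes = np.array(ens.final_sizes, float)
curve = theory.expected_population_conditioned(beta, 1 - beta, i_stop)
print(f"mean N_{i_stop}: simulated {sizes.mean():.2f} "
      f"+- {sizes.std(ddof=1) / np.sqrt(len(sizes)):.2f}, "
      f"conditioned chain {curve.values[i_stop]:.2f}, "
      f"linear approximation {curve.params['linear'][i_stop]:.2f}")

# (iii) small-j SFS against the first-order series
cfg = SimulationConfig(beta=beta, mu=2.0, stop=("size", 300),
                       track_matrix=True)
ens = run_ensemble(cfg, R=100, master_seed=9, stats=("sfs",))
mean, se = ens.mean_curve("sfs")
series = theory.expected_sfs_birth_death(2.0, beta, 1 - beta,
                                         expected_n=300.0, j_max=4)
print("j\tsimulated\tseries\tz")
for j in range(1, 5):
    z = (mean[j] - series[j]) / se[j]
    print(f"{j}\t{mean[j]:8.1f}\t{series[j]:8.1f}\t{z:+.2f}")
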