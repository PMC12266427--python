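"""Yule (pure-birth) division distribution vs the Stirling-number law.

For a pure-birth process stopped at N = 500 cells (i = 499 steps), the
expected number of cells at lineage depth l is E[D_l,i] = [i l] 2^l / i!,
with [i l] the unsigned Stirling numbers of the first kind.  A
100-replicate ensemble's per-depth means should sit within a few standard
errors of that curve; the printed z-scores say by how many SEs each
well-populated depth bin deviates.
"""

from mutburden import SimulationConfig, compare_to_theory, run_ensemble, theory

N = 500
config = SimulationConfig(beta=1.0, mu=0.0, stop=("size", N),
                          track_matrix=False)
ens = run_ensemble(config, R=100, master_seed=3, stats=("dd",))
curve = theory.dd_curve_pure_birth(N - 1)

mean, se = ens.mean_curve("dd")
print("depth l\tsimulated\texpected\tz")
for ell in range(len(mean)):
    if curve[ell] >= 5.0:
        z = (mean[ell] - curve[ell]) / se[ell]
        print(f"{ell}\t{mean[ell]:8.2f}\t{curve[ell]:8.2f}\t{z:+.2f}")

report = compare_to_theory(ens, curve, "dd", expected_floor=5.0)
print(f"\nall {len(report.compared_bins)} bins with >= 5 expected cells "
      f"within 3 SE: {report.passed} (max |z| = {report.max_abs_z:.2f})")
print(f"mean depth: simulated {ens.mean_histogram('dd').mean():.3f}, "
      f"theory 2(H_{N} - 1) = {theory.expected_mean_divisions(N - 1):.3f}")
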