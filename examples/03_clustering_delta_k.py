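"""Bayesian admixture clustering and model-order selection.

Three populations drift independently from separate founder pools; the
Gibbs sampler is run for K = 1..5 with replicate chains, the
second-difference criterion Delta K points at the number of clusters,
and herds are assigned to genetic groups by the mean-membership >= 0.7
rule.
"""

import flocknet as fn
from flocknet.synthetic import SimConfig, simulate_scenario

sim = simulate_scenario(SimConfig(
    n_herds=3, herd_size=20, n_loci=15, n_groups=3, migration_rate=0.0,
    generations=30, sample_per_herd=(15, 15), target_avg_degree=4 / 3,
    seed=31,
))
gt = sim.genotypes

runs = fn.run_k_range(gt, range(1, 6), runs_per_k=3,
                      burnin=300, iters=400, seed=7)
table = fn.evanno_delta_k(runs)
print(table.to_string(index=False,
                      float_format=lambda x: f"{x:.1f}"))
k = fn.best_k(table)
print(f"argmax Delta K = {k} (the simulator used 3 source pools)")

mem = fn.mean_membership([r for r in runs if r.K == k])
assigns = fn.assign_groups(fn.herd_membership(mem, gt.herd_of_birth))
for a in assigns:
    qtxt = " ".join(f"{v:.2f}" for v in a.q_bar)
    print(f"  herd {a.herd}: q_bar = [{qtxt}] -> group {a.group}")
print("Each herd's mean membership concentrates on one cluster, so the "
      "0.7 rule assigns every herd; mixed herds would stay UNASSIGNED.")
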