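"""Group comparison of induced gamma maps with the cluster permutation test.

Two groups of subjects share a narrowband-gamma burst; the patient group's
burst is attenuated to 50%.  Subject-level induced TFR maps are compared
pixel by pixel, suprathreshold neighbours form clusters, and cluster mass
is referred to a permutation distribution of the maximum mass.
"""

import numpy as np

from epiosc.cohort import CohortConfig, GroupEffect, InducedBurstSpec, generate_cohort
from epiosc.stats import cluster_permutation_test, fdr_bh, ranksum
from epiosc.tfr import induced_tfr

config = CohortConfig(
    n_control=10,
    n_patient=10,
    n_trials=60,
    bursts=(InducedBurstSpec("NBG", 45.0, 120.0, 150.0, amplitude=1.0),),
    group_effects=(GroupEffect("NBG", amplitude_ratio=0.5),),
    noise_scale=0.3,
    seed=3,
)
recordings, _ = generate_cohort(config)
maps = {"control": [], "patient": []}
for rec in recordings:
    maps[rec.group].append(induced_tfr(rec, "mid"))

result = cluster_permutation_test(
    maps["control"], maps["patient"], n_perm=500, seed=3
)
print(f"{len(result.clusters)} clusters; "
      f"max-|mass| null 99th percentile = {result.params['mass_threshold']:.0f}")
for c in result.significant_clusters:
    rows, cols = np.where(c["pixels"])
    print(f"  significant cluster: mass {c['mass']:.0f}, p = {c['p']:.4f}, "
          f"{result.frequencies[rows.min()]:.0f}-{result.frequencies[rows.max()]:.0f} Hz, "
          f"{result.times[cols.min()]:.0f}-{result.times[cols.max()]:.0f} ms")
# the significant cluster sits on the planted burst (around 45 Hz, 120 ms)
# with a positive mass: control power exceeds patient power there

# follow-up: subject-level mean RPC inside the significant window
sig = result.mask
rpc = {g: [m.values[sig].mean() for m in maps[g]] for g in maps}
stat, p = ranksum(rpc["control"], rpc["patient"])
p_adj, _ = fdr_bh([p])
print(f"mean RPC in cluster, control vs patient: "
      f"{np.mean(rpc['control']):.0f}% vs {np.mean(rpc['patient']):.0f}% "
      f"(rank-sum p = {p:.2g}, FDR-adjusted {p_adj[0]:.2g})")
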