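"""The two ground-truth ST simulators, composition corruption, and smoothing.

Cluster-based spots draw multinomial reads from cell-type mean profiles at
exactly M reads per spot; cell-based spots pool individual depth-normalized
reference cells.  Observed compositions can be pooled into superclasses and
corrupted with clipped Gaussian noise to emulate imperfect histology, and a
lattice smoothing filter adds local spatial correlation.
"""

import numpy as np

from stweave.simulate import (
    SimulationConfig, pool_and_corrupt, simulate_cell_spots,
    simulate_cluster_spots, smooth_array, synth_reference,
)

ref, truth = synth_reference(n_genes=80, n_types=3, markers_per_type=8, seed=2,
                             n_cells_per_type=60)
print(f"reference: {len(ref.gene_ids)} genes, 3 types, "
      f"{int(truth.is_de.sum())} planted DE (gene, type-pair) labels")

profiles = ref.planted_mean / ref.planted_mean.sum(axis=0, keepdims=True)
cfg = SimulationConfig(n_arrays=1, spots_per_array=100, reads_per_spot=1000,
                       regions={"crypt": [0, 1], "muscle": [2]}, seed=2)
cluster = simulate_cluster_spots(profiles, cfg, gene_ids=list(ref.gene_ids),
                                 celltypes=[str(t) for t in ref.types])
print(f"cluster-based: every spot has exactly "
      f"{np.unique(cluster.data.counts.sum(axis=0))[0]} reads")

cell = simulate_cell_spots(ref, cfg)
totals = cell.data.counts.sum(axis=0)
print(f"cell-based: 10 cells x 1,000 reads -> spot totals {totals.min()}-{totals.max()}")

S = np.array([[1, 1, 0], [0, 0, 1]], dtype=float)  # 3 types -> 2 superclasses
E_obs, _ = pool_and_corrupt(cluster.E_true, S, noise_sd=0.1, seed=0)
drift = np.abs(E_obs - cluster.E_true @ S.T).sum(axis=1).mean()
print(f"pooled+corrupted compositions: still simplexes "
      f"(row sums 1), mean L1 drift {drift:.3f}")

smoothed = smooth_array(cluster.data, weight=0.5)
changed = (smoothed.counts != cluster.data.counts).mean()
print(f"smoothing at weight 0.5 changed {100 * changed:.0f}% of count entries")
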