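"""Heterozygosity, AMOVA and F-statistics on a simulated panel.

Ho above He is the expected signature of polysomic tetraploid genotypes:
an autotetraploid carries both alleles far more often than 2pq. Phi_st
estimates the simulated differentiation; Fis is strongly negative for
binomial tetraploid dosages because Ho counts any both-allele carrier.
"""

import tuberpop as tp

panel, truth = tp.simulate_panel(tp.SimConfig(K=5, n_per_pop=40, L=500, fst=0.15, seed=2))
filtered = tp.filter_maf(panel)

summary = tp.diversity_summary(filtered, truth.labels)
print(summary.table.round(3))
print()

table, phi_stats = tp.amova(filtered, truth.labels, n_permutations=199, seed=2)
fis_stats = tp.fis(filtered, truth.labels, n_permutations=199, seed=2)
text, _ = tp.report_amova(table, f_is=fis_stats.f_is)
print(text)
print(f"p(Phi_st) = {phi_stats.p_phi:.3f}   p(Fis) = {fis_stats.p_fis:.3f}")
print(f"simulated Fst was {0.15}; estimated Phi_st = {table.phi_st:.3f}")

pw, _ = tp.pairwise_phi(filtered, truth.labels)
print("\npairwise Phi_st between subpopulations:")
print(pw.to_frame().round(3))
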