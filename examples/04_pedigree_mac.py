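"""Pedigree kinship, relationship coefficients and ancestor contributions.

Builds a full-sib toy to show the textbook identities, then simulates a
five-generation random-mating pedigree and tabulates each founder's
occurrence frequency and Maximum Average Contribution (MAC) on the
maternal path of the final generation.
"""

import tuberpop as tp

toy = tp.Pedigree({
    "A": (None, None), "B": (None, None),
    "S1": ("A", "B"), "S2": ("A", "B"), "X": ("S1", "S2"),
})
kin = tp.kinship(toy)
print(f"parent-offspring co-ancestry f(A,S1) = {kin.coancestry('A', 'S1')}")
print(f"full-sib co-ancestry f(S1,S2)       = {kin.coancestry('S1', 'S2')}")
print(f"inbreeding of full-sib offspring F(X) = {kin.F('X')}")
rel = tp.coefficient_of_relationship(kin)
print(f"CR(S1,S2) = {rel.to_frame().loc['S1', 'S2']}")

ped, truth = tp.simulate_pedigree(
    tp.PedigreeSimConfig(founders=6, generations=5, offspring_per_generation=10, seed=4)
)
members = [i for i in ped.individuals if i.startswith("G5")]
report = tp.mac(ped, members, side="maternal", max_gen=5)
print(f"\nmaternal-path ancestors of the {report.n_members} final-generation "
      f"individuals (5-generation cap):")
print(report.table.head(8).round(2).to_string(index=False))
# occurrence% says how widely an ancestor appears; MAC% is its mean
# genetic contribution among those appearances — a frequent but remote
# ancestor can rank below a rare, recent one.
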