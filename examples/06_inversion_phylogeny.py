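"""Polarize inversions with outgroups and build the inversion phylogeny.

Two inversions observed among the A, B and D wheat genomes: one derived
only in D, one shared by B and D. Outgroup grasses fix the ancestral
marker order; treating each inversion as an irreversible binary character
yields a perfect phylogeny grouping the genomes that share derived states.
"""

from emmermap.synteny import assign_ancestral_state, inversion_phylogeny

inv1 = assign_ancestral_state(
    {"A": "same", "B": "same", "D": "inverted",
     "Bd2": "same", "Os1": "same", "Sb3": "same"},
    outgroups=["Bd2", "Os1", "Sb3"])
inv3 = assign_ancestral_state(
    {"A": "same", "B": "inverted", "D": "inverted",
     "Bd1": "same", "Os6": "same", "Sb10": "same"},
    outgroups=["Bd1", "Os6", "Sb10"])
print(f"Inv(1): derived in {inv1.derived_genomes}")
print(f"Inv(3): derived in {inv3.derived_genomes}")

result = inversion_phylogeny(
    {"Inv1": set(inv1.derived_genomes), "Inv3": set(inv3.derived_genomes)},
    genomes=["A", "B", "D"])
print(f"phylogeny: {result.newick}")
print("Inv(3) marks the B+D stem, Inv(1) the D terminal branch: B and D are")
print("sisters, with A diverging first.")
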