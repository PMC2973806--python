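"""Score one protein family: per-residue KL, cMI, pMI, pC and Cls.

Builds a small synthetic family (an MSA with coevolving column pairs, a toy
structure whose catalytic site clusters those columns in space, and a
catalytic annotation), runs the full pipeline at the published default
parameters, and prints the top-ranked residues.
"""

import numpy as np

import catnets as cn

spec = cn.FamilySpec(
    n_sequences=300,
    n_columns=40,
    catalytic_columns=(8, 19, 30),
    conservation_level=np.where(np.isin(np.arange(40), [8, 19, 30]), 0.6, 0.15),
    coevolving_pairs=((8, 12, 0.8), (19, 24, 0.8), (30, 35, 0.8)),
    n_duplicate_clusters=3,
    contact_radius=8.0,
    seed=1,
)
family = cn.generate_family(spec, identifier="demo")

prepared = cn.prepare_family(family, n_permutations=100, seed=42)
table = cn.score_table(prepared, cn.ClsParams())  # z=5.5, d_mi=8, d_c=5.6, w=(0.6, 0.2)

print(table.sort_values("cls", ascending=False).head(8).to_string(index=False))
print(
    "\nkl: conservation in bits; cmi: summed significant MI; pmi/pc: [0,1]\n"
    "neighborhood averages of cMI/KL; cls = kl + 0.6*pmi + 0.2*pc.\n"
    "The planted active site — the catalytic residues (is_catalytic=True)\n"
    "and their coevolving partners — should fill the top ranks, far above\n"
    "the remaining residues."
)
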