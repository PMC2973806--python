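"""Benchmark six residue rankings on a planted 'hard' dataset.

Generates families whose catalytic columns are only partially conserved
(0.5-0.7) while decoy columns are strongly conserved — the regime where
plain conservation fails — and compares KL, pMI, pC and their combinations
by per-family ROC AUC.
"""

import catnets as cn

families = cn.generate_benchmark(8, difficulty="hard", seed=0)
prepared = [
    cn.prepare_family(f, n_permutations=100, seed=100 + i)
    for i, f in enumerate(families)
]
report = cn.evaluation_report(prepared, cn.ClsParams())

avg = report[report["family"] == "AVERAGE"]
print(avg[["method", "auc", "auc01", "sens@0.90"]].to_string(index=False))
print(
    "\nEach row averages per-family scores over the 8 families. The combined\n"
    "Cls should beat plain KL conservation here: the planted coevolution\n"
    "network around the catalytic site is what the pMI term picks up."
)
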