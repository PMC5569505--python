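"""Pathway presence calls and domain-level gene-family statistics.

A pathway is called present only if every key enzyme is confirmed by at
least two annotation sources AND strictly more than half of its
components are detected. Gene-family counts are compared between
archaeal and bacterial MAGs with a Mann-Whitney U test, Bonferroni
corrected.
"""

import numpy as np
import pandas as pd

from magsom import profiling, synthetic as syn

# -- pathway calls on simulated four-database annotations ----------------
truth = {
    "mag1": {"mcrA", "mcrB", "mcrG", "mtrA", "mer", "mtd", "ftr", "fwdA"},
    "mag2": {"mcrB", "mtrA", "mer"},  # partial pathway, no key enzyme
}
ann = syn.simulate_annotations(truth, ["hmmer", "blastp", "kaas"], 0.95, 0.0, seed=4)
calls = profiling.call_pathways(ann, profiling.starter_pathways())
sub = calls[calls.pathway_id == "reverse_methanogenesis"]
print(sub.to_string(index=False))
print("-> mag1 carries the full pathway incl. the key enzyme mcrA;")
print("   mag2 has 3/8 components and no confirmed key, so no call.\n")

# -- domain comparison of gene-family counts -----------------------------
rng = np.random.default_rng(0)
mags = [f"arch{i}" for i in range(10)] + [f"bact{i}" for i in range(15)]
matrix = pd.DataFrame(
    {
        "GH3": list(rng.poisson(0.3, 10)) + list(rng.poisson(4.0, 15)),
        "alpha_amylase": rng.poisson(2.0, 25),
        "peptidase_M24": rng.poisson(1.5, 25),
    },
    index=mags,
)
domains = {m: ("archaea" if m.startswith("arch") else "bacteria") for m in mags}
out = profiling.domain_comparison_test(matrix, domains)
print(out.to_string(index=False))
print("-> GH3 is enriched in bacteria (adjusted p < 0.05); the two")
print("   null families stay non-significant after Bonferroni.")
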