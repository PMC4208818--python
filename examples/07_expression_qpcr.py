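"""Expression profiling and qPCR quantification.

Simulates a tissue count table with designed preferences, normalizes to
RPKM, clusters the genes (Pearson distance, complete linkage), calls
tissue preferences, then quantifies simulated MeJA-style qPCR series via
2^-ddCt and classifies the regulation of each gene.
"""

import pandas as pd

from iqdfam.expression import (
    ExpressionMatrix,
    QPCRMeasurement,
    cluster_genes,
    regulation_call,
    relative_expression_ddct,
    rpkm_normalize,
    tissue_preference,
)
from iqdfam.simulate import generate_expression_counts, generate_qpcr_ct

tissues = {"young_leaf": 2_000_000, "flower": 1_500_000, "root": 1_800_000,
           "nodule": 1_200_000}
design = {"g1": ("flower", 8.0), "g2": ("flower", 6.0), "g3": ("nodule", 12.0)}
genes = [f"g{i}" for i in range(1, 7)]
counts = generate_expression_counts(design, tissues, genes, seed=6)

lengths = {g: 1200 for g in genes}
matrix = rpkm_normalize(counts, lengths, tissues)
_, leaf_order = cluster_genes(matrix)
print("clustered gene order:", leaf_order)

for gene, pref in tissue_preference(matrix).items():
    flag = " (single-tissue)" if pref.single_tissue else ""
    print(f"{gene}: highest in {pref.top_condition}{flag}")

# qPCR: one induced gene, one repressed gene, over a 1/4/8 h time course
qpcr = generate_qpcr_ct(
    {"gUp": {1.0: 3.0, 4.0: 12.0, 8.0: 5.0},
     "gDown": {1.0: 0.4, 4.0: 0.3, 8.0: 0.2}},
    n_replicates=3, noise_sd=0.0,
)
for gene, sub in qpcr.groupby("gene"):
    by_time = {
        t: QPCRMeasurement(gene, t, list(s.ct_target), list(s.ct_reference))
        for t, s in sub.groupby("timepoint")
    }
    folds = {
        t: relative_expression_ddct(m, by_time[0.0])
        for t, m in sorted(by_time.items()) if t > 0
    }
    call = regulation_call(list(folds.values()))
    pretty = ", ".join(f"{t:g}h: {f:.2f}x" for t, f in folds.items())
    print(f"{gene}: {pretty} -> {call}")
# Folds are relative to the 0-h control (==1 by construction); 'down'
# requires <0.5x at every timepoint, 'up' requires >2x somewhere.
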