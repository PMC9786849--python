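"""RNA-seq QC around an external differential-expression test.

TPM-normalizes a small staged counts matrix, screens replicate consistency
by Z-score complete-linkage biclustering (flagging a planted replicate that
clusters with the wrong group), intersects three per-stage DE lists, and
computes a ΔΔCt relative-expression fold.
"""

import numpy as np
import pandas as pd

from poolmap import expression_qc as eq

rng = np.random.default_rng(0)
genes = [f"g{i:03d}" for i in range(80)]
base = {"wt": rng.integers(100, 600, size=80), "mut": rng.integers(100, 600, size=80)}
cols, meta = {}, {}
for genotype in ("wt", "mut"):
    for r in (1, 2, 3):
        name = f"tet_{genotype}{r}"
        profile = base[genotype]
        if name == "tet_mut3":  # planted inconsistent replicate
            profile = base["wt"] + 40
        cols[name] = profile + rng.integers(0, 12, size=80)
        meta[name] = {"stage": "tetrad", "genotype": genotype, "replicate": r}
matrix = eq.CountsMatrix(pd.DataFrame(cols, index=genes),
                         pd.Series(1500, index=genes), pd.DataFrame(meta).T)

tpm = eq.tpm(matrix)
print("TPM column sums:", tpm.sum(axis=0).round(2).tolist())

qc = eq.replicate_consistency(matrix, top_k=50)
flagged = [s for s, f in qc.flagged.items() if f]
print("replicates flagged as inconsistent:", flagged)
# tet_mut3 clusters with the wild-type samples, so it is flagged for
# exclusion before differential-expression analysis.

de = eq.DEListSet({
    "tetrad": {"g001": "down", "g002": "up", "g003": "down"},
    "microspore": {"g001": "down", "g003": "up", "g004": "up"},
    "young_pollen": {"g001": "down", "g005": "up"},
})
overlap = eq.stage_overlap(de)
triple = overlap.regions[frozenset({"tetrad", "microspore", "young_pollen"})]
print("de-regulated at all three stages:", sorted(triple))
print(overlap.triple_directions)

fold = eq.ddct(ct_target_test=20, ct_ref_test=18,
               ct_target_calibrator=24, ct_ref_calibrator=18)
print(f"ddCt relative expression fold: {fold:g}")
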