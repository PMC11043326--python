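#!/usr/bin/env python
"""Butina-cluster the fingerprints and assign whole clusters to 6 CV folds.

Reads library.tsv, writes folds.csv (compound_id, cluster_id, fold_id) and
reports cluster- and fold-size statistics; no cluster may span folds.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
import pandas as pd

from common import GENERATOR, SEED, outpath
from phenoscreen import chem

tsv = pd.read_csv(outpath("library.tsv"), sep="\t", header=None,
                  names=["compound_id", "fp_hex"])
fps = chem.fingerprints_from_hex(list(tsv["fp_hex"]), GENERATOR.fp_bits)

clustering = chem.butina_cluster(fps, cutoff=0.6)
folds = chem.assign_folds(clustering, k=6, seed=SEED)
chem.write_folds_csv(outpath("folds.csv"), tsv["compound_id"], clustering, folds)

sizes = clustering.sizes()
print(f"Butina at Tanimoto-distance cutoff 0.6: {clustering.n_clusters} clusters "
      f"(sizes median {int(np.median(sizes))}, max {sizes.max()})")
print(f"fold sizes: {[int(s) for s in folds.fold_sizes()]} "
      f"(range {folds.fold_sizes().max() - folds.fold_sizes().min()} "
      f"<= max cluster {sizes.max()})")
for cid in range(clustering.n_clusters):
    assert len(set(folds.fold_ids[clustering.cluster_ids == cid])) == 1
print("verified: no cluster spans folds")
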