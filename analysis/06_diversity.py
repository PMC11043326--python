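#!/usr/bin/env python
"""Chemical diversity of the top-20 ranked compounds per assay and modality.

For every assay predicted above 0.6 mean ROC-AUC in all modalities, each
test split's top-20 ranked compounds are compared (max Tanimoto) to the known
actives of the corresponding training folds.  Lower similarity = more novel
chemotypes.  Writes diversity.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
import pandas as pd

from common import GENERATOR, outpath
from phenoscreen import chem, evaluate as ev
from phenoscreen.pipeline import read_label_table
from phenoscreen.screenlib import top_k_diversity

tsv = pd.read_csv(outpath("library.tsv"), sep="\t", header=None,
                  names=["compound_id", "fp_hex"])
labels = read_label_table(outpath("labels.csv")).reindex(list(tsv["compound_id"]))
folds = pd.read_csv(outpath("folds.csv")).set_index("compound_id").loc[
    labels.compounds, "fold_id"].to_numpy()
fp_matrix = chem.fingerprints_from_hex(list(tsv["fp_hex"]), GENERATOR.fp_bits)
fps = dict(zip(tsv["compound_id"], fp_matrix))
predictions = pd.read_csv(outpath("predictions.csv"))
auc_table = pd.read_csv(outpath("auc_table.csv"))

per_assay = auc_table.pivot_table(index="assay_id", columns="modality",
                                  values="roc_auc", aggfunc="mean")
eligible = set(per_assay.index[(per_assay > 0.6).all(axis=1)])
print(f"{len(eligible)} assays above 0.6 mean ROC-AUC in all modalities: "
      f"{sorted(eligible)}")

plan = ev.make_split_plan(6)
rows = []
for (modality, split_id), grp in predictions.groupby(["modality", "split_id"]):
    train_folds = plan.splits[split_id][0]
    train_mask = np.isin(folds, train_folds)
    for assay in eligible:
        if assay not in grp.columns:
            continue
        col_idx = labels.assays.index(assay)
        actives = [labels.compounds[i] for i in np.flatnonzero(
            train_mask & (labels.labels[:, col_idx] == 1))]
        if not actives:
            continue
        ranked = grp.sort_values(assay, ascending=False)["compound_id"].tolist()
        res = top_k_diversity(ranked, actives, fps, k=20, assay_id=assay)
        rows.append({"assay_id": assay, "modality": modality, "split_id": split_id,
                     "mean_top20_tanimoto": res.mean})

div = pd.DataFrame(rows)
div.to_csv(outpath("diversity.csv"), index=False)
print(div.groupby("modality")["mean_top20_tanimoto"].agg(["mean", "std"]).round(4))
print("higher = top predictions rehash known chemotypes; "
      "structure-based rankings are expected to score highest")
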