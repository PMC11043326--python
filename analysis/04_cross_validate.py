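#!/usr/bin/env python
"""Train the masked multi-task models under 6-fold nested scaffold CV.

Feature-vector (morphology) and fingerprint (structure) modalities share the
splits.  Writes auc_table.csv, predictions.csv (pooled test-split scores)
and summary.json; prints the per-modality headline numbers (mean +/- SD
ROC-AUC over assays and the >= 0.7 / 0.8 / 0.9 fractions).
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
import pandas as pd

from common import GENERATOR, MIN_ACTIVES, MIN_INACTIVES, MODEL, outpath
from phenoscreen import chem, evaluate as ev
from phenoscreen.pipeline import filter_assays, read_label_table
from phenoscreen.synthetic import CompoundLibrary, ProfileTable

tsv = pd.read_csv(outpath("library.tsv"), sep="\t", header=None,
                  names=["compound_id", "fp_hex"])
labels = read_label_table(outpath("labels.csv")).reindex(list(tsv["compound_id"]))
labels.truth = pd.read_csv(outpath("truth.csv"), index_col="compound_id").loc[
    labels.compounds, labels.assays].to_numpy()
labels = filter_assays(labels, MIN_ACTIVES, MIN_INACTIVES)

folds = pd.read_csv(outpath("folds.csv")).set_index("compound_id").loc[
    labels.compounds, "fold_id"].to_numpy()
profiles = ProfileTable.from_csv(outpath("profiles_normalized.csv"))
library = CompoundLibrary(
    compound_ids=list(tsv["compound_id"]),
    fingerprints=chem.fingerprints_from_hex(list(tsv["fp_hex"]), GENERATOR.fp_bits),
    mechanisms=np.zeros((len(tsv), 1)), cluster_ids=np.zeros(len(tsv), dtype=int),
    cluster_mechanisms=np.zeros((1, 1)),
)

plan = ev.make_split_plan(6)
bundles = {
    "features": ev.bundle_from_profiles(profiles, labels, folds),
    "structure": ev.bundle_from_fingerprints(library, labels, folds),
}
tables, preds = [], []
for modality, bundle in bundles.items():
    cfg = MODEL.with_(modality=modality)
    table, pms, _ = ev.cross_validate(bundle, cfg, plan)
    tables.append(table)
    for pm in pms:
        frame = pd.DataFrame(pm.scores, columns=labels.assays)
        frame.insert(0, "compound_id", pm.compounds)
        frame.insert(1, "modality", modality)
        frame.insert(2, "split_id", pm.split_id)
        preds.append(frame)

auc_table = pd.concat(tables, ignore_index=True)
auc_table.to_csv(outpath("auc_table.csv"), index=False)
pd.concat(preds, ignore_index=True).to_csv(outpath("predictions.csv"), index=False)

summary = ev.summarize(auc_table)
slim = {m: {k: v for k, v in s.items() if k != "per_assay_mean"}
        for m, s in summary.items()}
outpath("summary.json").write_text(json.dumps(slim, indent=2))

for modality, s in summary.items():
    print(f"{modality}: mean ROC-AUC {s['mean_auc_over_assays']:.3f} "
          f"+/- {s['sd_auc_over_assays']:.3f} over {s['n_assays']} assays; "
          f"fractions >=0.7/0.8/0.9 = {s['frac_assays_auc_ge_0.7']:.2f}/"
          f"{s['frac_assays_auc_ge_0.8']:.2f}/{s['frac_assays_auc_ge_0.9']:.2f}")
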