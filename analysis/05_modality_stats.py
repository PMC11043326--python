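#!/usr/bin/env python
"""Compare modalities and assay groups with rank statistics.

Friedman rank-sum test blocked by assay on per-assay mean AUC (features vs
structure), Nemenyi post-hoc, and Kruskal-Wallis + Conover over the panel's
linkage annotation.  Writes stats.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd

from common import outpath
from phenoscreen import stats as pst

auc_table = pd.read_csv(outpath("auc_table.csv"))
per_assay = (auc_table.groupby(["assay_id", "modality"])["roc_auc"]
             .mean().reset_index())

table = pst.BlockedTable.from_long(per_assay, "assay_id", "modality", "roc_auc")
fried = pst.friedman_blocked(table)
nem = pst.nemenyi_posthoc(table)
print(f"Friedman (assay-blocked) chi2 = {fried.statistic:.3f}, "
      f"p = {fried.p_value:.2e} [{pst.significance_stars(fried.p_value)}]")
print("Nemenyi pairwise p:")
print(nem.pairwise_p.round(4))

ann = pd.read_csv(outpath("assay_annotations.csv"))
feat = per_assay[per_assay["modality"] == "features"].merge(ann, on="assay_id")
report = {
    "modality_friedman": {"statistic": fried.statistic, "p_value": fried.p_value},
    "modality_nemenyi_pairwise_p": nem.pairwise_p.to_dict(),
}
groups = feat["linkage"]
if (groups.value_counts() >= 2).sum() >= 2:
    kr = pst.kruskal_conover(feat["roc_auc"], groups)
    print(f"Kruskal-Wallis over linkage groups: H = {kr.statistic:.3f}, "
          f"p = {kr.p_value:.3g} [{pst.significance_stars(kr.p_value)}]")
    report["linkage_kruskal"] = {"statistic": kr.statistic, "p_value": kr.p_value,
                                 "conover_pairwise_p": kr.pairwise_p.to_dict()}
outpath("stats.json").write_text(json.dumps(report, indent=2, default=float))
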