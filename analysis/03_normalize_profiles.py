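#!/usr/bin/env python
"""Normalise well profiles against per-plate DMSO controls and drop flat features.

Robust z-score (median/MAD of control wells, per plate and feature) followed
by the variance >= 1.0 filter.  Writes profiles_normalized.csv and
kept_features.txt.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import outpath
from phenoscreen import preprocess as pre
from phenoscreen.synthetic import ProfileTable

profiles = ProfileTable.from_csv(outpath("profiles.csv"))
normalized = pre.robust_z_normalize(profiles)
filtered, kept = pre.variance_filter(normalized, threshold=1.0)

filtered.to_csv(outpath("profiles_normalized.csv"))
outpath("kept_features.txt").write_text("\n".join(kept) + "\n")

n_before = len(profiles.feature_columns)
print(f"normalised {profiles.frame.shape[0]} wells on "
      f"{profiles.frame['plate_id'].nunique()} plates")
print(f"variance filter kept {len(kept)}/{n_before} features")
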