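#!/usr/bin/env python
"""Simulate the screening campaign: compound library, assay panel, labels, profiles.

Writes library.tsv (id + fingerprint hex), labels.csv (long ternary matrix),
truth.csv (latent ground truth, kept only to emulate follow-up screens),
assay_annotations.csv and profiles.csv, then reports the realised fill and
hit rates against the configured 47.8% / 3%.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd

from common import GENERATOR, outpath
from phenoscreen import synthetic as syn
from phenoscreen.pipeline import write_label_table

cfg = GENERATOR
library = syn.generate_library(cfg)
panel = syn.generate_panel(cfg)
labels = syn.generate_labels(library, panel, cfg)
profiles = syn.generate_profiles(library, panel, cfg)

library.to_tsv(outpath("library.tsv"))
write_label_table(labels, outpath("labels.csv"))
pd.DataFrame(labels.truth, index=labels.compounds, columns=labels.assays).to_csv(
    outpath("truth.csv"), index_label="compound_id")
panel.annotations().to_csv(outpath("assay_annotations.csv"), index=False)
profiles.to_csv(outpath("profiles.csv"))

print(f"simulated {library.n_compounds} compounds x {panel.n_assays} assays")
print(f"label-matrix fill rate: {labels.fill_rate():.3f} (configured {cfg.fill_rate})")
print(f"active fraction among observed labels: {labels.hit_rate():.3f} "
      f"(configured {cfg.hit_rate})")
print(f"profile table: {profiles.frame.shape[0]} wells "
      f"({int(profiles.frame['is_control'].sum())} DMSO controls) "
      f"x {len(profiles.feature_columns)} features")
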