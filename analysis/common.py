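"""Shared configuration and paths for the numbered analysis scripts.

The analysis emulates a full screening campaign at desk scale: 2,000 compounds in
~200 scaffold clusters screened against a mixed 8-assay panel (3 assays
readable from phenotype only, 2 from both modalities, 2 scaffold-confined
structure assays, 1 unlinked negative control), with a 50% label-matrix fill
rate and 3% hit rate.  Scripts are meant to be run in order from the
repository root; each reads the artifacts of its predecessors from
``results/analysis``.
"""

from pathlib import Path

from phenoscreen.model import ModelConfig
from phenoscreen.synthetic import GeneratorConfig

OUTDIR = Path("results/analysis")

SEED = 1

PANEL_LINKAGE = ("phenotype",) * 3 + ("both",) * 2 + ("structure",) * 2 + ("none",)

GENERATOR = GeneratorConfig(
    n_compounds=2000,
    n_assays=8,
    n_clusters=200,
    fp_bits=1024,
    fill_rate=0.478,
    hit_rate=0.03,
    n_plates=16,
    replicates_per_compound=2,
    n_features=96,
    phenotype_snr=5.0,
    plate_effect_sd=1.0,
    modality_linkage=PANEL_LINKAGE,
    seed=SEED,
)

MODEL = ModelConfig(hidden_layers=2, hidden_width=128, optimizer="adam",
                    learning_rate=1e-3, max_epochs=40, patience=6, seed=SEED)

# at 2,000 compounds an assay sees ~960 labels and ~29 actives; the full-scale
# 50/50 inclusion rule scales to 15/15 here
MIN_ACTIVES = MIN_INACTIVES = 15


def outpath(name: str) -> Path:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    return OUTDIR / name
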