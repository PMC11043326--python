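# phenoscreen

Phenotypic bioactivity prediction at desk scale: can a single morphological
profiling screen (Cell Painting-style), combined with cheap
single-concentration HTS readouts, predict which compounds are active across
a whole panel of assays — well enough to shrink follow-up screens?

`phenoscreen` implements that analysis as a tested, reusable pipeline for
computational chemists and screening scientists:

- a **synthetic campaign generator** (compound library with latent scaffold
  clusters, assay panel, incomplete ternary label matrix, plate-structured
  well profiles, optional tiny multichannel images) so every stage is
  testable without proprietary data;
- **scaffold-split cross-validation**: ECFP4 fingerprints → Butina
  sphere-exclusion clustering → whole clusters assigned to 6 folds, nested
  train/validation/test rotation;
- **masked multi-task learners**: one network with a sigmoid output per
  assay, trained with focal-modulated binary cross-entropy where unknown
  compound × assay cells contribute exactly zero loss and gradient;
- **evaluation**: per-assay ROC-AUC over known labels, threshold fractions
  (≥ 0.7 / 0.8 / 0.9), modality comparisons via assay-blocked Friedman +
  Nemenyi and Kruskal-Wallis + Conover;
- **screen planning**: top-k nearest-active Tanimoto diversity, simulated
  follow-up screens with bootstrap hit-rate enrichment, and the analytic
  enrichment ceiling min(1/f, 1/h) — selecting the top 5% of a library can
  never enrich more than 20-fold, the top 0.5% never more than 200-fold.

## The model in brief

For compound *i* with input x<sub>i</sub> (morphological feature vector,
1024-bit ECFP4 fingerprint, or image) and assay *a*, a network f predicts
p<sub>ia</sub> = σ(f<sub>a</sub>(x<sub>i</sub>)) ∈ [0, 1]. With ternary
labels y<sub>ia</sub> ∈ {0, 1, unknown} the training objective is the masked
focal loss

    L = mean over observed (i,a) of  −(1 − p_t)^γ log p_t ,
    p_t = p_ia if y_ia = 1 else 1 − p_ia ,   γ = 2 by default,

so the ~50%-empty label matrix needs no imputation and rare actives (~3% of
known labels) are up-weighted. Generalisation is measured across *scaffolds*:
Butina clusters at Tanimoto distance 0.6 never straddle a fold boundary, so
test compounds are new chemotypes. See `docs/methods.md` for the full
description.

## Worked example

The numbered scripts under `analysis/` run the whole campaign-shaped analysis
on a simulated campaign (2,000 compounds, 8 assays with mixed
modality-linkage, 47.8% label fill, 3% hit rate). From the repository root:

```bash
python analysis/01_simulate.py
python analysis/02_scaffold_split.py
python analysis/03_normalize_profiles.py
python analysis/04_cross_validate.py
python analysis/05_modality_stats.py
python analysis/06_diversity.py
python analysis/07_enrichment.py
```

Stage 1 reports the realised label-matrix structure:

```
simulated 2000 compounds x 8 assays
label-matrix fill rate: 0.476 (configured 0.478)
active fraction among observed labels: 0.032 (configured 0.03)
```

Stage 2 confirms split integrity (`200 clusters`, `fold sizes: [334, 334,
333, 333, 333, 333]`, `no cluster spans folds`). Stage 4 trains the
feature-vector and fingerprint models under 6-fold nested CV and prints the
headline numbers:

```
features:  mean ROC-AUC 0.777 +/- 0.256 over 8 assays; fractions >=0.7/0.8/0.9 = 0.62/0.62/0.50
structure: mean ROC-AUC 0.479 +/- 0.137 over 8 assays; fractions >=0.7/0.8/0.9 = 0.00/0.00/0.00
```

Read: the morphology model recovers the phenotype-linked assays
(individually 0.88–0.98 AUC) while the unlinked control assay stays at
chance; the fingerprint model is at chance *everywhere* because the planted
activity signal is confined to scaffold clusters and the split forces
prediction on unseen chemotypes — the scaffold-hopping failure mode
structure models are known for. Stage 7 turns rankings into screen design:

```
 assay_id  modality  mean_auc  median_enrichment  ceiling
ASSAY0003  features     0.984             15.000     20.0
ASSAY0001  features     0.980             18.258     20.0
ASSAY0004  features     0.875              6.818     20.0
...
```

Screening only the top 5% of the ranking multiplies the hit rate ~7–18×
for well-predicted assays (bounded by the 20× ceiling), and ~1× for
chance-level ones.

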