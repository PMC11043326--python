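# Methods

## Problem setting

High-throughput screening (HTS) campaigns test large compound libraries one
assay at a time. A cheaper alternative is to profile the whole library once
with a morphological assay (Cell Painting-style multichannel imaging, or
features derived from it) and train, per target, a model that predicts
single-concentration active/inactive calls from those profiles. The model
then ranks the library so only a small, enriched subset needs wet-lab
confirmation. `phenoscreen` implements that analysis end to end at desk
scale: a synthetic campaign generator, scaffold-aware cross-validation,
masked multi-task learners for three input modalities, per-assay ROC-AUC
evaluation, chemical-diversity scoring of top predictions, simulated
follow-up screens with bootstrap enrichment, and the rank statistics used to
compare modalities.

## The synthetic campaign generator

`synthetic.GeneratorConfig` fixes the campaign; all randomness flows through
one seeded `numpy` generator, so a config is a complete, reproducible
description of a dataset.

**Library.** Compounds belong to latent scaffold clusters (Dirichlet-uneven
sizes, every cluster nonempty). Each cluster has a sparse fingerprint
centroid (bit density 5%, ECFP-like) and each compound flips centroid bits
independently with probability 1%, so within-cluster Tanimoto similarity
(~0.7) far exceeds between-cluster similarity (~0.03). Each cluster also has
a nonnegative 16-dimensional *mechanism* vector (Gamma(2, 0.5) per
coordinate, mean 1); compounds apply multiplicative log-normal jitter
(sd 0.2 on the log scale). The mechanism is the single latent that drives
both labels and phenotype.

**Panel and ground truth.** Each assay probes a sparse nonnegative unit
target direction (3 of 16 mechanism coordinates). Truth is "mechanism-target
alignment above the per-assay (1 − hit rate) quantile", so the active
fraction equals the configured hit rate by construction. A per-assay
`linkage` flag decides which modality can in principle see the signal:
`phenotype`/`both` assays threshold the per-compound mechanism and imprint
it on the profiles; `structure` assays threshold the *cluster* mechanism
(signal confined to scaffolds and invisible in profiles); `none` assays are
independent Bernoulli labels — a built-in negative control.

**Labels.** Every compound × assay cell is observed independently with
probability `fill_rate` (default 0.478, the reference campaign's fill rate); observed
labels flip with probability `label_flip_rate` to emulate single-point
readout noise. The default flip rate is 0: the noise level of real
single-concentration readouts is not quantified anywhere usable, and a
nonzero default corrupts the *evaluation* labels too, capping every
measurable AUC. Noise is therefore an explicit dial, exercised by the
monotone-degradation test (AUC non-increasing over flip rates 0 → 0.2 →
0.4).

**Profiles.** Wells live on emulated 384-well plates with 16 DMSO control
wells each; compound replicates (default 2) are spread round-robin across
plates. A well's feature vector is

    baseline + plate offset + [snr x signature(mechanism) if truly active
    in any phenotype-linked assay] + N(0, 1) noise,

where the signature is a fixed nonnegative random projection of the
mechanism into feature space. Active compounds therefore shift a
mechanism-specific subset of features upward; `phenotype_snr = 0` makes
actives and inactives exchangeable. Plate offsets are additive
N(0, `plate_effect_sd`²) per plate and feature. Replicate rows share
everything but the well noise and their plate's offset.

**Images (optional).** Tiny multichannel (1/3/5-channel, ≤128 px) renders of
Gaussian-blob "cells" on a dim background, 16-bit intensity range; for
phenotype-active compounds, per-channel blob gain scales with the mechanism
through a fixed channel weighting. This is a statistical stand-in — no cell
morphology, staining physics or optics is modelled — sufficient to exercise
the CNN path and channel-expansion logic.

What the generator deliberately does *not* reproduce: real assay-to-assay
correlation structure, concentration-response behaviour, plate-position
(edge) effects, batch drifts, or chemically meaningful fingerprints. Tests
passing on this generator show the *pipeline machinery* is sound (masking,
splitting, normalisation, ranking arithmetic, statistics), not that any
particular real campaign would reach the same AUCs.

## Scaffold-split cross-validation

Fingerprints are clustered by sphere exclusion (Butina) at Tanimoto
*distance* ≤ 0.6 (similarity 0.4) — there is no canonical cutoff;
0.6 gives moderate clusters on sparse fingerprints and is configurable. The greedy rule is deterministic: the unassigned compound with
the most unassigned neighbours seeds each cluster (ties to the lowest input
index). Neighbour counts are maintained incrementally, so clustering is
O(n²) after the similarity matrix.

Whole clusters are then placed into k = 6 folds, largest cluster first, each
into the currently smallest fold — so structurally similar compounds never
straddle a fold boundary, and the fold-size range is bounded by the largest
cluster. Split *i* of the nested CV tests fold *i*, validates on fold
(*i*+1) mod k (checkpoint selection only), and trains on the remaining four.
Each compound is tested exactly once; training histories record the compound
ids seen so leakage is auditable.

## Preprocessing

- **Percentile clipping** (images): intensities clipped per channel to the
  [1, 99] percentile range. The bounds are order statistics (`lower`/
  `higher` percentile methods) rather than interpolated values; interpolated
  bounds would make the operation non-idempotent because clipping shifts the
  interpolated percentiles inward, whereas order-statistic bounds are fixed
  points. With 16-bit integer data the choice is visible.
- **Robust z-normalisation** (profiles): per plate and feature,
  x → (x − median of DMSO controls) / max(MAD of controls, 1e-6). The MAD is
  used raw — no 1.4826 Gaussian-consistency factor — the literal reading of
  median-absolute-deviation normalisation; `scale_mad=True` switches the
  Gaussian-consistent variant on. Zero-MAD features are logged
  and divided by the epsilon guard; the variance filter removes them in
  practice. Plates need ≥ 4 control wells (the generator provides 16).
- **Variance filter**: features with variance < 1.0 over all wells (after
  normalisation) are dropped as uninformative; the kept-feature list is part
  of the run's artifacts.
- **Replicate aggregation**: arithmetic column-wise mean, used both for
  per-compound prediction averaging and anywhere replicate rows collapse.

## The masked multi-task learner

One network predicts all assays at once (multi-label binary prediction, one
sigmoid output per assay). The objective is binary cross-entropy modulated
by the focal factor (1 − p_t)^γ with γ = 2 by default (γ = 0 is plain BCE) —
focal weighting matters at ~3% hit rates. The combination of BCE and focal weighting is
implemented as focal-modulated BCE (one term); a literal 1:1 sum is available as
`loss="bce+focal"`. Cells with unknown labels contribute *exactly* zero to
the loss and its gradient — verified by finite-difference tests — so the
incomplete label matrix needs no imputation.

Networks are numpy modules with hand-written backward passes (verified
against finite differences): an MLP (ReLU, He initialisation) for feature
vectors and fingerprints, and a small CNN (3×3 conv → ReLU → 2×2 mean-pool
blocks, global average pooling, linear head) for tiny images.
`expand_input_channels` widens a 3-input-channel first-layer kernel to 5 by
repeating channels 1, 2 — the standard trick for feeding 5-channel stains to
an RGB filter bank. The output bias is initialised to the log-odds of the
observed per-assay base rate, the usual prior-probability trick for rare
positives.

Training: minibatch SGD or Adam; after each epoch the mean per-assay
validation ROC-AUC is computed on per-compound averaged scores, the best
checkpoint is kept, the learning rate is divided by 10 after `patience`
epochs without improvement, and training stops after two reductions plus a
further exhausted patience. Reference hyperparameter settings for full-scale campaigns are exposed as
config factories (features: 3×1024 MLP, SGD lr 5.0;
structure: 3×512, SGD lr 2.0; images: SGD, weight decay 1e-4, learning rate
0.2·batch/256 with batch 64 — the per-sample reading of "0.2/256"). The
desk-scale experiments use a deliberately small configuration (2×128 MLP,
Adam 1e-3, ≤40 epochs, patience 6) that trains in seconds at 2,000
compounds; exact early-stopping schedules are package conventions, not
reproductions.

## Evaluation and summaries

ROC-AUC is computed by midrank (Mann-Whitney) over compounds with known
labels only; single-class label sets yield a NaN sentinel which is excluded
from means and counted, never imputed as 0.5. Summaries report per-assay
means over splits, the grand mean ± SD both over assays and over
assay × split cells (both averaging conventions appear in practice), and
the fractions of assays at ≥ 0.7 / 0.8 / 0.9.

## Diversity and follow-up enrichment

For each assay and split, the top 20 test-ranked compounds are compared to
the known actives of the training folds; each contributes its maximum
Tanimoto similarity, and the mean is the assay/split diversity score (lower
= more novel chemotypes). The assay filter — mean AUC > 0.6 in every
modality — is applied by the analysis driver.

Follow-up screens are simulated by pooling test-split scores into one
ranking per assay (raw score concatenation; per-split rank normalisation is
a caller option), selecting the top 5% plus a uniform random baseline, and
reading both sets' labels off the generator's latent truth (the stand-in for
a secondary-assay readout). Enrichment = selected hit rate / baseline hit
rate, bootstrapped (default n = 100, resampling both sets); replicates whose
resampled baseline has no actives are excluded and counted. The analytic
ceiling min(1/f, 1/h) bounds the *observed* (un-resampled) enrichment —
selecting 5% can never enrich more than 20-fold, 0.5% more than 200-fold;
individual bootstrap replicates can wobble past it because the denominator
is resampled. The baseline estimate uses the random sample, not the
unknowable full-library truth. In the frozen benchmark the baseline holds
2,000 compounds (500 is the usual minimum): at a 3% hit rate a
500-compound baseline carries a ~±25% Poisson error in the denominator,
which would dominate the null-enrichment band.

## Rank statistics

Modalities are compared with the Friedman rank-sum test using assays as
blocks (tie-corrected, Conover form; reduces to the classical
12/(bk(k+1))·ΣR² − 3b(k+1) without ties), followed by Nemenyi's post-hoc on
mean-rank differences referred to the studentized range (df = ∞). With few
blocks the chi-square reference is a poor approximation of the coarse,
discrete permutation null, so whenever that null has at most ~2×10⁵
outcomes ((k!)^b) the Friedman p value is computed by exact enumeration of
all within-block rank permutations; the chi-square asymptote is used beyond
that. Assay
groupings use Kruskal-Wallis plus Conover-Iman pairwise t statistics with
Holm adjustment (configurable: none/holm/bonferroni). Blocks missing a treatment are dropped complete-case with a
warning. Star bands for reports: * 0.05–0.01, ** 0.01–10⁻³, *** 10⁻³–10⁻⁴,
**** below.

## Frozen benchmark experiments (`benchmarks.py`)

- **Signal recovery**: 2,000 compounds, 200 clusters, 96 features, fill 0.5,
  hit rate 0.03, SNR 5; panel of 2 phenotype-linked + 6 unlinked assays.
  The 6 unlinked assays exist because a single assay at 3% hit rate holds
  only ~30 observed actives, making any single-assay AUC noisy (SD ≈ 0.05);
  the null statistic is the mean over the unlinked assays (~180 actives
  pooled). Expected behaviour: linked mean AUC ≫ 0.8, null mean within
  0.45–0.55, everything at chance after shuffling labels across compounds.
- **Enrichment recovery**: as above but 8,000 compounds and one
  phenotype-linked assay at SNR 8, so the pooled test AUC exceeds 0.9 and
  the 5% selection holds 400 compounds; with a random ranking the same
  machinery must report enrichment ≈ 1.
- **Diversity direction**: 8 scaffold-confined (`structure`-linked) assays,
  hit rate 0.05; structure-based rankings should show a higher mean top-20
  Tanimoto to training actives than phenotype-based rankings, which carry no
  signal on this panel and rank essentially at random.

Problem sizes are chosen so each experiment completes in roughly one to two
minutes on a single CPU.

## Known limitations

- The image path is a statistical emulation; no transfer learning or
  full-resolution training is provided.
- Butina cutoff, fold balancing, early-stopping schedule and the Conover
  adjustment are package conventions; outputs are structurally faithful to
  the emulated design, not bit-identical to any particular campaign.
- The generator's independence assumptions (assays independent given the
  mechanism, iid well noise) understate the correlation structure of real
  campaigns; real-data AUC distributions will be wider than the synthetic
  ones.
- Real-data adapters (`read_label_table`, `ProfileTable.from_csv`, SMILES
  TSV + `ecfp4_fingerprint`) accept the documented formats but no public
  dataset download is bundled.
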