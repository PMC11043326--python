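"""Synthetic compound-screening data with the structure of a Cell Painting / HTS campaign.

The generator emulates, at configurable scale, the joint structure the
analysis assumes:

* a compound library organised into latent scaffold clusters, each cluster
  sharing a sparse ECFP-like fingerprint centroid and a nonnegative latent
  *mechanism* vector (per-compound jitter on both);
* an assay panel in which each assay probes a sparse nonnegative *target*
  direction in mechanism space; ground-truth activity is "mechanism-target
  alignment above a per-assay quantile threshold", calibrated so the active
  fraction equals the configured hit rate;
* an incomplete compound x assay label matrix: each cell observed
  independently with probability ``fill_rate`` (default 0.478), observed
  labels flipped with probability ``label_flip_rate`` to emulate single-point
  readout noise;
* well-level morphological profiles on 384-well plates with DMSO control
  wells, additive plate effects, and a mechanism-specific feature signature
  added only for compounds truly active in a phenotype-linked assay;
* optionally, small multichannel images of Gaussian-blob "cells" whose
  intensities shift with the active mechanisms.

Assay ``linkage`` controls which input modality can in principle predict an
assay: ``phenotype``/``both`` assays derive truth from the per-compound
mechanism and imprint it on the profiles; ``structure`` assays derive truth
from the *cluster* mechanism (signal confined to scaffolds, invisible in the
profiles); ``none`` assays are labelled independently of everything.

All randomness flows through one :class:`numpy.random.Generator` derived from
``GeneratorConfig.seed``; identical configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayPanel",
    "CompoundLibrary",
    "GeneratorConfig",
    "ImageSet",
    "LabelMatrix",
    "ProfileTable",
    "generate_images",
    "generate_labels",
    "generate_library",
    "generate_panel",
    "generate_profiles",
    "latent_activity",
]

MECHANISM_DIM = 16
CENTROID_BIT_DENSITY = 0.05
WITHIN_CLUSTER_FLIP = 0.01
MECHANISM_JITTER = 0.2
CONTROLS_PER_PLATE = 16  # 384-well plate emulation; remaining 368 wells hold compounds
WELLS_PER_PLATE = 384

ASSAY_TYPES = ("cell-based", "biochemical")
TECHNOLOGIES = ("chemiluminescence", "fluorescence-intensity", "spectrophotometry", "TR-FRET")
TARGET_CLASSES = ("kinase", "protease", "GPCR", "ion-channel", "transferase", "oxidoreductase")
THERAPY_AREAS = ("oncology", "respiratory-immunology", "cardiovascular-renal-metabolism", "neuroscience")


class InvalidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic screening campaign.

    Defaults mirror the reference campaign this package emulates: 8,300
    compounds, 140 single-point
    assays, 1024-bit fingerprints, a 47.8% label-matrix fill rate and a 3%
    active fraction among observed labels.  ``label_flip_rate`` defaults to 0
    so single-point noise is an explicit experimental dial.
    """

    n_compounds: int = 8300
    n_assays: int = 140
    n_clusters: int = 600
    fp_bits: int = 1024
    fill_rate: float = 0.478
    hit_rate: float = 0.03
    label_flip_rate: float = 0.0
    n_plates: int = 48
    replicates_per_compound: int = 2
    n_features: int = 1176
    phenotype_snr: float = 3.0
    plate_effect_sd: float = 1.0
    modality_linkage: str | Sequence[str] = "phenotype"
    image_size: int = 32
    image_channels: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_compounds", "n_assays", "n_clusters", "fp_bits", "n_plates",
                     "replicates_per_compound", "n_features"):
            if int(getattr(self, name)) < 1:
                raise InvalidConfigError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_clusters > self.n_compounds:
            raise InvalidConfigError("n_clusters may not exceed n_compounds")
        if not 0.0 < self.fill_rate <= 1.0:
            raise InvalidConfigError(f"fill_rate must lie in (0, 1], got {self.fill_rate}")
        if not 0.0 < self.hit_rate < 1.0:
            raise InvalidConfigError(f"hit_rate must lie in (0, 1), got {self.hit_rate}")
        if not 0.0 <= self.label_flip_rate < 1.0:
            raise InvalidConfigError(f"label_flip_rate must lie in [0, 1), got {self.label_flip_rate}")
        if self.phenotype_snr < 0 or self.plate_effect_sd < 0:
            raise InvalidConfigError("phenotype_snr and plate_effect_sd must be nonnegative")
        if isinstance(self.modality_linkage, str):
            links = (self.modality_linkage,)
        else:
            links = tuple(self.modality_linkage)
            if len(links) != self.n_assays:
                raise InvalidConfigError("per-assay modality_linkage must have length n_assays")
        for flag in links:
            if flag not in {"phenotype", "structure", "both", "none"}:
                raise InvalidConfigError(f"unknown modality linkage {flag!r}")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed) % 2**31, stream]))

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)

    def linkage_list(self) -> list[str]:
        if isinstance(self.modality_linkage, str):
            return [self.modality_linkage] * self.n_assays
        return list(self.modality_linkage)


@dataclass
class CompoundLibrary:
    compound_ids: list[str]
    fingerprints: np.ndarray  # (n, fp_bits) bool
    mechanisms: np.ndarray  # (n, MECHANISM_DIM) nonneg
    cluster_ids: np.ndarray  # (n,) int
    cluster_mechanisms: np.ndarray  # (K, MECHANISM_DIM)
    smiles: list[str] | None = None
    fold_ids: np.ndarray | None = None

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def to_tsv(self, path) -> None:
        """``id<TAB>fingerprint-hex`` (or ``id<TAB>smiles`` when SMILES exist)."""
        from .chem import fingerprints_to_hex

        col = self.smiles if self.smiles is not None else fingerprints_to_hex(self.fingerprints)
        pd.DataFrame({"compound_id": self.compound_ids, "repr": col}).to_csv(
            path, sep="\t", header=False, index=False
        )


@dataclass
class AssayPanel:
    assay_ids: list[str]
    linkage: list[str]
    targets: np.ndarray  # (A, MECHANISM_DIM) nonneg, unit norm
    hit_rates: np.ndarray  # (A,)
    assay_type: list[str]
    technology: list[str]
    target_class: list[str]
    therapy_area: list[str]

    @property
    def n_assays(self) -> int:
        return len(self.assay_ids)

    def annotations(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "assay_id": self.assay_ids,
                "linkage": self.linkage,
                "hit_rate": self.hit_rates,
                "assay_type": self.assay_type,
                "technology": self.technology,
                "target_class": self.target_class,
                "therapy_area": self.therapy_area,
            }
        )


@dataclass
class LabelMatrix:
    """Compound x assay ternary labels: 1 active, 0 inactive, NaN unknown.

    ``truth`` holds the generator's complete latent activity matrix and exists
    only for synthetic data (used to simulate follow-up screens); real-data
    adapters leave it ``None``.
    """

    compounds: list[str]
    assays: list[str]
    labels: np.ndarray  # (n, A) float with NaN for missing
    truth: np.ndarray | None = field(default=None, repr=False)

    def observed_mask(self) -> np.ndarray:
        return ~np.isnan(self.labels)

    def fill_rate(self) -> float:
        return float(self.observed_mask().mean())

    def hit_rate(self) -> float:
        obs = self.observed_mask()
        if not obs.any():
            return float("nan")
        return float(np.nanmean(self.labels))

    def reindex(self, compounds: list[str]) -> "LabelMatrix":
        """Align rows to ``compounds``; compounds without any observed label get
        all-unknown rows (a long-format file cannot mention them)."""
        index = {c: i for i, c in enumerate(self.compounds)}
        labels = np.full((len(compounds), len(self.assays)), np.nan)
        truth = None if self.truth is None else np.zeros(
            (len(compounds), len(self.assays)), dtype=self.truth.dtype)
        for row, c in enumerate(compounds):
            if c in index:
                labels[row] = self.labels[index[c]]
                if truth is not None:
                    truth[row] = self.truth[index[c]]
        return LabelMatrix(list(compounds), list(self.assays), labels, truth)

    def counts_per_assay(self) -> pd.DataFrame:
        obs = self.observed_mask()
        actives = np.nansum(self.labels == 1, axis=0).astype(int)
        inactives = np.nansum(self.labels == 0, axis=0).astype(int)
        return pd.DataFrame(
            {"assay_id": self.assays, "n_active": actives, "n_inactive": inactives,
             "n_observed": obs.sum(axis=0)}
        )


@dataclass
class ProfileTable:
    """Well-level morphological profiles.

    ``frame`` columns: ``plate_id``, ``well_id``, ``compound_id`` (empty for
    controls), ``is_control`` plus one numeric column per feature.
    """

    frame: pd.DataFrame

    META_COLUMNS = ("plate_id", "well_id", "compound_id", "is_control")

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.META_COLUMNS]

    @property
    def features(self) -> np.ndarray:
        return self.frame[self.feature_columns].to_numpy(dtype=float)

    def with_features(self, values: np.ndarray, columns: list[str] | None = None) -> "ProfileTable":
        cols = columns if columns is not None else self.feature_columns
        out = self.frame[list(self.META_COLUMNS)].copy()
        out[cols] = values
        return ProfileTable(out)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ProfileTable":
        frame = pd.read_csv(path)
        missing = set(cls.META_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"profile CSV lacks required columns: {sorted(missing)}")
        frame["compound_id"] = frame["compound_id"].fillna("")
        return cls(frame)


@dataclass
class ImageSet:
    """Tiny multichannel images, one per compound replicate plus DMSO controls."""

    images: np.ndarray  # (n_images, channels, H, W) uint16
    compound_ids: list[str]  # "" for control images
    replicate: np.ndarray


# ---------------------------------------------------------------------------
# generators


def generate_library(config: GeneratorConfig) -> CompoundLibrary:
    """Draw a compound library with latent scaffold clusters.

    Fingerprints are cluster-centroid bit patterns (bit density
    ``CENTROID_BIT_DENSITY``) with independent per-compound bit flips, so
    within-cluster Tanimoto similarity exceeds between-cluster similarity in
    expectation.  Mechanisms are nonnegative cluster-level vectors with
    multiplicative log-normal per-compound jitter.
    """
    rng = config.rng(stream=1)
    n, k = config.n_compounds, config.n_clusters

    # uneven but nonempty cluster sizes: Dirichlet weights + guaranteed singleton seat
    weights = rng.dirichlet(np.full(k, 2.0))
    sizes = np.ones(k, dtype=np.int64)
    extra = rng.multinomial(n - k, weights)
    sizes += extra
    cluster_ids = np.repeat(np.arange(k), sizes)
    rng.shuffle(cluster_ids)

    centroids = rng.random((k, config.fp_bits)) < CENTROID_BIT_DENSITY
    flips = rng.random((n, config.fp_bits)) < WITHIN_CLUSTER_FLIP
    fingerprints = centroids[cluster_ids] ^ flips

    cluster_mech = rng.gamma(shape=2.0, scale=0.5, size=(k, MECHANISM_DIM))
    jitter = np.exp(MECHANISM_JITTER * rng.standard_normal((n, MECHANISM_DIM)))
    mechanisms = cluster_mech[cluster_ids] * jitter

    ids = [f"CPD{i:06d}" for i in range(n)]
    return CompoundLibrary(
        compound_ids=ids,
        fingerprints=fingerprints,
        mechanisms=mechanisms,
        cluster_ids=cluster_ids,
        cluster_mechanisms=cluster_mech,
    )


def generate_panel(config: GeneratorConfig) -> AssayPanel:
    """Draw an assay panel: sparse nonnegative target directions plus annotations."""
    rng = config.rng(stream=2)
    a = config.n_assays
    targets = np.zeros((a, MECHANISM_DIM))
    for i in range(a):
        dims = rng.choice(MECHANISM_DIM, size=3, replace=False)
        targets[i, dims] = np.abs(rng.standard_normal(3))
        targets[i] /= np.linalg.norm(targets[i])
    return AssayPanel(
        assay_ids=[f"ASSAY{i:04d}" for i in range(a)],
        linkage=config.linkage_list(),
        targets=targets,
        hit_rates=np.full(a, config.hit_rate),
        assay_type=list(rng.choice(ASSAY_TYPES, size=a)),
        technology=list(rng.choice(TECHNOLOGIES, size=a)),
        target_class=list(rng.choice(TARGET_CLASSES, size=a)),
        therapy_area=list(rng.choice(THERAPY_AREAS, size=a)),
    )


def latent_activity(library: CompoundLibrary, panel: AssayPanel,
                    config: GeneratorConfig) -> np.ndarray:
    """Ground-truth binary activity matrix (n_compounds x n_assays).

    Mechanism-linked assays threshold the mechanism-target alignment at the
    (1 - hit_rate) quantile over the library, so the active fraction matches
    the configured hit rate by construction.  ``structure``-linked assays use
    the cluster-level mechanism (scaffold-confined signal); ``none`` assays
    are independent Bernoulli draws.
    """
    rng = config.rng(stream=3)
    n = library.n_compounds
    truth = np.zeros((n, panel.n_assays), dtype=np.int8)
    cluster_mech_of = library.cluster_mechanisms[library.cluster_ids]
    for j, link in enumerate(panel.linkage):
        h = panel.hit_rates[j]
        if link == "none":
            truth[:, j] = rng.random(n) < h
            continue
        mech = cluster_mech_of if link == "structure" else library.mechanisms
        score = mech @ panel.targets[j]
        # tiny seeded dither breaks the exact ties of cluster-level scores
        score = score + 1e-9 * rng.standard_normal(n)
        threshold = np.quantile(score, 1.0 - h)
        truth[:, j] = score > threshold
    return truth


def generate_labels(library: CompoundLibrary, panel: AssayPanel,
                    config: GeneratorConfig) -> LabelMatrix:
    """Observe the truth matrix cell-wise at ``fill_rate`` and add flip noise."""
    if library.n_compounds == 0 or panel.n_assays == 0:
        raise ValueError("library and panel must be nonempty")
    rng = config.rng(stream=4)
    truth = latent_activity(library, panel, config)
    observed = rng.random(truth.shape) < config.fill_rate
    labels = truth.astype(float)
    if config.label_flip_rate > 0:
        flips = rng.random(truth.shape) < config.label_flip_rate
        labels = np.where(flips, 1.0 - labels, labels)
    labels[~observed] = np.nan
    return LabelMatrix(
        compounds=list(library.compound_ids),
        assays=list(panel.assay_ids),
        labels=labels,
        truth=truth,
    )


def _plate_layout(config: GeneratorConfig, n_rows: int):
    """Assign compound-replicate rows round-robin to plates; 16 control wells each."""
    capacity = config.n_plates * (WELLS_PER_PLATE - CONTROLS_PER_PLATE)
    if n_rows > capacity:
        raise InvalidConfigError(
            f"{n_rows} compound wells exceed capacity of {config.n_plates} plates "
            f"({capacity} wells); increase n_plates"
        )
    plate_of_row = np.arange(n_rows) % config.n_plates
    return plate_of_row


def generate_profiles(library: CompoundLibrary, panel: AssayPanel,
                      config: GeneratorConfig) -> ProfileTable:
    """Well-level feature table with plate effects, DMSO controls and replicates.

    Each well's feature vector is ``plate offset + control baseline
    [+ phenotype_snr * signature(mechanism) if the compound is truly active in
    any phenotype-linked assay] + unit Gaussian noise``.  The signature is a
    fixed nonnegative random projection of the compound mechanism, so active
    compounds shift a mechanism-specific subset of features upward.
    """
    rng = config.rng(stream=5)
    n, F = library.n_compounds, config.n_features
    truth = latent_activity(library, panel, config)
    pheno_linked = np.array([l in ("phenotype", "both") for l in panel.linkage])
    pheno_active = truth[:, pheno_linked].any(axis=1) if pheno_linked.any() else np.zeros(n, bool)

    baseline = rng.standard_normal(F)
    plate_offsets = config.plate_effect_sd * rng.standard_normal((config.n_plates, F))
    projection = np.abs(rng.standard_normal((MECHANISM_DIM, F))) / MECHANISM_DIM
    signature = library.mechanisms @ projection  # (n, F), O(1) scale entries

    reps = config.replicates_per_compound
    comp_idx = np.repeat(np.arange(n), reps)
    rep_idx = np.tile(np.arange(reps), n)
    plate_of_row = _plate_layout(config, len(comp_idx))

    values = (
        baseline[None, :]
        + plate_offsets[plate_of_row]
        + config.phenotype_snr * (pheno_active[comp_idx, None] * signature[comp_idx])
        + rng.standard_normal((len(comp_idx), F))
    )

    control_plates = np.repeat(np.arange(config.n_plates), CONTROLS_PER_PLATE)
    control_values = (
        baseline[None, :]
        + plate_offsets[control_plates]
        + rng.standard_normal((len(control_plates), F))
    )

    feat_cols = [f"f{j:04d}" for j in range(F)]
    well_counter: dict[int, int] = {}

    def next_well(plate: int) -> str:
        w = well_counter.get(plate, 0)
        well_counter[plate] = w + 1
        return f"W{w:03d}"

    rows_meta = {
        "plate_id": [f"P{p:03d}" for p in plate_of_row],
        "well_id": [next_well(int(p)) for p in plate_of_row],
        "compound_id": [library.compound_ids[i] for i in comp_idx],
        "is_control": np.zeros(len(comp_idx), dtype=bool),
    }
    ctrl_meta = {
        "plate_id": [f"P{p:03d}" for p in control_plates],
        "well_id": [next_well(int(p)) for p in control_plates],
        "compound_id": [""] * len(control_plates),
        "is_control": np.ones(len(control_plates), dtype=bool),
    }
    frame = pd.concat(
        [
            pd.DataFrame({**rows_meta, **dict(zip(feat_cols, values.T))}),
            pd.DataFrame({**ctrl_meta, **dict(zip(feat_cols, control_values.T))}),
        ],
        ignore_index=True,
    )
    return ProfileTable(frame)


def generate_images(library: CompoundLibrary, panel: AssayPanel, config: GeneratorConfig,
                    n_controls: int = 32, snr: float | None = None) -> ImageSet:
    """Tiny multichannel Gaussian-blob images whose intensities track mechanisms.

    Each image contains a handful of blob "cells" on a dim background.
    For compounds truly active in a phenotype-linked assay, per-channel blob
    gain is ``1 + snr * (w_c . mechanism)`` with a fixed nonnegative channel
    weighting, so active mechanisms brighten specific channels.  Intensities
    live in the 16-bit range.
    """
    if config.image_channels not in (1, 3, 5):
        raise ValueError(f"unsupported channel count {config.image_channels}; expected 1, 3 or 5")
    if config.image_size > 128:
        raise ValueError("image size limited to 128x128")
    rng = config.rng(stream=6)
    snr = config.phenotype_snr if snr is None else snr
    H = W = config.image_size
    C = config.image_channels
    truth = latent_activity(library, panel, config)
    pheno_linked = np.array([l in ("phenotype", "both") for l in panel.linkage])
    pheno_active = truth[:, pheno_linked].any(axis=1) if pheno_linked.any() else np.zeros(
        library.n_compounds, bool)

    channel_weights = np.abs(rng.standard_normal((C, MECHANISM_DIM))) / MECHANISM_DIM
    yy, xx = np.mgrid[0:H, 0:W]

    def render(gain: np.ndarray) -> np.ndarray:
        img = np.full((C, H, W), 800.0)
        n_cells = rng.poisson(10) + 3
        for _ in range(n_cells):
            cy, cx = rng.uniform(0, H), rng.uniform(0, W)
            sigma = rng.uniform(1.5, 3.5)
            blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
            amp = rng.uniform(3000, 9000, size=C) * gain
            img += amp[:, None, None] * blob[None, :, :]
        img += rng.normal(0, 60, size=img.shape)
        return np.clip(img, 0, 65535).astype(np.uint16)

    images, ids, reps = [], [], []
    for i in range(library.n_compounds):
        mech_gain = 1.0 + snr * (channel_weights @ library.mechanisms[i]) if pheno_active[i] else np.ones(C)
        for r in range(config.replicates_per_compound):
            images.append(render(mech_gain))
            ids.append(library.compound_ids[i])
            reps.append(r)
    for r in range(n_controls):
        images.append(render(np.ones(C)))
        ids.append("")
        reps.append(r)
    return ImageSet(images=np.stack(images), compound_ids=ids, replicate=np.asarray(reps))
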