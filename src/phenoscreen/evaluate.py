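"""Nested k-fold cross-validation and per-assay ROC-AUC reporting.

The splitting scheme follows scaffold-split practice: compounds are grouped
into clusters, clusters into k folds (default 6), and in split ``i`` fold
``i`` is the held-out test set, fold ``(i+1) mod k`` the validation set used
for checkpoint selection, and the remaining ``k - 2`` folds the training set.
Each fold is tested exactly once; the test fold never influences model
selection.

ROC-AUC is the probability that a random active outranks a random inactive
(ties counted one half), computed over compounds with known labels only; an
assay whose test labels are single-class gets a NaN sentinel rather than a
failure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import ModelConfig, PredictionMatrix, build_model, predict, train
from .synthetic import CompoundLibrary, LabelMatrix, ProfileTable

__all__ = [
    "DataBundle",
    "SplitPlan",
    "bundle_from_fingerprints",
    "bundle_from_profiles",
    "cross_validate",
    "make_split_plan",
    "roc_auc",
    "summarize",
]


def roc_auc(scores, labels) -> float:
    """Mann-Whitney ROC-AUC with midrank tie handling; NaN if single-class.

    ``labels`` may contain NaN (unknown); those entries are dropped before
    computing, mirroring evaluation over known activity values only.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError(f"length mismatch: {scores.shape} vs {labels.shape}")
    known = ~np.isnan(labels)
    scores, labels = scores[known], labels[known]
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class SplitPlan:
    """Train/validation/test fold rotation for nested cross-validation."""

    k: int
    splits: tuple[tuple[tuple[int, ...], int, int], ...]  # (train folds, val fold, test fold)

    def __iter__(self):
        return iter(self.splits)


def make_split_plan(k: int = 6) -> SplitPlan:
    """k rotations: test fold i, validation fold (i+1) mod k, rest train."""
    if k < 3:
        raise ValueError(f"nested CV needs k >= 3 folds, got {k}")
    splits = []
    for test in range(k):
        val = (test + 1) % k
        trains = tuple(f for f in range(k) if f not in (test, val))
        splits.append((trains, val, test))
    return SplitPlan(k=k, splits=tuple(splits))


@dataclass
class DataBundle:
    """One modality's inputs aligned with the label matrix and fold assignment.

    ``inputs`` holds replicate-level rows; ``row_compound`` gives the index of
    each row's compound into ``compound_ids``.  ``labels`` and ``fold_ids``
    are per compound.
    """

    compound_ids: list[str]
    assay_ids: list[str]
    labels: np.ndarray  # (n_compounds, n_assays) with NaN missing
    inputs: np.ndarray
    row_compound: np.ndarray
    fold_ids: np.ndarray
    modality: str

    def __post_init__(self) -> None:
        n = len(self.compound_ids)
        if self.labels.shape[0] != n or len(self.fold_ids) != n:
            raise ValueError("labels/folds not aligned with compound ids")
        if self.row_compound.max(initial=-1) >= n:
            raise ValueError("row_compound index out of range")

    @property
    def input_spec(self):
        return self.inputs.shape[1] if self.inputs.ndim == 2 else self.inputs.shape[1:]


def bundle_from_profiles(profiles: ProfileTable, labels: LabelMatrix,
                         fold_ids: np.ndarray) -> DataBundle:
    """Feature-modality bundle from a (normalised, filtered) profile table."""
    frame = profiles.frame
    rows = frame[~frame["is_control"].astype(bool)].reset_index(drop=True)
    comp_index = {c: i for i, c in enumerate(labels.compounds)}
    row_compound = rows["compound_id"].map(comp_index)
    if row_compound.isna().any():
        unknown = rows.loc[row_compound.isna(), "compound_id"].iloc[0]
        raise ValueError(f"profile compound {unknown!r} absent from label matrix")
    feat_cols = [c for c in rows.columns if c not in ProfileTable.META_COLUMNS]
    return DataBundle(
        compound_ids=list(labels.compounds),
        assay_ids=list(labels.assays),
        labels=labels.labels,
        inputs=rows[feat_cols].to_numpy(dtype=float),
        row_compound=row_compound.to_numpy(dtype=int),
        fold_ids=np.asarray(fold_ids),
        modality="features",
    )


def bundle_from_fingerprints(library: CompoundLibrary, labels: LabelMatrix,
                             fold_ids: np.ndarray) -> DataBundle:
    """Structure-modality bundle: one fingerprint row per compound."""
    if list(library.compound_ids) != list(labels.compounds):
        raise ValueError("library and label matrix list different compounds")
    return DataBundle(
        compound_ids=list(labels.compounds),
        assay_ids=list(labels.assays),
        labels=labels.labels,
        inputs=library.fingerprints.astype(float),
        row_compound=np.arange(library.n_compounds),
        fold_ids=np.asarray(fold_ids),
        modality="structure",
    )


def cross_validate(bundle: DataBundle, config: ModelConfig, plan: SplitPlan
                   ) -> tuple[pd.DataFrame, list[PredictionMatrix], list]:
    """Run the full nested CV loop for one modality.

    For every split: train on the training folds, keep the checkpoint with
    the best validation mean AUC, then score the test fold.  Returns the
    long-format AUC table (one row per assay x split, NaN sentinel for
    single-class test labels), the per-split prediction matrices, and the
    per-split training histories (whose ``train_groups`` audit trail lets
    callers verify that no validation or test compound entered a training
    batch).
    """
    fold_of_row = bundle.fold_ids[bundle.row_compound]
    groups = np.asarray(bundle.compound_ids, dtype=object)[bundle.row_compound]
    records = []
    predictions = []
    histories = []
    for split_id, (train_folds, val_fold, test_fold) in enumerate(plan):
        tr = np.isin(fold_of_row, train_folds)
        va = fold_of_row == val_fold
        te = fold_of_row == test_fold
        y_rows = bundle.labels[bundle.row_compound]
        model = build_model(config, bundle.input_spec, len(bundle.assay_ids))
        model, hist = train(
            model, bundle.inputs[tr], y_rows[tr], bundle.inputs[va], y_rows[va],
            config, train_groups=groups[tr], val_groups=groups[va],
        )
        assert hist.train_groups.isdisjoint(set(map(str, groups[va]))), "validation leakage"
        assert hist.train_groups.isdisjoint(set(map(str, groups[te]))), "test leakage"
        pm = predict(model, bundle.inputs[te], groups=groups[te], split_id=split_id)
        comp_index = {c: i for i, c in enumerate(bundle.compound_ids)}
        test_labels = bundle.labels[[comp_index[c] for c in pm.compounds]]
        for j, assay in enumerate(bundle.assay_ids):
            records.append(
                {"assay_id": assay, "split_id": split_id, "modality": bundle.modality,
                 "roc_auc": roc_auc(pm.scores[:, j], test_labels[:, j])}
            )
        predictions.append(pm)
        histories.append(hist)
    return pd.DataFrame(records), predictions, histories


def summarize(auc_table: pd.DataFrame) -> dict:
    """Aggregate an AUC table into the headline numbers.

    Per assay: mean over splits (NaN sentinel rows excluded, their count
    reported).  Grand summaries are given both averaged over assays and over
    assay x split cells.  Threshold fractions report the share of assays with
    mean AUC >= 0.7 / 0.8 / 0.9.  With several modalities present, each is
    summarised separately under its name.
    """
    if auc_table.empty:
        raise ValueError("empty AUC table")
    out: dict = {}
    for modality, sub in auc_table.groupby("modality"):
        per_assay = sub.groupby("assay_id")["roc_auc"].mean()
        defined = per_assay.dropna()
        cells = sub["roc_auc"].dropna()
        out[modality] = {
            "per_assay_mean": per_assay.to_dict(),
            "mean_auc_over_assays": float(defined.mean()),
            "sd_auc_over_assays": float(defined.std(ddof=1)) if len(defined) > 1 else 0.0,
            "mean_auc_over_cells": float(cells.mean()),
            "sd_auc_over_cells": float(cells.std(ddof=1)) if len(cells) > 1 else 0.0,
            "frac_assays_auc_ge_0.7": float((defined >= 0.7).mean()),
            "frac_assays_auc_ge_0.8": float((defined >= 0.8).mean()),
            "frac_assays_auc_ge_0.9": float((defined >= 0.9).mean()),
            "n_assays": int(len(per_assay)),
            "n_undefined_cells": int(sub["roc_auc"].isna().sum()),
        }
    return out
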