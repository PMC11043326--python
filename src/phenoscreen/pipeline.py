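"""End-to-end orchestration: simulate -> split -> preprocess -> train ->
evaluate -> diversity -> enrichment -> statistics -> report.

:func:`run_all` drives the whole analysis on synthetic data (or on
user-supplied tables loaded through the readers here), writing every
intermediate artifact as plain CSV/TSV/JSON so the stages also compose on
disk.  The numbered scripts under ``analysis/`` are thin wrappers over the
same stage functions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chem import assign_folds, butina_cluster
from .evaluate import (bundle_from_fingerprints, bundle_from_profiles, cross_validate,
                       make_split_plan, summarize)
from .model import ModelConfig
from .preprocess import robust_z_normalize, variance_filter
from .screenlib import bootstrap_enrichment, max_enrichment, select_followup, top_k_diversity
from .stats import BlockedTable, friedman_blocked, kruskal_conover, nemenyi_posthoc
from .synthetic import (GeneratorConfig, LabelMatrix, generate_labels, generate_library,
                        generate_panel, generate_profiles)

__all__ = [
    "RunConfig",
    "RunReport",
    "filter_assays",
    "read_label_table",
    "run_all",
    "write_label_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end run needs; serialisable to/from YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model_configs: dict = field(default_factory=dict)  # modality -> ModelConfig
    k_folds: int = 6
    butina_cutoff: float = 0.6
    min_actives: int = 50
    min_inactives: int = 50
    diversity_k: int = 20
    diversity_auc_threshold: float = 0.6
    enrichment_fraction: float = 0.05
    n_random: int = 500
    n_boot: int = 100
    outdir: str = "results/run"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generator.n_assays < 1:
            raise ValueError("config must request at least one assay")
        if self.k_folds < 3:
            raise ValueError("nested CV needs k_folds >= 3")
        if not 0.0 < self.enrichment_fraction <= 1.0:
            raise ValueError("enrichment_fraction must lie in (0, 1]")
        for modality in self.model_configs:
            if modality not in {"features", "structure"}:
                raise ValueError(f"run_all drives modalities 'features'/'structure', got {modality!r}")

    def resolved_model_configs(self) -> dict[str, ModelConfig]:
        """Fill in desk-scale defaults for any modality not explicitly configured."""
        if self.model_configs:
            return dict(self.model_configs)
        base = ModelConfig(hidden_layers=2, hidden_width=128, optimizer="adam",
                           learning_rate=1e-3, max_epochs=30, patience=5,
                           seed=self.seed)
        return {"features": base, "structure": base.with_(modality="structure")}

    def to_yaml(self, path) -> None:
        doc = dataclasses.asdict(self)
        doc["model_configs"] = {m: dataclasses.asdict(c) for m, c in self.model_configs.items()}
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        gen = doc.pop("generator", {})
        if isinstance(gen.get("modality_linkage"), list):
            gen["modality_linkage"] = tuple(gen["modality_linkage"])
        models = {m: ModelConfig(**{**c, "conv_channels": tuple(c.get("conv_channels", (8, 16, 32, 64)))})
                  for m, c in doc.pop("model_configs", {}).items()}
        return cls(generator=GeneratorConfig(**gen), model_configs=models, **doc)

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc.pop("outdir", None)  # where a run writes does not change what it computes
        doc["model_configs"] = {m: dataclasses.asdict(c) for m, c in
                                self.resolved_model_configs().items()}
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# label-table I/O


def read_label_table(path) -> LabelMatrix:
    """Read a long CSV (compound_id, assay_id, label in {0,1}) into a LabelMatrix.

    Pairs absent from the file are unknown.  Duplicate (compound, assay) rows
    and labels outside {0, 1} are errors.
    """
    frame = pd.read_csv(path, dtype={"compound_id": str, "assay_id": str})
    required = {"compound_id", "assay_id", "label"}
    if missing := required - set(frame.columns):
        raise ValueError(f"label CSV lacks columns: {sorted(missing)}")
    bad = ~frame["label"].isin([0, 1])
    if bad.any():
        line = int(frame.index[bad][0]) + 2  # header is line 1
        raise ValueError(f"unknown label value {frame.loc[bad, 'label'].iloc[0]!r} at line {line}")
    dup = frame.duplicated(subset=["compound_id", "assay_id"])
    if dup.any():
        pair = frame.loc[dup, ["compound_id", "assay_id"]].iloc[0]
        raise ValueError(f"duplicate label for pair ({pair.compound_id}, {pair.assay_id})")
    compounds = list(pd.unique(frame["compound_id"]))
    assays = list(pd.unique(frame["assay_id"]))
    labels = np.full((len(compounds), len(assays)), np.nan)
    ci = {c: i for i, c in enumerate(compounds)}
    ai = {a: j for j, a in enumerate(assays)}
    labels[frame["compound_id"].map(ci), frame["assay_id"].map(ai)] = frame["label"]
    return LabelMatrix(compounds=compounds, assays=assays, labels=labels)


def write_label_table(matrix: LabelMatrix, path) -> None:
    obs = matrix.observed_mask()
    rows, cols = np.nonzero(obs)
    pd.DataFrame(
        {
            "compound_id": [matrix.compounds[i] for i in rows],
            "assay_id": [matrix.assays[j] for j in cols],
            "label": matrix.labels[rows, cols].astype(int),
        }
    ).to_csv(path, index=False)


def filter_assays(matrix: LabelMatrix, min_actives: int = 50,
                  min_inactives: int = 50) -> LabelMatrix:
    """Drop assays with fewer than the required observed actives or inactives.

    The reference campaign's inclusion rule: an assay needs at least 50 observed active and
    50 observed inactive labels (boundary inclusive).  Dropped assay ids are
    logged; dropping everything raises.
    """
    counts = matrix.counts_per_assay()
    keep = (counts["n_active"] >= min_actives) & (counts["n_inactive"] >= min_inactives)
    if not keep.any():
        raise ValueError("assay filter removed every assay")
    dropped = counts.loc[~keep, "assay_id"].tolist()
    if dropped:
        logger.info("assay filter dropped %d assays: %s", len(dropped), dropped[:10])
    idx = np.flatnonzero(keep.to_numpy())
    return LabelMatrix(
        compounds=list(matrix.compounds),
        assays=[matrix.assays[j] for j in idx],
        labels=matrix.labels[:, idx],
        truth=None if matrix.truth is None else matrix.truth[:, idx],
    )


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class RunReport:
    summary: dict
    stats: dict
    diversity: pd.DataFrame
    enrichment: pd.DataFrame
    provenance: dict

    def to_json(self) -> str:
        doc = {
            "summary": self.summary,
            "stats": self.stats,
            "diversity": self.diversity.to_dict(orient="records"),
            "enrichment": self.enrichment.to_dict(orient="records"),
            "provenance": self.provenance,
        }
        return json.dumps(doc, indent=2, sort_keys=True, default=float)


def _stage(name: str):
    logger.info("stage: %s", name)
    return time.time()


def run_all(config: RunConfig) -> RunReport:
    """Execute the full analysis and write artifacts under ``config.outdir``.

    Deterministic under ``config.seed`` for the feature and structure
    modalities.  Aborts with the failing stage named if any stage raises.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen = config.generator.with_(seed=config.seed)
    stage = "simulate"
    try:
        _stage(stage)
        library = generate_library(gen)
        panel = generate_panel(gen)
        labels = generate_labels(library, panel, gen)
        profiles = generate_profiles(library, panel, gen)
        library.to_tsv(outdir / "library.tsv")
        write_label_table(labels, outdir / "labels.csv")
        panel.annotations().to_csv(outdir / "assay_annotations.csv", index=False)
        logger.info("simulated %d compounds x %d assays, fill %.3f, hit %.3f",
                    library.n_compounds, panel.n_assays, labels.fill_rate(), labels.hit_rate())

        stage = "filter_assays"
        _stage(stage)
        labels = filter_assays(labels, config.min_actives, config.min_inactives)

        stage = "split"
        _stage(stage)
        clustering = butina_cluster(library.fingerprints, cutoff=config.butina_cutoff)
        folds = assign_folds(clustering, k=config.k_folds, seed=config.seed)
        library.fold_ids = folds.fold_ids
        pd.DataFrame({"compound_id": library.compound_ids,
                      "cluster_id": clustering.cluster_ids,
                      "fold_id": folds.fold_ids}).to_csv(outdir / "folds.csv", index=False)

        stage = "preprocess"
        _stage(stage)
        normalized = robust_z_normalize(profiles)
        filtered, kept = variance_filter(normalized, threshold=1.0)
        (outdir / "kept_features.txt").write_text("\n".join(kept) + "\n")

        stage = "cross_validate"
        _stage(stage)
        plan = make_split_plan(config.k_folds)
        bundles = {
            "features": bundle_from_profiles(filtered, labels, folds.fold_ids),
            "structure": bundle_from_fingerprints(library, labels, folds.fold_ids),
        }
        model_cfgs = config.resolved_model_configs()
        auc_tables, predictions = [], {}
        for modality, cfg in model_cfgs.items():
            table, pms, _ = cross_validate(bundles[modality], cfg.with_(seed=config.seed), plan)
            auc_tables.append(table)
            predictions[modality] = pms
        auc_table = pd.concat(auc_tables, ignore_index=True)
        auc_table.to_csv(outdir / "auc_table.csv", index=False)

        stage = "summarize"
        _stage(stage)
        summary = summarize(auc_table)
        per_assay = {m: pd.Series(s["per_assay_mean"]) for m, s in summary.items()}

        stage = "stats"
        _stage(stage)
        stats_report = _run_stats(auc_table, panel, per_assay)
        (outdir / "stats.json").write_text(json.dumps(stats_report, indent=2, default=float))

        stage = "diversity"
        _stage(stage)
        diversity = _run_diversity(config, library, labels, predictions, per_assay, plan, folds)
        diversity.to_csv(outdir / "diversity.csv", index=False)

        stage = "enrichment"
        _stage(stage)
        enrichment = _run_enrichment(config, labels, predictions)
        enrichment.to_csv(outdir / "enrichment.csv", index=False)
    except Exception as err:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed (artifacts under {outdir})"
        ) from err

    provenance = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_compounds": library.n_compounds,
        "n_assays_retained": len(labels.assays),
    }
    report = RunReport(summary=summary, stats=stats_report, diversity=diversity,
                       enrichment=enrichment, provenance=provenance)
    (outdir / "report.json").write_text(report.to_json())
    return report


def _run_stats(auc_table: pd.DataFrame, panel, per_assay) -> dict:
    out: dict = {}
    modalities = sorted(auc_table["modality"].unique())
    if len(modalities) >= 2:
        long = pd.concat(
            [pd.DataFrame({"assay_id": s.index, "modality": m, "auc": s.values})
             for m, s in per_assay.items()], ignore_index=True).dropna()
        table = BlockedTable.from_long(long, "assay_id", "modality", "auc")
        fried = friedman_blocked(table)
        nem = nemenyi_posthoc(table)
        out["modality_friedman"] = {"statistic": fried.statistic, "p_value": fried.p_value}
        out["modality_nemenyi_pairwise_p"] = nem.pairwise_p.to_dict()
    ann = panel.annotations().set_index("assay_id")
    first = modalities[0] if modalities else None
    if first is not None:
        aucs = per_assay[first].dropna()
        groups = ann.loc[aucs.index, "target_class"]
        if groups.nunique() >= 2 and (groups.value_counts() >= 2).sum() >= 2:
            kr = kruskal_conover(aucs.values, groups.values)
            out["target_class_kruskal"] = {"statistic": kr.statistic, "p_value": kr.p_value,
                                           "pairwise_p": kr.pairwise_p.to_dict()}
    return out


def _run_diversity(config: RunConfig, library, labels: LabelMatrix, predictions,
                   per_assay, plan, folds) -> pd.DataFrame:
    fps = {c: library.fingerprints[i] for i, c in enumerate(library.compound_ids)}
    # inclusion rule for diversity scoring: assays predicted reasonably by every modality
    eligible = None
    for series in per_assay.values():
        ok = set(series[series > config.diversity_auc_threshold].index)
        eligible = ok if eligible is None else eligible & ok
    rows = []
    for modality, pms in predictions.items():
        for split_id, (train_folds, _val, _test) in enumerate(plan):
            pm = pms[split_id]
            train_mask = np.isin(folds.fold_ids, train_folds)
            for j, assay in enumerate(labels.assays):
                if assay not in (eligible or set()):
                    continue
                col = labels.labels[:, j]
                train_actives = [labels.compounds[i] for i in np.flatnonzero(
                    train_mask & (col == 1))]
                if not train_actives:
                    continue
                order = np.argsort(-pm.scores[:, j], kind="stable")
                ranking = [pm.compounds[i] for i in order]
                res = top_k_diversity(ranking, train_actives, fps, k=config.diversity_k,
                                      assay_id=assay)
                rows.append({"assay_id": assay, "modality": modality, "split_id": split_id,
                             "mean_top{}_tanimoto".format(config.diversity_k): res.mean})
    return pd.DataFrame(rows)


def _run_enrichment(config: RunConfig, labels: LabelMatrix, predictions) -> pd.DataFrame:
    """Simulated follow-up screens: rank by concatenated test-split scores, probe
    the top fraction plus a random baseline against the latent truth."""
    if labels.truth is None:
        raise ValueError("enrichment simulation needs a synthetic label matrix with truth")
    comp_index = {c: i for i, c in enumerate(labels.compounds)}
    rows = []
    for modality, pms in predictions.items():
        all_comp = np.concatenate([pm.compounds for pm in pms])
        all_scores = np.vstack([pm.scores for pm in pms])
        for j, assay in enumerate(labels.assays):
            order = np.lexsort((all_comp, -all_scores[:, j]))  # score desc, id asc on ties
            ranking = [all_comp[i] for i in order]
            if len(ranking) < config.n_random:
                continue
            top, rand = select_followup(ranking, config.enrichment_fraction,
                                        config.n_random, seed=config.seed)
            truth_col = labels.truth[:, j]
            sel = truth_col[[comp_index[c] for c in top]]
            base = truth_col[[comp_index[c] for c in rand]]
            if base.sum() == 0:
                continue
            res = bootstrap_enrichment(sel, base, n_boot=config.n_boot, seed=config.seed,
                                       fraction=config.enrichment_fraction, assay_id=assay)
            rows.append({
                "assay_id": assay, "modality": modality,
                "fraction": res.fraction, "baseline_hit_rate": res.baseline_hit_rate,
                "selected_hit_rate": res.selected_hit_rate,
                "median_enrichment": res.median,
                "iqr_low": res.iqr[0], "iqr_high": res.iqr[1],
                "ceiling": res.ceiling, "n_undefined_replicates": res.n_undefined,
            })
    return pd.DataFrame(rows)
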