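"""Chemical diversity of top predictions and follow-up screen enrichment.

Two questions follow a virtual screen: are the top-ranked compounds new
chemistry or rehashes of the known actives, and how much does screening only
the top-ranked fraction enrich the hit rate over a random sample?

Diversity is the Tanimoto similarity of each top-k ranked test compound to
its nearest known active in the training set (lower = more diverse).
Enrichment is the ratio of the selected subset's hit rate to a baseline hit
rate estimated from randomly sampled compounds, with uncertainty from
bootstrap resampling of both subsets.  Selecting a fraction ``f`` from a
library with baseline hit rate ``h`` caps the achievable enrichment at
``min(1/f, 1/h)``: at best every selected compound is active (factor ``1/h``)
and at best all actives land inside the selection (factor ``1/f``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chem import tanimoto_matrix

__all__ = [
    "DiversityResult",
    "EnrichmentResult",
    "bootstrap_enrichment",
    "max_enrichment",
    "select_followup",
    "top_k_diversity",
]


@dataclass
class DiversityResult:
    """Nearest-active Tanimoto similarity for each of the top-k ranked compounds."""

    assay_id: str
    compound_ids: list[str]
    nearest_active_similarity: np.ndarray
    mean: float


def top_k_diversity(ranking, train_actives, fps: dict, k: int = 20,
                    assay_id: str = "") -> DiversityResult:
    """Max Tanimoto of each top-k ranked compound to the training actives.

    ``ranking`` is an ordered compound-id list (best first); ``fps`` maps
    compound id to a boolean fingerprint.  Callers are expected to restrict
    the assays considered (e.g. to those with mean AUC above 0.6 in every
    modality) before invoking this.
    """
    ranking = list(ranking)
    train_actives = list(train_actives)
    if not ranking:
        raise ValueError("empty ranking")
    if not train_actives:
        raise ValueError("no known training actives to compare against")
    top = ranking[: min(k, len(ranking))]
    for cid in top + train_actives:
        if cid not in fps:
            raise KeyError(f"missing fingerprint for compound {cid!r}")
    top_fp = np.asarray([fps[c] for c in top], dtype=bool)
    act_fp = np.asarray([fps[c] for c in train_actives], dtype=bool)
    sims = tanimoto_matrix(top_fp, act_fp).max(axis=1)
    return DiversityResult(
        assay_id=assay_id, compound_ids=top,
        nearest_active_similarity=sims, mean=float(sims.mean()),
    )


def select_followup(ranking, fraction: float = 0.05, n_random: int = 500,
                    seed: int = 0) -> tuple[list, list]:
    """Pick the top-ranked fraction plus a uniform random baseline sample.

    The top set is the ``ceil(fraction * N)`` highest-ranked compounds (ties
    already resolved by the caller's ranking; equal scores should be ordered
    by compound id for determinism).  The random set is ``n_random`` compounds
    drawn without replacement from the full library; the two sets may overlap.
    """
    ranking = list(ranking)
    n = len(ranking)
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if n < n_random:
        raise ValueError(f"library of {n} compounds cannot yield {n_random} random picks")
    top = ranking[: math.ceil(fraction * n)]
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 21]))
    random_set = [ranking[i] for i in rng.choice(n, size=n_random, replace=False)]
    return top, random_set


def max_enrichment(fraction: float, baseline_hit_rate: float) -> float:
    """Analytic enrichment ceiling ``min(1/f, 1/h)``.

    At a vanishing baseline hit rate the bound is set purely by the selection
    size: screening the top 5% can enrich at most 20-fold, the top 0.5% at
    most 200-fold.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if not 0.0 <= baseline_hit_rate <= 1.0:
        raise ValueError(f"hit rate must lie in [0, 1], got {baseline_hit_rate}")
    if baseline_hit_rate == 0.0:
        return 1.0 / fraction
    return min(1.0 / fraction, 1.0 / baseline_hit_rate)


@dataclass
class EnrichmentResult:
    """Bootstrap distribution of hit-rate enrichment for one follow-up screen."""

    assay_id: str
    fraction: float
    baseline_hit_rate: float
    selected_hit_rate: float
    enrichments: np.ndarray = field(repr=False)
    median: float = float("nan")
    iqr: tuple[float, float] = (float("nan"), float("nan"))
    ceiling: float = float("nan")
    n_undefined: int = 0

    @property
    def observed_enrichment(self) -> float:
        return self.selected_hit_rate / self.baseline_hit_rate


def bootstrap_enrichment(selected_labels, baseline_labels, n_boot: int = 100,
                         seed: int = 0, fraction: float = 0.05,
                         assay_id: str = "") -> EnrichmentResult:
    """Bootstrap the hit-rate ratio between a selected set and a random baseline.

    Each replicate resamples both label lists with replacement and records
    ``selected hit rate / baseline hit rate``.  Replicates whose resampled
    baseline contains no actives are undefined; they are excluded from the
    summary and counted in ``n_undefined``.  An observed baseline with zero
    actives raises (the baseline sample is too small to estimate a hit rate).
    """
    sel = np.asarray(selected_labels, dtype=float)
    base = np.asarray(baseline_labels, dtype=float)
    if sel.size == 0 or base.size == 0:
        raise ValueError("selected and baseline label lists must be nonempty")
    if base.sum() == 0:
        raise ValueError(
            "baseline sample contains no actives; enlarge the random baseline "
            "to estimate the assay hit rate"
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, 22]))
    sel_rates = rng.choice(sel, size=(n_boot, sel.size), replace=True).mean(axis=1)
    base_rates = rng.choice(base, size=(n_boot, base.size), replace=True).mean(axis=1)
    defined = base_rates > 0
    enr = sel_rates[defined] / base_rates[defined]
    h = float(base.mean())
    q25, q50, q75 = (np.percentile(enr, [25, 50, 75]) if enr.size else
                     (float("nan"),) * 3)
    return EnrichmentResult(
        assay_id=assay_id,
        fraction=fraction,
        baseline_hit_rate=h,
        selected_hit_rate=float(sel.mean()),
        enrichments=enr,
        median=float(q50),
        iqr=(float(q25), float(q75)),
        ceiling=max_enrichment(fraction, h),
        n_undefined=int(n_boot - defined.sum()),
    )
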