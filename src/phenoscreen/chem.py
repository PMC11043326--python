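"""Fingerprints, Tanimoto similarity, Butina clustering and scaffold-aware folds.

Scaffold-split cross-validation requires that structurally similar compounds
never straddle a train/test boundary.  The workflow here is the standard one:
ECFP4 bit fingerprints -> sphere-exclusion (Butina) clustering at a Tanimoto
distance cutoff -> greedy balanced assignment of whole clusters to k folds.

Everything except :func:`ecfp4_fingerprint` operates on plain boolean bit
arrays, so the pipeline runs without a chemistry backend; RDKit is imported
lazily only when SMILES must be converted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Clustering",
    "FoldAssignment",
    "assign_folds",
    "butina_cluster",
    "ecfp4_fingerprint",
    "fingerprints_from_hex",
    "fingerprints_to_hex",
    "read_smiles_tsv",
    "tanimoto",
    "tanimoto_matrix",
]


class SmilesParseError(ValueError):
    """Raised when a SMILES record cannot be parsed."""


def ecfp4_fingerprint(smiles: str, n_bits: int = 1024) -> np.ndarray:
    """Extended-connectivity fingerprint of diameter 4 (radius 2), folded to ``n_bits``.

    Parameters
    ----------
    smiles:
        A single SMILES string.
    n_bits:
        Length of the folded bit vector.

    Returns
    -------
    numpy.ndarray
        Boolean array of length ``n_bits``.

    Raises
    ------
    SmilesParseError
        If the SMILES cannot be parsed; the message names the offending record.
    ImportError
        If RDKit is not installed.
    """
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES record: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    arr = np.zeros(n_bits, dtype=bool)
    arr[list(fp.GetOnBits())] = True
    return arr


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity |A∩B| / |A∪B| between two bit vectors.

    Both-empty fingerprints are defined as identical (similarity 1.0).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


def tanimoto_matrix(fps: np.ndarray, other: np.ndarray | None = None) -> np.ndarray:
    """Pairwise Tanimoto similarity between rows of two bit matrices.

    ``other`` defaults to ``fps`` (symmetric self-similarity).  Computed with a
    float32 inner product; both-empty pairs get similarity 1.0.
    """
    A = np.asarray(fps, dtype=bool)
    B = A if other is None else np.asarray(other, dtype=bool)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("expected 2-D bit matrices with equal width")
    Af = A.astype(np.float32)
    Bf = B.astype(np.float32)
    inter = Af @ Bf.T
    pa = Af.sum(axis=1)[:, None]
    pb = Bf.sum(axis=1)[None, :]
    union = pa + pb - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


@dataclass
class Clustering:
    """Sphere-exclusion clustering result.

    ``cluster_ids[i]`` is the cluster of input fingerprint ``i``;
    ``centroids[c]`` is the input index of the compound that seeded cluster
    ``c`` (every member of ``c`` lies within ``cutoff`` Tanimoto distance of
    it).
    """

    cluster_ids: np.ndarray
    centroids: np.ndarray
    cutoff: float

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_ids, minlength=self.n_clusters)


def butina_cluster(fps: np.ndarray, cutoff: float = 0.6) -> Clustering:
    """Greedy sphere-exclusion (Butina) clustering at a Tanimoto-distance cutoff.

    Neighbour lists are built at distance ``1 - tanimoto <= cutoff``.  The
    unassigned compound with the most unassigned neighbours seeds each new
    cluster and absorbs its unassigned neighbours; ties go to the lowest input
    index.  Singletons are permitted.

    Parameters
    ----------
    fps:
        (n, n_bits) boolean fingerprint matrix.
    cutoff:
        Tanimoto *distance* threshold in [0, 1]; the package default 0.6
        (similarity 0.4) gives moderate cluster sizes on sparse fingerprints.
    """
    fps = np.asarray(fps, dtype=bool)
    if fps.ndim != 2 or fps.shape[0] == 0:
        raise ValueError("butina_cluster requires a nonempty 2-D fingerprint matrix")
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must lie in [0, 1], got {cutoff}")
    n = fps.shape[0]
    neighbor = tanimoto_matrix(fps) >= (1.0 - cutoff) - 1e-12  # includes self
    np.fill_diagonal(neighbor, True)

    cluster_ids = np.full(n, -1, dtype=np.int64)
    centroids: list[int] = []
    unassigned = np.ones(n, dtype=bool)
    # unassigned-neighbour counts maintained incrementally: O(n^2) total
    counts = neighbor.sum(axis=1).astype(np.int64)
    while unassigned.any():
        masked = np.where(unassigned, counts, -1)
        centroid = int(np.argmax(masked))  # argmax takes the lowest tied index
        members = neighbor[centroid] & unassigned
        members[centroid] = True
        cid = len(centroids)
        cluster_ids[members] = cid
        centroids.append(centroid)
        unassigned &= ~members
        counts -= neighbor[:, members].sum(axis=1)
    return Clustering(cluster_ids=cluster_ids, centroids=np.asarray(centroids), cutoff=cutoff)


@dataclass
class FoldAssignment:
    """Fold id per compound, with the cluster structure it was derived from."""

    fold_ids: np.ndarray
    k: int
    cluster_ids: np.ndarray = field(repr=False)

    def fold_sizes(self) -> np.ndarray:
        return np.bincount(self.fold_ids, minlength=self.k)


def assign_folds(clustering: Clustering, k: int = 6, seed: int | None = None) -> FoldAssignment:
    """Distribute whole clusters across ``k`` folds of similar size.

    Clusters are sorted by size descending (ties by cluster id ascending) and
    greedily placed into the currently smallest fold (ties by lowest fold
    index), so no cluster is ever split across folds and the fold-size range
    is bounded by the largest cluster.  The procedure is deterministic;
    ``seed`` is accepted for interface symmetry and unused.
    """
    if k < 2:
        raise ValueError(f"need k >= 2 folds, got {k}")
    sizes = clustering.sizes()
    n_clusters = len(sizes)
    if k > n_clusters:
        warnings.warn(
            f"requested {k} folds but only {n_clusters} clusters; some folds will be empty",
            stacklevel=2,
        )
    order = sorted(range(n_clusters), key=lambda c: (-sizes[c], c))
    fold_of_cluster = np.empty(n_clusters, dtype=np.int64)
    fold_sizes = np.zeros(k, dtype=np.int64)
    for c in order:
        f = int(np.argmin(fold_sizes))
        fold_of_cluster[c] = f
        fold_sizes[f] += sizes[c]
    fold_ids = fold_of_cluster[clustering.cluster_ids]
    return FoldAssignment(fold_ids=fold_ids, k=k, cluster_ids=clustering.cluster_ids.copy())


# ---------------------------------------------------------------------------
# interchange helpers


def fingerprints_to_hex(fps: np.ndarray) -> list[str]:
    """Pack each boolean fingerprint row into a hex string (big-endian bits)."""
    fps = np.asarray(fps, dtype=bool)
    return [np.packbits(row).tobytes().hex() for row in np.atleast_2d(fps)]


def fingerprints_from_hex(hex_strings: list[str], n_bits: int) -> np.ndarray:
    """Inverse of :func:`fingerprints_to_hex`."""
    rows = []
    for h in hex_strings:
        bits = np.unpackbits(np.frombuffer(bytes.fromhex(h), dtype=np.uint8))
        if len(bits) < n_bits:
            raise ValueError(f"hex fingerprint shorter than {n_bits} bits")
        rows.append(bits[:n_bits].astype(bool))
    return np.asarray(rows)


def read_smiles_tsv(path) -> pd.DataFrame:
    """Read a two-column ``id<TAB>smiles`` file; ``#`` comment lines ignored."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=["compound_id", "smiles"], dtype=str)
    if df["compound_id"].duplicated().any():
        dup = df["compound_id"][df["compound_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate compound id in SMILES file: {dup}")
    return df


def write_folds_csv(path, compound_ids, clustering: Clustering, folds: FoldAssignment) -> None:
    pd.DataFrame(
        {
            "compound_id": list(compound_ids),
            "cluster_id": clustering.cluster_ids,
            "fold_id": folds.fold_ids,
        }
    ).to_csv(path, index=False)
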