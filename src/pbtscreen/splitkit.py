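"""Data partitioning strategies and their statistical auditing.

Three strategies are supported, all operating on sanitized records:

* ``random`` — uniform 80:20 split.
* ``cluster_singleton`` — Butina sphere-exclusion clustering of circular
  fingerprints; the test set is exactly the singleton clusters (molecules
  structurally distinct from everything else), the train set everything
  belonging to a cluster of size >= 2.
* ``cluster_centroid`` — train only on each multi-member cluster's centroid
  (its sphere-exclusion seed); test on singletons.

The IID audit compares per-bit fingerprint distributions between train and
test sides with two-sample Kolmogorov–Smirnov tests at a configurable
significance level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy import stats

from .chemprep import MoleculeRecord

FP_BITS = 2048
_morgan_gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=FP_BITS)
_rdkit_gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=FP_BITS)


@dataclass
class SplitResult:
    strategy: str
    train_ids: list[str]
    test_ids: list[str]
    val_ids: list[str] = field(default_factory=list)
    clusters: dict[int, list[str]] = field(default_factory=dict)
    centroids: dict[int, str] = field(default_factory=dict)
    seed: Optional[int] = None
    cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        sides = [set(self.train_ids), set(self.test_ids), set(self.val_ids)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sides[i] & sides[j]:
                    raise ValueError("train/val/test id sets must be disjoint")


@dataclass
class IIDReport:
    n_bits_tested: int
    n_significant: int
    alpha: float
    mean_ks_statistic: float
    aggregate_p: float  # median of per-bit p-values

    def __post_init__(self) -> None:
        if self.n_significant > self.n_bits_tested:
            raise ValueError("n_significant cannot exceed n_bits_tested")


def fingerprint(mol: MoleculeRecord | Chem.Mol | str, kind: str = "morgan") -> np.ndarray:
    """Deterministic 2048-bit fingerprint as a uint8 {0,1} vector.

    kind="morgan": circular, radius 2 (ECFP4-like); kind="rdkit": path-based.
    """
    if isinstance(mol, MoleculeRecord):
        smi = mol.smiles_canonical or mol.smiles_raw
        m = Chem.MolFromSmiles(smi)
    elif isinstance(mol, str):
        m = Chem.MolFromSmiles(mol)
    else:
        m = mol
    if m is None:
        raise ValueError("unparseable molecule")
    if kind == "morgan":
        fp = _morgan_gen.GetFingerprint(m)
    elif kind == "rdkit":
        fp = _rdkit_gen.GetFingerprint(m)
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    arr = np.zeros(FP_BITS, dtype=np.uint8)
    for b in fp.GetOnBits():
        arr[b] = 1
    return arr


def fingerprint_matrix(records: Sequence[MoleculeRecord], kind: str = "morgan") -> np.ndarray:
    return np.stack([fingerprint(r, kind) for r in records])


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """|a AND b| / |a OR b|; defined as 1.0 when both vectors are all-zero."""
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    a = a.astype(bool)
    b = b.astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarities between fingerprint matrix rows."""
    A = A.astype(np.float64)
    B = B.astype(np.float64)
    inter = A @ B.T
    union = A.sum(axis=1)[:, None] + B.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 1.0)
    return sim


def butina_cluster(
    fps: Sequence[np.ndarray] | np.ndarray, cutoff: float = 0.4
) -> list[list[int]]:
    """Sphere-exclusion (Butina) clustering at a Tanimoto *distance* cutoff.

    Neighbors are pairs at distance <= cutoff (similarity >= 1-cutoff).  The
    unassigned compound with the most unassigned neighbors seeds each cluster
    (ties: lowest input index), claiming itself and its unassigned neighbors.
    Returns clusters as index lists; element 0 of each is the centroid.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError(f"cutoff must be in [0, 1], got {cutoff}")
    X = np.asarray(fps)
    n = X.shape[0]
    sim = tanimoto_matrix(X, X)
    neighbor = (1.0 - sim) <= cutoff
    np.fill_diagonal(neighbor, False)
    unassigned = np.ones(n, dtype=bool)
    clusters: list[list[int]] = []
    while unassigned.any():
        counts = (neighbor & unassigned[None, :]).sum(axis=1)
        counts[~unassigned] = -1
        centroid = int(np.argmax(counts))  # argmax takes lowest index on ties
        members = [centroid] + [
            int(j) for j in np.flatnonzero(neighbor[centroid] & unassigned) if j != centroid
        ]
        clusters.append(members)
        unassigned[members] = False
    return clusters


def split_random(
    records: Sequence[MoleculeRecord], ratio: float = 0.8, seed: int = 0
) -> SplitResult:
    """Uniform split without replacement; train size = floor(ratio * n)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    n = len(records)
    if n < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(ratio * n))
    ids = [r.id for r in records]
    return SplitResult(
        strategy="random",
        train_ids=[ids[i] for i in perm[:n_train]],
        test_ids=[ids[i] for i in perm[n_train:]],
        seed=seed,
    )


def _cluster_records(
    records: Sequence[MoleculeRecord], cutoff: float, kind: str
) -> tuple[dict[int, list[str]], dict[int, str]]:
    fps = fingerprint_matrix(records, kind)
    clusters = butina_cluster(fps, cutoff)
    ids = [r.id for r in records]
    cluster_map = {ci: [ids[i] for i in members] for ci, members in enumerate(clusters)}
    centroid_map = {ci: ids[members[0]] for ci, members in enumerate(clusters)}
    return cluster_map, centroid_map


def split_cluster_singletons(
    records: Sequence[MoleculeRecord], cutoff: float = 0.4, kind: str = "morgan"
) -> SplitResult:
    """Test set = singleton clusters; train = members of clusters of size >= 2."""
    cluster_map, centroid_map = _cluster_records(records, cutoff, kind)
    train, test = [], []
    for ci, members in cluster_map.items():
        (test if len(members) == 1 else train).extend(members)
    if not test:
        warnings.warn("no singleton clusters: test set is empty")
    if not train:
        warnings.warn("all clusters are singletons: train set is empty")
    return SplitResult(
        strategy="cluster_singleton", train_ids=train, test_ids=test,
        clusters=cluster_map, centroids=centroid_map, cutoff=cutoff,
    )


def split_cluster_centroids(
    records: Sequence[MoleculeRecord], cutoff: float = 0.4, kind: str = "morgan"
) -> SplitResult:
    """Train = one centroid per multi-member cluster; test = singletons.

    Non-centroid members of multi-member clusters are excluded from both
    sides, exposing training to each structural motif exactly once.
    """
    cluster_map, centroid_map = _cluster_records(records, cutoff, kind)
    train, test = [], []
    for ci, members in cluster_map.items():
        if len(members) == 1:
            test.extend(members)
        else:
            train.append(centroid_map[ci])
    if not test:
        warnings.warn("no singleton clusters: test set is empty")
    if not train:
        warnings.warn("all clusters are singletons: train set is empty")
    return SplitResult(
        strategy="cluster_centroid", train_ids=train, test_ids=test,
        clusters=cluster_map, centroids=centroid_map, cutoff=cutoff,
    )


def carve_validation(split: SplitResult, fraction: float = 0.1, seed: int = 0) -> SplitResult:
    """Move a seeded random fraction of the train side into a validation set."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train = list(split.train_ids)
    n_val = max(1, int(np.floor(fraction * len(train))))
    perm = rng.permutation(len(train))
    val_ids = [train[i] for i in perm[:n_val]]
    train_ids = [train[i] for i in perm[n_val:]]
    return SplitResult(
        strategy=split.strategy, train_ids=train_ids, test_ids=list(split.test_ids),
        val_ids=val_ids, clusters=split.clusters, centroids=split.centroids,
        seed=seed, cutoff=split.cutoff,
    )


def max_similarity_profile(
    split: SplitResult,
    records: Sequence[MoleculeRecord],
    kind: str = "morgan",
    contiguity_cutoff: float = 0.6,
) -> dict:
    """Nearest-training-neighbor similarity profile of the test set.

    For every test molecule, the maximum Tanimoto similarity to any
    training molecule — the standard measure of train/test structural
    contiguity (a test compound with a close training neighbor is "easy").
    Returns median, quartiles and the fraction of maxima above the
    structural-contiguity cutoff (default similarity 0.6).
    """
    by_id = {r.id: r for r in records}
    train = [by_id[i] for i in split.train_ids]
    test = [by_id[i] for i in split.test_ids]
    if not train or not test:
        raise ValueError("both train and test sides must be non-empty")
    sims = tanimoto_matrix(fingerprint_matrix(test, kind), fingerprint_matrix(train, kind))
    maxima = sims.max(axis=1)
    q1, med, q3 = np.percentile(maxima, [25, 50, 75])
    return {
        "direction": "per_test_max_over_train",
        "n_train": len(train), "n_test": len(test),
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "frac_above_cutoff": float(np.mean(maxima > contiguity_cutoff)),
        "cutoff": contiguity_cutoff,
        "maxima": maxima,
    }


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def validate_iid(
    train: Sequence[MoleculeRecord],
    test: Sequence[MoleculeRecord],
    kind: str = "morgan",
    alpha: float = 0.05,
) -> IIDReport:
    """Per-bit KS audit of fingerprint distributions between train and test.

    Bits with zero variance in the pooled data count as tested but
    non-significant (D = 0, p = 1).  aggregate_p is the median of per-bit
    p-values (reported as such; a single summary p-value has no canonical
    definition for 2048 dependent tests).
    """
    if not train or not test:
        raise ValueError("both sides must be non-empty")
    return validate_iid_matrices(
        fingerprint_matrix(train, kind), fingerprint_matrix(test, kind), alpha
    )


def validate_iid_matrices(A: np.ndarray, B: np.ndarray, alpha: float = 0.05) -> IIDReport:
    """Matrix-level form of validate_iid (rows = molecules, columns = bits)."""
    n_bits = A.shape[1]
    pooled_var = np.concatenate([A, B]).std(axis=0) > 0
    d_stats = np.zeros(n_bits)
    p_vals = np.ones(n_bits)
    for bit in np.flatnonzero(pooled_var):
        d, p = ks_two_sample(A[:, bit], B[:, bit])
        d_stats[bit] = d
        p_vals[bit] = p
    n_sig = int(np.sum(p_vals < alpha))
    return IIDReport(
        n_bits_tested=n_bits,
        n_significant=n_sig,
        alpha=alpha,
        mean_ks_statistic=float(d_stats.mean()),
        aggregate_p=float(np.median(p_vals)),
    )
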