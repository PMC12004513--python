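"""Applicability-domain gate: PCA + Mahalanobis distance + percentile threshold.

The training matrix (circular fingerprints or global descriptors) is
projected onto the smallest number of principal components explaining a
target fraction of the variance (default 90%); the Mahalanobis distance of
a sample in that decorrelated space is

    dist(x) = sqrt( sum_j  score_j(x)^2 / lambda_j )

over the retained components with eigenvalues lambda_j.  A prediction is
in-domain when its distance does not exceed a percentile (default 99th) of
the training-set distances.  Two representations are fitted in the full
pipeline; the combined verdict is out-of-domain if ANY representation says
so (union rule, the conservative choice).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from sklearn.decomposition import PCA


@dataclass
class ADModel:
    representation: str
    mean: np.ndarray
    scale: Optional[np.ndarray]      # None when centering only
    components: np.ndarray           # (n_components, n_features)
    variances: np.ndarray            # eigenvalues of retained components
    n_components: int
    train_distances: np.ndarray
    threshold: float
    variance_target: float
    percentile: float


def _preprocess(X: np.ndarray, mean: np.ndarray, scale: Optional[np.ndarray]) -> np.ndarray:
    Xc = X - mean
    if scale is not None:
        Xc = Xc / scale
    return Xc


def _distances(model_components, variances, Xc) -> np.ndarray:
    scores = Xc @ model_components.T
    return np.sqrt(np.sum(scores**2 / variances[None, :], axis=1))


def fit_ad(
    train: np.ndarray,
    variance_target: float = 0.90,
    percentile: float = 99.0,
    representation: str = "descriptors",
    scale: Optional[bool] = None,
) -> ADModel:
    """Fit the gate on training features.

    Descriptors are z-scored before PCA (heterogeneous units); fingerprints
    are centered only (homogeneous binary features).  ``scale`` overrides
    that default when given.  Components are capped at n_train - 1 with a
    warning when the sample count is limiting.
    """
    X = np.asarray(train, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need at least 3 training samples")
    if scale is None:
        scale = representation in ("descriptors", "desc")
    mean = X.mean(axis=0)
    sd = None
    if scale:
        sd = X.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
    Xc = _preprocess(X, mean, sd)
    total_var = np.var(Xc, axis=0).sum()
    if total_var <= 0:
        raise ValueError("zero total variance in training matrix")
    max_comp = min(X.shape[0] - 1, X.shape[1])
    pca = PCA(n_components=max_comp, svd_solver="full")
    pca.fit(Xc)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = min(int(np.searchsorted(cum, variance_target) + 1), max_comp)
    if k >= X.shape[0] - 1 and X.shape[1] > k:
        warnings.warn("component count capped at n_train - 1; variance target met "
                      "only because the sample count limits the rank")
    components = pca.components_[:k]
    variances = pca.explained_variance_[:k]
    dists = _distances(components, variances, Xc)
    threshold = float(np.percentile(dists, percentile))  # linear interpolation
    return ADModel(
        representation=representation, mean=mean, scale=sd,
        components=components, variances=variances, n_components=k,
        train_distances=dists, threshold=threshold,
        variance_target=variance_target, percentile=percentile,
    )


def apply_ad(model: ADModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (distance, in_domain); in-domain iff distance <= threshold."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.mean.shape[0]:
        raise ValueError(
            f"feature dimension mismatch: {X.shape[1]} vs {model.mean.shape[0]}"
        )
    dists = _distances(model.components, model.variances, _preprocess(X, model.mean, model.scale))
    return dists, dists <= model.threshold


def combined_verdict(flags: Sequence[np.ndarray]) -> np.ndarray:
    """Union rule across representations: out-of-domain if any flags out."""
    if not flags:
        raise ValueError("no representations given")
    stacked = np.stack([np.asarray(f, dtype=bool) for f in flags])
    return stacked.all(axis=0)
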