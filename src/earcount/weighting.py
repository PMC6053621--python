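"""Feature normalization, importance weighting and kernel-PCA fusion.

Weighting rests on the within-class dispersion of each feature dimension: a
dimension whose values concentrate within a class is considered important
for that class.  With ``k_jn`` the population standard deviation of
dimension n inside class j (computed on min-max normalized features),

    I_jn = 1 / (1 + k_jn)            (importance, in (0, 1])
    W_jn = I_jn / sum_n I_jn         (per-class weights, sum to 1)

A single inference-time vector ``W_combined`` (the renormalized mean of the
two class weight vectors) multiplies the features of any sample, labeled or
not, so train and test see the same transform.  The weighted features are
optionally fused through RBF kernel PCA, keeping components until a
configured fraction of the centered kernel spectrum is explained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist

from .features import FeatureMatrix

__all__ = [
    "NormalizationParams",
    "ImportanceTable",
    "KpcaModel",
    "fit_normalizer",
    "apply_normalizer",
    "importance",
    "importance_from_std",
    "apply_weights",
    "kpca_fit",
    "kpca_transform",
]


@dataclass
class NormalizationParams:
    """Per-dimension min/max learned on the training set."""

    min_: np.ndarray
    max_: np.ndarray


@dataclass
class ImportanceTable:
    k: np.ndarray           # 2 x D within-class population std (rows: class 0, 1)
    I: np.ndarray           # 2 x D importances
    W: np.ndarray           # 2 x D per-class weights, each row sums to 1
    W_combined: np.ndarray  # D, the single inference-time weight vector


@dataclass
class KpcaModel:
    reference: np.ndarray       # n x D training samples (weighted features)
    gamma: float                # RBF bandwidth, K = exp(-gamma * ||x-y||^2)
    alphas: np.ndarray          # n x r projection coefficients (v / sqrt(lambda))
    eigenvalues: np.ndarray     # r retained eigenvalues, descending
    explained_fraction: float   # cumulative eigenvalue fraction retained
    col_means: np.ndarray       # n, column means of the training kernel
    grand_mean: float


def _same_matrix(values: np.ndarray, like: FeatureMatrix) -> FeatureMatrix:
    return FeatureMatrix(values=values, block_spans=dict(like.block_spans))


def fit_normalizer(train: FeatureMatrix) -> NormalizationParams:
    if train.n_samples < 2:
        raise ValueError("fit_normalizer needs at least 2 samples")
    return NormalizationParams(min_=train.values.min(axis=0),
                               max_=train.values.max(axis=0))


def apply_normalizer(params: NormalizationParams, fm: FeatureMatrix) -> FeatureMatrix:
    """Min-max scale to [0,1] on the training range; constant dims map to 0."""
    span = params.max_ - params.min_
    safe = np.where(span > 0, span, 1.0)
    out = (fm.values - params.min_) / safe
    out[:, span <= 0] = 0.0
    return _same_matrix(out, fm)


def importance_from_std(k: np.ndarray) -> np.ndarray:
    """Importance of a dimension with within-class standard deviation k."""
    k = np.asarray(k, dtype=float)
    if (k < 0).any():
        raise ValueError("standard deviations must be >= 0")
    return 1.0 / (1.0 + k)


def importance(train_normalized: FeatureMatrix, labels: np.ndarray) -> ImportanceTable:
    """Per-class dispersion-based importances and weights."""
    labels = np.asarray(labels)
    rows_k, rows_i, rows_w = [], [], []
    for cls in (0, 1):
        sel = train_normalized.values[labels == cls]
        if sel.shape[0] < 2:
            raise ValueError(f"class {cls} needs at least 2 samples (got {sel.shape[0]})")
        k = sel.std(axis=0, ddof=0)
        i = importance_from_std(k)
        rows_k.append(k)
        rows_i.append(i)
        rows_w.append(i / i.sum())
    k = np.stack(rows_k)
    i = np.stack(rows_i)
    w = np.stack(rows_w)
    combined = w.mean(axis=0)
    combined = combined / combined.sum()
    return ImportanceTable(k=k, I=i, W=w, W_combined=combined)


def apply_weights(features: FeatureMatrix, table: ImportanceTable) -> FeatureMatrix:
    if features.n_features != table.W_combined.shape[0]:
        raise ValueError(
            f"feature dimension {features.n_features} does not match weight "
            f"vector of length {table.W_combined.shape[0]}"
        )
    return _same_matrix(features.values * table.W_combined, features)


def _rbf(x: np.ndarray, y: np.ndarray, gamma: float) -> np.ndarray:
    return np.exp(-gamma * cdist(x, y, "sqeuclidean"))


def kpca_fit(
    train_weighted: FeatureMatrix,
    bandwidth: float | None = None,
    variance_retained: float = 0.95,
) -> KpcaModel:
    """Fit RBF kernel PCA on the (weighted) training features.

    ``bandwidth`` is the RBF gamma, defaulting to the scale-aware
    1/(D * Var(X)) so the kernel stays informative regardless of the
    magnitude the upstream weighting leaves on the features.  Components
    are kept,
    in descending eigenvalue order, until the cumulative fraction of the
    positive centered-kernel spectrum reaches ``variance_retained``.  The
    eigenvector sign is fixed by making each component's largest-magnitude
    coefficient positive, so fits are bit-reproducible.
    """
    x = train_weighted.values
    n, d = x.shape
    if bandwidth is None:
        var = float(x.var())
        gamma = 1.0 / (d * var) if var > 0 else 1.0 / d
    else:
        gamma = bandwidth
    if gamma <= 0:
        raise ValueError("bandwidth must be > 0")
    if not (0 < variance_retained <= 1):
        raise ValueError("variance_retained must be in (0, 1]")
    k = _rbf(x, x, gamma)
    col_means = k.mean(axis=0)
    grand = float(k.mean())
    kc = k - col_means[None, :] - col_means[:, None] + grand
    evals, evecs = eigh(kc)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0.0) * 1e-12
    evals, evecs = evals[pos], evecs[:, pos]
    total = evals.sum()
    cum = np.cumsum(evals) / total
    r = int(np.searchsorted(cum, variance_retained - 1e-12) + 1)
    r = min(r, len(evals))
    evals, evecs = evals[:r], evecs[:, :r]
    flip = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(r)])
    flip[flip == 0] = 1.0
    evecs = evecs * flip[None, :]
    alphas = evecs / np.sqrt(evals)[None, :]
    return KpcaModel(
        reference=x.copy(),
        gamma=gamma,
        alphas=alphas,
        eigenvalues=evals,
        explained_fraction=float(cum[r - 1]),
        col_means=col_means,
        grand_mean=grand,
    )


def kpca_transform(model: KpcaModel, features: FeatureMatrix) -> FeatureMatrix:
    """Project samples onto the retained components."""
    if model is None:
        raise ValueError("kpca_transform called before kpca_fit")
    k = _rbf(features.values, model.reference, model.gamma)
    kc = (
        k
        - model.col_means[None, :]
        - k.mean(axis=1, keepdims=True)
        + model.grand_mean
    )
    scores = kc @ model.alphas
    return FeatureMatrix(values=scores, block_spans={"kpca": (0, scores.shape[1])})
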