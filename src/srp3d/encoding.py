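"""Global image encodings of patch-descriptor sets: BOVW and Fisher vectors.

BOVW quantizes patch descriptors against a k-means codebook with hard
nearest-centroid assignment and sum pooling; the vocabulary size is chosen
by an automated elbow rule over a candidate grid.  The Fisher-vector path
fits a diagonal-covariance GMM and concatenates the mean and variance
log-likelihood gradients (dimension ``2*G*D``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

__all__ = [
    "DEFAULT_K_CANDIDATES",
    "Codebook",
    "GMMCodebook",
    "EncodedImage",
    "select_k_elbow",
    "build_codebook",
    "build_gmm",
    "encode_bovw",
    "encode_fv",
]

DEFAULT_K_CANDIDATES: Tuple[int, ...] = (32, 64, 96, 128, 160)


@dataclass(frozen=True)
class Codebook:
    """k-means visual vocabulary."""

    centroids: np.ndarray
    k: int
    seed: int
    inertia: float

    @property
    def dim(self) -> int:
        return self.centroids.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "kmeans-codebook",
                "version": 1,
                "k": self.k,
                "seed": self.seed,
                "dim": self.dim,
                "inertia": self.inertia,
                "centroids": self.centroids.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "Codebook":
        obj = json.loads(text)
        return cls(
            centroids=np.asarray(obj["centroids"], dtype=float),
            k=int(obj["k"]),
            seed=int(obj["seed"]),
            inertia=float(obj["inertia"]),
        )


@dataclass(frozen=True)
class GMMCodebook:
    """Diagonal-covariance Gaussian mixture vocabulary."""

    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    seed: int

    @property
    def G(self) -> int:
        return self.means.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": "gmm-codebook",
                "version": 1,
                "G": self.G,
                "dim": self.dim,
                "seed": self.seed,
                "weights": self.weights.tolist(),
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "GMMCodebook":
        obj = json.loads(text)
        return cls(
            weights=np.asarray(obj["weights"], dtype=float),
            means=np.asarray(obj["means"], dtype=float),
            variances=np.asarray(obj["variances"], dtype=float),
            seed=int(obj["seed"]),
        )


@dataclass(frozen=True)
class EncodedImage:
    """Global representation of one volume: a BOVW histogram or a Fisher vector."""

    vector: np.ndarray
    kind: str  # "bovw" | "fv"


def _sse_curve(
    descriptors: np.ndarray,
    candidates: Sequence[int],
    seed: int,
    n_init: int,
) -> Dict[int, float]:
    sses: Dict[int, float] = {}
    for k in candidates:
        if len(descriptors) < k:
            warnings.warn(
                f"only {len(descriptors)} descriptors; skipping candidate k={k}",
                stacklevel=3,
            )
            continue
        km = KMeans(n_clusters=k, random_state=seed, n_init=n_init, tol=1e-4)
        km.fit(descriptors)
        sses[k] = float(km.inertia_)
    return sses


def select_k_elbow(
    descriptors: np.ndarray,
    candidates: Sequence[int] = DEFAULT_K_CANDIDATES,
    seed: int = 42,
    n_init: int = 10,
    return_curve: bool = False,
):
    """Choose the vocabulary size at the elbow of the SSE-vs-k curve.

    k-means is run for every candidate and the candidate maximizing the
    discrete second difference of the SSE sequence (the sharpest bend) is
    returned.  Ties -- including a perfectly flat curve, e.g. duplicated
    data with SSE 0 everywhere -- resolve to the smallest candidate.
    """
    descriptors = np.asarray(descriptors, dtype=float)
    candidates = sorted(int(k) for k in candidates)
    sses = _sse_curve(descriptors, candidates, seed, n_init)
    if not sses:
        raise ValueError("no candidate k is feasible for this descriptor count")
    ks = sorted(sses)
    sse = np.array([sses[k] for k in ks])
    if len(ks) < 3 or np.allclose(sse, sse[0]):
        best = ks[0]
    else:
        d2 = sse[:-2] - 2.0 * sse[1:-1] + sse[2:]  # interior candidates only
        if np.allclose(d2, d2[0]):
            best = ks[0]
        else:
            best = ks[1 + int(np.argmax(d2))]
    if return_curve:
        return best, sses
    return best


def plot_sse_curve(sses: Dict[int, float], path: str, chosen: int | None = None) -> None:
    """Save the SSE-vs-k elbow plot backing an automated selection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ks = sorted(sses)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(ks, [sses[k] for k in ks], marker="o")
    if chosen is not None:
        ax.axvline(chosen, color="tab:red", ls="--", label=f"elbow k={chosen}")
        ax.legend()
    ax.set_xlabel("k")
    ax.set_ylabel("sum of squared errors")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def build_codebook(
    descriptors: np.ndarray, k: int, seed: int = 42, n_init: int = 10
) -> Codebook:
    """Fit a k-means codebook (k-means++ init, fixed seed, tol 1e-4)."""
    descriptors = np.asarray(descriptors, dtype=float)
    if len(descriptors) < k:
        raise ValueError(f"need at least k={k} descriptors, got {len(descriptors)}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init, tol=1e-4)
    km.fit(descriptors)
    return Codebook(
        centroids=km.cluster_centers_.copy(),
        k=k,
        seed=seed,
        inertia=float(km.inertia_),
    )


def build_gmm(features: np.ndarray, G: int, seed: int = 42) -> GMMCodebook:
    """Fit a diagonal-covariance GMM vocabulary with ``G`` components."""
    features = np.asarray(features, dtype=float)
    gm = GaussianMixture(
        n_components=G, covariance_type="diag", random_state=seed, reg_covar=1e-6
    )
    gm.fit(features)
    return GMMCodebook(
        weights=gm.weights_.copy(),
        means=gm.means_.copy(),
        variances=gm.covariances_.copy(),
        seed=seed,
    )


def encode_bovw(descriptor_set: np.ndarray, codebook: Codebook) -> EncodedImage:
    """Hard-assign each patch to its nearest centroid and sum-pool the counts.

    The resulting histogram has length ``k`` and sums to the patch count.
    """
    X = np.asarray(descriptor_set, dtype=float)
    if hasattr(descriptor_set, "matrix"):  # VolumeDescriptorSet
        X = descriptor_set.matrix()
    if X.ndim != 2 or X.shape[1] != codebook.dim:
        raise ValueError(
            f"descriptors of dim {X.shape[-1] if X.ndim == 2 else X.shape} "
            f"do not match codebook dim {codebook.dim}"
        )
    d2 = (
        (X**2).sum(axis=1, keepdims=True)
        - 2.0 * X @ codebook.centroids.T
        + (codebook.centroids**2).sum(axis=1)
    )
    assign = np.argmin(d2, axis=1)
    hist = np.bincount(assign, minlength=codebook.k).astype(float)
    return EncodedImage(vector=hist, kind="bovw")


def encode_fv(
    local_features: np.ndarray,
    gmm: GMMCodebook,
    improved: bool = True,
) -> EncodedImage:
    """Fisher vector of a feature set under a diagonal GMM.

    Concatenates the normalized gradients of the mean and variance
    parameters (the weight block is omitted), giving length ``2*G*D``.
    With ``improved=True`` the signed square root and L2 normalization are
    applied afterwards.
    """
    X = np.asarray(local_features, dtype=float)
    if X.ndim != 2 or X.shape[1] != gmm.dim:
        raise ValueError(
            f"features of shape {X.shape} do not match GMM dim {gmm.dim}"
        )
    T = X.shape[0]
    w = gmm.weights
    mu = gmm.means
    var = gmm.variances
    sd = np.sqrt(var)
    # posteriors via log-domain softmax
    log_det = np.sum(np.log(var), axis=1)
    diff = X[:, None, :] - mu[None, :, :]  # (T, G, D)
    maha = np.sum(diff**2 / var[None, :, :], axis=2)
    log_p = np.log(w)[None, :] - 0.5 * (maha + log_det[None, :])
    log_p -= log_p.max(axis=1, keepdims=True)
    gamma = np.exp(log_p)
    gamma /= gamma.sum(axis=1, keepdims=True)  # (T, G)

    u = diff / sd[None, :, :]
    g_mu = np.einsum("tg,tgd->gd", gamma, u) / (T * np.sqrt(w)[:, None])
    g_var = np.einsum("tg,tgd->gd", gamma, u**2 - 1.0) / (
        T * np.sqrt(2.0 * w)[:, None]
    )
    fv = np.concatenate([g_mu.ravel(), g_var.ravel()])
    if improved:
        fv = np.sign(fv) * np.sqrt(np.abs(fv))
        norm = np.linalg.norm(fv)
        if norm > 0:
            fv = fv / norm
    return EncodedImage(vector=fv, kind="fv")
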