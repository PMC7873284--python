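"""SVM-RBF phenotype classification under grouped 10-fold cross-validation.

Folds are built at the source-image level so no 3D image contributes cells
to both training and test sides.  Within each outer training set the
encoder artifacts (BOVW codebook / GMM), the feature scaler and the RBF
gamma (median pairwise-distance heuristic on 100 sampled rows) are fit
from scratch; the SVM uses the default regularization constant.  Model
comparison uses the Kruskal-Wallis rank test and a one-sided two-sample
t-test for the 3D-vs-pseudo-3D contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.metrics import (
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from srp3d.encoding import Codebook, build_codebook, build_gmm, encode_bovw, encode_fv

__all__ = [
    "LabelledFeatureTable",
    "EncoderConfig",
    "CVReport",
    "group_kfold_split",
    "tune_gamma",
    "run_cv",
    "kruskal_wallis_compare",
    "pseudo_vs_3d_ttest",
]

METRICS = ("auc", "f1", "precision", "recall")


@dataclass
class LabelledFeatureTable:
    """Per-cell features with binary labels and source-image group ids.

    ``samples`` holds one entry per cell object: either a 2D array of patch
    descriptors (rows = patches) to be encoded per fold, or an already
    encoded 1D vector.
    """

    samples: List[np.ndarray]
    labels: np.ndarray
    groups: np.ndarray
    positive_label: object = 1

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.groups = np.asarray(self.groups)
        n = len(self.samples)
        if len(self.labels) != n or len(self.groups) != n:
            raise ValueError("samples, labels and groups must have equal length")
        if len(np.unique(self.labels)) != 2:
            raise ValueError("exactly two classes are required")

    @property
    def y(self) -> np.ndarray:
        return (self.labels == self.positive_label).astype(int)


@dataclass(frozen=True)
class EncoderConfig:
    """How per-fold encoding of patch descriptors is performed.

    ``kind='none'`` expects pre-encoded vectors; ``'bovw'`` fits a k-means
    codebook on the fold's training descriptors; ``'fv'`` fits a GMM.
    ``max_fit_descriptors`` caps the number of descriptors used to fit the
    vocabulary (seeded subsample) to bound runtime.
    """

    kind: str = "bovw"
    k: int = 64
    G: int = 8
    n_init: int = 10
    max_fit_descriptors: Optional[int] = 20000


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validation metrics."""

    per_fold: Dict[str, np.ndarray]
    fold_assignments: np.ndarray
    roc_curves: List[Tuple[np.ndarray, np.ndarray]]
    seed: int

    def mean(self, metric: str) -> float:
        return float(np.mean(self.per_fold[metric]))

    def std(self, metric: str) -> float:
        return float(np.std(self.per_fold[metric]))

    def summary(self) -> Dict[str, Dict[str, float]]:
        return {
            m: {"mean": self.mean(m), "std": self.std(m)} for m in METRICS
        }


def group_kfold_split(
    groups: Sequence, k: int = 10, seed: int = 42
) -> np.ndarray:
    """Assign whole groups to ``k`` folds, balancing member counts greedily.

    Returns an integer fold id per sample.  Every sample of a group lands
    in the same fold; groups are shuffled with the seed before the greedy
    largest-first assignment so ties break reproducibly.
    """
    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < k:
        raise ValueError(f"need at least k={k} distinct groups, got {len(uniq)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    uniq, counts = uniq[order], counts[order]
    order = np.argsort(-counts, kind="stable")  # largest first
    fold_sizes = np.zeros(k, dtype=int)
    fold_ngroups = np.zeros(k, dtype=int)
    fold_of_group = {}
    for gi in order:
        # fewest members, then fewest groups, keeps folds balanced
        f = int(np.lexsort((fold_ngroups, fold_sizes))[0])
        fold_of_group[uniq[gi]] = f
        fold_sizes[f] += counts[gi]
        fold_ngroups[f] += 1
    return np.array([fold_of_group[g] for g in groups], dtype=int)


def tune_gamma(
    train_features: np.ndarray, n_samples: int = 100, seed: int = 42
) -> float:
    """Median heuristic: ``gamma = 1 / median(pairwise squared distances)``.

    Distances are measured among ``min(n_samples, n)`` seeded-sampled rows.
    If every sampled pair coincides the fallback is ``1/D``.
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or len(X) == 0:
        raise ValueError("training features must be a non-empty 2D array")
    rng = np.random.default_rng(seed)
    m = min(n_samples, len(X))
    idx = rng.choice(len(X), size=m, replace=False)
    S = X[idx]
    d2 = (
        (S**2).sum(axis=1)[:, None]
        - 2.0 * S @ S.T
        + (S**2).sum(axis=1)[None, :]
    )
    iu = np.triu_indices(m, k=1)
    med = float(np.median(d2[iu])) if iu[0].size else 0.0
    if med <= 0:
        warnings.warn("sampled points are identical; falling back to gamma=1/D",
                      stacklevel=2)
        return 1.0 / X.shape[1]
    return 1.0 / med


def _encode_fold(
    table: LabelledFeatureTable,
    train_idx: np.ndarray,
    config: EncoderConfig,
    seed: int,
) -> Tuple[np.ndarray, object]:
    """Fit encoder artifacts on the training rows only and encode all rows."""
    if config.kind == "none":
        X = np.stack([np.ravel(s) for s in table.samples])
        return X, None
    train_desc = np.concatenate(
        [np.atleast_2d(table.samples[i]) for i in train_idx], axis=0
    )
    cap = config.max_fit_descriptors
    if cap is not None and len(train_desc) > cap:
        rng = np.random.default_rng(seed)
        train_desc = train_desc[rng.choice(len(train_desc), cap, replace=False)]
    if config.kind == "bovw":
        codebook = build_codebook(train_desc, config.k, seed=seed, n_init=config.n_init)
        X = np.stack(
            [encode_bovw(np.atleast_2d(s), codebook).vector for s in table.samples]
        )
        return X, codebook
    if config.kind == "fv":
        gmm = build_gmm(train_desc, config.G, seed=seed)
        X = np.stack(
            [encode_fv(np.atleast_2d(s), gmm).vector for s in table.samples]
        )
        return X, gmm
    raise ValueError(f"unknown encoder kind {config.kind!r}")


def run_cv(
    table: LabelledFeatureTable,
    encoder_config: EncoderConfig | None = None,
    seed: int = 42,
    k_folds: int = 10,
    standardize: bool = True,
    C: float = 1.0,
) -> CVReport:
    """Grouped k-fold cross-validation of the SVM-RBF classifier.

    Per fold: encoder artifacts are fit on the outer training set, features
    standardized, gamma tuned with the median heuristic on 100 sampled
    training rows, and an RBF SVM with default regularization trained.
    Decision values feed the ROC/AUC.  Deterministic for a fixed seed.
    """
    if encoder_config is None:
        encoder_config = EncoderConfig(kind="none")
    folds = group_kfold_split(table.groups, k=k_folds, seed=seed)
    y = table.y
    per_fold: Dict[str, List[float]] = {m: [] for m in METRICS}
    rocs: List[Tuple[np.ndarray, np.ndarray]] = []
    for f in range(k_folds):
        test_mask = folds == f
        train_idx = np.flatnonzero(~test_mask)
        test_idx = np.flatnonzero(test_mask)
        # grouped integrity: a group never crosses folds
        assert not set(table.groups[train_idx]) & set(table.groups[test_idx])
        if len(np.unique(y[test_idx])) < 2 or len(np.unique(y[train_idx])) < 2:
            warnings.warn(f"fold {f} is single-class; skipped", stacklevel=2)
            continue
        X, _ = _encode_fold(table, train_idx, encoder_config, seed=seed + f)
        X_train, X_test = X[train_idx], X[test_idx]
        if standardize:
            scaler = StandardScaler().fit(X_train)
            X_train = scaler.transform(X_train)
            X_test = scaler.transform(X_test)
        gamma = tune_gamma(X_train, n_samples=100, seed=seed + f)
        clf = SVC(C=C, kernel="rbf", gamma=gamma)
        clf.fit(X_train, y[train_idx])
        scores = clf.decision_function(X_test)
        preds = clf.predict(X_test)
        y_test = y[test_idx]
        per_fold["auc"].append(float(roc_auc_score(y_test, scores)))
        per_fold["f1"].append(float(f1_score(y_test, preds, zero_division=0)))
        per_fold["precision"].append(
            float(precision_score(y_test, preds, zero_division=0))
        )
        per_fold["recall"].append(float(recall_score(y_test, preds, zero_division=0)))
        fpr, tpr, _ = roc_curve(y_test, scores)
        rocs.append((fpr, tpr))
    return CVReport(
        per_fold={m: np.array(v) for m, v in per_fold.items()},
        fold_assignments=folds,
        roc_curves=rocs,
        seed=seed,
    )


@dataclass(frozen=True)
class KruskalWallisReport:
    H: float
    p_value: float
    alpha: float
    reject: bool
    mean_ranks: Dict[str, float]
    intervals: Dict[str, Tuple[float, float]]


def kruskal_wallis_compare(
    metric_samples: Dict[str, Sequence[float]], alpha: float = 0.01
) -> KruskalWallisReport:
    """Rank-based one-way comparison of several methods' metric samples.

    Reports the H statistic, p-value at the given level, per-method mean
    ranks and normal-approximation comparison intervals for plotting.
    All-tied data yields ``p = 1`` (nothing to distinguish).
    """
    names = list(metric_samples)
    if len(names) < 2:
        raise ValueError("need at least two methods")
    groups = [np.asarray(metric_samples[n], dtype=float) for n in names]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least two samples per method")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        H, p = 0.0, 1.0
    else:
        H, p = stats.kruskal(*groups)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    intervals = {}
    N = len(pooled)
    start = 0
    se_base = np.sqrt(N * (N + 1) / 12.0)
    zcrit = stats.norm.ppf(1 - alpha / 2) / np.sqrt(2.0)
    for name, g in zip(names, groups):
        mr = float(np.mean(ranks[start : start + len(g)]))
        hw = float(zcrit * se_base / np.sqrt(len(g)))
        mean_ranks[name] = mr
        intervals[name] = (mr - hw, mr + hw)
        start += len(g)
    return KruskalWallisReport(
        H=float(H),
        p_value=float(p),
        alpha=alpha,
        reject=bool(p < alpha),
        mean_ranks=mean_ranks,
        intervals=intervals,
    )


@dataclass(frozen=True)
class TTestReport:
    t_statistic: float
    p_value: float
    alpha: float
    reject: bool
    mean_3d: float
    mean_pseudo: float


def pseudo_vs_3d_ttest(
    metric_3d: Sequence[float],
    metric_pseudo: Sequence[float],
    alpha: float = 0.05,
) -> TTestReport:
    """One-sided two-sample t-test of whether the full 3D descriptor wins.

    H0: the pseudo-3D variant performs at least as well; rejection (small
    p) supports the full 3D variant.  Equal zero-variance samples give
    ``p = 1``.
    """
    a = np.asarray(metric_3d, dtype=float)
    b = np.asarray(metric_pseudo, dtype=float)
    if a.shape != b.shape:
        raise ValueError("per-fold metric vectors must have equal length")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_ind(a, b, alternative="greater")
        if np.isnan(p):
            t, p = 0.0, 1.0
    return TTestReport(
        t_statistic=float(t),
        p_value=float(p),
        alpha=alpha,
        reject=bool(p < alpha),
        mean_3d=float(np.mean(a)),
        mean_pseudo=float(np.mean(b)),
    )
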