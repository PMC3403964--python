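"""Feature scaling, PCA, k-means clustering, accuracy scoring and group statistics.

The analysis chain is the one used throughout the package: scale every
feature to unit variance (sample s.d., n-1 denominator), reduce by PCA,
cluster the scores from *all* principal components with k-means (k = 2),
and score the clustering against known class labels with the
best-permutation accuracy.  Because all components are retained, the PCA is
an orthogonal rotation and k-means on the scores is equivalent to k-means
on the scaled feature matrix; the first two PC scores are kept for 2-D
display.

`PCAKMeans` packages the chain as a scikit-learn estimator; the module-level
functions are thin wrappers kept for scripting.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_array, check_is_fitted

from .errors import ValidationError
from .io import FeatureTable


# ---------------------------------------------------------------------------
# scaling


def scale_unit_variance(table: FeatureTable):
    """Center each feature and scale to unit sample variance (ddof = 1).

    Zero-variance columns carry no information and would divide by zero;
    they are dropped with a warning.  Returns ``(scaled_table, means,
    scales)`` where means/scales refer to the retained columns.
    """
    if table.n_cells < 2:
        raise ValidationError("scaling needs at least 2 rows")
    values = table.values
    means = values.mean(axis=0)
    scales = values.std(axis=0, ddof=1)
    keep = scales > 0
    if not keep.any():
        raise ValidationError("all feature columns have zero variance")
    dropped = [n for n, k in zip(table.feature_names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance features: {dropped}", stacklevel=2)
    scaled = (values[:, keep] - means[keep]) / scales[keep]
    out = FeatureTable(
        cell_ids=list(table.cell_ids),
        feature_names=[n for n, k in zip(table.feature_names, keep) if k],
        values=scaled,
        class_labels=None if table.class_labels is None else list(table.class_labels),
    )
    return out, means[keep], scales[keep]


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    component_loadings: np.ndarray        # (n_components, n_features)
    scores: np.ndarray                    # (n_cells, n_components)
    explained_variance_fractions: np.ndarray
    means: np.ndarray
    scales: np.ndarray


def _fix_signs(components: np.ndarray, scores: np.ndarray):
    """Make each loading vector's largest-magnitude entry positive."""
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1.0
            scores[:, i] *= -1.0
    return components, scores


def pca(scaled_values: np.ndarray, means: np.ndarray | None = None,
        scales: np.ndarray | None = None) -> PCAResult:
    """Full PCA of a scaled, centered matrix with a fixed sign convention."""
    X = np.asarray(scaled_values, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("PCA needs a 2D matrix with at least 2 rows")
    model = PCA(n_components=None, svd_solver="full")
    scores = model.fit_transform(X)
    components, scores = _fix_signs(model.components_.copy(), scores)
    return PCAResult(
        component_loadings=components,
        scores=scores,
        explained_variance_fractions=model.explained_variance_ratio_.copy(),
        means=np.zeros(X.shape[1]) if means is None else np.asarray(means),
        scales=np.ones(X.shape[1]) if scales is None else np.asarray(scales),
    )


# ---------------------------------------------------------------------------
# k-means


@dataclass
class ClusterResult:
    assignments: np.ndarray
    k: int
    objective: float
    seed: int
    accuracy: float | None = None
    confusion_table: np.ndarray | None = None
    mapping: dict | None = None


def _wcss(X: np.ndarray, labels: np.ndarray, k: int) -> float:
    out = 0.0
    for c in range(k):
        member = X[labels == c]
        if len(member):
            out += float(((member - member.mean(axis=0)) ** 2).sum())
    return out


def _hartigan_wong_once(X: np.ndarray, k: int, rng: np.random.Generator,
                        max_iter: int):
    """One Hartigan-Wong-style run from random distinct initial centres.

    Points are transferred one at a time using the size-corrected criterion
    ``n2/(n2+1) d(x,c2)^2 < n1/(n1-1) d(x,c1)^2`` with centroids updated
    incrementally; every accepted transfer strictly decreases the objective,
    so the procedure terminates.  This single-point-transfer rule is what
    distinguishes Hartigan-Wong from Lloyd iterations and lets it step out
    of Lloyd fixed points.
    """
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    d2 = ((X[:, None, :] - centers[None]) ** 2).sum(axis=-1)
    labels = d2.argmin(axis=1)
    counts = np.bincount(labels, minlength=k)
    for c in range(k):
        if counts[c] == 0:  # duplicate rows can empty a cluster at init
            far = int(d2.min(axis=1).argmax())
            counts[labels[far]] -= 1
            labels[far] = c
            counts[c] += 1
            d2 = None
    for c in range(k):
        centers[c] = X[labels == c].mean(axis=0)

    for _ in range(max_iter):
        moved = False
        for i in range(n):
            c1 = int(labels[i])
            n1 = counts[c1]
            if n1 <= 1:
                continue
            d = ((centers - X[i]) ** 2).sum(axis=1)
            removal = n1 / (n1 - 1.0) * d[c1]
            gain = counts / (counts + 1.0) * d
            gain[c1] = np.inf
            c2 = int(gain.argmin())
            if removal - gain[c2] > 1e-12 * max(1.0, removal):
                centers[c1] = (centers[c1] * n1 - X[i]) / (n1 - 1)
                n2 = counts[c2]
                centers[c2] = (centers[c2] * n2 + X[i]) / (n2 + 1)
                counts[c1] -= 1
                counts[c2] += 1
                labels[i] = c2
                moved = True
        if not moved:
            break
    return labels, _wcss(X, labels, k)


def kmeans(points: np.ndarray, k: int = 2, seed: int = 0, n_init: int = 10,
           max_iter: int = 300,
           algorithm: str = "hartigan-wong") -> ClusterResult:
    """k-means with ``n_init`` restarts, Hartigan-Wong by default.

    ``algorithm="hartigan-wong"`` uses single-point transfers with the
    size-corrected improvement criterion (the classical Hartigan-Wong
    scheme, initialized from random distinct data points);
    ``algorithm="lloyd"`` delegates to scikit-learn's Lloyd iterations with
    k-means++ starts.  Both are deterministic given ``seed`` and return the
    best restart by within-cluster sum of squares.
    """
    X = np.asarray(points, dtype=np.float64)
    if X.ndim != 2:
        raise ValidationError("points must be a 2D array")
    if k > X.shape[0]:
        raise ValidationError(f"k={k} exceeds number of points {X.shape[0]}")
    if algorithm == "lloyd":
        model = KMeans(n_clusters=k, init="k-means++", n_init=n_init,
                       max_iter=max_iter, algorithm="lloyd", random_state=seed)
        labels = model.fit_predict(X)
        return ClusterResult(assignments=labels.astype(int), k=k,
                             objective=float(model.inertia_), seed=seed)
    if algorithm != "hartigan-wong":
        raise ValidationError(f"unknown k-means algorithm {algorithm!r}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        labels, obj = _hartigan_wong_once(X, k, rng, max_iter)
        if best is None or obj < best[1]:
            best = (labels, obj)
    return ClusterResult(assignments=best[0].astype(int), k=k,
                         objective=float(best[1]), seed=seed)


# ---------------------------------------------------------------------------
# accuracy


def best_permutation_accuracy(assignments, true_labels):
    """Accuracy under the best cluster-to-class bijection.

    Maximizes the matched fraction over all bijections between cluster
    indices and class labels; ties pick the lexicographically smallest
    mapping.  Returns ``(accuracy, mapping, confusion_table)`` where the
    confusion table rows are clusters and columns are classes (sorted).
    """
    a = np.asarray(assignments)
    t = np.asarray(true_labels)
    if a.shape != t.shape:
        raise ValidationError(
            f"assignment count {a.size} != label count {t.size}"
        )
    classes = sorted(set(t.tolist()))
    clusters = sorted(set(a.tolist()))
    if len(classes) != len(clusters):
        raise ValidationError(
            f"{len(clusters)} clusters but {len(classes)} distinct labels"
        )
    k = len(classes)
    confusion = np.zeros((k, k), dtype=int)
    for ci, cl in enumerate(clusters):
        for yi, y in enumerate(classes):
            confusion[ci, yi] = int(((a == cl) & (t == y)).sum())
    best = (-1, None)
    for perm in itertools.permutations(range(k)):
        correct = sum(confusion[ci, perm[ci]] for ci in range(k))
        mapping = tuple(classes[perm[ci]] for ci in range(k))
        if correct > best[0] or (correct == best[0] and mapping < best[1]):
            best = (correct, mapping)
    accuracy = best[0] / a.size
    mapping = {clusters[ci]: best[1][ci] for ci in range(k)}
    return float(accuracy), mapping, confusion


# ---------------------------------------------------------------------------
# RWC joining


def append_rwc(table: FeatureTable, rwc_by_cell, name: str = "rwc") -> FeatureTable:
    """Append the per-cell RWC coefficient as one additional feature column."""
    if name in table.feature_names:
        raise ValidationError(f"table already has a {name!r} column")
    mapping = dict(rwc_by_cell) if not isinstance(rwc_by_cell, dict) else rwc_by_cell
    missing = [cid for cid in table.cell_ids if cid not in mapping]
    if missing:
        raise ValidationError(f"missing RWC for cells: {missing}")
    col = np.array([float(mapping[cid]) for cid in table.cell_ids])
    return FeatureTable(
        cell_ids=list(table.cell_ids),
        feature_names=list(table.feature_names) + [name],
        values=np.column_stack([table.values, col]),
        class_labels=None if table.class_labels is None else list(table.class_labels),
    )


# ---------------------------------------------------------------------------
# group comparison


@dataclass
class GroupComparison:
    group_names: list
    overall_p: float
    pairwise: list = field(default_factory=list)  # (pair, mean_diff, p_adj, significant)


def compare_groups(groups: dict, alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA plus pairwise Tukey-Kramer tests with Welch adjustment.

    ``groups`` maps group name to a 1-D array of values.  The overall p is
    the raw ANOVA F-test; each unordered pair gets a studentized-range
    p-value whose standard error and degrees of freedom use the
    Welch-Satterthwaite construction, so unequal variances and sample sizes
    are accommodated.  Only the post-hoc family is adjusted.
    """
    names = list(groups.keys())
    if len(names) < 2:
        raise ValidationError("need at least two groups")
    arrays = {n: np.asarray(groups[n], dtype=np.float64).ravel() for n in names}
    for n, arr in arrays.items():
        if arr.size < 2:
            raise ValidationError(f"group {n!r} has fewer than 2 values")
    k = len(names)
    overall = stats.f_oneway(*[arrays[n] for n in names])
    pairwise = []
    for n1, n2 in itertools.combinations(names, 2):
        x, y = arrays[n1], arrays[n2]
        v1, v2 = x.var(ddof=1), y.var(ddof=1)
        nx, ny = x.size, y.size
        se2 = v1 / nx + v2 / ny
        diff = float(x.mean() - y.mean())
        if se2 == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            df = se2**2 / ((v1 / nx) ** 2 / (nx - 1) + (v2 / ny) ** 2 / (ny - 1))
            q = abs(diff) / np.sqrt(se2 / 2.0)
            p = float(stats.studentized_range.sf(q, k, df))
        pairwise.append(((n1, n2), diff, p, bool(p < alpha)))
    return GroupComparison(group_names=names, overall_p=float(overall.pvalue),
                           pairwise=pairwise)


# ---------------------------------------------------------------------------
# estimator


class PCAKMeans(ClusterMixin, BaseEstimator):
    """Unit-variance scaling -> full PCA -> k-means on all PC scores.

    Parameters
    ----------
    n_clusters : int, default=2
        Number of k-means centres.
    n_init, max_iter : int
        Passed to the k-means restarts.
    random_state : int or None
        Seed for the k-means initialization; the rest of the chain is
        deterministic.

    Attributes
    ----------
    labels_ : ndarray of shape (n_samples,)
        Cluster assignment per sample.
    scores_ : ndarray of shape (n_samples, n_components)
        PC scores (all components retained).
    explained_variance_ratio_ : ndarray
        Fraction of variance per component; sums to 1.
    components_ : ndarray
        PCA loadings on the retained (non-constant) features.
    kept_features_ : ndarray of int
        Indices of input columns that survived the zero-variance filter.
    inertia_ : float
        Within-cluster sum of squares of the best restart.
    """

    def __init__(self, n_clusters: int = 2, n_init: int = 10,
                 max_iter: int = 300, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X, dtype=np.float64, ensure_min_samples=2)
        self.n_features_in_ = X.shape[1]
        means = X.mean(axis=0)
        scales = X.std(axis=0, ddof=1)
        keep = scales > 0
        if not keep.any():
            raise ValidationError("all feature columns have zero variance")
        self.kept_features_ = np.nonzero(keep)[0]
        self.means_ = means[keep]
        self.scales_ = scales[keep]
        Z = (X[:, keep] - self.means_) / self.scales_
        res = pca(Z)
        self.components_ = res.component_loadings
        self.explained_variance_ratio_ = res.explained_variance_fractions
        self.scores_ = res.scores
        seed = 0 if self.random_state is None else int(self.random_state)
        cluster = kmeans(self.scores_, k=self.n_clusters, seed=seed,
                         n_init=self.n_init, max_iter=self.max_iter)
        self.labels_ = cluster.assignments
        self.inertia_ = cluster.objective
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X, y).labels_

    def transform(self, X):
        """Project new data onto the fitted PC axes (scaled first)."""
        check_is_fitted(self, "components_")
        X = check_array(X, dtype=np.float64)
        Z = (X[:, self.kept_features_] - self.means_) / self.scales_
        return Z @ self.components_.T

    def score_accuracy(self, y):
        """Best-permutation accuracy of ``labels_`` against true labels."""
        check_is_fitted(self, "labels_")
        acc, mapping, confusion = best_permutation_accuracy(self.labels_, y)
        return acc


# ---------------------------------------------------------------------------
# end-to-end


def run_pipeline(table: FeatureTable, rwc_by_cell=None, k: int = 2,
                 seed: int = 0, n_init: int = 10):
    """Full analysis: scale -> PCA -> k-means, without and (optionally) with RWC.

    The texture-only run scales the 24 features to unit variance, takes the
    full PCA and clusters all PC scores.  The with-RWC run uses the texture
    *PC scores* — not the raw features — as the independent variables, to
    sidestep the strong multi-collinearity of the texture battery: the
    scores are scaled to unit variance (which whitens the texture block),
    the per-cell RWC coefficient is appended as one additional feature, and
    the 25-column dataset is scaled, reduced by PCA and clustered in the
    same manner as before.  Without the whitening step the texture
    covariance dominates the k-means objective and a single co-localization
    feature could never influence the partition.

    Returns ``(result, report)`` where ``result`` is the ClusterResult of the
    final run (with RWC when supplied) and ``report`` is a JSON-serializable
    dictionary including explained-variance fractions, the first two PC
    scores for display, and best-permutation accuracies whenever the feature
    table carries class labels.
    """
    def _one_run(tbl: FeatureTable):
        scaled, means, scales = scale_unit_variance(tbl)
        p = pca(scaled.values)
        cl = kmeans(p.scores, k=k, seed=seed, n_init=n_init)
        acc = None
        confusion = None
        mapping = None
        if tbl.class_labels is not None:
            acc, mapping, confusion = best_permutation_accuracy(
                cl.assignments, tbl.class_labels
            )
        cl.accuracy = acc
        cl.confusion_table = confusion
        cl.mapping = mapping
        return scaled, p, cl

    _, pca_wo, cl_wo = _one_run(table)
    report = {
        "params": {"k": k, "seed": seed, "n_init": n_init,
                   "with_rwc": rwc_by_cell is not None},
        "n_cells": table.n_cells,
        "features_used": list(table.feature_names),
        "explained_variance": pca_wo.explained_variance_fractions.tolist(),
        "assignments": cl_wo.assignments.tolist(),
        "pc_scores_2d": pca_wo.scores[:, :2].tolist(),
    }
    if cl_wo.accuracy is not None:
        report["accuracy_without_rwc"] = cl_wo.accuracy
    result = cl_wo
    if rwc_by_cell is not None:
        # Texture PC scores as independent variables (decorrelated), then RWC.
        # Components below the numerical-rank tolerance are float noise; they
        # must not survive the unit-variance rescaling that follows.
        sds = pca_wo.scores.std(axis=0, ddof=1)
        tol = max(pca_wo.scores.shape) * np.finfo(np.float64).eps * sds.max()
        rank = np.nonzero(sds > tol)[0]
        score_table = FeatureTable(
            cell_ids=list(table.cell_ids),
            feature_names=[f"pc_{i + 1:02d}" for i in rank],
            values=pca_wo.scores[:, rank].copy(),
            class_labels=None if table.class_labels is None
            else list(table.class_labels),
        )
        extended = append_rwc(score_table, rwc_by_cell)
        _, pca_w, cl_w = _one_run(extended)
        report["features_used"] = list(extended.feature_names)
        report["explained_variance"] = pca_w.explained_variance_fractions.tolist()
        report["assignments"] = cl_w.assignments.tolist()
        report["pc_scores_2d"] = pca_w.scores[:, :2].tolist()
        if cl_w.accuracy is not None:
            report["accuracy_with_rwc"] = cl_w.accuracy
        result = cl_w
    return result, report
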