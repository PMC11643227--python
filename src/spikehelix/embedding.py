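"""Fingerprint distances, eigen-embedding, clustering, and trial decoding.

Once every trial's spike pattern is reduced to its complex fingerprint, trials
live in C^N with the ordinary Euclidean metric, ``d(a, b) = ||mu_a - mu_b||``.
The pairwise distance matrix D over N_T trials is then eigendecomposed and
trials are embedded as ``P = D @ [v_1 ... v_n]`` using the eigenvectors with
largest-modulus eigenvalues (D is symmetric but indefinite, so modulus and
algebraic orderings differ; both are offered, modulus is the default).
Clustering (spectral on a Gaussian affinity of D, or K-means on P),
cluster-separability scoring, nearest-centroid decoding of condition labels
from P, and linear-SVM decoding from selected helix contributions all operate
downstream of this embedding.

By default the projection is computed once from all trials and the decoder is
then cross-validated inside it, mirroring the embed-then-fold workflow this
analysis is built around; that shares marginal information across folds, so a
strict mode that refits the embedding from the training trials of each fold
(projecting test trials through their distances to the training set) is also
provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans, SpectralClustering
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from .errors import (
    DegenerateClustersError,
    InvalidDimensionError,
    ShapeMismatchError,
    StratificationError,
)
from .transform import Fingerprint, ms_dht

__all__ = [
    "TrialEnsemble",
    "DistanceMatrix",
    "Projection",
    "DecodeResult",
    "fingerprint_distance",
    "distance_matrix",
    "eigen_projection",
    "spectral_cluster",
    "kmeans_cluster",
    "cluster_distance_ratio",
    "nearest_centroid_decode",
    "svm_decode",
]


@dataclass(frozen=True)
class TrialEnsemble:
    """Fingerprints (and optional condition labels) across N_T trials."""

    fingerprints: np.ndarray = field(repr=False)  # (N_T, N) complex
    labels: np.ndarray | None = None
    trial_ids: np.ndarray | None = None
    window: float = 1.0

    def __post_init__(self) -> None:
        fps = np.atleast_2d(np.asarray(self.fingerprints, dtype=complex))
        object.__setattr__(self, "fingerprints", fps)
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.size != fps.shape[0]:
                raise ShapeMismatchError("labels length != number of trials")
            object.__setattr__(self, "labels", labels)
        ids = (
            np.arange(fps.shape[0])
            if self.trial_ids is None
            else np.asarray(self.trial_ids)
        )
        if ids.size != fps.shape[0]:
            raise ShapeMismatchError("trial_ids length != number of trials")
        object.__setattr__(self, "trial_ids", ids)

    @property
    def n_trials(self) -> int:
        return int(self.fingerprints.shape[0])

    @property
    def n_neurons(self) -> int:
        return int(self.fingerprints.shape[1])

    @classmethod
    def from_patterns(
        cls,
        patterns,
        labels=None,
        trial_ids=None,
        phase_offset: float = 0.0,
    ) -> "TrialEnsemble":
        """Transform a sequence of spike patterns into an ensemble."""
        fps = [ms_dht(p, phase_offset) for p in patterns]
        n = {fp.n_neurons for fp in fps}
        if len(n) != 1:
            raise ShapeMismatchError("patterns disagree on population size")
        return cls(
            np.array([fp.mu for fp in fps]),
            labels=labels,
            trial_ids=trial_ids,
            window=fps[0].window,
        )


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise fingerprint distances with zero diagonal."""

    values: np.ndarray = field(repr=False)
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ShapeMismatchError("distance matrix must be square")
        if np.max(np.abs(d - d.T)) > 1e-12 or np.max(np.abs(np.diag(d))) > 1e-12:
            raise ShapeMismatchError("distance matrix must be symmetric, zero diagonal")
        object.__setattr__(self, "values", d)

    @property
    def n_trials(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class Projection:
    """Trials embedded via the leading eigenvectors of the distance matrix."""

    coords: np.ndarray = field(repr=False)  # (N_T, n) real
    eigenvalues: np.ndarray = field(repr=False)
    ordering: str = "modulus"

    @property
    def n_trials(self) -> int:
        return int(self.coords.shape[0])

    @property
    def n_dims(self) -> int:
        return int(self.coords.shape[1])


def _as_mu(obj) -> np.ndarray:
    return obj.mu if isinstance(obj, Fingerprint) else np.asarray(obj, dtype=complex)


def fingerprint_distance(a, b) -> float:
    """Euclidean distance between two fingerprints over complex components."""
    mu_a, mu_b = _as_mu(a), _as_mu(b)
    if mu_a.shape != mu_b.shape:
        raise ShapeMismatchError("fingerprints differ in length")
    return float(np.linalg.norm(mu_a - mu_b))


def distance_matrix(ensemble: TrialEnsemble) -> DistanceMatrix:
    """All pairwise fingerprint distances of an ensemble."""
    fps = ensemble.fingerprints
    real = np.hstack([fps.real, fps.imag])  # complex 2-norm == real 2-norm on [Re, Im]
    return DistanceMatrix(squareform(pdist(real)))


def _ordered_eig(d: np.ndarray, ordering: str):
    lam, vec = np.linalg.eigh(d)
    if ordering == "modulus":
        order = np.argsort(-np.abs(lam), kind="stable")
    elif ordering == "algebraic":
        order = np.argsort(-lam, kind="stable")
    else:
        raise ValueError(f"unknown eigenvalue ordering {ordering!r}")
    return lam[order], vec[:, order]


def eigen_projection(
    d: DistanceMatrix, n: int = 2, ordering: str = "modulus"
) -> Projection:
    """Embed trials as ``P = D @ [v_1 ... v_n]``.

    Eigenvectors are taken in descending order of eigenvalue modulus by
    default ("largest modulus" embedding); ``ordering="algebraic"`` sorts by
    signed value instead.  Column i of P equals ``lambda_i * v_i``, so the
    embedding weights each eigendirection by its eigenvalue.
    """
    n_t = d.n_trials
    if not (2 <= n <= n_t):
        raise InvalidDimensionError(f"embedding dimension {n} outside 2..{n_t}")
    lam, vec = _ordered_eig(d.values, ordering)
    coords = d.values @ vec[:, :n]
    return Projection(coords=coords, eigenvalues=lam[:n], ordering=ordering)


def _median_bandwidth(d: np.ndarray) -> float:
    off = d[~np.eye(d.shape[0], dtype=bool)]
    return float(np.median(off))


def spectral_cluster(d: DistanceMatrix, k_clusters: int, seed: int = 0) -> np.ndarray:
    """Normalized spectral clustering of trials from their distance matrix.

    Distances are converted to affinities with a Gaussian kernel whose
    bandwidth is the median off-diagonal distance, then clustered with
    standard normalized spectral clustering.  Labels are 0..k_clusters-1.
    """
    n_t = d.n_trials
    if not (2 <= k_clusters < n_t):
        raise InvalidDimensionError(f"k_clusters {k_clusters} outside 2..{n_t - 1}")
    sigma = _median_bandwidth(d.values)
    if sigma <= 0 or np.ptp(d.values[~np.eye(n_t, dtype=bool)]) == 0:
        warnings.warn(
            "degenerate distance matrix (all pairwise distances equal); "
            "returning an arbitrary balanced labeling",
            stacklevel=2,
        )
        return np.arange(n_t) % k_clusters
    affinity = np.exp(-(d.values**2) / (2.0 * sigma**2))
    model = SpectralClustering(
        n_clusters=k_clusters, affinity="precomputed", random_state=seed
    )
    return model.fit_predict(affinity)


def kmeans_cluster(p: Projection, k_clusters: int, seed: int = 0) -> np.ndarray:
    """K-means on the projection coordinates (seed-deterministic)."""
    if not (1 <= k_clusters <= p.n_trials):
        raise InvalidDimensionError("k_clusters outside 1..n_trials")
    model = KMeans(n_clusters=k_clusters, n_init=10, random_state=seed)
    return model.fit_predict(p.coords)


def cluster_distance_ratio(p: Projection, labels: np.ndarray) -> float:
    """Mean inter-centroid distance over mean point-to-own-centroid distance.

    Values well above one indicate separable clusters; values below one
    indicate clusters that substantially overlap.  If every point coincides
    (both spreads zero) the ratio is undefined and an error is raised; if
    only the within-cluster spread is zero the ratio is +inf with a warning.
    """
    labels = np.asarray(labels)
    if labels.size != p.n_trials:
        raise ShapeMismatchError("labels length != number of trials")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise DegenerateClustersError("need at least two clusters")
    centroids = np.array([p.coords[labels == c].mean(axis=0) for c in uniq])
    inter = float(np.mean(pdist(centroids)))
    intra = float(
        np.mean(
            np.concatenate(
                [
                    np.linalg.norm(p.coords[labels == c] - centroids[i], axis=1)
                    for i, c in enumerate(uniq)
                ]
            )
        )
    )
    if intra == 0.0:
        if inter == 0.0:
            raise DegenerateClustersError("all points coincide; ratio undefined (0/0)")
        warnings.warn("zero within-cluster spread; ratio is +inf", stacklevel=2)
        return float("inf")
    return inter / intra


@dataclass(frozen=True)
class DecodeResult:
    """Cross-validated decoding outcome."""

    accuracy: float
    fold_accuracies: np.ndarray
    k_folds: int
    seed: int
    method: str

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "accuracy": float(self.accuracy),
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "k_folds": int(self.k_folds),
            "seed": int(self.seed),
        }


def _check_stratifiable(labels: np.ndarray, k_folds: int) -> None:
    counts = pd.Series(labels).value_counts()
    if (counts < k_folds).any():
        small = counts[counts < k_folds]
        raise StratificationError(
            f"classes with fewer trials than folds ({k_folds}): {dict(small)}"
        )


def nearest_centroid_decode(
    p: Projection,
    labels: np.ndarray,
    k_folds: int = 10,
    seed: int = 0,
    refit_from: DistanceMatrix | None = None,
    n_dims: int | None = None,
    ordering: str = "modulus",
) -> DecodeResult:
    """Decode condition labels by nearest class centroid in the embedding.

    Stratified K-fold: per fold, class centroids are the mean projection
    coordinates of the training trials, and each test trial takes the label
    of its closest centroid.  With ``refit_from`` (the distance matrix), the
    embedding itself is recomputed per fold from training trials only and
    test trials are projected through their distances to the training set —
    the strict variant that avoids sharing embedding information across
    folds.
    """
    labels = np.asarray(labels)
    if labels.size != p.n_trials:
        raise ShapeMismatchError("labels length != number of trials")
    _check_stratifiable(labels, k_folds)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    uniq = np.unique(labels)
    fold_acc = []
    for train, test in skf.split(np.zeros(labels.size), labels):
        if refit_from is None:
            coords_train, coords_test = p.coords[train], p.coords[test]
        else:
            d_tt = refit_from.values[np.ix_(train, train)]
            lam, vec = _ordered_eig(d_tt, ordering)
            ndim = p.n_dims if n_dims is None else n_dims
            v = vec[:, :ndim]
            coords_train = d_tt @ v
            coords_test = refit_from.values[np.ix_(test, train)] @ v
        cents = np.array([coords_train[labels[train] == c].mean(axis=0) for c in uniq])
        dists = np.linalg.norm(coords_test[:, None, :] - cents[None, :, :], axis=2)
        pred = uniq[np.argmin(dists, axis=1)]
        fold_acc.append(float(np.mean(pred == labels[test])))
    fold_acc = np.asarray(fold_acc)
    return DecodeResult(
        accuracy=float(fold_acc.mean()),
        fold_accuracies=fold_acc,
        k_folds=int(k_folds),
        seed=int(seed),
        method="nearest_centroid",
    )


def svm_decode(
    ensemble: TrialEnsemble,
    helix_subset,
    k_folds: int = 10,
    seed: int = 0,
    c: float = 1.0,
) -> DecodeResult:
    """Linear-SVM decoding from the selected helix contributions.

    The feature vector of each trial concatenates the real and imaginary
    parts of the chosen helix contributions.  A maximum-margin linear
    classifier (C = 1 by default) is scored with stratified K-fold
    cross-validation.
    """
    helix_subset = np.asarray(helix_subset, dtype=int)
    if helix_subset.size == 0:
        raise ValueError("helix_subset must be non-empty")
    if ensemble.labels is None:
        raise ValueError("ensemble has no condition labels to decode")
    labels = np.asarray(ensemble.labels)
    if np.unique(labels).size < 2:
        raise ValueError("decoding needs at least two classes")
    _check_stratifiable(labels, k_folds)
    mu = ensemble.fingerprints[:, helix_subset - 1]
    features = np.hstack([mu.real, mu.imag])
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    scores = cross_val_score(
        SVC(kernel="linear", C=c), features, labels, cv=skf, scoring="accuracy"
    )
    return DecodeResult(
        accuracy=float(scores.mean()),
        fold_accuracies=np.asarray(scores),
        k_folds=int(k_folds),
        seed=int(seed),
        method="svm_linear",
    )
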