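"""Null-model significance for helix contributions and condition selectivity.

Two questions are answered here.  First, is a helix contribution larger than
expected from unstructured spiking?  The null model redraws every spike time
uniformly on [0, T) while keeping the observed spike counts — by default the
per-neuron counts, the stricter reading of "matched numbers of spikes and
neurons" — and a helix is flagged when its observed magnitude strictly
exceeds all ``n_null`` null magnitudes.  An add-one empirical p-value
``(1 + #{null >= obs}) / (n_null + 1)`` is reported alongside the flag.

Second, does a helix's contribution differ between trial conditions?  For
each condition we bootstrap the trial-mean contribution (a cloud of
``n_boot`` complex centroids); a helix is condition-selective when the
clouds' 2-D convex hulls are pairwise disjoint.  The hull criterion is a
parameter-free geometric operationalization of "non-overlapping centroid
sets"; a stricter quantile-ellipse variant is available.

No multiple-testing correction is applied across the N helices by default;
an optional Bonferroni flag adjusts the reported p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import MultiPoint, Polygon

from .errors import (
    DegeneratePatternError,
    InsufficientTrialsError,
    ShapeMismatchError,
)
from .transform import Fingerprint, _mu_from_sums
from .geometry import SpikePattern

__all__ = [
    "NullDistribution",
    "HelixSelectivity",
    "sample_null",
    "significant_helices",
    "condition_selective_helices",
    "rank_helices_for_decoding",
]


@dataclass(frozen=True)
class NullDistribution:
    """Magnitudes of helix contributions under matched random spiking.

    ``magnitudes[r, k-1]`` is ``|mu_k|`` of the r-th null pattern.  The seed
    is recorded so the distribution is reproducible.
    """

    magnitudes: np.ndarray = field(repr=False)
    n_neurons: int
    spike_counts: np.ndarray = field(repr=False)
    window: float
    seed: int
    match_per_neuron: bool = True

    @property
    def n_null(self) -> int:
        return int(self.magnitudes.shape[0])


def _batch_null_magnitudes(
    rng: np.random.Generator,
    n_null: int,
    n_neurons: int,
    counts: np.ndarray,
    match_per_neuron: bool,
) -> np.ndarray:
    """Vectorized: magnitudes of mu for n_null uniform-time random patterns."""
    m = int(counts.sum())
    theta = rng.uniform(0.0, 2.0 * np.pi, size=(n_null, m))
    phasors = np.exp(1j * theta)
    sums = np.zeros((n_null, n_neurons), dtype=complex)
    if match_per_neuron:
        ids = np.repeat(np.arange(n_neurons), counts)  # 0-based, fixed margins
        np.add.at(sums, (np.arange(n_null)[:, None], ids[None, :]), phasors)
    else:
        ids = rng.integers(0, n_neurons, size=(n_null, m))
        np.add.at(sums, (np.arange(n_null)[:, None], ids), phasors)
    return np.abs(_mu_from_sums(sums))


def sample_null(
    pattern: SpikePattern,
    n_null: int = 1000,
    seed: int = 0,
    match_per_neuron: bool = True,
) -> NullDistribution:
    """Null distribution of ``|mu_k|`` for random patterns matched to ``pattern``.

    Each null pattern keeps the observed per-neuron spike counts (or, with
    ``match_per_neuron=False``, only the total count, redrawing neuron IDs
    uniformly) and redraws every spike time i.i.d. uniform on [0, T).  Only
    phases matter for the transform, so times are drawn directly as phases.
    """
    if pattern.n_spikes == 0:
        raise DegeneratePatternError("cannot build a null for an empty pattern")
    if n_null < 1:
        raise ValueError(f"n_null must be >= 1, got {n_null}")
    counts = pattern.spike_counts()
    rng = np.random.default_rng(seed)
    mags = _batch_null_magnitudes(
        rng, int(n_null), pattern.n_neurons, counts, match_per_neuron
    )
    return NullDistribution(
        magnitudes=mags,
        n_neurons=pattern.n_neurons,
        spike_counts=counts,
        window=pattern.window,
        seed=int(seed),
        match_per_neuron=match_per_neuron,
    )


def significant_helices(
    fp: Fingerprint, null: NullDistribution, bonferroni: bool = False
) -> pd.DataFrame:
    """Flag helices whose magnitude strictly exceeds every null magnitude.

    Returns a DataFrame with one row per helix: ``helix``, ``magnitude``,
    ``p_value`` (add-one empirical), ``significant``.  With ``bonferroni``
    the p-values are multiplied by N (clipped at 1); the exceed-all flag is
    unchanged.
    """
    if null.n_neurons != fp.n_neurons:
        raise ShapeMismatchError(
            f"null built for N={null.n_neurons}, fingerprint has N={fp.n_neurons}"
        )
    obs = fp.magnitudes
    n_null = null.n_null
    n_ge = (null.magnitudes >= obs[None, :]).sum(axis=0)
    p = (1.0 + n_ge) / (n_null + 1.0)
    flag = (null.magnitudes < obs[None, :]).all(axis=0) & (obs > 0)
    if bonferroni:
        p = np.minimum(1.0, p * fp.n_neurons)
    return pd.DataFrame(
        {
            "helix": np.arange(1, fp.n_neurons + 1),
            "magnitude": obs,
            "p_value": p,
            "significant": flag,
        }
    )


@dataclass(frozen=True)
class HelixSelectivity:
    """Result of the bootstrap condition-selectivity test.

    ``clouds[c]`` is the (n_boot, N) complex array of bootstrapped per-helix
    centroid means for condition ``c``; ``selected`` lists the 1-based helix
    indices whose clouds are pairwise disjoint across conditions.
    """

    selected: np.ndarray
    clouds: dict = field(repr=False)
    n_boot: int
    seed: int

    def cloud(self, condition, k: int) -> np.ndarray:
        """Bootstrap centroid cloud of helix k (1-based) for one condition."""
        return self.clouds[condition][:, k - 1]


def _hull_polygon(points: np.ndarray):
    """Convex hull of 2-D points as a shapely geometry (handles degeneracy)."""
    if points.shape[0] >= 3:
        try:
            hull = ConvexHull(points)
            return Polygon(points[hull.vertices])
        except QhullError:
            pass  # collinear / coincident points
    return MultiPoint(points).convex_hull


def _clouds_disjoint(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff the convex hulls of two complex point clouds do not touch."""
    pa = np.column_stack([a.real, a.imag])
    pb = np.column_stack([b.real, b.imag])
    # cheap bounding-box reject before building hulls
    if (
        pa[:, 0].max() < pb[:, 0].min()
        or pb[:, 0].max() < pa[:, 0].min()
        or pa[:, 1].max() < pb[:, 1].min()
        or pb[:, 1].max() < pa[:, 1].min()
    ):
        return True
    return not _hull_polygon(pa).intersects(_hull_polygon(pb))


def condition_selective_helices(
    fingerprints,
    labels: np.ndarray | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> HelixSelectivity:
    """Helices whose bootstrapped condition centroids form disjoint clouds.

    Parameters
    ----------
    fingerprints
        (N_T, N) complex matrix of trial fingerprints.
    labels
        Condition label per trial (at least two distinct conditions, each
        with at least two trials; fewer than five trials per condition is
        allowed but warned about, as the bootstrap becomes coarse).

    A :class:`~spikehelix.embedding.TrialEnsemble` may be passed as the first
    argument instead, in which case its labels are used and ``labels`` may be
    omitted.
    """
    if hasattr(fingerprints, "fingerprints"):
        if labels is None:
            labels = fingerprints.labels
        fingerprints = fingerprints.fingerprints
    fingerprints = np.asarray(fingerprints, dtype=complex)
    labels = np.asarray(labels)
    if fingerprints.ndim != 2 or fingerprints.shape[0] != labels.size:
        raise ShapeMismatchError("fingerprints must be (n_trials, N) matching labels")
    conditions = list(pd.unique(labels))
    if len(conditions) < 2:
        raise InsufficientTrialsError("need at least two conditions")
    rng = np.random.default_rng(seed)
    clouds: dict = {}
    for c in conditions:
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise InsufficientTrialsError(
                f"condition {c!r} has {idx.size} trial(s); need >= 2"
            )
        if idx.size < 5:
            warnings.warn(
                f"condition {c!r} has only {idx.size} trials; bootstrap is coarse",
                stacklevel=2,
            )
        mu_c = fingerprints[idx]
        draws = rng.integers(0, idx.size, size=(n_boot, idx.size))
        clouds[c] = mu_c[draws].mean(axis=1)  # (n_boot, N)
    n = fingerprints.shape[1]
    selected = []
    for k in range(n):
        disjoint = all(
            _clouds_disjoint(clouds[a][:, k], clouds[b][:, k])
            for i, a in enumerate(conditions)
            for b in conditions[i + 1 :]
        )
        if disjoint:
            selected.append(k + 1)
    return HelixSelectivity(
        selected=np.asarray(selected, dtype=int),
        clouds=clouds,
        n_boot=int(n_boot),
        seed=int(seed),
    )


def rank_helices_for_decoding(
    fingerprints,
    labels: np.ndarray | None,
    n_keep: int,
    selectivity: HelixSelectivity | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Top condition-selective helices ranked by centroid-cloud separation.

    Selective helices are ordered by the minimum pairwise distance between
    their condition centroid-cloud means, descending — the most reliably
    separated helices first — and the first ``n_keep`` are returned.  If
    fewer helices are selective than requested, all of them are returned
    with a warning.
    """
    if n_keep < 0:
        raise ValueError("n_keep must be >= 0")
    if n_keep == 0:
        return np.asarray([], dtype=int)
    if selectivity is None:
        selectivity = condition_selective_helices(
            fingerprints, labels, n_boot=n_boot, seed=seed
        )
    conditions = list(selectivity.clouds)
    scores = []
    for k in selectivity.selected:
        means = [selectivity.clouds[c][:, k - 1].mean() for c in conditions]
        sep = min(
            abs(means[i] - means[j])
            for i in range(len(means))
            for j in range(i + 1, len(means))
        )
        scores.append(sep)
    order = np.argsort(scores)[::-1]
    ranked = selectivity.selected[order]
    if ranked.size < n_keep:
        warnings.warn(
            f"only {ranked.size} selective helices available, requested {n_keep}",
            stacklevel=2,
        )
        return ranked
    return ranked[:n_keep]
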