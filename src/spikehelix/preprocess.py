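"""Firing-rate event extraction and path-distance utilities.

For cortical recordings where single neurons emit bursts of spikes rather
than isolated, precisely timed spikes, the transform is applied to *spiking
events*: per neuron, the smoothed firing rate is estimated with a Gaussian
kernel and every contiguous epoch where the rate exceeds a fraction
(default 80%) of that neuron's in-window peak becomes one event, placed at
the epoch's temporal center.  The resulting event train flows into the
transform exactly like a spike pattern.

The path utilities support the error-prediction analysis: trials whose spike
patterns cluster with the "wrong" condition can be checked against behaviour
by comparing each misplaced trial's 2-D navigation path (discrete Fréchet
distance) with the paths of its predicted versus its true cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ShapeMismatchError
from .geometry import SpikePattern

__all__ = [
    "EventTrain",
    "Path2D",
    "extract_events",
    "discrete_frechet",
    "misplaced_trial_path_test",
    "MisplacedPathSummary",
]


@dataclass(frozen=True)
class EventTrain:
    """Centers of supra-threshold firing-rate epochs, one row per event."""

    times: np.ndarray
    neuron_ids: np.ndarray
    window: float
    n_neurons: int
    kernel_width: float
    threshold_fraction: float

    @property
    def n_events(self) -> int:
        return int(np.asarray(self.times).size)

    def to_spike_pattern(self) -> SpikePattern:
        """View the event centers as a spike pattern for the transform."""
        return SpikePattern(self.times, self.neuron_ids, self.window, self.n_neurons)


@dataclass(frozen=True)
class Path2D:
    """An ordered 2-D polyline (e.g. a navigation trajectory)."""

    vertices: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 2:
            raise ShapeMismatchError("a path needs >= 2 (x, y) vertices")
        if not np.all(np.isfinite(v)):
            raise ShapeMismatchError("path vertices must be finite")
        object.__setattr__(self, "vertices", v)

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])


def _neuron_events(
    times: np.ndarray,
    t0: float,
    t1: float,
    kernel_width: float,
    threshold_fraction: float,
    center: str,
    dt: float,
) -> np.ndarray:
    """Event centers for one neuron's spike times (may be empty)."""
    times = np.asarray(times, dtype=float)
    times = times[(times >= t0) & (times <= t1)]
    if times.size == 0:
        return np.empty(0)
    grid = np.arange(t0, t1 + dt / 2, dt)
    # Gaussian-kernel rate estimate on the grid (sum of kernels, one per spike)
    z = (grid[:, None] - times[None, :]) / kernel_width
    rate = np.exp(-0.5 * z**2).sum(axis=1)
    peak = rate.max()
    above = rate >= threshold_fraction * peak
    # contiguous supra-threshold runs
    edges = np.flatnonzero(np.diff(above.astype(int)))
    starts = list(edges[~above[edges]] + 1) if edges.size else []
    ends = list(edges[above[edges]]) if edges.size else []
    if above[0]:
        starts = [0] + starts
    if above[-1]:
        ends = ends + [above.size - 1]
    epochs = list(zip(starts, ends))
    # merge epochs separated by less than one kernel width (rate jitter)
    merged = [epochs[0]]
    for s, e in epochs[1:]:
        if grid[s] - grid[merged[-1][1]] < kernel_width:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    centers = []
    for s, e in merged:
        if center == "midpoint":
            centers.append(0.5 * (grid[s] + grid[e]))
        elif center == "argmax":
            centers.append(grid[s + int(np.argmax(rate[s : e + 1]))])
        else:
            raise ValueError(f"unknown center rule {center!r}")
    return np.asarray(centers)


def extract_events(
    spike_times_by_neuron,
    window,
    kernel_width: float = 0.05,
    threshold_fraction: float = 0.8,
    center: str = "midpoint",
    grid_step: float | None = None,
) -> EventTrain:
    """Extract per-neuron spiking events from raw spike times.

    Parameters
    ----------
    spike_times_by_neuron
        Sequence of per-neuron spike-time arrays (index i = neuron ID i+1).
        Neurons with no spikes yield no events.
    window
        ``(t0, t1)`` analysis window in seconds, or a scalar T for ``(0, T)``.
    kernel_width
        Standard deviation of the Gaussian smoothing kernel, seconds.
    threshold_fraction
        Fraction of each neuron's peak rate that defines an event epoch
        (in (0, 1]; 0.8 reproduces the 80%-of-peak rule).
    center
        ``"midpoint"`` of the supra-threshold epoch (default) or ``"argmax"``
        of the rate within it.

    Event times are reported relative to ``t0`` so the resulting train can be
    consumed directly as a spike pattern over ``[0, t1 - t0]``.
    """
    if not (0.0 < threshold_fraction <= 1.0):
        raise ValueError("threshold_fraction must be in (0, 1]")
    if kernel_width <= 0:
        raise ValueError("kernel_width must be > 0")
    t0, t1 = (0.0, float(window)) if np.isscalar(window) else map(float, window)
    if t1 <= t0:
        raise ValueError("window end must exceed window start")
    dt = kernel_width / 20.0 if grid_step is None else float(grid_step)
    all_times, all_ids = [], []
    for i, times in enumerate(spike_times_by_neuron):
        centers = _neuron_events(
            times, t0, t1, kernel_width, threshold_fraction, center, dt
        )
        all_times.append(centers - t0)
        all_ids.append(np.full(centers.size, i + 1, dtype=np.int64))
    times = np.concatenate(all_times) if all_times else np.empty(0)
    ids = np.concatenate(all_ids) if all_ids else np.empty(0, dtype=np.int64)
    # numerical guard: clip centers that round a hair outside the window
    times = np.clip(times, 0.0, t1 - t0)
    return EventTrain(
        times=times,
        neuron_ids=ids,
        window=t1 - t0,
        n_neurons=len(spike_times_by_neuron),
        kernel_width=kernel_width,
        threshold_fraction=threshold_fraction,
    )


def discrete_frechet(a: Path2D, b: Path2D) -> float:
    """Discrete Fréchet distance between two polylines.

    The minimal over all monotone couplings of the maximal vertex-pair
    distance, computed by the standard dynamic program over the coupling
    lattice.
    """
    pa, pb = a.vertices, b.vertices
    dist = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    na, nb = dist.shape
    ca = np.empty((na, nb))
    ca[0, 0] = dist[0, 0]
    for j in range(1, nb):
        ca[0, j] = max(ca[0, j - 1], dist[0, j])
    for i in range(1, na):
        ca[i, 0] = max(ca[i - 1, 0], dist[i, 0])
        for j in range(1, nb):
            ca[i, j] = max(
                min(ca[i - 1, j], ca[i - 1, j - 1], ca[i, j - 1]), dist[i, j]
            )
    return float(ca[-1, -1])


@dataclass(frozen=True)
class MisplacedPathSummary:
    """Path-similarity outcome for misclustered trials.

    ``mean_to_predicted`` / ``mean_to_true`` average, over misplaced trials,
    the mean Fréchet distance to correctly clustered paths of the predicted
    and the true cluster; ``p_value`` is the one-sided permutation p for the
    hypothesis that misplaced paths are closer to their predicted cluster.
    """

    trial_indices: np.ndarray
    to_predicted: np.ndarray
    to_true: np.ndarray
    mean_to_predicted: float
    mean_to_true: float
    statistic: float
    p_value: float
    n_permutations: int
    seed: int

    @property
    def n_misplaced(self) -> int:
        return int(self.trial_indices.size)


def misplaced_trial_path_test(
    predicted_labels,
    true_labels,
    paths,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> MisplacedPathSummary | None:
    """Are misclustered trials' paths more like their predicted cluster's paths?

    For each trial whose predicted cluster differs from its true condition,
    compute the mean Fréchet distance to the correctly clustered paths of
    (a) the predicted cluster and (b) the true cluster.  The statistic is the
    mean of (b) - (a) across misplaced trials (positive when paths resemble
    the predicted cluster).  Significance comes from a one-sided permutation
    test that shuffles the cluster labels of the comparison (correctly
    clustered) paths.

    Returns ``None`` when no trial is misclustered.
    """
    pred = np.asarray(predicted_labels)
    true = np.asarray(true_labels)
    if pred.size != true.size or pred.size != len(paths):
        raise ShapeMismatchError("labels and paths must have matching lengths")
    mis = np.flatnonzero(pred != true)
    if mis.size == 0:
        return None
    correct = np.flatnonzero(pred == true)
    for c in np.unique(np.concatenate([pred[mis], true[mis]])):
        if np.sum(true[correct] == c) < 2:
            raise ShapeMismatchError(
                f"cluster {c!r} has fewer than 2 correctly clustered trials"
            )
    # distances from each misplaced trial to every correctly clustered path
    dmat = np.array(
        [[discrete_frechet(paths[i], paths[j]) for j in correct] for i in mis]
    )
    ref_labels = true[correct]

    def stat(ref: np.ndarray):
        to_pred = np.array(
            [dmat[r, ref == pred[i]].mean() for r, i in enumerate(mis)]
        )
        to_true = np.array(
            [dmat[r, ref == true[i]].mean() for r, i in enumerate(mis)]
        )
        return to_pred, to_true, float(np.mean(to_true - to_pred))

    to_pred, to_true, observed = stat(ref_labels)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ref_labels)
        _, _, s = stat(perm)
        if s >= observed:
            n_ge += 1
    p = (1.0 + n_ge) / (n_permutations + 1.0)
    return MisplacedPathSummary(
        trial_indices=mis,
        to_predicted=to_pred,
        to_true=to_true,
        mean_to_predicted=float(to_pred.mean()),
        mean_to_true=float(to_true.mean()),
        statistic=observed,
        p_value=p,
        n_permutations=int(n_permutations),
        seed=int(seed),
    )
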