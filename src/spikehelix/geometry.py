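"""Cylindrical geometry for population spike patterns.

A *spike pattern* is the full set of (time, neuron ID) pairs emitted by a
population of N neurons inside an analysis window of length T seconds.  The
geometry used throughout the package maps each spike time to the unit circle
in the complex plane (a *phasor*), one circle per neuron, stacking the
circles into a cylinder of height N.  On that cylinder the natural "building
block" patterns are helices: one spike per neuron, at phases given by the
powers of an N-th root of unity.  The N helices are exactly the columns of a
(row/column-shifted) DFT matrix, which is what makes the downstream
decomposition invertible.

Conventions
-----------
* Neuron IDs are 1-based (``y in 1..N``); array code subtracts 1 internally.
* The phase of a spike at time t is ``theta = 2*pi*t/T`` by default.  An
  optional global ``phase_offset`` (e.g. ``-pi``) is supported; a global
  offset multiplies every transform component by a common unit factor and
  therefore changes no magnitude or pairwise distance.
* ``t = T`` is accepted and identified with ``t = 0`` (periodic window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InvalidHelixError,
    InvalidSizeError,
    InvalidWindowError,
    OutOfWindowError,
    ShapeMismatchError,
)

__all__ = [
    "SpikePattern",
    "PhasorPattern",
    "HelixBasis",
    "times_to_phasors",
    "build_helix_basis",
    "helix_as_pattern",
]

#: absolute tolerance for unit-modulus checks on phasors
PHASOR_ATOL = 1e-12


@dataclass(frozen=True)
class SpikePattern:
    """An ordered set of spikes over a population within a window.

    Parameters
    ----------
    times
        Spike times in seconds, each in ``[0, T]``.
    neuron_ids
        1-based neuron IDs in ``1..n_neurons``, one per spike.
    window
        Window length T in seconds (strictly positive).
    n_neurons
        Population size N.

    Spikes are stored sorted by time, ties broken by neuron ID.  The empty
    pattern (M = 0) is legal.
    """

    times: np.ndarray
    neuron_ids: np.ndarray
    window: float
    n_neurons: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.window) or self.window <= 0:
            raise InvalidWindowError(f"window length must be > 0, got {self.window!r}")
        if int(self.n_neurons) < 1:
            raise InvalidSizeError(f"n_neurons must be >= 1, got {self.n_neurons!r}")
        times = np.asarray(self.times, dtype=float).ravel()
        ids = np.asarray(self.neuron_ids, dtype=np.int64).ravel()
        if times.shape != ids.shape:
            raise ShapeMismatchError(
                f"times ({times.size}) and neuron_ids ({ids.size}) differ in length"
            )
        bad = np.flatnonzero((times < 0.0) | (times > self.window) | ~np.isfinite(times))
        if bad.size:
            j = int(bad[0])
            raise OutOfWindowError(
                f"spike {j} at t={times[j]!r} outside window [0, {self.window}]"
            )
        if ids.size and (ids.min() < 1 or ids.max() > self.n_neurons):
            off = ids[(ids < 1) | (ids > self.n_neurons)][0]
            raise InvalidSizeError(
                f"neuron id {off} outside 1..{self.n_neurons}"
            )
        order = np.lexsort((ids, times))  # stable: time, then neuron id
        object.__setattr__(self, "times", times[order])
        object.__setattr__(self, "neuron_ids", ids[order])
        object.__setattr__(self, "window", float(self.window))
        object.__setattr__(self, "n_neurons", int(self.n_neurons))

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def union(self, other: "SpikePattern") -> "SpikePattern":
        """Pointwise union of two patterns over the same population/window."""
        if other.n_neurons != self.n_neurons:
            raise ShapeMismatchError("patterns have different population sizes")
        if other.window != self.window:
            raise InvalidWindowError("patterns have different windows")
        return SpikePattern(
            np.concatenate([self.times, other.times]),
            np.concatenate([self.neuron_ids, other.neuron_ids]),
            self.window,
            self.n_neurons,
        )

    def spike_counts(self) -> np.ndarray:
        """Per-neuron spike counts, length ``n_neurons``."""
        return np.bincount(self.neuron_ids - 1, minlength=self.n_neurons)


@dataclass(frozen=True)
class PhasorPattern:
    """A spike pattern with times replaced by unit-modulus complex phasors."""

    phasors: np.ndarray
    neuron_ids: np.ndarray
    n_neurons: int
    window: float

    def __post_init__(self) -> None:
        phasors = np.asarray(self.phasors, dtype=complex).ravel()
        ids = np.asarray(self.neuron_ids, dtype=np.int64).ravel()
        if phasors.shape != ids.shape:
            raise ShapeMismatchError("phasors and neuron_ids differ in length")
        if phasors.size and np.max(np.abs(np.abs(phasors) - 1.0)) > PHASOR_ATOL:
            raise ShapeMismatchError("phasors must have unit modulus")
        object.__setattr__(self, "phasors", phasors)
        object.__setattr__(self, "neuron_ids", ids)

    @property
    def n_spikes(self) -> int:
        return int(self.phasors.size)


def times_to_phasors(pattern: SpikePattern, phase_offset: float = 0.0) -> PhasorPattern:
    """Map each spike time to the unit circle: ``x = exp(i*(2*pi*t/T + offset))``.

    ``t = 0`` and ``t = T`` map to the same phasor (periodic boundary).  The
    optional global phase offset rotates every phasor by the same angle and
    is irrelevant for magnitudes and distances.
    """
    theta = 2.0 * np.pi * pattern.times / pattern.window + phase_offset
    return PhasorPattern(
        np.exp(1j * theta), pattern.neuron_ids, pattern.n_neurons, pattern.window
    )


@dataclass(frozen=True)
class HelixBasis:
    """The N helices as columns of an N x N complex matrix H.

    ``H[j-1, k-1] = exp(-2j*pi*j*k/N)`` for 1-based neuron index j and helix
    index k.  H is a Vandermonde matrix of roots of unity with its rows and
    columns cyclically shifted so the ones sit in the last row/column; its
    inverse is ``H* / N`` (conjugate transpose over N).  Helix ``k = N`` is
    the constant (zero spatial frequency) sequence; ``k`` and ``N - k`` wind
    around the cylinder in opposite directions.
    """

    n_neurons: int
    matrix: np.ndarray = field(repr=False)

    def column(self, k: int) -> np.ndarray:
        """The k-th helix (1-based) as a length-N vector of phasors."""
        _check_helix_index(k, self.n_neurons)
        return self.matrix[:, k - 1]

    def inverse(self) -> np.ndarray:
        """Exact inverse ``H* / N``."""
        return self.matrix.conj().T / self.n_neurons


def _check_helix_index(k: int, n_neurons: int) -> None:
    if not (1 <= int(k) <= n_neurons):
        raise InvalidHelixError(f"helix index {k} outside 1..{n_neurons}")


def build_helix_basis(n_neurons: int) -> HelixBasis:
    """Construct the helix basis matrix for a population of ``n_neurons``."""
    n = int(n_neurons)
    if n < 1:
        raise InvalidSizeError(f"n_neurons must be >= 1, got {n_neurons!r}")
    j = np.arange(1, n + 1)
    matrix = np.exp(-2j * np.pi * np.outer(j, j) / n)
    return HelixBasis(n_neurons=n, matrix=matrix)


def helix_as_pattern(k: int, n_neurons: int, window: float = 1.0) -> SpikePattern:
    """The k-th helix realized as a spike pattern (one spike per neuron).

    Neuron j spikes at the time whose phasor equals ``omega_k**j`` with
    ``omega_k = exp(-2j*pi*k/N)``; the phase is normalized to ``[0, 2*pi)``
    and mapped back through ``t = T * phase / (2*pi)``.  For ``k = N`` all
    spikes land at ``t = 0`` (the constant helix).
    """
    n = int(n_neurons)
    if n < 1:
        raise InvalidSizeError(f"n_neurons must be >= 1, got {n_neurons!r}")
    _check_helix_index(k, n)
    j = np.arange(1, n + 1)
    phase = np.mod(-2.0 * np.pi * k * j / n, 2.0 * np.pi)
    times = window * phase / (2.0 * np.pi)
    return SpikePattern(times, j, window, n)
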