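"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from spikehelix.geometry import SpikePattern


def naive_contribution(pattern: SpikePattern, k: int) -> complex:
    """Literal spike-by-spike evaluation of the generalized inner product.

    Independent of the package's fast path: loops over spikes, maps each
    time to its phasor, and compares it against the conjugated helix element
    selected by the spike's neuron ID.
    """
    n = pattern.n_neurons
    total = 0.0 + 0.0j
    for t, y in zip(pattern.times, pattern.neuron_ids):
        x = np.exp(2j * np.pi * t / pattern.window)
        h_elem = np.exp(-2j * np.pi * k * y / n)
        total += x * np.conj(h_elem)
    return total / n


def naive_transform(pattern: SpikePattern) -> np.ndarray:
    """All N contributions via the literal double loop (vectorized over spikes)."""
    n = pattern.n_neurons
    x = np.exp(2j * np.pi * pattern.times / pattern.window)
    out = np.empty(n, dtype=complex)
    for k in range(1, n + 1):
        out[k - 1] = np.sum(x * np.exp(2j * np.pi * k * pattern.neuron_ids / n)) / n
    return out


def random_spike_pattern(
    rng: np.random.Generator,
    n_neurons: int | None = None,
    max_spikes: int = 60,
) -> SpikePattern:
    """A random test pattern with uneven per-neuron counts (may be empty)."""
    n = int(rng.integers(2, 40)) if n_neurons is None else n_neurons
    m = int(rng.integers(0, max_spikes))
    times = rng.uniform(0.0, 1.0, size=m)
    ids = rng.integers(1, n + 1, size=m)
    return SpikePattern(times, ids, 1.0, n)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)
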