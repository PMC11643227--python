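"""Seeded generators for synthetic spike patterns and trial ensembles.

Every input the package's demonstrations and tests need is generated here:
uniform-random background spiking with specified per-neuron counts, planted
helices (full, partial, phase-jittered, phase-shifted), the worked two-helix
union pattern, and multi-trial multi-condition ensembles in which each trial
is a random background plus a partial copy of its condition's helix.  All
generators are pure functions of their arguments and the seed: the same call
with the same seed is bit-identical.

Defaults emulate sparse cortical data at the scale the method is typically
demonstrated on: N = 100 neurons, a 1 s window, one background spike per
neuron per trial, and planted helices at fraction 0.5 — strong enough to be
individually detectable yet partial, the regime the decomposition is
designed for.
"""

from __future__ import annotations

import numpy as np

from .embedding import TrialEnsemble
from .errors import InvalidHelixError
from .geometry import SpikePattern, helix_as_pattern
from .transform import rotate_pattern

__all__ = [
    "random_pattern",
    "embed_helix",
    "two_helix_pattern",
    "three_condition_ensemble",
    "two_condition_ensemble",
]


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_pattern(
    n_neurons: int,
    counts=1,
    window: float = 1.0,
    seed=0,
) -> SpikePattern:
    """Background pattern: each neuron fires ``counts`` i.i.d. uniform spikes.

    ``counts`` may be a scalar (same count for every neuron) or a length-N
    array of per-neuron counts; zero counts give silent neurons and an
    all-zero ``counts`` gives the empty pattern.
    """
    rng = _rng(seed)
    counts = np.broadcast_to(np.asarray(counts, dtype=int), (n_neurons,))
    ids = np.repeat(np.arange(1, n_neurons + 1), counts)
    times = rng.uniform(0.0, window, size=ids.size)
    return SpikePattern(times, ids, window, n_neurons)


def embed_helix(
    pattern: SpikePattern,
    k: int,
    fraction: float = 1.0,
    jitter_sd: float = 0.0,
    sigma: float = 0.0,
    seed=0,
) -> SpikePattern:
    """Union a (possibly partial, jittered, shifted) copy of helix k into a pattern.

    A uniformly chosen subset of ``ceil(fraction * N)`` neurons each receive
    one extra spike at the helix-k phase of that neuron, rotated by ``sigma``
    and perturbed by wrapped-Gaussian angular jitter with standard deviation
    ``jitter_sd`` radians.  ``fraction = 0`` returns the pattern unchanged.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    n = pattern.n_neurons
    if not (1 <= int(k) <= n):
        raise InvalidHelixError(f"helix index {k} outside 1..{n}")
    n_sub = int(np.ceil(fraction * n))
    if n_sub == 0:
        return pattern
    rng = _rng(seed)
    neurons = rng.choice(np.arange(1, n + 1), size=n_sub, replace=False)
    phase = np.mod(-2.0 * np.pi * k * neurons / n + sigma, 2.0 * np.pi)
    if jitter_sd > 0:
        phase = np.mod(phase + rng.normal(0.0, jitter_sd, size=n_sub), 2.0 * np.pi)
    times = pattern.window * phase / (2.0 * np.pi)
    extra = SpikePattern(times, neurons, pattern.window, n)
    return pattern.union(extra)


def two_helix_pattern(
    n_neurons: int,
    sigma: float,
    window: float = 1.0,
    k_first: int = 2,
    k_second: int = 3,
) -> SpikePattern:
    """Union of helix ``k_first`` with a ``sigma``-rotated copy of ``k_second``.

    The canonical worked example: the transform of this 2N-spike pattern has
    unit magnitude at components ``k_first`` and ``k_second`` (the latter
    with phase ``sigma``) and zero everywhere else.
    """
    a = helix_as_pattern(k_first, n_neurons, window)
    b = rotate_pattern(helix_as_pattern(k_second, n_neurons, window), sigma)
    return a.union(b)


def _condition_ensemble(
    n_neurons: int,
    helices,
    n_trials_per: int,
    fraction: float,
    background_counts,
    jitter_sd: float,
    window: float,
    seed,
    return_patterns: bool,
):
    rng = _rng(seed)
    patterns, labels = [], []
    for c, k in enumerate(helices):
        for _ in range(n_trials_per):
            bg = random_pattern(n_neurons, background_counts, window, rng)
            patterns.append(
                embed_helix(bg, k, fraction=fraction, jitter_sd=jitter_sd, seed=rng)
            )
            labels.append(c)
    labels = np.asarray(labels)
    ensemble = TrialEnsemble.from_patterns(patterns, labels=labels)
    if return_patterns:
        return ensemble, patterns
    return ensemble


def three_condition_ensemble(
    n_neurons: int = 100,
    n_trials: int = 75,
    helices=(2, 5, 9),
    fraction: float = 0.5,
    background_counts=1,
    jitter_sd: float = 0.0,
    window: float = 1.0,
    seed=0,
    return_patterns: bool = False,
):
    """Three-condition ensemble: 75 trials, one partial planted helix each.

    ``n_trials`` is split evenly over the three conditions (25/25/25 by
    default); each trial is a fresh uniform background with a partial copy of
    its condition's helix embedded.  Returns a labelled
    :class:`~spikehelix.embedding.TrialEnsemble` (and the raw patterns too
    when ``return_patterns`` is set).
    """
    if len(helices) != 3:
        raise ValueError("three_condition_ensemble needs exactly 3 helices")
    if n_trials % 3:
        raise ValueError("n_trials must divide evenly over 3 conditions")
    return _condition_ensemble(
        n_neurons,
        helices,
        n_trials // 3,
        fraction,
        background_counts,
        jitter_sd,
        window,
        seed,
        return_patterns,
    )


def two_condition_ensemble(
    n_neurons: int = 100,
    n_trials_per: int = 25,
    helices=(2, 8),
    fraction: float = 0.6,
    background_counts=1,
    jitter_sd: float = 0.0,
    window: float = 1.0,
    seed=0,
    return_patterns: bool = False,
):
    """Two-condition ensemble with one planted partial helix per condition.

    A synthetic stand-in for a two-perturbation motor experiment: condition 0
    trials carry helix ``helices[0]``, condition 1 trials carry
    ``helices[1]``, both embedded at ``fraction`` into uniform background
    spiking.  Used to exercise helix ranking and SVM decoding end to end.
    """
    if len(helices) != 2:
        raise ValueError("two_condition_ensemble needs exactly 2 helices")
    return _condition_ensemble(
        n_neurons,
        helices,
        n_trials_per,
        fraction,
        background_counts,
        jitter_sd,
        window,
        seed,
        return_patterns,
    )
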