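# spikehelix

A multi-sample **Discrete Helix Transform (ms-DHT)** for population spike
patterns, with the significance testing, distance geometry, clustering, and
trial decoding needed to use it on multi-trial experiments.

## The problem

Modern probes record spikes from hundreds to thousands of neurons at once.
A *spike pattern* — the full set of (spike time, neuron ID) pairs emitted by
a population in a window `[0, T]` — has a different number of spikes `M` on
every trial, so the ordinary inner product (and with it, every standard
decomposition) does not apply: you cannot compare vectors of different
lengths element by element. The usual escapes (smoothing spikes into rates,
or keeping one spike per neuron) throw away exactly the fine temporal
structure one might want to study.

## The method

Map each spike time to a *phasor* on the unit circle, `x_j = e^{2πi t_j/T}`,
and stack one circle per neuron into a cylinder of height `N`. The natural
building blocks on the cylinder are **helices**: one spike per neuron at
phases given by powers of a root of unity, `h⃗_k = (ω_k, ω_k², …, ω_k^N)`
with `ω_k = e^{−2πik/N}` — the columns of a (shifted) DFT matrix `H`.

The **generalized inner product** walks spike by spike and uses each spike's
neuron ID to pick the helix element it is compared against:

    μ_k = (1/N) Σ_{j=1}^{M} x_j · h⃗_k[y_j]*

This works for *any* number of spikes per neuron. The vector
`μ⃗ = Ψ_H(s) ∈ C^N` of all contributions is the pattern's **fingerprint**:
`|μ_k| = 1` exactly when one clean copy of helix k is present, and
`Arg μ_k` is its time shift. The transform is linear over pattern union,
invertible down to per-neuron phasor sums (`s̃ = H μ⃗`, unique up to
origin-centered phasor polygons), and pairwise fingerprint distances are
invariant under a common relabeling of the neurons.

Downstream, the package provides a matched-count null model for flagging
significant helices, bootstrapped condition-selectivity of helix
contributions, Euclidean fingerprint distances, eigen-embedding of the trial
distance matrix (`P = D·[v⃗_1 … v⃗_n]`), spectral/K-means clustering, a
cluster distance ratio, nearest-centroid and linear-SVM decoders, an
80%-of-peak-rate event extractor for burst-like units, and discrete Fréchet
comparison of behavioral paths.

## Worked example

```python
import numpy as np
import spikehelix as sh
from spikehelix.synthetic import two_helix_pattern

# union of helix 2 with a pi/3-shifted copy of helix 3, N = 100 neurons
pattern = two_helix_pattern(100, sigma=np.pi / 3)
fp = sh.ms_dht(pattern)
print(round(abs(fp.component(2)), 6), round(abs(fp.component(3)), 6))
print(round(np.angle(fp.component(3)), 6))
print(f"{np.delete(fp.magnitudes, [1, 2]).max():.2e}")
```

prints

```
1.0 1.0
1.047198
2.51e-16
```

Both embedded helices are detected with magnitude exactly 1, the phase of
component 3 reads out the applied shift (`π/3 ≈ 1.047198`), and every other
component is zero to machine precision — the decomposition separates
overlapping sequences cleanly.

The same pipeline is available from the shell:

```sh
spikehelix simulate --fixture three-condition --seed 4 --out spikes.csv --manifest m.json
spikehelix cluster --in spikes.csv -k 3 --out-prefix run
```

which clusters 75 synthetic trials (three conditions, one partial planted
helix each) and reports the cluster distance ratio.

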