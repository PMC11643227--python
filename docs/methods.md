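# Methods

## Model

A spike pattern is a finite subset of `S¹ × {1, …, N}`: each spike is a
unit-modulus phasor `x_j = e^{iθ_j}` with `θ_j = 2π t_j / T`, attached to a
1-based neuron ID `y_j`. The analysis window is periodic — `t = 0` and
`t = T` are the same phase — so the transform is designed for windows in
which the pattern of interest may appear at any circular shift. Patterns of
any size are legal, including the empty pattern.

The helix basis is the `N × N` matrix `H[j,k] = e^{−2πi jk/N}` (1-based
`j, k`), a Vandermonde matrix of roots of unity with rows and columns
cyclically shifted; `H⁻¹ = H*/N` exactly. Helix `k = N` is the constant
sequence; helices `k` and `N − k` are complex conjugates and wind around the
cylinder in opposite directions.

The generalized inner product `μ_k = (1/N) Σ_j x_j · conj(H[y_j, k])` is a
sum over spikes, not vector components, which is what removes every
restriction on spikes-per-neuron. Its key algebra, all verified to 1e-10 in
the test suite:

* linearity over pattern union;
* `Ψ(helix k) = e⃗_k` exactly; rotating all phasors by σ multiplies `Ψ` by
  `e^{iσ}`;
* `‖Ψ(s)‖² = ‖s̃‖²/N` where `s̃` holds per-neuron phasor sums, and
  `s̃ = H Ψ(s)` — the transform is an isomorphism on phasor sums, so two
  patterns share a fingerprint iff their per-neuron sums agree (they can
  differ only by origin-centered phasor polygons within single neurons);
* pairwise fingerprint distances are invariant under a common permutation of
  neuron IDs (individual fingerprints are not).

**Phase convention.** `θ = 2π t/T` with no global offset. A global offset
(e.g. `−π`, which some formulations use) multiplies every `μ_k` by one unit
complex factor and changes no magnitude, phase *difference*, or distance; a
`phase_offset` argument is provided for exact emulation.

**Normalization.** The `1/N` normalization means `|μ_k|` may exceed 1 when a
helix repeats within a pattern (`|μ_k| ≤ M/N` always). Values are reported
as-is, never clipped.

**Fast path.** `Ψ` is computed by accumulating `s̃` in `O(M)` and evaluating
one length-N inverse DFT with an index-shift twiddle. Tests pin it to the
literal spike-by-spike sum up to `N = 2048, M = 10N` at 1e-10.

## Significance of single-pattern contributions

The null model redraws each spike's phase i.i.d. uniform on the circle while
keeping the observed per-neuron spike counts (matching both margins — the
stricter reading of "matched numbers of spikes and neurons"; a
total-count-only variant redraws neuron IDs too). A helix is flagged when
its observed `|μ_k|` strictly exceeds all `n_null = 1000` null magnitudes;
the add-one empirical p-value `(1 + #{null ≥ obs})/(n_null + 1)` is reported
alongside. Under the null the flag fires at rate `1/(n_null+1)` per helix by
exchangeability — the calibration test verifies this over 200 runs. No
multiple-testing correction across the N helices is applied by default
(optional Bonferroni flag), matching how the flag is meant to be read: a
per-helix exceedance marker, not a familywise claim.

## Condition selectivity and helix ranking

Per condition, the trial-mean of `μ_k` is bootstrapped (1000 resamples of
trials with replacement), giving a cloud of complex centroids per helix and
condition. A helix is condition-selective when the 2-D convex hulls of its
clouds are pairwise disjoint. The hull rule is a deliberate, parameter-free
operationalization of "non-overlapping centroid sets"; it is conservative
(hulls grow with n_boot) and a quantile-ellipse variant would be stricter.
For decoding, selective helices are ranked by the minimum pairwise distance
between their condition cloud means, descending — a documented proxy for
"most reliably occurring, selective" since no sharper criterion is defined.

## Embedding, clustering, decoding

Trial distances are plain Euclidean norms between fingerprints. The trial
distance matrix `D` is symmetric, nonnegative, and indefinite; eigenvectors
are ordered by *modulus* of eigenvalue by default (algebraic ordering behind
a flag — with mixed-sign spectra the two differ) and trials are embedded as
`P = D[v⃗_1 … v⃗_n]`, i.e. column i is `λ_i v⃗_i`.

Because `D` is entrywise nonnegative, its leading eigenvector is a
near-constant Perron-like direction carrying bulk scale, not contrast.
Cluster contrasts live in the next eigendirections, so separating `k`
conditions needs `k` embedding dimensions (1 bulk + k−1 contrasts); the
package defaults to `n = 2` for visualization but the decoding analyses of
three-condition ensembles use `n = 3`. This follows from the closed-form
eigenstructure of a block distance matrix, and the exact-block test case
exercises it.

Spectral clustering uses a Gaussian affinity `exp(−d²/2σ²)` with σ = median
off-diagonal distance (the method's own choice; only the clustering family
is prescribed). The cluster distance ratio is mean inter-centroid distance
over mean point-to-own-centroid distance; below 1 means overlapping
clusters. Nearest-centroid decoding is stratified 10-fold on the projection
coordinates. By default the projection is computed once from **all** trials
before folding — mirroring the embed-then-fold workflow this analysis
replicates, and documented as mild information sharing; a strict mode refits
the eigenbasis per fold from the training submatrix and projects test trials
through their distances to the training set. SVM decoding uses a linear
kernel, `C = 1`, on concatenated real and imaginary parts of the selected
helix contributions, stratified 10-fold.

## Event extraction and paths

For burst-firing units, events are extracted per neuron from a Gaussian
kernel rate estimate (SD 50 ms by default — the smoothing underlying the
original rule is not restated anywhere, so this is a declared default, fully
configurable). A contiguous epoch where the rate is at least
`threshold_fraction` (default 0.8) of that neuron's in-window peak becomes
one event at the epoch midpoint (argmax variant by flag); epochs separated
by less than one kernel width are merged to suppress ripple splitting. The
rate grid step is kernel_width/20.

*Limitation:* epoch-count monotonicity in the threshold holds only for
bursts separated by silence deeper than the threshold range. Overlapping
bursts merge into one epoch at low thresholds and resolve into several at
high thresholds, so raising the threshold can increase the count — an
intrinsic property of any epoch-based rule, not an implementation artifact.
The monotonicity tests therefore use resolvable bursts, the regime the
80%-of-peak rule is intended for.

The discrete Fréchet distance is the textbook dynamic program over vertex
couplings, validated in tests against brute-force coupling enumeration. The
misplaced-trial path test compares, for each trial clustered away from its
true condition, mean Fréchet distance to correctly clustered paths of the
predicted versus the true cluster, with a one-sided permutation test
(default 10,000 shuffles of the comparison paths' cluster labels).

## Synthetic generators

The generators define the study conditions for every demonstration:

* background: each neuron fires its specified count of i.i.d. uniform spikes
  (default 1 spike/neuron — sparse-regime spiking where single embedded
  sequences remain individually visible);
* planted helices: `⌈fraction·N⌉` neurons (sampled uniformly without
  replacement, per trial) each get one extra spike at the helix phase,
  optionally shifted by σ and jittered by wrapped-Gaussian angular noise
  (SD in radians; the jitter distribution is a package choice — only
  "noisy" is prescribed);
* the two-helix worked fixture: helix 2 ∪ σ-rotated helix 3;
* the three-condition ensemble: 75 trials, 25 per condition, helices
  (2, 5, 9), fraction 0.5, N = 100 — fraction and density chosen to visually
  and statistically match the sparse demonstration regime (partial helices
  well above the uniform-background noise floor `≈ √(πM)/2N ≈ 0.13` yet far
  from complete);
* the two-condition ensemble: helices (2, 8) at fraction 0.6, the synthetic
  stand-in for a two-perturbation motor experiment.

All generators are pure functions of (parameters, seed).

What the generators do *not* emulate: refractory periods, rate
nonstationarity, correlated (non-uniform) background noise, electrode drift,
or sorting errors. Passing tests show the machinery is correct and
calibrated under matched-count uniform noise; they do not certify detection
performance on real recordings, whose noise is structured.

## Problem sizes and numerical choices

The validation suites run at the scale the demonstrations use: N = 100
neurons, 75-trial ensembles, 1000-replicate nulls, 200-run calibrations,
and a single N = 2048 / M = 20480 equivalence check — sizes at which every
quantity is stable yet the whole suite completes in well under a minute of
compute. Complex comparisons use absolute tolerance 1e-10 (1e-12 for
unit-modulus checks); ties in spike ordering are broken by neuron ID
(ordering never affects Ψ, which is a sum); eigen-ordering ties keep a
stable sort; K-means uses 10 restarts with a fixed seed; the degenerate
all-equal distance matrix returns an arbitrary balanced labeling with a
warning rather than failing.

## Known limitations

* The transform identifies patterns only up to per-neuron origin-centered
  phasor polygons — by design, but it means antipodal spike pairs within a
  neuron are invisible.
* The hull-based selectivity rule has no significance level; it is a
  geometric criterion whose strictness scales with n_boot.
* Spike attribution (the phase-cone rule, default half-angle π/4) is a
  formalization of a procedure that is otherwise only shown graphically;
  with uniformly spread off-target terms, a cone of half-angle δ admits a
  fraction ≈ δ/π of them, so exact attribution claims require δ smaller
  than the term spacing 2π/N.
* Real-data decoding accuracies depend on recordings that are not part of
  this package; the synthetic analogues demonstrate the pipeline, not the
  biology.
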