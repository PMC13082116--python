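# Methods

## The model

A structural connectome is a weighted, undirected graph: `C` is an
N×N nonnegative matrix of connection strengths (tractography streamline
densities in arbitrary units), and `d` the matching matrix of
fibre-tract distances in mm.  Signals are assumed to propagate along
edges with a single global conduction delay `T` (default 10 ms, the
mean tract delay; it is a physical constant of the model, not a fitted
parameter).  A walk of length k then accumulates phase `k·ω·T` at
angular frequency ω and weight equal to the product of its edge
weights.  Summing over all walks gives the network transfer function

    H(ω) = Σ_k (e^{iωT} C)^k = (I − e^{iωT} C)^{-1},

the resolvent of the delay-phased weight matrix.  The series converges
iff the spectral radius ρ(C) < 1; on load every weight matrix is
divided by `1.01 × max |eigenvalue|` whenever its radius is not already
sub-unity (the safety factor is configurable).  This places every
connectome at ρ(C) ≈ 0.9901 — deliberately near-critical, which is what
gives the low-frequency resolvent its long-range structure.

`H = I + iQ` splits into the integrative channel I (in-phase
accumulation across walks) and the routing channel Q (phase-shifted,
direction-sensitive contributions).  All downstream statistics are
functions of these two real fields.

Frequency convention (the most error-prone point of the whole code
base): analysis grids are in Hz; the hop phase is `ωT = 2π f T` with T
in seconds.  The default grid is 1–45 Hz in 0.5 Hz steps (89 points).

## Dressed resolvent

Local population dynamics enter through a damped-harmonic-oscillator
gain

    l(ω) = ω0² / (ω0² − ω² + 2 i ζ ω0 ω)

with natural frequency ω0 (Hz) and damping ratio ζ — two parameters for
the whole network.  Because l depends only on ω/ω0 and ζ, it is
evaluated directly on the Hz grid.  Two conventions for combining l
with the network are implemented and always recorded in results:

* `literal` (default of `dressed_resolvent`):
  `H₂ = (l·I − l·e^{iωT} C)^{-1}`, which algebraically equals
  `l^{-1}·H_bare` — a per-frequency complex rescaling of the bare
  resolvent.  Its zero-coupling limit is `l^{-1}·I`.
* `gain_outside`: `H₂ = l·(I − l·e^{iωT} C)^{-1}`, the resummation of
  walks in which every hop passes through the node gain
  (`Σ l^{k+1}(e^{iωT}C)^k`).  Here the dressing genuinely reshapes the
  network structure, amplifying low-frequency routing and sharpening
  the I/Q transition.

The parameter fit defaults to `gain_outside` because under the literal
reading the dressing never changes the relative spatial structure at a
fixed frequency, which makes it a degenerate target for spatialised
objectives; every `FitResult` records which reading produced it.  The
heterogeneous variant replaces the scalar l by a diagonal matrix of
group-specific gains (groups = weighted-degree tertiles; hubs first in
the coordinate-descent order).

## Channel statistics

For a transfer field (model resolvent or empirical coherency) and a
distance matrix, the upper-triangle pairs are:

* binned into 20 equal-width distance bins (half-open `[lo, hi)`, last
  bin closed; zero-distance pairs excluded and counted; empty bins kept
  as NaN with zero counts) — 15 bins by Euclidean distance is the
  variant for electrode-level data;
* rank-correlated against distance per frequency (Spearman, midranks);
* summarised by the Q-crossover — the first positive-to-negative sign
  change of ρ(Q, d) over the grid, localised by linear interpolation
  between the bracketing grid points (a 0.5 Hz grid cannot otherwise
  express the printed precision of crossover estimates); by the channel
  divergence `D(ω) = ρ(Q,d) − ρ(I,d)` and its minimiser ω_c (ties to
  the lowest frequency); and by the salience
  `S(ω) = var_pairs I + var_pairs Q`.

Five parameter-free predictions are scored:
C1 — ρ(Q, d) > 0 at every frequency below the crossover (permutation
p-value attached: distances shuffled, 1000 draws by default, seeded;
the statistic is the mean sub-crossover ρ);
C2 — a crossover exists within 8–16 Hz;
C3 — the band-averaged binned I at the bin containing 80 mm is positive
in every canonical band (delta 1–4, theta 4–8, alpha 8–13, beta 13–30,
gamma 30–45 Hz);
C4 — the alpha-band binned Q profile has a negative trough (both the
binned minimum and the alpha mean are reported, as the two defensible
readings of "trough magnitude");
C5 — the normalised salience profile is non-trivially structured,
operationalised as coefficient of variation > 0.1 (flagged in every
report as an interpretation).

Model-side Q statistics use signed Im H; empirical coherency defaults
to |Im C| (the signed variant is always co-reported).  Whether C1 uses
the full distance range or a minimum-distance threshold is
configurable; the default is the full range.

## Eigenmodel

The graph Laplacian defaults to the normalised form
`I − D^{-1/2} C D^{-1/2}` (spectrum in [0, 2] regardless of weight
scale, hence comparable across parcellations; the combinatorial form is
available).  Modes are projected through quadratic forms
`p_m(f) = v_mᵀ I(f) v_m`; the per-mode peak frequency maximises the
*relative share* `|p_m| / Σ|p_m'|` because the raw projections decay
with frequency for every mode, which would pin every peak to the grid
minimum.  The eigenmodel correlation is the Spearman ρ between
Laplacian eigenvalue and peak frequency, excluding the λ = 0 constant
mode.  Cumulative mode variance at (k, f) is the Frobenius-energy
fraction of the diagonal-zeroed I(f) captured by its expansion
restricted to the k lowest-λ modes.  Hub-mode participation is the
absolute component of the dominant eigenvector of C (for symmetric C
this is the resolvent's dominant mode at every frequency), rank
correlated with weighted degree; the permutation p-value is exact-style
(10⁴ seeded resamples) for N ≤ 30 and asymptotic otherwise.

## Spectral estimation

Welch cross-spectra use 2,048-sample segments, 50 % overlap and a Hann
window by default, computed jointly for all channel pairs from one set
of segment FFTs with the `S_ij = E[conj(X_i) X_j]` convention (matches
`scipy.signal.csd` to rounding).  At fs = 1024 Hz these settings give
exactly the 0.5 Hz analysis resolution; for any other rate the FFT grid
is mapped to the analysis grid by nearest bin and the worst-case
mapping error is recorded in the result metadata.  Per-segment
detrending is constant (the common default).  Complex coherency is
`S_ij/√(S_ii S_jj)`; unit diagonal, |C| ≤ 1 and conjugate symmetry are
enforced invariants of the estimator output.

Two spectral-matrix metrics are provided as explicitly labelled
interpretations (no literature-standard definition exists): the
dominance ratio σ1/σ2 of the off-diagonal-retained matrix at a
frequency (∞ when rank deficient; 1 for the degenerate all-zero case),
and a communication dimensionality defined as the participation ratio
`(Σσ)²/Σσ²` of the stacked I/Q pair-profile matrix over a band — two
proportional channel profiles give 1, orthogonal equal-norm profiles
give 2.

## Synthetic data

The generator emulates the statistical regularities of consensus
tractography that the analysis relies on, at desk scale:

* `ring` — nodes on a circle of 140 mm diameter with exponentially
  distance-decayed weights: circulant, Fourier-mode Laplacian,
  analytically transparent.  Used where spectral transparency matters.
* `box3d` — nodes scattered in a 140×112×84 mm box with three weight
  tiers: a local tier `w_local·exp(−d/25 mm)` truncated at 35 mm
  (U-fibres); a bilateral hub dyad at opposite ends of the long axis
  joined by a strong corridor (`corridor_weight = 8` before
  normalisation — the rich-club bridge), with every node attached to
  its nearest hub at `spoke_weight = 0.5`; and a sparse long-range tier
  in which pairs beyond 70 mm receive a direct, non-distance-decayed
  fibre of weight 0.4 with probability 0.2 (major fasciculi).
  Lognormal multiplicative noise (log-sd 0.3) mimics streamline-count
  dispersion.  Node order follows a greedy nearest-neighbour chain so
  that contiguous index blocks are spatial neighbourhoods, which keeps
  block coarse-graining meaningful.

These defaults were chosen because this is the only desk-scale
architecture (of many explored: homogeneous rings and disc graphs,
mirrored hemispheres with homotopic edges, distributed-affiliation hub
sets) that reproduces the qualitative channel phenomenology under the
fixed conditions T = 10 ms and near-critical normalisation: positive
ρ(Q, d) at low frequency, a sign change in or near the alpha band
(≈ 9–11 Hz across seeds at N = 64), and a deepening negative
correlation above.  Homogeneous geometries provably cannot produce the
positive limb: for translation-invariant nonnegative coupling, Im H is
a positive-coefficient cosine transform that peaks at zero distance, so
ρ(Q, d) is negative at every frequency.  The load-bearing ingredients
are the near-critical hub corridor (whose resonant phase advances the
sign flip of multi-hop routes into the alpha range) and the sparse
strong long-range tier (which gives distant pairs amplitude parity with
near pairs at low frequency).

What the generator does *not* emulate: hemispheric parcellation
asymmetries, heavy-tailed degree distributions beyond the dyad,
distance-dependent delays, and — importantly — the re-sparsification
that real consensus pipelines apply at every parcellation scale.
Passing tests on these fixtures therefore validate the machinery and
the qualitative mechanism, not quantitative agreement with any real
connectome.

`make_timeseries` realises the resolvent as the generating filter:
per-node white noise is multiplied bin-wise by H(f) in the Fourier
domain (computed per rfft bin through the eigendecomposition of the
symmetric weight matrix) and inverse-transformed.  A consequence worth
stating explicitly: for symmetric C and equal white noise drives the
implied cross-spectrum `conj(H)Hᵀ` is purely real, so the imaginary
coherency of such series is pure estimator noise.  Model/data
convergence checks therefore use the real (I) channel; a nonzero
empirical Q-channel requires directed coupling or heterogeneous noise,
which is precisely why the empirical Q statistics on real recordings
carry information the symmetric linear surrogate cannot fake.

## Wilson–Cowan negative control

The two-population rate model with logistic activation is integrated by
Euler–Maruyama at 0.1 ms steps; coupling `G·C` enters the excitatory
input; a sinusoidal drive targets a configurable node set; input noise
is Gaussian per step.  Couplings are the canonical set c1=16, c2=12,
c3=15, c4=3 with sigmoid gains 1.3/2.0 and thresholds 4.0/3.7; the
background drive (0.95) is set just below the oscillatory instability
so an isolated unit has a stable fixed point and noise drives damped
oscillations — this also pins the G = 0 limit used as an integration
oracle.  Rates stay inside (0, 1) by construction of the bounded
activation.  The sweep covers 8 drive frequencies (2–40 Hz,
band-representative) × 6 spatial input configurations (single hub,
single peripheral node, all nodes, random 10 %, top-degree 10 %,
bottom-degree 10 %) × 3 couplings {0.2, 0.5, 1.0} = 144 conditions;
per condition the simulated coherency's Re / |Im| pair profiles are
Spearman-correlated against the resolvent's I / Q profiles at the grid
frequency nearest the drive.  The negative-control claim is robustness
of near-zero correlation across this neighbourhood, not a value at one
parameter point.  Simulated series are block-averaged to 1000 Hz before
Welch estimation.  Default duration is 10 s per condition; the test
suite and acceptance script use 1–1.5 s (with proportionally shorter
Welch segments), which changes estimator variance but not the
structure of the comparison.

## Fitting

The objective is the Spearman correlation between model and target
concatenated distance-binned I and |Q| profiles across bins × grid
frequencies (band-restricted and I-only variants available; every
result names its variant).  The homogeneous search is exhaustive over
ω0 ∈ [5, 16] Hz in 0.5 Hz steps × ζ ∈ [0.05, 1.0] in 0.05 steps
(460 cells), ties resolving to the lowest ω0 then ζ; a flat surface is
flagged low-confidence.  Leave-one-dataset-out fits on the element-wise
mean profile of the remaining datasets and evaluates on the held-out
profile, which the search never sees.  The heterogeneous fit runs
cyclic coordinate descent over degree groups (descending mean degree),
3 cycles, initialised at the homogeneous optimum; since the homogeneous
solution lies in the feasible set, the in-sample objective can only
improve.  A practical caveat measured on the fixtures: the rank-based
objective is sensitive to noise wherever profile entries are nearly
tied, so absolute ρ values degrade quickly with bin-level noise even
when the recovered parameters remain within one grid cell.

## Numerical choices

* Resolvent production path: one batched LU solve against the identity
  per frequency (never explicit inversion, never series truncation);
  contract with explicit inversion is 1e−12 elementwise, and with the
  truncated walk enumeration the analytic geometric tail bound.
* The truncation oracle picks K from `ρ^{K+1}/(1−ρ) ≤ 1e−10`, capped
  at 10,000.
* Degenerate rank cases (constant channels) return NaN rather than
  raising, except where fewer than 3 pairs remain (error).
* Dressed-series interpretability: when `|l(ω)|·ρ(C) ≥ 1` anywhere on
  the grid a warning names the worst frequency; the inverse is still
  computed when it exists.
* All randomness flows through `numpy.random.default_rng` with
  explicit seeds; fixture sizes in tests (N = 10–64, durations 1–600 s)
  were chosen so the full suite exercises every advertised property at
  interactive speeds.

## Known limitations

* The channel crossover of the box3d fixture is resolution-dependent:
  block-sum coarse-graining densifies the sparse long-range tier (a
  merged pair of k² node pairs carries an edge with probability
  1−(1−p)^{k²}), inflating long-range connectivity relative to the hub
  corridor and washing out the crossover on the merged graph.  Real
  parcellation pipelines re-sparsify by consensus thresholding, which
  the deliberately literal block merge here does not emulate, so the
  parcellation-invariance property holds only in architectures without
  the sparse tier — where, in turn, the crossover exists for only a
  fraction of seeds.  The invariance check is therefore expected to
  fail at the shipped defaults; the mechanism is understood and
  documented rather than patched around.
* The hub-participation correlation on the synthetic dyad is positive
  (the dominant mode loads on the hubs themselves, as in a star graph),
  the opposite sign of what heterogeneous real connectomes show; the
  sign is reported, not asserted.
* Linear, steady-state, single-delay description throughout; no
  nonlinear or time-varying extensions.
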