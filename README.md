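# walksum

Walk-sum resolvent analysis of frequency-dependent communication on
structural connectomes.

## The problem

Brain electrophysiology organises into canonical frequency bands, yet
there is no agreed analytical route from a wiring diagram — a
tractography connectome — to the spatial organisation of communication
at each frequency.  `walksum` implements one: if signals hop along
weighted edges with a conduction delay T, every walk of length k
contributes the product of its edge weights times a phase e^{ikωT}, and
the sum over all walks is the network's transfer function,

    H(ω) = (I − e^{iωT} C)^{-1},        ρ(C) < 1,

the resolvent of the delay-phased weight matrix.  Its real part I(ω)
is an integrative channel (in-phase accumulation), its imaginary part
Q(ω) a routing channel (phase-shifted, direction-sensitive).  From
these two fields the package derives distance-resolved channel
profiles, the Q-crossover frequency (where ρ(Q, distance) changes
sign), the channel divergence D(ω) = ρ(Q,d) − ρ(I,d) and its minimiser
ω_c, channel salience, a five-point parameter-free prediction battery,
a Laplacian eigenmode model linking each mode's eigenvalue to its peak
frequency, a two-parameter "dressed" resolvent with local
damped-oscillator gains l(ω) = ω0²/(ω0² − ω² + 2iζω0ω), complex
coherency estimation for empirical comparison, and a Wilson–Cowan
simulation sweep as a dynamical negative control.

It is aimed at researchers in network neuroscience who have a weighted
connectome (and optionally multichannel recordings) and want the
frequency-resolved communication structure that the topology alone
implies.

## Worked example

```python
import walksum as ws

# a 64-node synthetic connectome with brain-like weight tiers
conn = ws.make_connectome(ws.SynthConfig(n_nodes=64, geometry="box3d", seed=3))

fld = ws.bare_resolvent(conn)                      # 89 frequencies, 1-45 Hz
rep = ws.evaluate_predictions(fld, conn.distances, perm_seed=0)
print(f"Q-crossover: {rep.q_crossover_hz:.2f} Hz")
print(f"convergence frequency: {rep.omega_c_hz:.1f} Hz")
print("verdicts:", rep.verdicts)

eig = ws.run_eigenmodel(conn, fld)
print(f"eigenvalue-peak-frequency rho: {eig.rho_lambda_f:.3f}")
```

prints (seed 3):

```
Q-crossover: 11.08 Hz
convergence frequency: 24.0 Hz
verdicts: {'c1': True, 'c2': True, 'c3': False, 'c4': False, 'c5': True}
eigenvalue-peak-frequency rho: 0.930
```

The routing channel correlates positively with fibre distance at low
frequencies and flips sign at ≈ 11.1 Hz — long-range routing is a
low-frequency phenomenon on this network, and the flip lands in the
alpha band.  The eigenmodel correlation near 0.93 says a mode's
Laplacian eigenvalue almost perfectly rank-predicts the frequency at
which that mode's share of the integrative channel peaks: global
low-eigenvalue modes dominate slow bands and hand off to local modes
as frequency rises.  On this synthetic fixture C3/C4 (long-range
positivity and the alpha trough of the binned profiles) are not
guaranteed — see `docs/methods.md` for exactly what the generator does
and does not emulate.

A command line mirrors the library:

```bash
walksum synth --n-nodes 64 --geometry box3d --seed 1 --out conn/
walksum channels conn/weights.csv conn/distances.csv --out report.json
walksum eigenmodel conn/weights.csv conn/distances.csv --out eig.json
```

## Layout

| module | contents |
| --- | --- |
| `walksum.connectome` | containers, validation, spectral-radius normalisation, degree partitions, delimited I/O |
| `walksum.synthetic` | distance-embedded connectome generator, coarse-graining, network-filtered noise series |
| `walksum.resolvent` | frequency grids, bare/dressed/heterogeneous resolvents, local gain, walk-sum oracle |
| `walksum.channels` | distance binning, channel-distance correlations, crossover, divergence, salience, C1-C5 |
| `walksum.eigenmodel` | Laplacian spectra, mode projections, peak frequencies, hub-mode participation |
| `walksum.spectra` | Welch cross-spectra, complex coherency, dominance ratio, communication dimensionality |
| `walksum.neural_mass` | Wilson-Cowan simulation and the negative-control sweep |
| `walksum.fitting` | (ω0, ζ) grid search, leave-one-dataset-out CV, heterogeneous coordinate descent |
| `walksum.cli` | `walksum` command with synth/resolvent/channels/eigenmodel/coherency/negctrl/fit |
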