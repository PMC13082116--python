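"""Synthetic distance-embedded connectomes and network-filtered noise.

Stands in for consensus tractography so every downstream stage can be
exercised without external data.  Two geometries are provided:

``ring``
    Nodes evenly spaced on a circle of brain-like diameter with purely
    distance-decayed weights — a circulant, analytically transparent
    network whose Laplacian modes are Fourier modes.  Used where
    spectral transparency matters more than realism.

``box3d``
    Nodes scattered in a brain-bounding box, wired with the three tiers
    that dominate real tractography connectomes: (i) a local tier of
    distance-decayed edges within a neighbourhood radius (U-fibres);
    (ii) a hub tier — by default a bilateral pair of high-degree hubs at
    opposite ends of the box joined by a strong corridor (the rich-club
    bridge), with every other node attached to its nearest hub; and
    (iii) a sparse tier of strong long-range association fibres whose
    weights are *not* distance-decayed (major fasciculi).  Multiplicative
    lognormal noise mimics streamline-count dispersion.

On the box3d defaults the bare resolvent reproduces the qualitative
channel phenomenology the analysis targets: the routing channel's
distance correlation is positive at low frequencies, crosses to
negative in the alpha range, and deepens beyond — driven by the
near-critical hub corridor whose resonant phase advances the sign flip
of multi-hop routes.

``make_timeseries`` produces multichannel noise whose cross-spectrum is
shaped exactly by the network transfer function H(ω): per-node white
noise is filtered frequency-bin-wise in the Fourier domain (circular
convolution), realising the resolvent as the generating filter of the
signals — the statistical structure the coherency stage assumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .connectome import Connectome, normalize_spectral_radius
from .errors import DimensionMismatchError
from .resolvent import LocalGainParams, local_gain

__all__ = ["SynthConfig", "make_connectome", "coarse_grain", "make_timeseries"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings for a distance-embedded connectome.

    All lengths are mm.  ``decay_length`` is the exponential length
    constant of the local weight–distance falloff; ``local_radius``
    truncates the local tier (no direct local edges beyond it);
    ``spoke_weight`` and ``corridor_weight`` set the hub tier;
    ``hub_boost`` additionally multiplies every hub-incident edge;
    ``long_range_density`` is the probability that a pair beyond
    ``long_range_min`` receives a direct association fibre of weight
    ``long_range_weight``; ``weight_noise_sd`` is the log-scale sd of
    multiplicative lognormal weight noise.
    """

    n_nodes: int = 64
    geometry: str = "ring"  # ring | box3d
    decay_length: float = 25.0
    hub_fraction: float = 0.03
    hub_boost: float = 1.0
    weight_noise_sd: float = 0.3
    extent_mm: float = 140.0
    local_weight: float = 0.04
    local_radius: float = 35.0
    spoke_weight: float = 0.5
    corridor_weight: float = 8.0
    long_range_weight: float = 0.4
    long_range_density: float = 0.2
    long_range_min: float = 70.0
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 4:
            raise ValueError("n_nodes must be >= 4")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        if not 0.0 <= self.hub_fraction <= 1.0:
            raise ValueError("hub_fraction must lie in [0, 1]")
        if self.hub_boost < 1.0:
            raise ValueError("hub_boost must be >= 1")
        if self.geometry not in ("ring", "box3d"):
            raise ValueError(f"unknown geometry {self.geometry!r}")

    @property
    def n_hubs(self) -> int:
        if self.hub_fraction == 0:
            return 0
        return max(2, int(round(self.hub_fraction * self.n_nodes)))


def _pairwise_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return d


def _chain_order(coords: np.ndarray, start: int) -> list[int]:
    """Greedy nearest-neighbour tour: contiguous indices are neighbours.

    Keeps coarse-graining of consecutive blocks spatially meaningful.
    """
    d = _pairwise_distances(coords)
    left = list(range(len(coords)))
    order = [left.pop(left.index(start))]
    while left:
        last = order[-1]
        nxt = min(left, key=lambda j: d[last, j])
        left.remove(nxt)
        order.append(nxt)
    return order


def make_connectome(cfg: SynthConfig) -> Connectome:
    """Generate a distance-embedded connectome (same seed → same output).

    Designated hubs are recorded on the result as ``hub_indices``
    (generator ground truth for tests).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nodes

    if cfg.geometry == "ring":
        theta = 2 * np.pi * np.arange(n) / n
        r = cfg.extent_mm / 2.0
        coords = np.column_stack(
            [r * np.cos(theta), r * np.sin(theta), np.zeros(n)]
        )
    else:
        span = np.array([1.0, 0.8, 0.6]) * cfg.extent_mm
        coords = rng.uniform(0.0, 1.0, size=(n, 3)) * span
        if cfg.n_hubs >= 2:
            # bilateral hub pair at opposite ends of the long axis
            coords[-2] = np.array([0.1, 0.5, 0.5]) * span
            coords[-1] = np.array([0.9, 0.5, 0.5]) * span

    for _ in range(10):
        d = _pairwise_distances(coords)
        off = d[~np.eye(n, dtype=bool)]
        if off.min() > 1e-9:
            break
        log.warning("coincident nodes in synthetic geometry; jittering")
        coords = coords + rng.normal(0.0, 1e-3 * cfg.extent_mm, coords.shape)

    if cfg.geometry == "box3d":
        start = n - 2 if cfg.n_hubs >= 2 else 0
        order = _chain_order(coords, start)
        coords = coords[order]
        hub_pool = [order.index(n - 2), order.index(n - 1)] if cfg.n_hubs >= 2 else []
        d = _pairwise_distances(coords)
    else:
        hub_pool = [0] if cfg.n_hubs >= 2 else []
        d = _pairwise_distances(coords)

    # tier 1: local distance-decayed edges
    w = cfg.local_weight * np.exp(-d / cfg.decay_length)
    np.fill_diagonal(w, 0.0)
    if cfg.geometry == "box3d":
        w[d > cfg.local_radius] = 0.0
        # tier 3: sparse long-range association fibres, not decayed
        iu = np.triu_indices(n, k=1)
        far = (d[iu] > cfg.long_range_min) & (
            rng.random(iu[0].size) < cfg.long_range_density
        )
        fi, fj = iu[0][far], iu[1][far]
        w[fi, fj] = np.maximum(w[fi, fj], cfg.long_range_weight)
        w[fj, fi] = w[fi, fj]

    # tier 2: hubs with nearest-hub spokes and a corridor clique
    hubs = list(hub_pool)
    while len(hubs) < cfg.n_hubs:
        md = d[:, hubs].min(axis=1) if hubs else d.mean(axis=1)
        if hubs:
            md[hubs] = -1.0
        hubs.append(int(np.argmax(md)))
    hubs_arr = np.array(sorted(hubs), dtype=int)
    if hubs_arr.size:
        for i in range(n):
            if i in hubs:
                continue
            h = hubs_arr[np.argmin(d[i, hubs_arr])]
            val = cfg.spoke_weight * cfg.hub_boost
            w[i, h] = w[h, i] = max(w[i, h], val)
        for a in hubs_arr:
            for b in hubs_arr:
                if a != b:
                    w[a, b] = max(w[a, b], cfg.corridor_weight * cfg.hub_boost)

    if cfg.weight_noise_sd > 0:
        noise = np.exp(rng.normal(0.0, cfg.weight_noise_sd, size=(n, n)))
        noise = np.sqrt(noise * noise.T)
        w = w * noise
    np.fill_diagonal(w, 0.0)

    w, factor = normalize_spectral_radius(w)
    conn = Connectome(
        weights=w, distances=d, coords=coords, normalisation_factor=factor
    )
    conn.hub_indices = hubs_arr
    return conn


def coarse_grain(conn: Connectome, factor: int) -> Connectome:
    """Merge contiguous blocks of ``factor`` nodes into super-nodes.

    Weights are summed across blocks (then spectral-radius renormalised);
    distances are averaged over cross-block pairs.  A remainder smaller
    than ``factor`` forms the final block on its own.  Total weight is
    preserved up to the renormalisation.
    """
    n = conn.n_nodes
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor >= n:
        raise DimensionMismatchError(f"factor {factor} >= n_nodes {n}")
    blocks = [np.arange(s, min(s + factor, n)) for s in range(0, n, factor)]
    m = len(blocks)
    wc = np.zeros((m, m))
    dc = np.zeros((m, m))
    for a in range(m):
        for b in range(a + 1, m):
            sub_w = conn.weights[np.ix_(blocks[a], blocks[b])]
            sub_d = conn.distances[np.ix_(blocks[a], blocks[b])]
            wc[a, b] = wc[b, a] = 0.5 * (sub_w.sum() + sub_w.T.sum())
            dc[a, b] = dc[b, a] = sub_d.mean()
    coords = None
    if conn.coords is not None:
        coords = np.array([conn.coords[b].mean(axis=0) for b in blocks])
    wc, factor_norm = normalize_spectral_radius(wc)
    return Connectome(
        weights=wc,
        distances=dc,
        labels=[f"block{a}" for a in range(m)],
        coords=coords,
        normalisation_factor=factor_norm,
    )


def transfer_gains(
    conn: Connectome,
    freqs_hz: np.ndarray,
    T: float,
    dressing: LocalGainParams | None = None,
    reading: str = "literal",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode resolvent gains on an arbitrary (dense) frequency axis.

    For symmetric weights C = U Λ Uᵀ the resolvent diagonalises in the
    same basis, H(f) = U diag(g(f)) Uᵀ, which makes dense-frequency
    filtering affordable.  Returns (g, U) with g of shape
    (n_modes, n_freqs).
    """
    if not np.allclose(conn.weights, conn.weights.T):
        raise DimensionMismatchError("eigenmode filtering requires symmetric weights")
    lam, U = np.linalg.eigh(conn.weights)
    z = np.exp(2j * np.pi * np.asarray(freqs_hz) * T)
    if dressing is None:
        g = 1.0 / (1.0 - z[None, :] * lam[:, None])
    else:
        lv = np.asarray(local_gain(np.asarray(freqs_hz), dressing))
        if reading == "literal":
            g = 1.0 / (lv[None, :] * (1.0 - z[None, :] * lam[:, None]))
        elif reading == "gain_outside":
            g = lv[None, :] / (1.0 - lv[None, :] * z[None, :] * lam[:, None])
        else:
            raise ValueError(f"unknown dressing reading {reading!r}")
    return g, U


def make_timeseries(
    conn: Connectome,
    fs: float,
    duration: float,
    dressing: LocalGainParams | None = None,
    noise_seed: int = 0,
    T: float = 0.010,
    reading: str = "literal",
    nperseg_hint: int = 2048,
) -> np.ndarray:
    """Network-filtered Gaussian noise, channels × samples.

    Per-node white noise is transformed to the frequency domain,
    multiplied bin-wise by H(f) (bare or dressed), and inverse
    transformed — an exact realisation of the resolvent as the
    generating linear filter (circular convolution).  Same seed →
    identical series.
    """
    n_samples = int(round(fs * duration))
    if n_samples < nperseg_hint:
        warnings.warn(
            f"duration gives {n_samples} samples, fewer than one Welch "
            f"segment of {nperseg_hint}; coherency estimates will be poor",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(noise_seed)
    noise = rng.standard_normal((conn.n_nodes, n_samples))
    spec = np.fft.rfft(noise, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    g, U = transfer_gains(conn, freqs, T, dressing=dressing, reading=reading)
    spec = U @ (g * (U.T @ spec))
    return np.fft.irfft(spec, n=n_samples, axis=1)
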