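"""Cross-spectral density, complex coherency and spectral-matrix metrics.

The estimator is Welch's averaged periodogram (2,048-sample segments,
50% overlap, Hann window by default) computed jointly for all channel
pairs from one set of segment FFTs.  Complex coherency is
C_ij(f) = S_ij(f) / sqrt(S_ii(f) S_jj(f)).  The estimator's FFT grid is
mapped to the 0.5 Hz analysis grid by nearest-bin lookup; the mapping is
recorded in the result's metadata (for fs = 1024 Hz and nperseg = 2048
the grids coincide exactly).

Spectral-matrix metrics: the dominance ratio (ratio of the two largest
singular values of the off-diagonal coherency at a frequency) and a
participation-ratio "communication dimensionality" of the stacked I/Q
pair-profile matrix — the latter is an explicit interpretation of a
quantity with no standard definition, and is labelled as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .channels import upper_triangle
from .errors import DimensionMismatchError, EstimatorError
from .resolvent import FrequencyGrid, ResolventField

__all__ = [
    "CSDResult",
    "CoherencyField",
    "welch_csd",
    "coherency",
    "implied_coherency",
    "empirical_channels",
    "dominance_ratio",
    "communication_dimensionality",
]


@dataclass
class CSDResult:
    """Cross-spectral matrices S (n_freqs, N, N) on the estimator grid."""

    S: np.ndarray
    freqs: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class CoherencyField:
    """Complex coherency matrices over a frequency grid.

    Exposes the same surface as a resolvent field (``H``, ``I``, ``Q``,
    ``grid``) so channel statistics apply unchanged.  Invariants: unit
    diagonal, |C_ij| ≤ 1, conjugate symmetry.
    """

    C: np.ndarray
    grid: FrequencyGrid
    meta: dict = field(default_factory=dict)

    @property
    def H(self) -> np.ndarray:
        return self.C

    @property
    def I(self) -> np.ndarray:  # noqa: E743
        return self.C.real

    @property
    def Q(self) -> np.ndarray:
        return self.C.imag

    @property
    def n_nodes(self) -> int:
        return self.C.shape[1]

    def at(self, f_hz: float) -> np.ndarray:
        return self.C[self.grid.index_of(f_hz)]


def welch_csd(
    series: np.ndarray,
    fs: float,
    nperseg: int = 2048,
    overlap: float = 0.5,
    window: str = "hann",
    detrend: str | bool = "constant",
) -> CSDResult:
    """Welch cross-spectral density for all channel pairs.

    ``series`` is channels × samples.  Segment FFTs are computed once per
    channel; S_ij(f) averages X_i(f) conj(X_j(f)) over segments with
    one-sided density scaling.  Matches ``scipy.signal.csd`` with the
    same settings.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    n_ch, n_samp = x.shape
    if n_samp < nperseg:
        raise EstimatorError(
            f"{n_samp} samples < one segment of {nperseg}"
        )
    step = int(nperseg * (1.0 - overlap))
    if step < 1:
        raise EstimatorError("overlap too large: empty hop")
    win = sps.get_window(window, nperseg)
    n_seg = (n_samp - nperseg) // step + 1
    idx = np.arange(nperseg)[None, :] + step * np.arange(n_seg)[:, None]
    nf = nperseg // 2 + 1
    S = np.zeros((nf, n_ch, n_ch), dtype=complex)
    # chunk over segments to bound memory on long recordings
    chunk = max(1, int(2e7 / (n_ch * nperseg)))
    for s0 in range(0, n_seg, chunk):
        seg = x[:, idx[s0 : s0 + chunk]]  # (n_ch, chunk, nperseg)
        if detrend == "constant":
            seg = seg - seg.mean(axis=-1, keepdims=True)
        elif detrend == "linear":
            seg = sps.detrend(seg, axis=-1, type="linear")
        X = np.fft.rfft(seg * win, axis=-1)
        # scipy convention: S_ij = E[conj(X_i) X_j]
        S += np.einsum("isf,jsf->fij", np.conj(X), X, optimize=True)
    scale = 1.0 / (fs * (win**2).sum() * n_seg)
    S *= scale
    S[1:-1] *= 2.0  # one-sided density (DC and Nyquist not doubled)
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return CSDResult(
        S=S,
        freqs=freqs,
        meta={
            "fs": fs,
            "nperseg": nperseg,
            "overlap": overlap,
            "window": window,
            "n_segments": int(n_seg),
            "detrend": detrend,
        },
    )


def _to_analysis_grid(
    freqs: np.ndarray, grid: FrequencyGrid
) -> tuple[np.ndarray, float]:
    """Nearest-bin mapping from estimator FFT grid to analysis grid."""
    idx = np.array([int(np.argmin(np.abs(freqs - f))) for f in grid.f])
    worst = float(np.max(np.abs(freqs[idx] - grid.f)))
    return idx, worst


def coherency(
    csd: CSDResult, grid: FrequencyGrid | None = None, T: float = 0.0
) -> CoherencyField:
    """Complex coherency C_ij = S_ij / sqrt(S_ii S_jj).

    When ``grid`` is given, the estimator grid is mapped onto it by
    nearest bin (mapping error recorded in metadata); otherwise the
    positive estimator frequencies are kept as-is.
    """
    S = csd.S
    auto = np.real(np.einsum("fii->fi", S))
    bad = np.argwhere(auto <= 0)
    if bad.size:
        f_i, ch = bad[0]
        raise EstimatorError(
            f"non-positive auto-spectrum at channel {ch}, "
            f"frequency bin {csd.freqs[f_i]:g} Hz"
        )
    norm = np.sqrt(auto[:, :, None] * auto[:, None, :])
    C = S / norm
    meta = dict(csd.meta)
    if grid is not None:
        idx, worst = _to_analysis_grid(csd.freqs, grid)
        C = C[idx]
        meta["grid_mapping"] = "nearest_bin"
        meta["grid_mapping_max_error_hz"] = worst
    else:
        pos = csd.freqs > 0
        C = C[pos]
        grid = FrequencyGrid(f=csd.freqs[pos], T=T)
    return CoherencyField(C=C, grid=grid, meta=meta)


def implied_coherency(fld: ResolventField) -> CoherencyField:
    """Coherency implied by a transfer field driving unit white noise.

    With x̂ = H n̂ and ⟨n̂ n̂†⟩ = I, the cross-spectrum in the estimator's
    convention S_ij = E[conj(x̂_i) x̂_j] is S = conj(H) Hᵀ; the coherency
    follows by auto-spectrum normalisation.
    """
    S = np.conj(fld.H) @ np.swapaxes(fld.H, -1, -2)
    auto = np.real(np.einsum("fii->fi", S))
    norm = np.sqrt(auto[:, :, None] * auto[:, None, :])
    return CoherencyField(C=S / norm, grid=fld.grid, meta={"source": "model"})


def empirical_channels(
    coh: CoherencyField,
    distances: np.ndarray,
    q_channel: str = "absQ",
    **kwargs,
):
    """Channel prediction battery on empirical coherency.

    Delegates to :func:`walksum.channels.evaluate_predictions` with the
    empirical-side default Q statistic |Im(C)|.
    """
    from .channels import evaluate_predictions

    if coh.n_nodes != np.asarray(distances).shape[0]:
        raise DimensionMismatchError("distance matrix does not match channel count")
    return evaluate_predictions(coh, distances, q_channel=q_channel, **kwargs)


def dominance_ratio(fld, f_hz: float) -> float:
    """σ1/σ2 of the off-diagonal-retained complex matrix at a frequency.

    Returns ``inf`` when the second singular value vanishes (rank-1).
    """
    m = np.array(fld.at(f_hz), dtype=complex)
    if m.shape[0] < 2:
        raise DimensionMismatchError("need at least 2 channels")
    np.fill_diagonal(m, 0.0)
    s = np.linalg.svd(m, compute_uv=False)
    if s[0] == 0:
        return 1.0  # degenerate: all singular values equal (zero)
    if s[1] <= s[0] * 1e-12:
        return float("inf")
    return float(s[0] / s[1])


def communication_dimensionality(
    fld, f_lo: float, f_hi: float | None = None
) -> float:
    """Participation ratio of the stacked I/Q pair-profile matrix.

    Rows are the upper-triangle I and Q profiles at each grid frequency
    in [f_lo, f_hi] (a single frequency when f_hi is omitted); the
    statistic is (Σσ)²/Σσ² over the singular values.  Two proportional
    channel profiles give 1; orthogonal equal-norm profiles give 2.
    This construction is an explicit interpretation, not a literature
    standard, and results should be labelled accordingly.
    """
    freqs = np.asarray(fld.grid.f)
    if f_hi is None:
        f_hi = f_lo
    mask = (freqs >= f_lo - 1e-9) & (freqs <= f_hi + 1e-9)
    if not mask.any():
        raise DimensionMismatchError("no grid frequencies in the requested range")
    rows = np.vstack(
        [upper_triangle(fld.I[mask]), upper_triangle(fld.Q[mask])]
    )
    rows = rows[np.any(rows != 0, axis=1)]
    if rows.size == 0:
        return 0.0
    s = np.linalg.svd(rows, compute_uv=False)
    return float(s.sum() ** 2 / (s**2).sum())
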