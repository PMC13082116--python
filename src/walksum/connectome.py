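"""Structural connectome containers, validation, normalisation and I/O.

A :class:`Connectome` couples a nonnegative weight matrix (tractography
streamline counts or densities, normalised on load so the walk series
converges) with a matching fibre-tract distance matrix in millimetres.
Weights are divided by ``safety × max |eigenvalue|`` whenever the spectral
radius is not already below one; the applied divisor is recorded so the
original scale can be recovered.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    AsymmetryError,
    DimensionMismatchError,
    NegativeEntryError,
    NonFiniteError,
)

__all__ = [
    "Connectome",
    "NodePartition",
    "load_connectome",
    "load_connectome_dir",
    "save_connectome",
    "normalize_spectral_radius",
    "spectral_radius",
    "weighted_degree",
    "partition_by_degree",
]


def spectral_radius(w: np.ndarray) -> float:
    """Largest eigenvalue magnitude of a square matrix."""
    w = np.asarray(w, dtype=float)
    if w.size == 0 or not np.any(w):
        return 0.0
    if np.allclose(w, w.T):
        return float(np.max(np.abs(np.linalg.eigvalsh(w))))
    return float(np.max(np.abs(np.linalg.eigvals(w))))


def normalize_spectral_radius(
    w: np.ndarray, safety: float = 1.01
) -> tuple[np.ndarray, float]:
    """Rescale ``w`` so its spectral radius is strictly below one.

    Division is applied only when necessary: a matrix whose radius is
    already sub-unity (including the all-zero matrix) is returned
    unchanged with factor 1.  Otherwise the divisor is
    ``safety * spectral_radius(w)``.

    Returns
    -------
    (matrix, factor)
        The rescaled matrix and the divisor that was applied.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise DimensionMismatchError(f"expected a square matrix, got {w.shape}")
    if not np.all(np.isfinite(w)):
        raise NonFiniteError("matrix contains non-finite entries")
    rho = spectral_radius(w)
    if rho < 1.0:
        return w, 1.0
    factor = safety * rho
    return w / factor, float(factor)


@dataclass
class Connectome:
    """A weighted structural connectome with fibre-tract distances.

    Attributes
    ----------
    weights
        N×N nonnegative connectivity, spectral radius < 1 after load.
    distances
        N×N nonnegative fibre-tract (or Euclidean) distances, mm.
    labels
        N node identifiers.
    coords
        Optional N×3 node positions, mm.
    normalisation_factor
        The divisor applied to the raw weights on load (1 if none).
    directed
        Whether asymmetric weights are permitted.
    """

    weights: np.ndarray
    distances: np.ndarray
    labels: list[str] = field(default_factory=list)
    coords: np.ndarray | None = None
    normalisation_factor: float = 1.0
    directed: bool = False

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if not self.labels:
            self.labels = [f"node{i}" for i in range(self.weights.shape[0])]
        self.validate()

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def validate(self) -> None:
        w, d = self.weights, self.distances
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise DimensionMismatchError(f"weights must be square, got {w.shape}")
        if d.shape != w.shape:
            raise DimensionMismatchError(
                f"distances shape {d.shape} != weights shape {w.shape}"
            )
        if w.shape[0] < 2:
            raise DimensionMismatchError("a connectome needs at least 2 nodes")
        if len(self.labels) != w.shape[0]:
            raise DimensionMismatchError("label count does not match matrix size")
        if not np.all(np.isfinite(w)):
            raise NonFiniteError("weights contain non-finite entries")
        if not np.all(np.isfinite(d)):
            raise NonFiniteError("distances contain non-finite entries")
        if np.any(w < 0):
            raise NegativeEntryError("weights contain negative entries")
        if np.any(d < 0):
            raise NegativeEntryError("distances contain negative entries")
        if np.any(np.diag(w) != 0) or np.any(np.diag(d) != 0):
            raise NegativeEntryError("diagonals of weights and distances must be zero")
        if not np.allclose(d, d.T):
            raise AsymmetryError("distance matrix must be symmetric")
        if not self.directed and not np.allclose(w, w.T):
            raise AsymmetryError(
                "asymmetric weights with directed=False; pass directed=True "
                "or symmetrise explicitly"
            )
        if self.coords is not None:
            self.coords = np.asarray(self.coords, dtype=float)
            if self.coords.shape != (w.shape[0], 3):
                raise DimensionMismatchError(
                    f"coords must be N×3, got {self.coords.shape}"
                )

    @property
    def spectral_radius(self) -> float:
        return spectral_radius(self.weights)


@dataclass
class NodePartition:
    """Assignment of nodes to degree groups (0 = hub, highest degree)."""

    group_of: np.ndarray  # int group index per node
    thresholds: np.ndarray  # n_groups-1 degree cut values (upper bound per group)
    n_groups: int = 3

    def members(self, group: int) -> np.ndarray:
        return np.flatnonzero(self.group_of == group)


def weighted_degree(conn: Connectome, binary: bool = False) -> np.ndarray:
    """Node strength: row sums of the weight matrix.

    With ``binary=True``, counts nonzero connections instead.
    """
    w = conn.weights
    if binary:
        return (w > 0).sum(axis=1).astype(float)
    return w.sum(axis=1)


def partition_by_degree(
    conn: Connectome, n_groups: int = 3, binary: bool = False
) -> NodePartition:
    """Split nodes into equal-count degree groups (group 0 = hubs).

    Quantile boundaries use equal counts; ties are broken by node index,
    so the assignment is a deterministic function of (degree, index).
    """
    n = conn.n_nodes
    if n_groups > n:
        raise DimensionMismatchError(
            f"cannot split {n} nodes into {n_groups} groups"
        )
    deg = weighted_degree(conn, binary=binary)
    order = np.lexsort((np.arange(n), deg))  # ascending degree, index tie-break
    chunks = np.array_split(order, n_groups)
    group_of = np.empty(n, dtype=int)
    for j, chunk in enumerate(chunks):
        group_of[chunk] = n_groups - 1 - j  # lowest-degree chunk -> last group
    thresholds = np.array([deg[chunk[-1]] for chunk in chunks[:-1]])
    return NodePartition(group_of=group_of, thresholds=thresholds, n_groups=n_groups)


# ---------------------------------------------------------------------------
# File I/O: delimited text matrices with a JSON metadata sidecar.


def _read_matrix(path: str | Path) -> np.ndarray:
    """Read a delimited numeric matrix; comma or tab auto-detected."""
    path = Path(path)
    text = path.read_text()
    first = text.lstrip().splitlines()[0] if text.strip() else ""
    delim = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    skip = 0
    # optional header row: first field non-numeric
    lead = first.split(delim)[0].strip()
    try:
        float(lead)
    except ValueError:
        if lead != "":
            skip = 1
    try:
        mat = np.genfromtxt(path, delimiter=delim, skip_header=skip)
    except Exception as exc:  # pragma: no cover - malformed files
        raise NonFiniteError(f"could not parse matrix file {path}: {exc}") from exc
    return np.atleast_2d(mat)


def load_connectome(
    weights_path: str | Path,
    distances_path: str | Path,
    directed: bool = False,
    safety: float = 1.01,
    labels: list[str] | None = None,
    coords: np.ndarray | None = None,
) -> Connectome:
    """Load, validate and spectral-radius-normalise a connectome.

    Raises distinct errors for dimension mismatch, negative entries and
    non-finite values.
    """
    w = _read_matrix(weights_path)
    d = _read_matrix(distances_path)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise DimensionMismatchError(f"weights file is not square: {w.shape}")
    if d.shape != w.shape:
        raise DimensionMismatchError(
            f"distances {d.shape} do not match weights {w.shape}"
        )
    if not np.all(np.isfinite(w)):
        raise NonFiniteError("weights file contains non-finite values")
    if not np.all(np.isfinite(d)):
        raise NonFiniteError("distances file contains non-finite values")
    if np.any(w < 0) or np.any(d < 0):
        raise NegativeEntryError("input matrices contain negative entries")
    np.fill_diagonal(w, 0.0)
    np.fill_diagonal(d, 0.0)
    w, factor = normalize_spectral_radius(w, safety=safety)
    return Connectome(
        weights=w,
        distances=d,
        labels=labels or [],
        coords=coords,
        normalisation_factor=factor,
        directed=directed,
    )


def save_connectome(conn: Connectome, directory: str | Path) -> Path:
    """Write weights/distances as CSV plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / "weights.csv", conn.weights, delimiter=",")
    np.savetxt(directory / "distances.csv", conn.distances, delimiter=",")
    if conn.coords is not None:
        np.savetxt(directory / "coords.csv", conn.coords, delimiter=",")
    meta = {
        "labels": conn.labels,
        "normalisation_factor": conn.normalisation_factor,
        "directed": conn.directed,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_connectome_dir(directory: str | Path) -> Connectome:
    """Load a connectome written by :func:`save_connectome`."""
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    coords_path = directory / "coords.csv"
    coords = _read_matrix(coords_path) if coords_path.exists() else None
    conn = load_connectome(
        directory / "weights.csv",
        directory / "distances.csv",
        directed=meta.get("directed", False),
        labels=meta.get("labels") or None,
        coords=coords,
    )
    # weights were stored already normalised; keep the original factor
    conn.normalisation_factor = meta.get("normalisation_factor", 1.0)
    return conn
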