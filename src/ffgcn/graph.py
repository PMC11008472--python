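"""Functional-connectivity graphs for multichannel recordings.

EEG electrodes are modelled as nodes of an undirected weighted graph
``G = (V, E, A)``; edge weights are the absolute Pearson correlation
between the two channels' time series, so ``w_ij`` quantifies how
strongly two scalp sites co-fluctuate regardless of polarity.  From the
adjacency the usual Laplacian machinery follows: the combinatorial
Laplacian ``L = D - A``, the symmetric normalized Laplacian
``I - D^{-1/2} A D^{-1/2}``, its eigendecomposition (which defines the
graph Fourier transform) and the rescaling ``2L/lambda_max - I`` used by
Chebyshev polynomial filters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultichannelRecording",
    "WeightedGraph",
    "GraphSpectrum",
    "compute_pcc_adjacency",
    "degree_matrix",
    "combinatorial_laplacian",
    "normalized_laplacian",
    "spectrum",
    "rescale_laplacian",
    "write_edge_list",
    "read_edge_list",
]

_SYM_TOL = 1e-10


@dataclass
class MultichannelRecording:
    """One trial: a channels-by-samples signal block plus metadata.

    Parameters
    ----------
    signals : ndarray of shape (n_channels, n_samples)
        Amplitudes in arbitrary units (typically microvolts).
    channel_names : list of str
        Montage labels (10-10 system for real EEG), one per row.
    sampling_rate : float
        Sampling frequency in Hz.
    label : int or None
        Class index in ``{0..C-1}``; ``None`` for unlabeled data.
    """

    signals: np.ndarray
    channel_names: list[str]
    sampling_rate: float
    label: int | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D channels x samples array")
        if self.signals.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.signals.shape[0]} signal rows but "
                f"{len(self.channel_names)} channel names"
            )
        if self.signals.shape[1] < 2:
            raise ValueError("each channel needs at least 2 samples")
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]


@dataclass
class WeightedGraph:
    """Symmetric nonnegative adjacency with zero diagonal (no self-loops)."""

    adjacency: np.ndarray
    node_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.all(np.isfinite(a)):
            raise ValueError("adjacency contains non-finite values")
        if np.max(np.abs(a - a.T)) > _SYM_TOL:
            raise ValueError("adjacency must be symmetric")
        a = 0.5 * (a + a.T)
        if a.min() < 0.0 or a.max() > 1.0 + _SYM_TOL:
            raise ValueError("edge weights must lie in [0, 1]")
        np.fill_diagonal(a, 0.0)
        self.adjacency = a
        if not self.node_names:
            self.node_names = [f"n{i}" for i in range(a.shape[0])]
        if len(self.node_names) != a.shape[0]:
            raise ValueError("node_names length must match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class GraphSpectrum:
    """Eigendecomposition ``M = U diag(eigenvalues) U^T`` of a Laplacian.

    Eigenvalues ascending; eigenvectors orthonormal with a deterministic
    sign convention (largest-magnitude entry of each eigenvector is
    positive, earliest index winning ties).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    source: str = "laplacian"

    @property
    def lambda_max(self) -> float:
        return float(self.eigenvalues[-1])


def compute_pcc_adjacency(
    trials: MultichannelRecording | list[MultichannelRecording],
) -> WeightedGraph:
    """Absolute-Pearson-correlation adjacency of the channel graph.

    ``w_ij = |corr(x_i, x_j)|``; with several trials the samples are
    concatenated along time before correlating, yielding one graph for
    the whole collection.  Zero-variance (flat) channels get weight 0 on
    every edge, with a warning, so dead electrodes do not abort a run.
    The diagonal is zeroed: self-correlation is trivially 1 and would
    distort degrees in ``L = D - A``.
    """
    if isinstance(trials, MultichannelRecording):
        trials = [trials]
    if not trials:
        raise ValueError("need at least one recording")
    names = trials[0].channel_names
    for t in trials[1:]:
        if t.channel_names != names:
            raise ValueError("all trials must share the same channel ordering")
    x = np.concatenate([t.signals for t in trials], axis=1)
    sd = x.std(axis=1)
    # relative tolerance: a constant channel's std is zero only up to
    # round-off in the mean subtraction
    flat = sd <= 1e-12 * (np.abs(x).mean(axis=1) + 1.0)
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance channel(s); their edge weights "
            "are set to 0 (correlation undefined)",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    a = np.abs(c)
    a[flat, :] = 0.0
    a[:, flat] = 0.0
    # round-off can push |r| a hair above 1
    np.clip(a, 0.0, 1.0, out=a)
    a = 0.5 * (a + a.T)
    np.fill_diagonal(a, 0.0)
    return WeightedGraph(a, list(names))


def degree_matrix(g: WeightedGraph) -> np.ndarray:
    """Diagonal degree matrix ``D_ii = sum_j A_ij``."""
    return np.diag(g.adjacency.sum(axis=1))


def combinatorial_laplacian(g: WeightedGraph) -> np.ndarray:
    """Combinatorial Laplacian ``L = D - A``."""
    return degree_matrix(g) - g.adjacency


def normalized_laplacian(g: WeightedGraph) -> np.ndarray:
    """Symmetric normalized Laplacian ``I - D^{-1/2} A D^{-1/2}``.

    Isolated (degree-0) nodes, where ``D^{-1/2}`` is undefined, keep an
    identity row/column — the pseudo-inverse convention.
    """
    deg = g.adjacency.sum(axis=1)
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = deg[nz] ** -0.5
    ln = -inv_sqrt[:, None] * g.adjacency * inv_sqrt[None, :]
    np.fill_diagonal(ln, 1.0)
    # an isolated node gets exactly the identity row
    ln[~nz, :] = 0.0
    ln[:, ~nz] = 0.0
    ln[np.ix_(~nz, ~nz)] = np.eye(int((~nz).sum()))
    return 0.5 * (ln + ln.T)


def spectrum(mat: np.ndarray, source: str = "laplacian") -> GraphSpectrum:
    """Eigendecompose a symmetric matrix with a reproducible convention."""
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("input must be square")
    if np.max(np.abs(mat - mat.T)) > 1e-8:
        raise ValueError("input must be symmetric")
    lam, u = np.linalg.eigh(0.5 * (mat + mat.T))
    # sign convention: make each eigenvector's largest-magnitude entry
    # positive so repeated calls (and repeated eigenvalues) are stable
    for k in range(u.shape[1]):
        col = u[:, k]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            u[:, k] = -col
    return GraphSpectrum(lam, u, source)


def rescale_laplacian(L: np.ndarray, lambda_max: float) -> np.ndarray:
    """Map the Laplacian spectrum into Chebyshev's domain: ``2L/lmax - I``."""
    if lambda_max <= 0:
        raise ValueError("lambda_max must be positive")
    L = np.asarray(L, dtype=float)
    return 2.0 * L / lambda_max - np.eye(L.shape[0])


def write_edge_list(g: WeightedGraph, path) -> None:
    """Export as tab-delimited ``node_i  node_j  weight`` (upper triangle)."""
    with open(path, "w") as fh:
        fh.write("# nodes: " + ",".join(g.node_names) + "\n")
        n = g.n_nodes
        for i in range(n):
            for j in range(i + 1, n):
                w = g.adjacency[i, j]
                if w != 0.0:
                    fh.write(f"{g.node_names[i]}\t{g.node_names[j]}\t{w:.17g}\n")


def read_edge_list(path) -> WeightedGraph:
    """Inverse of :func:`write_edge_list`."""
    names: list[str] = []
    edges: list[tuple[str, str, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("# nodes:"):
                names = line.split(":", 1)[1].strip().split(",")
                continue
            a, b, w = line.split("\t")
            edges.append((a, b, float(w)))
    if not names:
        raise ValueError("edge-list file lacks a '# nodes:' header")
    idx = {nm: i for i, nm in enumerate(names)}
    adj = np.zeros((len(names), len(names)))
    for a, b, w in edges:
        adj[idx[a], idx[b]] = w
        adj[idx[b], idx[a]] = w
    return WeightedGraph(adj, names)
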