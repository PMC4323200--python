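"""Weighted graphs, Laplacians and heat-kernel derived quantities.

Everything downstream of the spectrum lives here: the heat kernel
``H_t = sum_k exp(-lambda_k t) phi_k phi_k^T`` of the normalized Laplacian,
per-node average temperatures, the kernel-induced squared distance
``D_t(i,j) = H(i,i) + H(j,j) - 2 H(i,j)``, the matching spectral embedding
whose axes are ``exp(-lambda_k t / 2) phi_k``, and distance-based ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse
import scipy.sparse.linalg

__all__ = [
    "WeightedGraph",
    "SpectralDecomposition",
    "HeatKernel",
    "TemperatureVector",
    "HeatDistanceMatrix",
    "EmbeddingCoordinates",
    "build_weighted_graph",
    "graph_laplacian",
    "normalized_laplacian",
    "spectral_decompose",
    "heat_kernel",
    "average_temperature",
    "heat_distance",
    "heat_coordinates",
    "rank_by_heat_distance",
    "distances_to_weights",
    "default_truncation",
]

SYMMETRY_RTOL = 1e-8


@dataclass(frozen=True)
class WeightedGraph:
    """Undirected weighted graph with symmetric nonnegative weights.

    ``labels`` are the external node identifiers (1-based integers by
    default); matrix rows/columns follow label order.
    """

    n: int
    labels: tuple
    W: np.ndarray

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("graph needs at least one node")
        if self.W.shape != (self.n, self.n):
            raise ValueError("weight matrix shape does not match node count")
        if len(self.labels) != self.n:
            raise ValueError("label count does not match node count")

    @property
    def degrees(self) -> np.ndarray:
        return self.W.sum(axis=1)

    def index_of(self, label: Hashable) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown node label {label!r}") from None


@dataclass(frozen=True)
class SpectralDecomposition:
    """The ``k`` smallest eigenpairs of a symmetric Laplacian, ascending."""

    n: int
    k: int
    eigenvalues: np.ndarray   # (k,)
    eigenvectors: np.ndarray  # (n, k), columns unit-norm


@dataclass(frozen=True)
class HeatKernel:
    t: float
    H: np.ndarray
    k_used: int


@dataclass(frozen=True)
class TemperatureVector:
    temp: np.ndarray


@dataclass(frozen=True)
class HeatDistanceMatrix:
    D: np.ndarray
    labels: tuple = field(default=())


@dataclass(frozen=True)
class EmbeddingCoordinates:
    dim: int
    coords: np.ndarray  # (n, dim)


def _merge_edges(edges: Iterable[tuple]) -> tuple[list, dict]:
    """Collect an edge list into labels + a dict keyed by unordered pair."""
    weights: dict[tuple, float] = {}
    labels: list = []
    seen = set()
    n_loops = 0
    for entry in edges:
        if len(entry) == 2:
            i, j = entry
            w = 1.0
        else:
            i, j, w = entry
        w = float(w)
        if not np.isfinite(w):
            raise ValueError(f"non-finite weight on edge ({i!r}, {j!r})")
        if w < 0:
            raise ValueError(f"negative weight {w} on edge ({i!r}, {j!r})")
        for node in (i, j):
            if node not in seen:
                seen.add(node)
                labels.append(node)
        if i == j:
            n_loops += 1
            continue
        key = (i, j) if labels.index(i) <= labels.index(j) else (j, i)
        if key in weights and not np.isclose(weights[key], w, rtol=SYMMETRY_RTOL):
            raise ValueError(
                f"conflicting weights for edge {key!r}: {weights[key]} vs {w}"
            )
        weights[key] = w
    if n_loops:
        warnings.warn(f"dropped {n_loops} self-loop(s); W_ii is forced to zero")
    return labels, weights


def build_weighted_graph(
    data,
    labels: Sequence | None = None,
    symmetry_rtol: float = SYMMETRY_RTOL,
) -> WeightedGraph:
    """Build a :class:`WeightedGraph` from an edge list or a dense matrix.

    Edge lists are iterables of ``(i, j)`` or ``(i, j, weight)`` tuples;
    ``(i, j, w)`` and ``(j, i, w)`` are merged, self-loops dropped with a
    warning.  Dense input must be square, nonnegative and symmetric within
    ``symmetry_rtol`` (it is then exactly symmetrized and its diagonal
    zeroed).
    """
    if isinstance(data, np.ndarray) or scipy.sparse.issparse(data):
        W = np.asarray(
            data.todense() if scipy.sparse.issparse(data) else data, dtype=float
        )
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("dense weight input must be a square matrix")
        n = W.shape[0]
        if n == 0:
            raise ValueError("empty weight matrix")
        if not np.all(np.isfinite(W)):
            raise ValueError("weight matrix contains non-finite entries")
        asym = np.abs(W - W.T)
        scale = max(np.abs(W).max(), 1.0)
        if asym.max() > symmetry_rtol * scale:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            raise ValueError(
                f"matrix is not symmetric: W[{i},{j}]={W[i, j]} vs W[{j},{i}]={W[j, i]}"
            )
        W = (W + W.T) / 2.0
        if np.any(W < 0):
            i, j = np.unravel_index(np.argmin(W), W.shape)
            raise ValueError(f"negative weight W[{i},{j}]={W[i, j]}")
        if np.any(np.diagonal(W) != 0):
            warnings.warn("nonzero diagonal entries zeroed (no self-loops allowed)")
            np.fill_diagonal(W, 0.0)
        if labels is None:
            labels = tuple(range(1, n + 1))
        return WeightedGraph(n=n, labels=tuple(labels), W=W)

    edges = list(data)
    if not edges:
        raise ValueError("empty edge list")
    found, weights = _merge_edges(edges)
    if labels is None:
        try:
            labels = tuple(sorted(found))
        except TypeError:
            labels = tuple(found)
    else:
        labels = tuple(labels)
        missing = set(found) - set(labels)
        if missing:
            raise ValueError(f"edge list refers to unknown labels {missing!r}")
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    W = np.zeros((n, n))
    for (i, j), w in weights.items():
        W[index[i], index[j]] = w
        W[index[j], index[i]] = w
    return WeightedGraph(n=n, labels=labels, W=W)


def graph_laplacian(g: WeightedGraph) -> np.ndarray:
    """Combinatorial Laplacian ``L = D - W``; every row sums to zero."""
    L = -g.W.copy()
    np.fill_diagonal(L, g.degrees)
    return L


def normalized_laplacian(g: WeightedGraph) -> np.ndarray:
    """Symmetric normalized Laplacian ``D^{-1/2} (D - W) D^{-1/2}``.

    Spectrum lies in [0, 2].  Rejects graphs with an isolated node, for
    which the normalization is undefined.
    """
    d = g.degrees
    dead = np.flatnonzero(d <= 0)
    if dead.size:
        names = [g.labels[i] for i in dead[:5]]
        raise ValueError(
            f"isolated node(s) with zero degree: {names!r} — "
            "normalized Laplacian undefined"
        )
    inv_sqrt = 1.0 / np.sqrt(d)
    LN = graph_laplacian(g) * inv_sqrt[:, None] * inv_sqrt[None, :]
    return (LN + LN.T) / 2.0


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip each column so its first entry of nonnegligible magnitude is > 0."""
    out = vecs.copy()
    for j in range(out.shape[1]):
        nz = np.flatnonzero(np.abs(out[:, j]) > 1e-12)
        if nz.size and out[nz[0], j] < 0:
            out[:, j] = -out[:, j]
    return out


def spectral_decompose(LN: np.ndarray, k: int | str = "full") -> SpectralDecomposition:
    """The ``k`` smallest eigenpairs of a symmetric matrix, ascending.

    Eigenvectors have unit sum of squared entries and a deterministic sign
    (first nonzero entry positive).  ``k="full"`` keeps the whole spectrum.
    """
    LN = np.asarray(LN, dtype=float)
    n = LN.shape[0]
    if LN.ndim != 2 or LN.shape[1] != n:
        raise ValueError("Laplacian must be square")
    if not np.allclose(LN, LN.T, atol=1e-8 * max(1.0, np.abs(LN).max())):
        raise ValueError("Laplacian must be symmetric")
    if k == "full":
        k = n
    k = int(k)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range [1, {n}]")
    if k < n and n > 1500:
        # large problems: Lanczos on the k smallest pairs only
        vals, vecs = scipy.sparse.linalg.eigsh(
            scipy.sparse.csr_matrix(LN), k=k, which="SM"
        )
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    else:
        vals, vecs = scipy.linalg.eigh(LN, subset_by_index=[0, k - 1])
    vecs = vecs / np.linalg.norm(vecs, axis=0)
    return SpectralDecomposition(
        n=n, k=k, eigenvalues=vals, eigenvectors=_fix_signs(vecs)
    )


def default_truncation(n: int) -> int | str:
    """Full spectrum for small graphs, 200 smallest pairs beyond that."""
    return "full" if n <= 2000 else min(n, 200)


def heat_kernel(dec: SpectralDecomposition, t: float) -> HeatKernel:
    """``H[i,j] = sum_k exp(-lambda_k t) phi_k(i) phi_k(j)`` over retained k."""
    if t < 0:
        raise ValueError(f"diffusion time must be >= 0, got {t}")
    scaled = dec.eigenvectors * np.exp(-dec.eigenvalues * t)[None, :]
    H = scaled @ dec.eigenvectors.T
    return HeatKernel(t=float(t), H=(H + H.T) / 2.0, k_used=dec.k)


def average_temperature(kernel: HeatKernel) -> TemperatureVector:
    """Row sums of the heat kernel with the diagonal excluded."""
    H = kernel.H
    return TemperatureVector(temp=H.sum(axis=1) - np.diagonal(H))


def heat_distance(kernel: HeatKernel, labels: Sequence = ()) -> HeatDistanceMatrix:
    """Kernel-induced squared distance ``H(i,i) + H(j,j) - 2 H(i,j)``."""
    H = kernel.H
    d = np.diagonal(H)
    D = d[:, None] + d[None, :] - 2.0 * H
    np.fill_diagonal(D, 0.0)
    return HeatDistanceMatrix(D=(D + D.T) / 2.0, labels=tuple(labels))


def heat_coordinates(
    dec: SpectralDecomposition, t: float, k: int | None = None
) -> EmbeddingCoordinates:
    """Embedding whose axes are ``exp(-lambda_j t / 2) phi_j``.

    Squared Euclidean distances between rows reproduce the heat distance
    when the full spectrum is kept.
    """
    if t < 0:
        raise ValueError(f"diffusion time must be >= 0, got {t}")
    if k is None:
        k = dec.k
    if not 1 <= k <= dec.k:
        raise ValueError(f"dimension k={k} exceeds retained spectrum size {dec.k}")
    coords = dec.eigenvectors[:, :k] * np.exp(-dec.eigenvalues[:k] * t / 2.0)[None, :]
    return EmbeddingCoordinates(dim=k, coords=coords)


def rank_by_heat_distance(D: HeatDistanceMatrix, query: Hashable) -> list:
    """Nodes sorted by ascending heat distance to ``query``.

    Ties are broken by ascending node label; the query itself comes first.
    """
    labels = D.labels if D.labels else tuple(range(1, D.D.shape[0] + 1))
    try:
        q = labels.index(query)
    except ValueError:
        raise KeyError(f"unknown query label {query!r}") from None
    row = D.D[q]
    order = sorted(range(len(labels)), key=lambda i: (row[i], labels[i]))
    return [labels[i] for i in order]


def distances_to_weights(
    D: np.ndarray, sigma: float | None = None, knn: int | None = None
) -> np.ndarray:
    """Gaussian affinity ``W_ij = exp(-d_ij^2 / sigma^2)`` with zero diagonal.

    ``sigma`` defaults to the median off-diagonal distance.  With ``knn``,
    weights outside the mutual k-nearest-neighbour graph are dropped.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("distance matrix must be square")
    off = D[~np.eye(n, dtype=bool)]
    if sigma is None:
        sigma = float(np.median(off))
        if sigma <= 0:
            sigma = 1.0
    W = np.exp(-(D ** 2) / sigma ** 2)
    np.fill_diagonal(W, 0.0)
    if knn is not None:
        keep = np.zeros_like(W, dtype=bool)
        for i in range(n):
            nearest = np.argsort(D[i])[: knn + 1]
            keep[i, nearest] = True
        keep &= keep.T  # mutual kNN
        W = np.where(keep, W, 0.0)
        np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0
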