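"""Common-line distance between projection images.

By the Fourier slice theorem, two projections of the same 3-D object share
a line through the origin of their 2-D Fourier transforms.  Each image is
resampled into polar Fourier lines at a constant angular step; the distance
between two images is the best (smallest) line-to-line discrepancy over
all ordered line pairs.  The resulting distance matrix converts into a
Gaussian-affinity network ready for heat passing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import WeightedGraph, build_weighted_graph, distances_to_weights

__all__ = [
    "ProjectionImage",
    "PolarFourier",
    "ImageDistanceMatrix",
    "polar_fourier",
    "line_distance",
    "image_distance",
    "best_line_pair",
    "pairwise_image_distances",
    "build_image_network",
]

DEFAULT_N_LINES = 200


@dataclass(frozen=True)
class ProjectionImage:
    pixels: np.ndarray

    def __post_init__(self):
        px = self.pixels
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError("projection image must be a square 2-D grid")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite pixels")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass(frozen=True)
class PolarFourier:
    """Complex Fourier samples along rays from the origin.

    ``values[l, i]`` is the 2-D DFT of the image, bilinearly interpolated
    at radius ``i + 1`` (DC excluded) along the ray with angle
    ``l * delta_theta`` degrees.
    """

    n_lines: int
    delta_theta: float
    n_radial: int
    values: np.ndarray  # (n_lines, n_samples) complex
    r_min: int = 1


@dataclass(frozen=True)
class ImageDistanceMatrix:
    D: np.ndarray

    @property
    def m(self) -> int:
        return self.D.shape[0]


def _bilinear_complex(F: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Sample complex grid F at fractional (row=y, col=x) positions."""
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx, fy = x - x0, y - y0
    # upper neighbour clipped at the grid edge (reached only with weight ~0)
    x1 = np.minimum(x0 + 1, F.shape[1] - 1)
    y1 = np.minimum(y0 + 1, F.shape[0] - 1)
    return (
        F[y0, x0] * (1 - fx) * (1 - fy)
        + F[y0, x1] * fx * (1 - fy)
        + F[y1, x0] * (1 - fx) * fy
        + F[y1, x1] * fx * fy
    )


def polar_fourier(
    img: ProjectionImage,
    n_lines: int = DEFAULT_N_LINES,
    n_radial: int | None = None,
    r_min: int = 1,
) -> PolarFourier:
    """Polar resampling of the centered 2-D DFT of a mean-subtracted image.

    ``n_lines`` rays spanning 360 degrees at constant step; each ray is
    sampled at integer radii ``r_min .. n_radial`` (DC excluded; default
    outer radius ``floor(s/2) - 1``).  Raising ``r_min`` drops the radii
    nearest the origin, whose interpolation straddles the zeroed DC bin.
    """
    s = img.size
    if s < 8:
        raise ValueError("image side must be at least 8 pixels")
    if n_lines < 2:
        raise ValueError("need at least 2 lines")
    if n_radial is None:
        n_radial = s // 2 - 1
    if n_radial > s // 2:
        raise ValueError(f"n_radial={n_radial} beyond Nyquist limit {s // 2}")
    if not 1 <= r_min < n_radial:
        raise ValueError(f"need 1 <= r_min < n_radial, got r_min={r_min}")
    pixels = img.pixels - img.pixels.mean()
    # ifftshift puts the image-center pixel (s//2, s//2) at the DFT origin so
    # line values carry no angle-dependent phase ramp
    F = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(pixels)))
    center = s // 2
    delta_theta = 360.0 / n_lines
    theta = np.deg2rad(np.arange(n_lines) * delta_theta)
    radii = np.arange(r_min, n_radial + 1, dtype=float)
    x = center + np.cos(theta)[:, None] * radii[None, :]
    y = center + np.sin(theta)[:, None] * radii[None, :]
    values = _bilinear_complex(F, x, y)
    return PolarFourier(
        n_lines=n_lines,
        delta_theta=delta_theta,
        n_radial=n_radial,
        values=values,
        r_min=r_min,
    )


def line_distance(a: np.ndarray, b: np.ndarray, literal: bool = False) -> float:
    """Mean per-sample modulus of the difference of two complex lines.

    ``literal=True`` instead takes the modulus of the *summed* difference
    (an alternative reading of the same discrepancy; it cannot separate
    lines whose sample sums agree and is provided for comparison only).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"line lengths differ: {a.shape} vs {b.shape}")
    n = a.shape[-1]
    if literal:
        return float(np.abs((a - b).sum()) / n)
    return float(np.abs(a - b).mean())


def _line_distance_table(
    A: PolarFourier, B: PolarFourier, magnitude_only: bool, literal: bool
) -> np.ndarray:
    """All line-to-line distances between two polar transforms, (L, L)."""
    va, vb = A.values, B.values
    if magnitude_only:
        va, vb = np.abs(va), np.abs(vb)
    diff = va[:, None, :] - vb[None, :, :]
    if literal:
        return np.abs(diff.sum(axis=2)) / va.shape[1]
    return np.abs(diff).mean(axis=2)


def _check_compatible(A: PolarFourier, B: PolarFourier) -> None:
    if A.values.shape != B.values.shape:
        raise ValueError(
            f"polar transforms differ: {A.values.shape} vs {B.values.shape}"
        )


def image_distance(
    A: PolarFourier,
    B: PolarFourier,
    magnitude_only: bool = False,
    literal: bool = False,
) -> float:
    """Smallest line-to-line distance over all ordered line pairs.

    The best-matching pair of lines is the putative common line; two
    projections of the same object score near zero there.
    ``magnitude_only`` compares moduli, making the score invariant to
    image center shifts (which add phase ramps along lines).
    """
    _check_compatible(A, B)
    return float(_line_distance_table(A, B, magnitude_only, literal).min())


def best_line_pair(
    A: PolarFourier, B: PolarFourier, magnitude_only: bool = False
) -> tuple[int, int, float]:
    """Indices (and distance) of the best-matching line pair."""
    _check_compatible(A, B)
    table = _line_distance_table(A, B, magnitude_only, literal=False)
    l1, l2 = np.unravel_index(np.argmin(table), table.shape)
    return int(l1), int(l2), float(table[l1, l2])


def pairwise_image_distances(
    images,
    n_lines: int = DEFAULT_N_LINES,
    n_radial: int | None = None,
    r_min: int = 1,
    magnitude_only: bool = False,
) -> ImageDistanceMatrix:
    """Full symmetric matrix of common-line distances for an image set."""
    images = [
        im if isinstance(im, ProjectionImage) else ProjectionImage(np.asarray(im, float))
        for im in images
    ]
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    sizes = {im.size for im in images}
    if len(sizes) > 1:
        raise ValueError(f"images have mixed sizes {sorted(sizes)}")
    pfs = [
        polar_fourier(im, n_lines=n_lines, n_radial=n_radial, r_min=r_min)
        for im in images
    ]
    m = len(pfs)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = image_distance(
                pfs[i], pfs[j], magnitude_only=magnitude_only
            )
    return ImageDistanceMatrix(D=D)


def build_image_network(
    images,
    n_lines: int = DEFAULT_N_LINES,
    n_radial: int | None = None,
    r_min: int = 1,
    magnitude_only: bool = False,
    sigma: float | None = None,
    knn: int | None = None,
) -> WeightedGraph:
    """Common-line distances -> Gaussian-affinity weighted graph.

    ``W_ij = exp(-D_ij^2 / sigma^2)`` with sigma defaulting to the median
    off-diagonal distance; diagonal zeroed.  With ``knn`` the graph is
    sparsified to mutual k-nearest neighbours (any node isolated by the
    sparsification is reconnected to its nearest neighbour so the
    normalized Laplacian stays defined).  Output feeds directly into the
    heat-passing pipeline.
    """
    dm = pairwise_image_distances(
        images,
        n_lines=n_lines,
        n_radial=n_radial,
        r_min=r_min,
        magnitude_only=magnitude_only,
    )
    W = distances_to_weights(dm.D, sigma=sigma, knn=knn)
    if knn is not None:
        for i in np.flatnonzero(W.sum(axis=1) == 0):
            order = np.argsort(dm.D[i])
            j = order[1] if order[0] == i else order[0]
            W[i, j] = W[j, i] = np.exp(-1.0)
    return build_weighted_graph(W)
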