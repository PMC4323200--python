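"""Built-in datasets and simulators.

Everything the rest of the package is demonstrated and tested on lives
here: the Zachary karate-club network with its observed factional split,
planted-partition (stochastic block) random graphs, and a two-state 3-D
Gaussian-blob phantom whose noisy random-view projections emulate a
heterogeneous single-particle imaging experiment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .commonline import ProjectionImage
from .evaluation import LabeledPartition
from .graph_core import WeightedGraph, build_weighted_graph

__all__ = [
    "karate_graph",
    "karate_factions",
    "planted_partition_graph",
    "PhantomVolume",
    "SimulatedImageSet",
    "default_phantom",
    "make_two_state_dataset",
    "common_line_ground_truth",
    "line_angle_error",
]

# Zachary's karate club: 34 members, 78 unweighted friendship edges,
# node numbering 1..34 (1 = instructor, 34 = club president).
_KARATE_EDGES = """
1 2; 1 3; 1 4; 1 5; 1 6; 1 7; 1 8; 1 9; 1 11; 1 12; 1 13; 1 14; 1 18;
1 20; 1 22; 1 32; 2 3; 2 4; 2 8; 2 14; 2 18; 2 20; 2 22; 2 31; 3 4;
3 8; 3 9; 3 10; 3 14; 3 28; 3 29; 3 33; 4 8; 4 13; 4 14; 5 7; 5 11;
6 7; 6 11; 6 17; 7 17; 9 31; 9 33; 9 34; 10 34; 14 34; 15 33; 15 34;
16 33; 16 34; 19 33; 19 34; 20 34; 21 33; 21 34; 23 33; 23 34; 24 26;
24 28; 24 30; 24 33; 24 34; 25 26; 25 28; 25 32; 26 32; 27 30; 27 34;
28 34; 29 32; 29 34; 30 33; 30 34; 31 33; 31 34; 32 33; 32 34; 33 34
"""

# Observed post-split factions (leader labels): member 9 sided with the
# instructor's faction during the conflict although he later joined the
# president's club for rank reasons.
_KARATE_FACTION_34 = frozenset(
    {10, 15, 16, 19, 21, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34}
)


def karate_graph() -> WeightedGraph:
    """The 34-node Zachary karate-club network with unit edge weights."""
    edges = []
    for chunk in _KARATE_EDGES.replace("\n", " ").split(";"):
        chunk = chunk.strip()
        if chunk:
            i, j = chunk.split()
            edges.append((int(i), int(j), 1.0))
    return build_weighted_graph(edges, labels=range(1, 35))


def karate_factions() -> LabeledPartition:
    """Observed factional split, labeled by faction leader (1 or 34),
    ordered by node label 1..34."""
    return LabeledPartition.from_sequence(
        34 if i in _KARATE_FACTION_34 else 1 for i in range(1, 35)
    )


def planted_partition_graph(
    block_sizes, p_in: float, p_out: float, seed: int
) -> tuple[WeightedGraph, LabeledPartition]:
    """Bernoulli random graph with planted blocks.

    Edges appear independently with probability ``p_in`` within a block
    and ``p_out`` across blocks.  A node left with zero degree gets one
    extra within-block edge (with a warning) so the normalized Laplacian
    stays defined.  Deterministic given ``seed``.
    """
    if not 0 <= p_out < p_in <= 1:
        raise ValueError("need 0 <= p_out < p_in <= 1")
    block_sizes = [int(b) for b in block_sizes]
    if any(b < 1 for b in block_sizes):
        raise ValueError("block sizes must be positive")
    rng = np.random.default_rng(seed)
    membership = np.repeat(np.arange(len(block_sizes)), block_sizes)
    n = membership.size
    same = membership[:, None] == membership[None, :]
    probs = np.where(same, p_in, p_out)
    upper = np.triu(rng.random((n, n)) < probs, k=1)
    W = (upper | upper.T).astype(float)
    degrees = W.sum(axis=1)
    for i in np.flatnonzero(degrees == 0):
        mates = np.flatnonzero((membership == membership[i]) & (np.arange(n) != i))
        pool = mates if mates.size else np.flatnonzero(np.arange(n) != i)
        j = int(rng.choice(pool))
        W[i, j] = W[j, i] = 1.0
        warnings.warn(f"node {i + 1} had zero degree; added edge to {j + 1}")
    graph = build_weighted_graph(W)
    return graph, LabeledPartition.from_sequence(membership.tolist())


def planted_affinity_problem(
    block_sizes,
    seed: int,
    within=(0.8, 1.2),
    between=(0.01, 0.04),
    pref: float = 0.1,
):
    """Block-structured affinity problem for exemplar-clustering tests.

    Off-diagonal affinities are sampled uniformly from ``within`` inside a
    block and ``between`` across blocks (symmetrized), so the
    within/between ratio stays >= 10 by construction; the diagonal holds a
    flat preference.  Returns an :class:`~heatpass.heat_passing.AffinityProblem`.
    """
    from .heat_passing import AffinityProblem

    rng = np.random.default_rng(seed)
    block_sizes = [int(b) for b in block_sizes]
    n = sum(block_sizes)
    member = np.repeat(np.arange(len(block_sizes)), block_sizes)
    W = rng.uniform(*within, (n, n))
    B = rng.uniform(*between, (n, n))
    S = np.where(member[:, None] == member[None, :], W, B)
    S = (S + S.T) / 2.0
    np.fill_diagonal(S, pref)
    return AffinityProblem(n=n, S=S)


@dataclass(frozen=True)
class PhantomVolume:
    """Sum of isotropic 3-D Gaussian blobs inside a unit box.

    ``blobs`` rows are (cx, cy, cz, width, amplitude) with centers and
    widths in box-fraction units (centers in [-0.5, 0.5]).
    """

    blobs: np.ndarray
    state_id: int = 0

    def render(self, v: int) -> np.ndarray:
        """Densities on a v^3 voxel grid (for inspection; projections are
        computed analytically, not from this grid)."""
        ax = (np.arange(v) - v / 2.0 + 0.5) / v
        X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
        grid = np.zeros((v, v, v))
        for cx, cy, cz, w, a in self.blobs:
            r2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
            grid += a * np.exp(-r2 / (2.0 * w ** 2))
        return grid

    def project(self, R: np.ndarray, size: int, shift=(0, 0)) -> np.ndarray:
        """Analytic projection along the viewing axis of rotation ``R``.

        The image at (x, y) integrates the rotated density along z; each
        isotropic blob projects to a 2-D Gaussian of the same width whose
        center is the in-plane part of the rotated blob center.  ``shift``
        translates the image in pixels.
        """
        ax = np.arange(size) - size // 2  # origin on the (s//2, s//2) pixel
        X, Y = np.meshgrid(ax, ax, indexing="xy")
        img = np.zeros((size, size))
        for cx, cy, cz, w, a in self.blobs:
            c = R @ np.array([cx, cy, cz])
            px = c[0] * size + shift[0]
            py = c[1] * size + shift[1]
            sig = w * size
            amp = a * sig * math.sqrt(2.0 * math.pi)
            img += amp * np.exp(
                -((X - px) ** 2 + (Y - py) ** 2) / (2.0 * sig ** 2)
            )
        return img


# Blob table shared by both conformations.  Uniform widths keep the radial
# power profile predictable so the common-line band (radii ~2-10 at s=64)
# carries most of the signal energy.
_BASE_BLOBS = np.array(
    [
        #     cx         cy         cz     width     amp
        [-0.222858, -0.000433,  0.060899, 0.034, 0.986829],
        [-0.282787, -0.211244,  0.256927, 0.034, 0.910858],
        [-0.257748, -0.222136,  0.268997, 0.034, 0.833247],
        [ 0.073130, -0.078604,  0.006834, 0.034, 1.158378],
        [ 0.097706, -0.134815, -0.217219, 0.034, 0.971979],
        [ 0.172824,  0.102216,  0.007429, 0.034, 0.859077],
        [ 0.190042,  0.029445,  0.288548, 0.034, 1.069345],
        [-0.177294,  0.032238, -0.009825, 0.034, 0.880886],
        [-0.088035,  0.054957, -0.158819, 0.034, 1.160572],
        [ 0.181322,  0.220400, -0.222744, 0.034, 0.886859],
    ]
)
RATCHET_DEGREES = 40.0


def default_phantom(state: int, ratchet_degrees: float = RATCHET_DEGREES,
                    displacement=None) -> PhantomVolume:
    """Two-conformation phantom.

    State 1 rigidly rotates the upper (cz > 0) blobs about the z axis —
    a ratcheting-subunit-style global rearrangement that every projection
    direction sees — and optionally displaces blob 0 on top of that.
    """
    if state not in (0, 1):
        raise ValueError("state must be 0 or 1")
    blobs = _BASE_BLOBS.copy()
    if state == 1:
        R = Rotation.from_euler("z", ratchet_degrees, degrees=True).as_matrix()
        moving = blobs[:, 2] > 0
        blobs[moving, :3] = blobs[moving, :3] @ R.T
        if displacement is not None:
            blobs[0, :3] += np.asarray(displacement, dtype=float)
    return PhantomVolume(blobs=blobs, state_id=state)


@dataclass(frozen=True)
class SimulatedImageSet:
    """Noisy random-view projections of two phantom conformations with
    full ground truth (state, rotation, shift) retained per image."""

    images: list
    true_state: np.ndarray        # (m,) 0/1
    rotations: np.ndarray         # (m, 3, 3)
    shifts: np.ndarray            # (m, 2) integer pixels
    snr: float
    max_shift_frac: float
    seed: int
    noise_sigma: np.ndarray = field(default=None)

    @property
    def m(self) -> int:
        return len(self.images)

    @property
    def true_angles(self) -> np.ndarray:
        """Euler angles (zyz, degrees) of each viewing orientation."""
        return Rotation.from_matrix(self.rotations).as_euler("zyz", degrees=True)


def make_two_state_dataset(
    n_per_state: int,
    image_size: int = 64,
    snr: float = 1.0,
    max_shift_frac: float = 0.06,
    seed: int = 0,
    ratchet_degrees: float = RATCHET_DEGREES,
    displacement=None,
) -> SimulatedImageSet:
    """Simulate ``2 * n_per_state`` projections of the two-state phantom.

    Per image: a uniform random orientation, an analytic projection, an
    integer center shift uniform within ``max_shift_frac * image_size``
    per axis, then zero-mean Gaussian noise with variance
    ``var(signal) / snr`` (SNR defined as signal variance over noise
    variance; ``snr=inf`` disables noise).  Bit-reproducible given
    ``seed``.
    """
    if n_per_state < 1:
        raise ValueError("n_per_state must be >= 1")
    if not snr > 0:
        raise ValueError(f"snr must be positive, got {snr}")
    rng = np.random.default_rng(seed)
    volumes = [
        default_phantom(0),
        default_phantom(1, ratchet_degrees=ratchet_degrees, displacement=displacement),
    ]
    m = 2 * n_per_state
    states = np.repeat([0, 1], n_per_state)
    rotations = Rotation.random(m, rng=rng).as_matrix()
    max_shift = int(max_shift_frac * image_size)
    shifts = rng.integers(-max_shift, max_shift + 1, size=(m, 2))
    images = []
    sigmas = np.zeros(m)
    for i in range(m):
        clean = volumes[states[i]].project(
            rotations[i], image_size, shift=shifts[i]
        )
        if math.isinf(snr):
            noisy = clean
        else:
            sigmas[i] = math.sqrt(clean.var() / snr)
            noisy = clean + rng.normal(0.0, sigmas[i], size=clean.shape)
        images.append(ProjectionImage(pixels=noisy))
    return SimulatedImageSet(
        images=images,
        true_state=states,
        rotations=rotations,
        shifts=shifts,
        snr=snr,
        max_shift_frac=max_shift_frac,
        seed=seed,
        noise_sigma=sigmas,
    )


def common_line_ground_truth(Ra: np.ndarray, Rb: np.ndarray) -> tuple[float, float]:
    """In-plane angles (degrees, mod 360) of the true common line of two
    viewing orientations, derived from the slice geometry.

    The central Fourier slice of view ``R`` spans the first two rows of
    ``R``; the slices intersect along the cross product of the two slice
    normals (third rows).
    """
    n_a, n_b = Ra[2], Rb[2]
    c = np.cross(n_a, n_b)
    norm = np.linalg.norm(c)
    if norm < 1e-12:
        raise ValueError("views share a projection axis; common line undefined")
    c = c / norm
    alpha_a = math.degrees(math.atan2(float(c @ Ra[1]), float(c @ Ra[0]))) % 360.0
    alpha_b = math.degrees(math.atan2(float(c @ Rb[1]), float(c @ Rb[0]))) % 360.0
    return alpha_a, alpha_b


def line_angle_error(measured_deg: float, truth_deg: float) -> float:
    """Angular error between two line directions, folded to [0, 90]."""
    d = abs(measured_deg - truth_deg) % 180.0
    return min(d, 180.0 - d)
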