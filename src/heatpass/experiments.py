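"""Prepackaged experiment pipelines used by the test suite and reports.

These wire the simulators to the clustering/evaluation stack with the
parameter sets used in the benchmark studies: the karate-club community
run, planted-partition recovery and the two-state phantom SNR sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .commonline import pairwise_image_distances, best_line_pair, polar_fourier
from .evaluation import accuracy_index, quality_index, rand_index
from .graph_core import build_weighted_graph, distances_to_weights
from .heat_passing import ClusteringResult, cluster_graph
from .synthetic_data import (
    common_line_ground_truth,
    karate_factions,
    karate_graph,
    line_angle_error,
    make_two_state_dataset,
)

__all__ = [
    "karate_experiment",
    "TwoStateOutcome",
    "two_state_experiment",
    "common_line_error_stats",
]

# polar-transform band for 64-px phantom images: the blob spectrum carries
# most of its energy at radii ~2-10
PHANTOM_N_LINES = 72
PHANTOM_N_RADIAL = 10
PHANTOM_R_MIN = 2
PHANTOM_KNN = 15
PHANTOM_TIME = 8.0


def karate_experiment(t: float = 4.0):
    """Cluster the karate club with defaults; returns (graph, result,
    per-node center labels, node labels disagreeing with the observed
    factional split)."""
    g = karate_graph()
    result = cluster_graph(g, t=t)
    assigned = result.assignment_labels()
    truth = karate_factions().labels
    disagree = [
        lab for lab, a, tr in zip(g.labels, assigned, truth) if a != tr
    ]
    return g, result, assigned, disagree


@dataclass(frozen=True)
class TwoStateOutcome:
    snr: float
    n_clusters: int
    ai: float
    ri: float
    qi: float
    result: ClusteringResult


def two_state_experiment(
    n_per_state: int,
    snr: float,
    seed: int,
    image_size: int = 64,
    n_lines: int = PHANTOM_N_LINES,
    knn: int | None = PHANTOM_KNN,
    t: float = PHANTOM_TIME,
    pref_scale: float = 0.1,
) -> TwoStateOutcome:
    """Full pipeline: simulate -> common-line distances -> heat passing.

    Images are generated without center shifts: complex-valued line
    comparison needs a common origin, and shift compensation is out of
    scope at this image size.
    """
    ds = make_two_state_dataset(
        n_per_state, image_size=image_size, snr=snr, max_shift_frac=0.0,
        seed=seed,
    )
    dm = pairwise_image_distances(
        ds.images, n_lines=n_lines, n_radial=PHANTOM_N_RADIAL,
        r_min=PHANTOM_R_MIN,
    )
    W = distances_to_weights(dm.D, knn=knn)
    if knn is not None:
        for i in np.flatnonzero(W.sum(axis=1) == 0):
            order = np.argsort(dm.D[i])
            j = order[1] if order[0] == i else order[0]
            W[i, j] = W[j, i] = np.exp(-1.0)
    g = build_weighted_graph(W)
    result = cluster_graph(g, t=t, pref_scale=pref_scale)
    pred = result.membership()
    return TwoStateOutcome(
        snr=snr,
        n_clusters=result.n_clusters,
        ai=accuracy_index(pred, ds.true_state),
        ri=rand_index(pred, ds.true_state),
        qi=quality_index(dm.D, pred) if result.n_clusters >= 2 else 0.5,
        result=result,
    )


def common_line_error_stats(
    snr: float,
    seed: int,
    n_images: int = 24,
    image_size: int = 64,
    n_lines: int = PHANTOM_N_LINES,
) -> tuple[float, float]:
    """(mean common-line angle error in degrees, fraction within 5 deg)
    over all pairs of one-state noisy projections, against the geometric
    ground truth from the known viewing orientations."""
    ds = make_two_state_dataset(
        n_images, image_size=image_size, snr=snr, max_shift_frac=0.0,
        seed=seed,
    )
    images = ds.images[:n_images]  # single conformation
    pfs = [
        polar_fourier(im, n_lines=n_lines, n_radial=PHANTOM_N_RADIAL,
                      r_min=PHANTOM_R_MIN)
        for im in images
    ]
    step = 360.0 / n_lines
    errors = []
    for i in range(n_images):
        for j in range(i + 1, n_images):
            l1, l2, _ = best_line_pair(pfs[i], pfs[j])
            truth_a, truth_b = common_line_ground_truth(
                ds.rotations[i], ds.rotations[j]
            )
            err = 0.5 * (
                line_angle_error(l1 * step, truth_a)
                + line_angle_error(l2 * step, truth_b)
            )
            errors.append(err)
    errors = np.asarray(errors)
    return float(errors.mean()), float((errors <= 5.0).mean())
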