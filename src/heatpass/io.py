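"""Readers and writers for the on-disk formats the CLI speaks.

Edge lists are 2/3-column TSV with ``#`` comments; matrices are CSV with
an optional label header row+column; cluster tables and labelings are TSV.
Image stacks come either as a directory of per-image CSV grids or as a
minimal single-stack MRC file (mode-2 float, handled here directly since
no MRC library is assumed).
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .graph_core import (
    WeightedGraph,
    build_weighted_graph,
    distances_to_weights,
)

__all__ = [
    "read_edgelist",
    "read_matrix_csv",
    "load_graph",
    "write_clusters",
    "read_labels_tsv",
    "write_matrix_csv",
    "read_image_stack",
    "write_image_stack",
    "read_mrc",
    "write_mrc",
]


def read_edgelist(path) -> list[tuple]:
    """TSV edge list: source, target[, weight]; '#' starts a comment."""
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", "\t").split()
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns")
            i, j = (_coerce_label(p) for p in parts[:2])
            w = float(parts[2]) if len(parts) == 3 else 1.0
            edges.append((i, j, w))
    if not edges:
        raise ValueError(f"{path}: empty edge list")
    return edges


def _coerce_label(token: str):
    try:
        return int(token)
    except ValueError:
        return token


def read_matrix_csv(path) -> tuple[np.ndarray, tuple | None]:
    """Square CSV matrix; detects an optional label header row/column."""
    df = pd.read_csv(path, header=None)
    try:
        values = df.to_numpy(dtype=float)
        return values, None
    except (TypeError, ValueError):
        pass
    df = pd.read_csv(path, index_col=0)
    labels = tuple(_coerce_label(str(x)) for x in df.index)
    return df.to_numpy(dtype=float), labels


def load_graph(path, fmt: str = "edgelist", sigma: float | None = None,
               knn: int | None = None) -> WeightedGraph:
    """Load a graph in any supported input format.

    ``fmt``: ``edgelist`` | ``weight`` (matrix used as-is) | ``distance``
    (Gaussian-affinity conversion) | ``similarity`` (off-diagonal used as
    weights, diagonal zeroed).
    """
    if fmt == "edgelist":
        return build_weighted_graph(read_edgelist(path))
    M, labels = read_matrix_csv(path)
    if fmt == "weight":
        return build_weighted_graph(M, labels=labels)
    if fmt == "distance":
        W = distances_to_weights(M, sigma=sigma, knn=knn)
        return build_weighted_graph(W, labels=labels)
    if fmt == "similarity":
        W = (M + M.T) / 2.0
        np.fill_diagonal(W, 0.0)
        return build_weighted_graph(W, labels=labels)
    raise ValueError(f"unknown input format {fmt!r}")


def write_clusters(path, labels, center_labels, centers) -> None:
    center_set = set(centers)
    df = pd.DataFrame(
        {
            "label": list(labels),
            "center_label": list(center_labels),
            "is_center": [int(l in center_set) for l in labels],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_labels_tsv(path) -> tuple[list, list]:
    """Two-column TSV (element label, cluster label); header optional."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least 2 TSV columns")
    col0, col1 = df.columns[:2]
    return (
        [_coerce_label(str(x)) for x in df[col0]],
        [_coerce_label(str(x)) for x in df[col1]],
    )


def write_matrix_csv(path, M: np.ndarray, labels=None) -> None:
    if labels is None:
        pd.DataFrame(M).to_csv(path, header=False, index=False)
    else:
        pd.DataFrame(M, index=list(labels), columns=list(labels)).to_csv(path)


# -- image stacks -----------------------------------------------------------

def read_image_stack(path) -> list[np.ndarray]:
    """A stack of square grayscale images.

    Accepts a directory of per-image CSV grids (sorted by filename) or a
    single ``.mrc`` file.
    """
    p = Path(path)
    if p.is_dir():
        files = sorted(q for q in p.iterdir() if q.suffix.lower() == ".csv")
        if not files:
            raise ValueError(f"{path}: no per-image .csv files found")
        return [np.loadtxt(f, delimiter=",", ndmin=2) for f in files]
    if p.suffix.lower() == ".mrc":
        return list(read_mrc(p))
    raise ValueError(f"{path}: expected a directory of CSVs or an .mrc stack")


def write_image_stack(path, images) -> None:
    """Write images as per-image CSVs into a directory (or one MRC file)."""
    p = Path(path)
    arrays = [np.asarray(getattr(im, "pixels", im), dtype=float) for im in images]
    if p.suffix.lower() == ".mrc":
        write_mrc(p, np.stack(arrays))
        return
    p.mkdir(parents=True, exist_ok=True)
    width = len(str(len(arrays) - 1))
    for i, arr in enumerate(arrays):
        np.savetxt(p / f"image_{i:0{width}d}.csv", arr, delimiter=",")


_MRC_HEADER_BYTES = 1024


def read_mrc(path) -> np.ndarray:
    """Minimal MRC2014 reader: mode-2 (float32) volumes/stacks only."""
    with open(path, "rb") as fh:
        header = fh.read(_MRC_HEADER_BYTES)
        if len(header) < _MRC_HEADER_BYTES:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz, mode = struct.unpack("<4i", header[:16])
        if mode != 2:
            raise ValueError(f"{path}: unsupported MRC mode {mode} (only 2/float32)")
        nsymbt = struct.unpack("<i", header[92:96])[0]
        fh.seek(_MRC_HEADER_BYTES + nsymbt)
        data = np.frombuffer(fh.read(4 * nx * ny * nz), dtype="<f4")
    if data.size != nx * ny * nz:
        raise ValueError(f"{path}: truncated MRC data block")
    return data.reshape(nz, ny, nx).astype(float)


def write_mrc(path, stack: np.ndarray) -> None:
    """Minimal MRC2014 writer (mode 2, float32)."""
    stack = np.asarray(stack, dtype="<f4")
    if stack.ndim == 2:
        stack = stack[None]
    nz, ny, nx = stack.shape
    header = bytearray(_MRC_HEADER_BYTES)
    struct.pack_into("<4i", header, 0, nx, ny, nz, 2)
    struct.pack_into("<3i", header, 28, nx, ny, nz)   # mx, my, mz
    struct.pack_into("<3f", header, 40, nx, ny, nz)   # cell dims
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)      # axis order
    struct.pack_into("<3f", header, 76, float(stack.min()), float(stack.max()),
                     float(stack.mean()))
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"             # little-endian stamp
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(stack.tobytes())
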