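"""Coordinate bookkeeping and local geometric frames.

This module owns everything about raw 3D coordinates: removing and restoring
the center of mass, building deterministic k-nearest-neighbor graph topology,
and constructing the per-edge orthonormal frames that make scalar features
chirality-sensitive.

A frame for a directed edge (i, j) over *centered* coordinates is the triple

    a_ij = (x_i - x_j) / ||x_i - x_j||
    b_ij = (x_i x x_j) / ||x_i x x_j||      (cross product)
    c_ij = a_ij x b_ij

which is orthonormal and right-handed whenever x_i, x_j are not collinear
with the origin.  Under a rotation Q all three axes rotate by Q; under point
inversion the axes pick up signs (-, +, -).  That sign pattern is what lets
scalar features built from frame projections distinguish a molecule from its
mirror image, while remaining rotation-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import special_ortho_group

__all__ = [
    "centralize",
    "decentralize",
    "knn_graph",
    "Frames",
    "localize",
    "random_rotation",
    "random_rigid_motion",
    "read_xyz",
    "write_xyz",
    "frames_to_csv",
]


def _check_coords(x: np.ndarray, name: str = "X") -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != 3:
        raise ValueError(f"{name} must be an N x 3 array, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name} contains non-finite coordinates")
    return x


def centralize(x: np.ndarray, graph_id: np.ndarray | None = None,
               n_graphs: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Remove the (unit-mass) center of mass from node positions.

    Parameters
    ----------
    x
        N x 3 coordinates.
    graph_id, n_graphs
        Optional batching: per-node graph membership.  Each graph in the
        disjoint union is centered independently and ``center`` has one row
        per graph.  Without them the whole cloud is one graph and ``center``
        has shape (1, 3).

    Returns
    -------
    (x_centered, center)
    """
    x = _check_coords(x)
    if x.shape[0] < 1:
        raise ValueError("need at least one node")
    if graph_id is None:
        center = x.mean(axis=0, keepdims=True)
        return x - center, center
    graph_id = np.asarray(graph_id, dtype=np.intp)
    if n_graphs is None:
        n_graphs = int(graph_id.max()) + 1
    counts = np.bincount(graph_id, minlength=n_graphs).astype(np.float64)
    acc = np.zeros((n_graphs, 3))
    np.add.at(acc, graph_id, x)
    center = acc / counts[:, None]
    return x - center[graph_id], center


def decentralize(x_centered: np.ndarray, center: np.ndarray,
                 graph_id: np.ndarray | None = None) -> np.ndarray:
    """Add the center of mass back; exact inverse of :func:`centralize`."""
    x_centered = _check_coords(x_centered, "x_centered")
    center = np.asarray(center, dtype=np.float64)
    if center.ndim == 1:
        center = center[None, :]
    if center.shape[1] != 3:
        raise ValueError(f"center must have 3 columns, got shape {center.shape}")
    if graph_id is None:
        if center.shape[0] != 1:
            raise ValueError("multi-row center requires graph_id")
        return x_centered + center
    graph_id = np.asarray(graph_id, dtype=np.intp)
    return x_centered + center[graph_id]


def knn_graph(x: np.ndarray, k: int) -> np.ndarray:
    """Directed k-nearest-neighbor edges (i, j), j among the k nearest of i.

    Distances are compared in double precision with ties broken toward the
    lower node index (stable sort), so the topology is bit-reproducible.
    Returns an E x 2 integer array with E = N * min(k, N - 1); self-loops are
    excluded, duplicate coordinates are legal neighbors.
    """
    x = _check_coords(x)
    n = x.shape[0]
    if n < 2:
        raise ValueError("knn_graph needs at least 2 nodes")
    if k < 1:
        raise ValueError("k must be >= 1")
    k_eff = min(k, n - 1)
    d2 = np.sum((x[:, None, :] - x[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    # stable argsort => ties resolved toward the lower index
    order = np.argsort(d2, axis=1, kind="stable")[:, :k_eff]
    src = np.repeat(np.arange(n), k_eff)
    dst = order.reshape(-1)
    return np.stack([src, dst], axis=1).astype(np.int64)


@dataclass(frozen=True)
class Frames:
    """Per-edge right-handed orthonormal triple (a, b, c), each E x 3.

    ``degenerate`` marks edges whose centered endpoints are (near-)collinear
    with the origin; for those b and c are the zero vector rather than an
    arbitrary axis, so degenerate edges simply contribute nothing.
    """

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    degenerate: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        """E x 3 x 3 stack with rows (a, b, c) per edge."""
        return np.stack([self.a, self.b, self.c], axis=1)

    def __len__(self) -> int:
        return self.a.shape[0]


def localize(x_centered: np.ndarray, edges: np.ndarray, eps: float = 1e-8) -> Frames:
    """Build SO(3)-equivariant frames for each directed edge of centered coords.

    The caller must pass *centered* coordinates: the b axis depends on the
    absolute positions (it is the normal of the plane through the origin and
    both endpoints), so translation invariance is obtained by centering
    first, not by the formula itself.
    """
    x_centered = _check_coords(x_centered, "x_centered")
    edges = np.asarray(edges, dtype=np.intp)
    xi = x_centered[edges[:, 0]]
    xj = x_centered[edges[:, 1]]
    diff = xi - xj
    a = diff / np.sqrt(np.sum(diff**2, axis=1, keepdims=True) + eps**2)
    cross = np.cross(xi, xj)
    cross_norm = np.sqrt(np.sum(cross**2, axis=1, keepdims=True))
    degenerate = cross_norm[:, 0] < eps
    b = np.where(degenerate[:, None], 0.0,
                 cross / np.sqrt(cross_norm**2 + eps**2))
    c = np.cross(a, b)
    return Frames(a=a, b=b, c=c, degenerate=degenerate)


def random_rotation(seed_or_rng) -> np.ndarray:
    """A rotation matrix drawn uniformly (Haar) from SO(3)."""
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    return special_ortho_group.rvs(3, random_state=rng)


def random_rigid_motion(seed_or_rng) -> tuple[np.ndarray, np.ndarray]:
    """A reproducible random rigid motion: Haar rotation Q and translation g.

    The translation is uniform in [-10, 10]^3 (arbitrary length units).
    """
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    q = special_ortho_group.rvs(3, random_state=rng)
    g = rng.uniform(-10.0, 10.0, size=(1, 3))
    return q, g


# -- text I/O -------------------------------------------------------------


def read_xyz(path) -> tuple[list[str], np.ndarray, str]:
    """Read an XYZ file: (element symbols, N x 3 coordinates, comment line)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0].strip())
    comment = lines[1] if len(lines) > 1 else ""
    symbols, coords = [], []
    for line in lines[2:2 + n]:
        parts = line.split()
        symbols.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    return symbols, np.asarray(coords, dtype=np.float64), comment


def write_xyz(path, symbols, coords: np.ndarray, comment: str = "") -> None:
    coords = _check_coords(coords)
    if len(symbols) != coords.shape[0]:
        raise ValueError("one element symbol per coordinate row required")
    with open(path, "w") as fh:
        fh.write(f"{coords.shape[0]}\n{comment}\n")
        for sym, (px, py, pz) in zip(symbols, coords):
            fh.write(f"{sym} {px:.10f} {py:.10f} {pz:.10f}\n")


def frames_to_csv(path, edges: np.ndarray, frames: Frames) -> None:
    """Dump edges and their frame axes as a CSV table (debugging aid)."""
    import pandas as pd

    cols = {"src": edges[:, 0], "dst": edges[:, 1]}
    for name, arr in (("a", frames.a), ("b", frames.b), ("c", frames.c)):
        for axis, label in enumerate("xyz"):
            cols[f"{name}{label}"] = arr[:, axis]
    cols["degenerate"] = frames.degenerate.astype(int)
    pd.DataFrame(cols).to_csv(path, index=False)
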