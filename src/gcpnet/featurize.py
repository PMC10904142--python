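"""Turn raw point clouds into featurized graph states.

Feature families (all scalar features E(3)-invariant, all vector features
rotation-equivariant and translation-invariant):

* node scalars — one-hot particle/atom type, plus the speed ``||v||`` when
  velocities are present;
* node vectors — unit displacements to the previous and next node in the
  declared node order ("orientation" vectors, zero at the termini), plus the
  velocity vector when present;
* edge scalars — Gaussian radial-basis embedding of the edge length, plus a
  same-type/different-type one-hot when edge typing is enabled (for charged
  particles this encodes the sign of q_i * q_j);
* edge vectors — the unit displacement (x_i - x_j)/||x_i - x_j||.

Topology comes from the deterministic k-NN construction; coordinates are
kept raw — centering happens inside the network forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .gcp_core import ScalarVector
from .geometry import knn_graph
from .network import GraphState

__all__ = ["RawPointCloud", "FeaturizeConfig", "rbf_expand", "featurize_cloud",
           "dump_graph_state", "load_graph_state"]


@dataclass
class RawPointCloud:
    """Positions with per-node attributes, before any graph construction."""

    positions: np.ndarray                 # N x 3
    types: np.ndarray                     # N categorical labels (ints)
    velocities: np.ndarray | None = None  # N x 3, optional
    node_order: np.ndarray | None = None  # permutation; default = input order

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.types = np.asarray(self.types)
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=np.float64)
            if not np.all(np.isfinite(self.velocities)):
                raise ValueError("non-finite velocities")


@dataclass
class FeaturizeConfig:
    """Feature-construction switches and widths."""

    vocab: tuple = (0, 1)
    k: int = 4
    n_rbf: int = 16
    d_max: float = 10.0
    edge_types: bool = False     # append same/different type one-hot to edges
    use_scalars: bool = True     # False: 1-wide constant scalar channel
    use_vectors: bool = True     # False: no vector channels at all

    def node_widths(self, has_velocity: bool) -> tuple[int, int]:
        t = (len(self.vocab) + int(has_velocity)) if self.use_scalars else 1
        r = (2 + int(has_velocity)) if self.use_vectors else 0
        return t, r

    def edge_widths(self) -> tuple[int, int]:
        t = (self.n_rbf + 2 * int(self.edge_types)) if self.use_scalars else 1
        r = 1 if self.use_vectors else 0
        return t, r


def rbf_expand(d, n_basis: int, d_max: float) -> np.ndarray:
    """Gaussian radial basis values of distances ``d`` on [0, d_max].

    Centers are evenly spaced on [0, d_max] and the width equals the center
    spacing, so each basis function peaks at 1 on its own center.
    """
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    centers = np.linspace(0.0, d_max, n_basis)
    sigma = d_max / (n_basis - 1) if n_basis > 1 else d_max
    return np.exp(-((d[..., None] - centers) ** 2) / (2.0 * sigma**2))


def featurize_cloud(raw: RawPointCloud, config: FeaturizeConfig) -> GraphState:
    """Build a :class:`GraphState` from a raw cloud (one graph, unbatched)."""
    x = raw.positions
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes to build a graph")
    vocab = list(config.vocab)
    type_idx = np.empty(n, dtype=np.intp)
    for i, label in enumerate(raw.types):
        try:
            type_idx[i] = vocab.index(label)
        except ValueError:
            raise ValueError(
                f"unknown type label {label!r}; vocabulary is {vocab}"
            ) from None

    edges = knn_graph(x, config.k)
    src, dst = edges[:, 0], edges[:, 1]
    has_vel = raw.velocities is not None

    # node scalars
    if config.use_scalars:
        onehot = np.zeros((n, len(vocab)))
        onehot[np.arange(n), type_idx] = 1.0
        parts = [onehot]
        if has_vel:
            parts.append(np.linalg.norm(raw.velocities, axis=1, keepdims=True))
        node_s = np.concatenate(parts, axis=1)
    else:
        node_s = np.ones((n, 1))

    # node vectors: orientation along node_order (+ velocity)
    if config.use_vectors:
        order = (np.arange(n) if raw.node_order is None
                 else np.asarray(raw.node_order, dtype=np.intp))
        pos_ord = x[order]
        fwd = np.zeros((n, 3))
        bwd = np.zeros((n, 3))
        step = pos_ord[1:] - pos_ord[:-1]
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        unit = np.divide(step, norm, out=np.zeros_like(step), where=norm > 0)
        fwd[order[:-1]] = unit        # toward the next node in the order
        bwd[order[1:]] = -unit        # toward the previous node
        chans = [fwd[:, None, :], bwd[:, None, :]]
        if has_vel:
            chans.append(raw.velocities[:, None, :])
        node_v = np.concatenate(chans, axis=1)
    else:
        node_v = None

    # edge features
    disp = x[src] - x[dst]
    dist = np.linalg.norm(disp, axis=1)
    if config.use_scalars:
        parts = [rbf_expand(dist, config.n_rbf, config.d_max)]
        if config.edge_types:
            same = (type_idx[src] == type_idx[dst]).astype(np.float64)
            parts.append(np.stack([same, 1.0 - same], axis=1))
        edge_s = np.concatenate(parts, axis=1)
    else:
        edge_s = np.ones((edges.shape[0], 1))
    if config.use_vectors:
        unit_disp = disp / np.maximum(dist, 1e-12)[:, None]
        edge_v = unit_disp[:, None, :]
    else:
        edge_v = None

    return GraphState(
        node=ScalarVector(Tensor(node_s),
                          None if node_v is None else Tensor(node_v)),
        edge=ScalarVector(Tensor(edge_s),
                          None if edge_v is None else Tensor(edge_v)),
        X=x,
        edges=edges,
    )


def dump_graph_state(path, state) -> None:
    """Write a featurized graph as JSON (regression-test fixture format)."""
    import json

    payload = {
        "node_s": state.node.s.data.tolist(),
        "node_v": None if state.node.V is None else state.node.V.data.tolist(),
        "edge_s": state.edge.s.data.tolist(),
        "edge_v": None if state.edge.V is None else state.edge.V.data.tolist(),
        "X": state.X.tolist(),
        "edges": state.edges.tolist(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_graph_state(path):
    """Read a graph written by :func:`dump_graph_state`."""
    import json

    from .gcp_core import ScalarVector
    from .network import GraphState

    with open(path) as fh:
        payload = json.load(fh)
    as_tensor = lambda v: None if v is None else Tensor(np.asarray(v))
    return GraphState(
        node=ScalarVector(as_tensor(payload["node_s"]), as_tensor(payload["node_v"])),
        edge=ScalarVector(as_tensor(payload["edge_s"]), as_tensor(payload["edge_v"])),
        X=np.asarray(payload["X"], dtype=np.float64),
        edges=np.asarray(payload["edges"], dtype=np.int64),
    )
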