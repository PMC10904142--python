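"""Geometry-complete graph convolution and the full GCPNet forward pass.

The forward pass follows a fixed recipe: center the coordinates, build
per-edge frames once, embed raw node/edge features with one GCP each, run L
rounds of message passing (each round: per-edge messages from a stack of
omega GCPs on (dst || src || edge) features, mean-aggregated at the
receiving node, residual node update, optional equivariant position
update), then — if positions were updated — rebuild frames from the final
coordinates and restore the original center of mass before a final GCP
projection.  Scalar outputs are SE(3)-invariant; vector outputs and output
positions are SE(3)-equivariant.

Edge features are embedded once and reused by every layer; frames are
likewise computed once from the input geometry and refreshed only after the
last layer when positions move.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, gather_rows, scatter_mean
from .gcp_core import GCP, GCPConfig, ResGCP, ScalarVector
from .geometry import Frames, centralize, localize

__all__ = ["GraphState", "NetConfig", "GCPConv", "GCPNet", "pool_graph", "update_positions"]


@dataclass
class GraphState:
    """A (possibly batched) featurized 3D graph.

    Batching is the usual disjoint union: ``graph_id`` maps each node to its
    graph, and edges never cross graphs.
    """

    node: ScalarVector
    edge: ScalarVector
    X: np.ndarray
    edges: np.ndarray
    graph_id: np.ndarray | None = None
    n_graphs: int = 1
    frames: Frames | None = None

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    @property
    def ids(self) -> np.ndarray:
        if self.graph_id is None:
            return np.zeros(self.n_nodes, dtype=np.intp)
        return self.graph_id


@dataclass
class NetConfig:
    """Architecture hyperparameters for a GCPNet."""

    n_layers: int = 4
    node_dims: tuple[int, int] = (100, 16)
    edge_dims: tuple[int, int] = (32, 4)
    out_node_dims: tuple[int, int] | None = None   # default: node_dims
    out_edge_dims: tuple[int, int] | None = None   # default: edge_dims
    update_positions: bool = False
    gcp: GCPConfig = field(default_factory=GCPConfig)

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("need at least one layer")
        if self.out_node_dims is None:
            self.out_node_dims = self.node_dims
        if self.out_edge_dims is None:
            self.out_edge_dims = self.edge_dims


def update_positions(x_prev: Tensor, chi_v: Tensor) -> Tensor:
    """Residual position update x + chi (chi is an N x 1 x 3 vector channel)."""
    n = chi_v.shape[0]
    return x_prev + chi_v.reshape(n, 3)


def pool_graph(node_s: Tensor, graph_id: np.ndarray | None = None,
               n_graphs: int = 1, mode: str = "mean") -> Tensor:
    """Permutation-invariant graph readout of node scalars."""
    if node_s.shape[0] == 0:
        raise ValueError("cannot pool an empty graph")
    if graph_id is None:
        graph_id = np.zeros(node_s.shape[0], dtype=np.intp)
    out = scatter_mean(node_s, graph_id, n_graphs)
    if mode == "mean":
        return out
    if mode == "sum":
        counts = np.bincount(graph_id, minlength=n_graphs).astype(np.float64)
        return out * counts[:, None]
    raise ValueError(f"unknown pooling mode {mode!r}")


class GCPConv:
    """One round of geometry-complete message passing."""

    def __init__(self, rng, node_dims, edge_dims, config: GCPConfig,
                 update_pos: bool = False):
        t_n, r_n = node_dims
        t_e, r_e = edge_dims
        msg_in = (2 * t_n + t_e, 2 * r_n + r_e)
        self.message_proj = GCP(rng, msg_in, node_dims, config)
        block = ResGCP if config.use_residual else (
            lambda rng_, dims, cfg: GCP(rng_, dims, dims, cfg))
        self.message_blocks = [
            block(rng, node_dims, config) for _ in range(max(0, config.omega - 1))
        ]
        self.node_update = GCP(rng, (2 * t_n, 2 * r_n), node_dims, config)
        self.position_gcp = (
            GCP(rng, node_dims, (t_n, 1), config) if update_pos else None
        )

    def forward(self, node: ScalarVector, edge0: ScalarVector, x: Tensor,
                frames_mat: np.ndarray, edges: np.ndarray, n_nodes: int):
        src, dst = edges[:, 0], edges[:, 1]
        sv_dst = ScalarVector(
            None if node.s is None else gather_rows(node.s, src),
            None if node.V is None else gather_rows(node.V, src),
        )
        sv_src = ScalarVector(
            None if node.s is None else gather_rows(node.s, dst),
            None if node.V is None else gather_rows(node.V, dst),
        )
        msg = sv_dst.cat(sv_src).cat(edge0)
        msg = self.message_proj(msg, frames_mat, edges, "edge")
        for blk in self.message_blocks:
            msg = blk(msg, frames_mat, edges, "edge")
        agg = ScalarVector(
            None if msg.s is None else scatter_mean(msg.s, src, n_nodes),
            None if msg.V is None else scatter_mean(msg.V, src, n_nodes),
        )
        node = node + self.node_update(
            node.cat(agg), frames_mat, edges, "node", n_nodes)
        if self.position_gcp is not None:
            chi = self.position_gcp(node, frames_mat, edges, "node", n_nodes).V
            x = update_positions(x, chi)
        return node, x

    __call__ = forward

    def parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = self.message_proj.parameters(prefix + "msg0.")
        for i, blk in enumerate(self.message_blocks):
            out.update(blk.parameters(f"{prefix}msg{i + 1}."))
        out.update(self.node_update.parameters(prefix + "update."))
        if self.position_gcp is not None:
            out.update(self.position_gcp.parameters(prefix + "pos."))
        return out


class GCPNet:
    """The full network: embed -> L x GCPConv -> (re-localize) -> project."""

    def __init__(self, rng: np.random.Generator, in_node_dims, in_edge_dims,
                 config: NetConfig | None = None):
        self.config = config or NetConfig()
        cfg = self.config
        self.embed_node = GCP(rng, in_node_dims, cfg.node_dims, cfg.gcp)
        self.embed_edge = GCP(rng, in_edge_dims, cfg.edge_dims, cfg.gcp)
        self.layers = [
            GCPConv(rng, cfg.node_dims, cfg.edge_dims, cfg.gcp,
                    update_pos=cfg.update_positions)
            for _ in range(cfg.n_layers)
        ]
        self.project_node = GCP(rng, cfg.node_dims, cfg.out_node_dims, cfg.gcp)
        self.project_edge = GCP(rng, cfg.edge_dims, cfg.out_edge_dims, cfg.gcp)

    def forward(self, state: GraphState):
        """Run the network; returns (node_out, edge_out, X_out).

        ``X_out`` is the input coordinate array itself (bitwise) when
        position updates are off, and a Tensor of updated positions carrying
        gradients when they are on.
        """
        n = state.n_nodes
        ids = state.ids
        xc, center = centralize(state.X, ids, state.n_graphs)
        frames0 = localize(xc, state.edges)
        f0 = frames0.matrix
        node = self.embed_node(state.node, f0, state.edges, "node", n)
        edge0 = self.embed_edge(state.edge, f0, state.edges, "edge")
        x = Tensor(xc)
        for layer in self.layers:
            node, x = layer(node, edge0, x, f0, state.edges, n)
        if self.config.update_positions:
            # frames are refreshed from the final geometry (stop-gradient);
            # restoring the center of mass makes positions translation-equivariant
            f_final = localize(x.data, state.edges).matrix
            x_out = x + Tensor(center[ids])
        else:
            f_final = f0
            x_out = state.X
        node_out = self.project_node(node, f_final, state.edges, "node", n)
        edge_out = self.project_edge(edge0, f_final, state.edges, "edge")
        return node_out, edge_out, x_out

    __call__ = forward

    def parameters(self) -> dict[str, Tensor]:
        out = self.embed_node.parameters("embed_node.")
        out.update(self.embed_edge.parameters("embed_edge."))
        for i, layer in enumerate(self.layers):
            out.update(layer.parameters(f"layer{i}."))
        out.update(self.project_node.parameters("project_node."))
        out.update(self.project_edge.parameters("project_edge."))
        return out
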