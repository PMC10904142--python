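"""Training utilities: graph batching, Adam, and checkpoint I/O.

Reference mode is single-threaded double precision throughout, so a fixed
seed reproduces losses and metrics bit-for-bit.
"""

from __future__ import annotations

import numpy as np
import yaml

from .autodiff import Tensor
from .gcp_core import ScalarVector
from .network import GraphState

__all__ = ["batch_graphs", "Adam", "save_checkpoint", "load_checkpoint"]


def batch_graphs(states: list[GraphState]) -> GraphState:
    """Disjoint-union batch of single graphs (node indices offset per graph)."""
    if not states:
        raise ValueError("empty batch")
    node_s, node_v, edge_s, edge_v = [], [], [], []
    coords, edges, graph_id = [], [], []
    offset = 0
    for i, st in enumerate(states):
        n = st.n_nodes
        node_s.append(st.node.s.data)
        if st.node.V is not None:
            node_v.append(st.node.V.data)
        edge_s.append(st.edge.s.data)
        if st.edge.V is not None:
            edge_v.append(st.edge.V.data)
        coords.append(st.X)
        edges.append(st.edges + offset)
        graph_id.append(np.full(n, i, dtype=np.intp))
        offset += n
    return GraphState(
        node=ScalarVector(
            Tensor(np.concatenate(node_s)),
            Tensor(np.concatenate(node_v)) if node_v else None,
        ),
        edge=ScalarVector(
            Tensor(np.concatenate(edge_s)),
            Tensor(np.concatenate(edge_v)) if edge_v else None,
        ),
        X=np.concatenate(coords),
        edges=np.concatenate(edges),
        graph_id=np.concatenate(graph_id),
        n_graphs=len(states),
    )


class Adam:
    """Adam over a named parameter dict of Tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for key, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g**2
            m_hat = self.m[key] / (1 - self.b1**self.t)
            v_hat = self.v[key] / (1 - self.b2**self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def save_checkpoint(path, params: dict[str, Tensor], config: dict | None = None) -> None:
    """Named arrays keyed by module path (.npz) plus a YAML config sidecar."""
    np.savez(path, **{k: p.data for k, p in params.items()})
    if config is not None:
        with open(str(path) + ".yaml", "w") as fh:
            yaml.safe_dump(config, fh)


def load_checkpoint(path, params: dict[str, Tensor]) -> dict | None:
    """Load arrays into an existing parameter dict; returns the config if present."""
    with np.load(path) as data:
        missing = set(params) - set(data.files)
        if missing:
            raise ValueError(f"checkpoint is missing parameters: {sorted(missing)}")
        for key, p in params.items():
            if data[key].shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {key}: checkpoint {data[key].shape} "
                    f"vs model {p.data.shape}")
            p.data = data[key].copy()
    import os

    cfg_path = str(path) + ".yaml"
    if os.path.exists(cfg_path):
        with open(cfg_path) as fh:
            return yaml.safe_load(fh)
    return None
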