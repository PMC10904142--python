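"""Property audits: numeric checks of the symmetry claims.

These are the executable versions of the network's three guarantees —
SE(3) equivariance of the forward pass, geometric self-consistency (rigid
pairs indistinguishable, mirror pairs distinguishable) and frame
completeness (orthonormal, right-handed, non-degenerate on generic
clouds).  They are shared by the test-suite, the ``gcpnet audit`` CLI and
the acceptance script.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .featurize import FeaturizeConfig, RawPointCloud, featurize_cloud
from .geometry import localize, random_rigid_motion
from .network import GCPNet, GraphState, pool_graph

__all__ = [
    "random_cloud",
    "transform_state",
    "mirror_state",
    "equivariance_audit",
    "self_consistency_audit",
    "frames_audit",
]


def random_cloud(n_nodes: int, rng: np.random.Generator,
                 n_types: int = 3, with_velocity: bool = False) -> RawPointCloud:
    """A generic Gaussian point cloud with random types (and velocities)."""
    return RawPointCloud(
        positions=rng.normal(size=(n_nodes, 3)),
        types=rng.integers(0, n_types, size=n_nodes),
        velocities=rng.normal(size=(n_nodes, 3)) if with_velocity else None,
    )


def _apply(cloud: RawPointCloud, mat: np.ndarray, g: np.ndarray) -> RawPointCloud:
    return RawPointCloud(
        positions=cloud.positions @ mat.T + g,
        types=cloud.types.copy(),
        velocities=None if cloud.velocities is None else cloud.velocities @ mat.T,
    )


def transform_state(cloud: RawPointCloud, config: FeaturizeConfig,
                    q: np.ndarray, g: np.ndarray) -> GraphState:
    """Featurize the cloud after the rigid motion x -> xQ^T + g, v -> vQ^T."""
    return featurize_cloud(_apply(cloud, q, np.asarray(g).reshape(1, 3)), config)


def mirror_state(cloud: RawPointCloud, config: FeaturizeConfig) -> GraphState:
    """Featurize the reflection of the cloud through the yz-plane."""
    mat = np.diag([-1.0, 1.0, 1.0])
    return featurize_cloud(_apply(cloud, mat, np.zeros((1, 3))), config)


def equivariance_audit(net: GCPNet, cloud: RawPointCloud,
                       config: FeaturizeConfig, n_motions: int = 100,
                       seed: int = 0) -> dict[str, float]:
    """Max deviations of the forward pass under random rigid motions.

    For each sampled (Q, g): scalar node outputs must be unchanged, vector
    node outputs must equal the reference rotated by Q, and output positions
    must equal Q x_ref + g.
    """
    state = featurize_cloud(cloud, config)
    node_ref, _, x_ref = net(state)
    x_ref_data = x_ref.data if isinstance(x_ref, Tensor) else x_ref
    dev = {"scalar": 0.0, "vector": 0.0, "position": 0.0}
    rng = np.random.default_rng(seed)
    for _ in range(n_motions):
        q, g = random_rigid_motion(rng)
        node_t, _, x_t = net(transform_state(cloud, config, q, g))
        dev["scalar"] = max(dev["scalar"],
                            float(np.abs(node_t.s.data - node_ref.s.data).max()))
        if node_ref.V is not None:
            dev["vector"] = max(dev["vector"],
                                float(np.abs(node_t.V.data
                                             - node_ref.V.data @ q.T).max()))
        x_t_data = x_t.data if isinstance(x_t, Tensor) else x_t
        dev["position"] = max(dev["position"],
                              float(np.abs(x_t_data - (x_ref_data @ q.T + g)).max()))
    return dev


def self_consistency_audit(net: GCPNet, cloud: RawPointCloud,
                           config: FeaturizeConfig, seed: int = 0) -> dict[str, float]:
    """Pooled-scalar distance for a rigid-motion pair and a mirror pair."""
    def pooled(state: GraphState) -> np.ndarray:
        node, _, _ = net(state)
        return pool_graph(node.s).data

    ref = pooled(featurize_cloud(cloud, config))
    q, g = random_rigid_motion(seed)
    rigid = pooled(transform_state(cloud, config, q, g))
    mirror = pooled(mirror_state(cloud, config))
    return {
        "rigid_max_abs_diff": float(np.abs(rigid - ref).max()),
        "mirror_max_abs_diff": float(np.abs(mirror - ref).max()),
    }


def frames_audit(n_edges: int = 1000, seed: int = 0) -> dict[str, float]:
    """Orthonormality / handedness / degeneracy of frames on generic clouds."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_edges + 1, 3))
    x = x - x.mean(axis=0)
    idx = np.arange(n_edges)
    edges = np.stack([idx, idx + 1], axis=1)
    frames = localize(x, edges)
    mats = frames.matrix
    gram = np.einsum("eij,ekj->eik", mats, mats)
    eye = np.eye(3)
    return {
        "max_orthonormality_error": float(np.abs(gram - eye).max()),
        "max_det_error": float(np.abs(np.linalg.det(mats) - 1.0).max()),
        "max_cross_error": float(
            np.abs(np.cross(frames.a, frames.b) - frames.c).max()),
        "degeneracy_rate": float(frames.degenerate.mean()),
        "n_edges": float(n_edges),
    }
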