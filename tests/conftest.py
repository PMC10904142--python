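import numpy as np
import pytest

from gcpnet import FeaturizeConfig, GCPConfig, GCPNet, NetConfig
from gcpnet.audits import random_cloud


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_feat_config():
    return FeaturizeConfig(vocab=(0, 1, 2), k=4, n_rbf=8, d_max=6.0)


@pytest.fixture
def small_net_factory(small_feat_config):
    """Build a small GCPNet (and a matching random cloud) reproducibly."""

    def build(seed=0, n_nodes=12, update_positions=False, with_velocity=False,
              **gcp_kw):
        rng = np.random.default_rng(seed)
        cloud = random_cloud(n_nodes, rng, with_velocity=with_velocity)
        cfg = NetConfig(
            n_layers=2, node_dims=(10, 3), edge_dims=(6, 2),
            update_positions=update_positions,
            gcp=GCPConfig(omega=2, **gcp_kw),
        )
        net = GCPNet(
            rng,
            small_feat_config.node_widths(with_velocity),
            small_feat_config.edge_widths(),
            cfg,
        )
        return net, cloud

    return build
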