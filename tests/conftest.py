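import numpy as np
import pytest

import lpsignal as L


@pytest.fixture
def chain():
    """Noise-free chain s -> a -> t with full single-knockdown design."""
    genes = ["s", "a", "t"]
    net = L.SignalingNetwork.from_edges(
        genes, [("s", "a", 1.0), ("a", "t", 1.0)],
        bias={"s": 0.95}, sources=["s"], sinks=["t"],
    )
    theta = L.Thresholds.constant(0.5, 3)
    Z = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, 0]])
    design = L.KnockdownDesign(Z, ["kd_s", "kd_a", "kd_t", "control"], genes)
    X = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1]], float)
    D = np.where(X == 1, 0.95, 0.245)
    obs = L.ObservationMatrix(D, design.experiment_ids, genes)
    return net, theta, design, obs, X


@pytest.fixture
def ten_node_study():
    """One simulated ten-node study at low noise."""
    cfg = L.SimulationConfig(n_nodes=10, n_edges=13, sigma=0.01, seed=17)
    return L.simulate_study(cfg)


def random_network(rng, n, n_edges, positive_only=False, bias_sources=True):
    """Random signed network helper for property tests."""
    slots = rng.choice(n * (n - 1), size=n_edges, replace=False)
    w = np.zeros((n, n))
    for p in slots:
        j, r = divmod(int(p), n - 1)
        i = r if r < j else r + 1
        w[j, i] = 1.0 if positive_only else rng.choice([-1.0, 1.0])
    has_in = (w != 0).any(axis=0)
    bias = np.where(~has_in, 0.95, 0.0) if bias_sources else np.zeros(n)
    nodes = [f"g{i}" for i in range(n)]
    return L.SignalingNetwork(nodes, w, bias)
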