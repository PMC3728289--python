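"""Ground-truth network, knockdown-design and data simulation.

The generator emulates an RNAi perturbation assay over a sparse signaling
network: every gene is knocked down singly, a few random pairs are knocked
down jointly, and one experiment is left unperturbed.  True activity
states follow the deterministic threshold model; measurements are then
drawn from one of two Gaussians (active vs inactive), the only stochastic
stage.  Receptor-like source nodes (no incoming edges) get their baseline
activity redrawn from N(source_bias_mean, source_bias_sd) per replicate
and experiment unless they are themselves targeted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_model import ActivityState, propagate_states
from .data import KnockdownDesign, ReplicatedObservations
from .network import SignalingNetwork, Thresholds

__all__ = [
    "SimulationConfig",
    "generate_network",
    "generate_design",
    "simulate_dataset",
    "simulate_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic perturbation assay.

    Defaults mirror the simulation protocol the method was benchmarked
    under: 3 replicates per experiment, measurement s.d. sigma = 0.01,
    source baseline activity N(0.95, 0.01), all edge weights +1 (a random
    fraction flipped to -1 when ``frac_inhibitory > 0``).  The Gaussian
    measurement means (0.95 active / 0.245 inactive) and the common
    threshold 0.6 put the data on a [0, 1] activity scale with
    well-separated states.
    """

    n_nodes: int = 10
    n_edges: int = 13
    frac_inhibitory: float = 0.0
    n_double_knockdowns: int = 5
    n_replicates: int = 3
    sigma: float = 0.01
    mu_active: float = 0.95
    mu_inactive: float = 0.245
    source_bias_mean: float = 0.95
    source_bias_sd: float = 0.01
    theta_default: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_edges > self.n_nodes * (self.n_nodes - 1):
            raise ValueError("n_edges exceeds the number of ordered node pairs")
        if self.mu_active <= self.mu_inactive:
            raise ValueError("mu_active must exceed mu_inactive")
        if self.sigma <= 0 or self.theta_default <= 0:
            raise ValueError("sigma and theta_default must be positive")
        if not 0 <= self.frac_inhibitory <= 1:
            raise ValueError("frac_inhibitory must lie in [0, 1]")


def generate_network(cfg: SimulationConfig) -> tuple[SignalingNetwork, Thresholds]:
    """Sample a random signed network (a stand-in for curated pathway maps).

    ``n_edges`` distinct ordered pairs (no self-loops) are drawn uniformly;
    weights are +1 with ``round(frac_inhibitory * n_edges)`` of them
    flipped to -1.  Nodes without incoming edges become sources and carry
    baseline activity ``source_bias_mean``; all other biases are 0.  Nodes
    without outgoing edges become sinks.  Pure function of ``cfg`` (seed
    included).
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nodes
    nodes = [f"g{i+1}" for i in range(n)]
    # Ordered off-diagonal slot p -> (j, i)
    slots = rng.choice(n * (n - 1), size=cfg.n_edges, replace=False)
    weights = np.zeros((n, n))
    pairs = []
    for p in slots:
        j, r = divmod(int(p), n - 1)
        i = r if r < j else r + 1
        pairs.append((j, i))
        weights[j, i] = 1.0
    n_inhib = int(round(cfg.frac_inhibitory * cfg.n_edges))
    if n_inhib:
        for idx in rng.choice(len(pairs), size=n_inhib, replace=False):
            j, i = pairs[idx]
            weights[j, i] = -1.0
    has_in = (weights != 0).any(axis=0)
    has_out = (weights != 0).any(axis=1)
    sources = frozenset(nodes[i] for i in range(n) if not has_in[i])
    sinks = frozenset(nodes[i] for i in range(n) if not has_out[i])
    bias = np.where(~has_in, cfg.source_bias_mean, 0.0)
    net = SignalingNetwork(nodes, weights, bias, sources, sinks)
    return net, Thresholds.constant(cfg.theta_default, n)


def generate_design(
    n_nodes: int, n_double_knockdowns: int, seed: int, genes: list[str] | None = None
) -> KnockdownDesign:
    """Single knockdowns of every gene, random double knockdowns, and one
    unperturbed control experiment (m = n + doubles + 1)."""
    rng = np.random.default_rng(seed)
    genes = genes or [f"g{i+1}" for i in range(n_nodes)]
    n_pairs = n_nodes * (n_nodes - 1) // 2
    if n_double_knockdowns > n_pairs:
        raise ValueError("more double knockdowns than distinct pairs")
    m = n_nodes + n_double_knockdowns + 1
    Z = np.zeros((m, n_nodes), dtype=np.int8)
    ids = []
    for i in range(n_nodes):
        Z[i, i] = 1
        ids.append(f"kd_{genes[i]}")
    if n_double_knockdowns:
        chosen = rng.choice(n_pairs, size=n_double_knockdowns, replace=False)
        all_pairs = [(a, b) for a in range(n_nodes) for b in range(a + 1, n_nodes)]
        for r, c in enumerate(chosen):
            a, b = all_pairs[int(c)]
            Z[n_nodes + r, a] = 1
            Z[n_nodes + r, b] = 1
            ids.append(f"kd_{genes[a]}+{genes[b]}")
    ids.append("control")
    return KnockdownDesign(Z, ids, genes)


def simulate_dataset(
    net: SignalingNetwork,
    theta: Thresholds,
    design: KnockdownDesign,
    cfg: SimulationConfig,
) -> tuple[ReplicatedObservations, ActivityState]:
    """Simulate replicate measurements and the ground-truth states.

    Per replicate and experiment, source biases are redrawn from
    N(source_bias_mean, source_bias_sd) unless the source is targeted;
    states are propagated deterministically; each gene's measurement is
    drawn from N(mu_active, sigma) or N(mu_inactive, sigma) according to
    its state.  The returned ActivityState holds the states under the
    nominal (mean) biases with per-experiment convergence flags.
    """
    rng = np.random.default_rng(cfg.seed)
    m, n = design.Z.shape
    if net.n != n:
        raise ValueError("network and design sizes differ")
    src_idx = np.array([net.index(s) for s in sorted(net.sources)], dtype=int)

    values = np.empty((cfg.n_replicates, m, n))
    for r in range(cfg.n_replicates):
        for k in range(m):
            sim_net = net
            if src_idx.size:
                bias = net.bias.copy()
                draws = rng.normal(cfg.source_bias_mean, cfg.source_bias_sd, src_idx.size)
                for s, d in zip(src_idx, draws):
                    if design.Z[k, s] == 0:
                        bias[s] = d
                sim_net = SignalingNetwork(
                    net.nodes, net.weights, bias, net.sources, net.sinks
                )
            st = propagate_states(sim_net, theta, design.Z[k])
            mu = np.where(st.x >= 0.5, cfg.mu_active, cfg.mu_inactive)
            values[r, k] = rng.normal(mu, cfg.sigma)

    # Ground truth under the nominal biases (deterministic).
    true_x = np.empty((m, n))
    flags = np.empty(m, dtype=bool)
    for k in range(m):
        st = propagate_states(net, theta, design.Z[k])
        true_x[k] = st.x
        flags[k] = bool(st.converged)
    obs = ReplicatedObservations(values, design.experiment_ids, design.genes)
    return obs, ActivityState(true_x, converged=flags)


def simulate_study(
    cfg: SimulationConfig,
) -> tuple[SignalingNetwork, Thresholds, KnockdownDesign, ReplicatedObservations, ActivityState]:
    """Network + design + data in one deterministic call (derived seeds)."""
    net, theta = generate_network(cfg)
    design = generate_design(
        cfg.n_nodes, cfg.n_double_knockdowns, seed=cfg.seed + 1, genes=net.nodes
    )
    obs, states = simulate_dataset(net, theta, design, replace(cfg, seed=cfg.seed + 2))
    return net, theta, design, obs, states
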