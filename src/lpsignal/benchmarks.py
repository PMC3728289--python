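"""End-to-end simulation benchmarks: noise, missing-data, prior-knowledge
and network-size sweeps.

Each protocol simulates ground-truth networks, runs the cross-validated
inference, and scores |median weight| against the generating topology by
ROC AUC, alongside an edge-count-preserving permutation baseline.  Grids
and fold counts default to reduced settings sized for a single CPU; they
are arguments, not constants.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import permutation_baseline, roc_pr_auc
from .lp_infer import InferenceConfig
from .model_select import select_lambda_cv, summarize_edges
from .network import SignalingNetwork
from .simulate import SimulationConfig, simulate_study

__all__ = [
    "TEN_NODE_EDGE_COUNTS",
    "LARGE_NETWORK_SIZES",
    "infer_auc",
    "noise_sweep",
    "missing_data_sweep",
    "prior_knowledge_sweep",
    "large_network_benchmark",
]

# Edge counts of the ten 10-node benchmark topologies (five with 7 edges,
# the rest with 5, 8, 10, 12 and 13).
TEN_NODE_EDGE_COUNTS = (5, 7, 7, 7, 7, 7, 8, 10, 12, 13)

# Node counts of the larger benchmark networks; edges ~ 1.3 per node.
LARGE_NETWORK_SIZES = (16, 24, 32, 44, 52)

REDUCED_GRID = (0.1, 1.0)

# The slack cap c * Var(D) must exceed the margin gap 2 * epsilon for a
# single label contradiction to be absorbable; on [0, 1]-scale bimodal
# data Var(D) ~ 0.12, so c = 2 keeps the LP solvable under heavy
# missingness where contradictions are unavoidable.
BENCHMARK_CONFIG = InferenceConfig(slack_cap_factor=2.0)


def _auc_metric(pred: SignalingNetwork, ref: SignalingNetwork) -> float:
    return roc_pr_auc(pred, ref)[0]


def infer_auc(
    cfg: SimulationConfig,
    grid=REDUCED_GRID,
    scheme: str = "loo_cells",
    k: int = 4,
    n_holdouts: int = 20,
    missing_gene_fraction: float = 0.0,
    prior_fraction: float = 0.0,
    use_source_sink: bool = False,
    n_perm: int = 20,
    replicate_method: str = "mean",
) -> dict[str, float]:
    """Simulate one study under ``cfg``, infer, and score against truth.

    Optionally blanks a random fraction of genes entirely (all their
    measurements across experiments), supplies a random fraction of the
    true edges as signed priors, or discloses the true source/sink sets.
    Returns ROC/PR AUC of |median CV weight| and a permutation-baseline
    mean AUC for the same edge count.
    """
    net, theta, design, replicates, _ = simulate_study(cfg)
    D = replicates.summarize(method=replicate_method)

    rng = np.random.default_rng(cfg.seed + 7)
    if missing_gene_fraction > 0:
        n_hide = int(round(missing_gene_fraction * cfg.n_nodes))
        hidden = rng.choice(cfg.n_nodes, size=n_hide, replace=False)
        D.D[:, hidden] = np.nan

    known_act: list[tuple[str, str]] = []
    known_inh: list[tuple[str, str]] = []
    if prior_fraction > 0:
        edges = net.edges()
        n_prior = int(round(prior_fraction * len(edges)))
        for idx in rng.choice(len(edges), size=n_prior, replace=False):
            src, tgt, w = edges[int(idx)]
            (known_act if w > 0 else known_inh).append((src, tgt))

    cv = select_lambda_cv(
        D, design, theta, grid=grid, scheme=scheme, k=k, n_holdouts=n_holdouts,
        seed=cfg.seed + 11, cfg=BENCHMARK_CONFIG,
        known_activations=known_act, known_inhibitions=known_inh,
        sources=sorted(net.sources) if use_source_sink else None,
        sinks=sorted(net.sinks) if use_source_sink else None,
    )
    summary = summarize_edges(cv.run_weights, nodes=net.nodes)
    scores = np.abs(summary.median_weight)
    auc_roc, auc_pr = roc_pr_auc(scores, net)
    perm = permutation_baseline(
        net, _auc_metric, n_perm=n_perm, seed=cfg.seed + 13
    )
    return {
        "auc_roc": auc_roc,
        "auc_pr": auc_pr,
        "baseline_auc_roc": float(perm.null.mean()),
        "best_lambda": cv.best_lambda,
        "n_nodes": cfg.n_nodes,
        "n_edges": cfg.n_edges,
    }


def _ten_node_cfgs(seed: int, sigma: float, frac_inhibitory: float = 0.0):
    for t, n_edges in enumerate(TEN_NODE_EDGE_COUNTS):
        yield SimulationConfig(
            n_nodes=10, n_edges=n_edges, sigma=sigma,
            frac_inhibitory=frac_inhibitory, seed=seed + 100 * t,
        )


def noise_sweep(
    sigmas=(0.01, 0.05, 0.1, 0.2), seed: int = 0, grid=REDUCED_GRID,
    n_holdouts: int = 20,
) -> pd.DataFrame:
    """AUC vs measurement noise over the ten-node benchmark topologies."""
    rows = []
    for sigma in sigmas:
        for t, cfg in enumerate(_ten_node_cfgs(seed, sigma)):
            r = infer_auc(cfg, grid=grid, n_holdouts=n_holdouts)
            rows.append({"sigma": sigma, "network": t, **r})
    return pd.DataFrame(rows)


def missing_data_sweep(
    fractions=(0.1, 0.2, 0.4, 0.5), sigma: float = 0.01, seed: int = 0,
    grid=REDUCED_GRID, n_holdouts: int = 20,
) -> pd.DataFrame:
    """AUC when a fraction of genes is left entirely unobserved."""
    rows = []
    for frac in fractions:
        for t, cfg in enumerate(_ten_node_cfgs(seed, sigma)):
            r = infer_auc(cfg, grid=grid, n_holdouts=n_holdouts,
                          missing_gene_fraction=frac)
            rows.append({"missing_fraction": frac, "network": t, **r})
    return pd.DataFrame(rows)


def prior_knowledge_sweep(
    fractions=(0.0, 0.1, 0.25, 0.5, 1.0), sigma: float = 0.01, seed: int = 0,
    grid=REDUCED_GRID, n_holdouts: int = 20,
) -> pd.DataFrame:
    """AUC as a growing fraction of true edges is supplied as priors."""
    rows = []
    for frac in fractions:
        for t, cfg in enumerate(_ten_node_cfgs(seed, sigma)):
            r = infer_auc(cfg, grid=grid, n_holdouts=n_holdouts,
                          prior_fraction=frac)
            rows.append({"prior_fraction": frac, "network": t, **r})
    return pd.DataFrame(rows)


def large_network_benchmark(
    sizes=LARGE_NETWORK_SIZES, seed: int = 0, grid=REDUCED_GRID, k: int = 10,
    sigma: float = 0.01, edges_per_node: float = 1.3,
) -> pd.DataFrame:
    """Sparse random networks of 16-52 nodes, full single-knockdown design
    plus 5 doubles and a control, 3 replicates, 10-fold CV."""
    rows = []
    for t, n in enumerate(sizes):
        cfg = SimulationConfig(
            n_nodes=n, n_edges=int(round(edges_per_node * n)), sigma=sigma,
            n_double_knockdowns=5, seed=seed + 1000 * (t + 1),
        )
        r = infer_auc(cfg, grid=grid, scheme="kfold", k=k, n_perm=20)
        rows.append({"n_nodes": n, **{kk: v for kk, v in r.items() if kk != "n_nodes"}})
    return pd.DataFrame(rows)
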