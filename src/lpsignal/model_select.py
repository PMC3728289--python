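"""Cross-validated slack-penalty selection and robust edge summarization.

The regularization parameter lambda is chosen on a grid by hold-out
prediction: observation cells are hidden from the LP, networks are
inferred from the rest, states are propagated through the inferred
network, and the hidden measurements are predicted via per-gene Gaussian
means estimated from the training cells.  The grid value with minimal
mean squared prediction error wins (ties break to the smallest lambda).
Edges are then kept only when learned robustly across CV runs: the median
weight across runs must exceed its (unscaled) median absolute deviation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_model import GaussianObservationModel, discretize_observations, propagate_states
from .data import KnockdownDesign, ObservationMatrix, ReplicatedObservations
from .lp_infer import InferenceConfig, infer_network
from .network import Thresholds

__all__ = [
    "LambdaGrid",
    "CVResult",
    "EdgeSummary",
    "select_lambda_cv",
    "summarize_edges",
    "bootstrap_aggregate",
    "estimate_state_means",
]

DEFAULT_GRID = (0.0, 0.01, 0.1, 0.5, 1.0, 5.0, 10.0, 50.0)


@dataclass(frozen=True)
class LambdaGrid:
    """Ascending, unique, non-empty grid of candidate slack penalties."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if not vals:
            raise ValueError("lambda grid is empty")
        if any(v < 0 for v in vals):
            raise ValueError("lambda values must be non-negative")
        if sorted(set(vals)) != list(vals):
            raise ValueError("lambda grid must be sorted and unique")
        object.__setattr__(self, "values", vals)

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class CVResult:
    """Outcome of the lambda grid search."""

    best_lambda: float
    mse_table: pd.DataFrame  # rows = lambda, cols = fold
    run_weights: list[np.ndarray]  # per-fold weights at best_lambda
    run_biases: list[np.ndarray]
    fold_assignment: dict[tuple[int, int], int]  # (experiment, gene) cell -> fold
    seed: int
    nodes: list[str]

    def mean_mse(self) -> pd.Series:
        return self.mse_table.mean(axis=1, skipna=True)

    def to_json(self) -> str:
        return json.dumps({
            "best_lambda": self.best_lambda,
            "seed": self.seed,
            "mean_mse": {f"{lam:g}": float(v) for lam, v in self.mean_mse().items()},
            "n_folds": int(self.mse_table.shape[1]),
        }, indent=2)

    def mse_to_tsv(self, path) -> None:
        self.mse_table.to_csv(path, sep="\t", index_label="lambda", na_rep="NA")


@dataclass
class EdgeSummary:
    """Median/MAD summary of edge weights across runs.

    An edge is kept iff |median| > MAD (unscaled, no normal-consistency
    factor); the final weight is median * keep_mask.
    """

    median_weight: np.ndarray
    mad_weight: np.ndarray
    keep_mask: np.ndarray
    nodes: list[str] | None = None

    @property
    def final_weight(self) -> np.ndarray:
        return self.median_weight * self.keep_mask

    def to_json(self) -> str:
        nodes = self.nodes or [f"g{i+1}" for i in range(self.median_weight.shape[0])]
        edges = [
            {"source": nodes[j], "target": nodes[i],
             "median": float(self.median_weight[j, i]),
             "mad": float(self.mad_weight[j, i]),
             "kept": bool(self.keep_mask[j, i])}
            for j in range(len(nodes)) for i in range(len(nodes))
            if j != i and self.median_weight[j, i] != 0.0
        ]
        return json.dumps({"edges": edges}, indent=2)


def estimate_state_means(
    D: np.ndarray, X: np.ndarray, theta: Thresholds, sigma: float = 0.01
) -> GaussianObservationModel:
    """Per-gene Gaussian means from observed cells split by binary state.

    A gene seen in only one state borrows the global (cross-gene) mean of
    the other state; with no information at all the threshold itself is
    used as a last resort.
    """
    n = D.shape[1]
    mu_a = np.full(n, np.nan)
    mu_i = np.full(n, np.nan)
    act = (X == 1.0) & ~np.isnan(D)
    ina = (X == 0.0) & ~np.isnan(D)
    for i in range(n):
        if act[:, i].any():
            mu_a[i] = D[act[:, i], i].mean()
        if ina[:, i].any():
            mu_i[i] = D[ina[:, i], i].mean()
    glob_a = D[act].mean() if act.any() else None
    glob_i = D[ina].mean() if ina.any() else None
    for i in range(n):
        if np.isnan(mu_a[i]):
            mu_a[i] = glob_a if glob_a is not None else theta.theta[i]
        if np.isnan(mu_i[i]):
            mu_i[i] = glob_i if glob_i is not None else theta.theta[i]
    return GaussianObservationModel(mu_a, mu_i, sigma=max(sigma, 1e-12))


def _eligible_cells(D: ObservationMatrix, Z: KnockdownDesign) -> list[tuple[int, int]]:
    """Observed, non-targeted (experiment, gene) cells, row-major order."""
    out = []
    for k in range(D.m):
        for i in range(D.n):
            if Z.Z[k, i] == 0 and not np.isnan(D.D[k, i]):
                out.append((k, i))
    return out


def _make_folds(
    cells: list[tuple[int, int]],
    X: np.ndarray,
    scheme: str,
    k: int,
    n_holdouts: int,
    rng: np.random.Generator,
) -> list[list[tuple[int, int]]]:
    if scheme == "loo_cells":
        n_pick = min(n_holdouts, len(cells))
        picked = rng.choice(len(cells), size=n_pick, replace=False)
        return [[cells[int(p)]] for p in picked]
    if scheme == "kfold":
        if not 2 <= k <= len(cells):
            raise ValueError(f"kfold needs 2 <= k <= {len(cells)}, got {k}")
        # Stratify by discretized state so folds balance active/inactive.
        folds: list[list[tuple[int, int]]] = [[] for _ in range(k)]
        for label in (1.0, 0.0):
            stratum = [c for c in cells if X[c] == label]
            order = rng.permutation(len(stratum))
            for pos, idx in enumerate(order):
                folds[pos % k].append(stratum[int(idx)])
        return [f for f in folds if f]
    raise ValueError(f"unknown CV scheme: {scheme!r}")


def select_lambda_cv(
    D: ObservationMatrix,
    Z: KnockdownDesign,
    theta: Thresholds,
    grid: LambdaGrid | Sequence[float] = DEFAULT_GRID,
    scheme: str = "loo_cells",
    k: int = 10,
    n_holdouts: int = 100,
    seed: int = 0,
    cfg: InferenceConfig = InferenceConfig(),
    known_activations: Sequence[tuple[str, str]] = (),
    known_inhibitions: Sequence[tuple[str, str]] = (),
    sources: Iterable[str] | None = None,
    sinks: Iterable[str] | None = None,
) -> CVResult:
    """Grid-search lambda by hold-out prediction MSE.

    ``scheme="loo_cells"`` holds out ``n_holdouts`` random single cells
    (one per fold); ``scheme="kfold"`` partitions all eligible cells into
    ``k`` state-stratified folds.  Fold assignment is a pure function of
    ``seed``.
    """
    if not isinstance(grid, LambdaGrid):
        grid = LambdaGrid(tuple(grid))
    D.check_matches(Z)
    rng = np.random.default_rng(seed)
    X_full = discretize_observations(D, theta)
    cells = _eligible_cells(D, Z)
    if not cells:
        raise ValueError("no eligible (observed, non-targeted) cells for CV")
    folds = _make_folds(cells, X_full, scheme, k, n_holdouts, rng)
    fold_assignment = {c: f for f, fold in enumerate(folds) for c in fold}

    lams = list(grid)
    mse = np.full((len(lams), len(folds)), np.nan)
    weights_by_lam: dict[float, list[np.ndarray]] = {lam: [] for lam in lams}
    biases_by_lam: dict[float, list[np.ndarray]] = {lam: [] for lam in lams}
    for f, fold in enumerate(folds):
        if not fold:
            warnings.warn(f"fold {f} holds no observed cells; skipped", stacklevel=2)
            continue
        D_train = D.with_missing(fold)
        X_train = discretize_observations(D_train, theta)
        obs_model = estimate_state_means(D_train.D, X_train, theta)
        for li, lam in enumerate(lams):
            result = infer_network(
                D_train, Z, theta, cfg, lam=lam,
                known_activations=known_activations,
                known_inhibitions=known_inhibitions,
                sources=sources, sinks=sinks,
            )
            if result.status != "optimal":
                warnings.warn(
                    f"fold {f}, lambda {lam:g}: solver status {result.status}",
                    stacklevel=2,
                )
                continue
            net = result.network()
            errs = []
            by_exp: dict[int, list[int]] = {}
            for ke, i in fold:
                by_exp.setdefault(ke, []).append(i)
            for ke, genes_held in by_exp.items():
                st = propagate_states(net, theta, Z.Z[ke])
                for i in genes_held:
                    pred = obs_model.mu_active[i] if st.x[i] >= 0.5 else obs_model.mu_inactive[i]
                    errs.append((pred - D.D[ke, i]) ** 2)
            mse[li, f] = float(np.mean(errs))
            weights_by_lam[lam].append(result.weights)
            biases_by_lam[lam].append(result.bias)

    mse_table = pd.DataFrame(
        mse, index=pd.Index(lams, name="lambda"),
        columns=[f"fold{f}" for f in range(len(folds))],
    )
    mean_mse = mse_table.mean(axis=1, skipna=True).dropna()
    if mean_mse.empty:
        raise RuntimeError("no lambda produced a solvable fold; cannot select")
    # Ties break to the smallest lambda (grid is ascending; idxmin does this).
    best_lambda = float(mean_mse.idxmin())
    return CVResult(
        best_lambda=best_lambda,
        mse_table=mse_table,
        run_weights=weights_by_lam[best_lambda],
        run_biases=biases_by_lam[best_lambda],
        fold_assignment=fold_assignment,
        seed=seed,
        nodes=list(D.genes),
    )


def summarize_edges(
    run_weights: Sequence[np.ndarray], nodes: list[str] | None = None
) -> EdgeSummary:
    """Median/MAD across runs; keep an edge iff |median| > MAD."""
    if len(run_weights) == 0:
        raise ValueError("need at least one run")
    stack = np.stack([np.asarray(w, dtype=float) for w in run_weights])
    med = np.median(stack, axis=0)
    mad = np.median(np.abs(stack - med), axis=0)
    keep = (np.abs(med) > mad).astype(float)
    np.fill_diagonal(keep, 0.0)
    np.fill_diagonal(med, 0.0)
    return EdgeSummary(median_weight=med, mad_weight=mad, keep_mask=keep, nodes=nodes)


def bootstrap_aggregate(
    replicates: ReplicatedObservations,
    Z: KnockdownDesign,
    theta: Thresholds,
    cfg: InferenceConfig = InferenceConfig(),
    n_boot: int = 10,
    seed: int = 0,
    grid: LambdaGrid | Sequence[float] = DEFAULT_GRID,
    scheme: str = "loo_cells",
    k: int = 10,
    n_holdouts: int = 100,
    summarize_method: str = "mean",
) -> EdgeSummary:
    """Bootstrap replicate measurements and aggregate CV inferences.

    Each bootstrap sample resamples the replicate values per cell with
    replacement, summarizes them, and runs the full lambda grid search.
    The per-sample edge weights (median across that sample's CV runs) are
    then summarized across samples by median/MAD.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    per_sample = []
    for b in range(n_boot):
        resampled = replicates.resample(rng)
        D = resampled.summarize(method=summarize_method)
        cv = select_lambda_cv(
            D, Z, theta, grid=grid, scheme=scheme, k=k,
            n_holdouts=n_holdouts, seed=seed + 1000 + b, cfg=cfg,
        )
        per_sample.append(np.median(np.stack(cv.run_weights), axis=0))
    return summarize_edges(per_sample, nodes=list(Z.genes))
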