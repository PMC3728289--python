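"""Model/Results interface tying the pipeline together.

``SignalingLPModel`` holds the data (observations, knockdown design,
thresholds, optional priors); ``fit`` solves the inference LP at a fixed
slack penalty and returns a results object with the estimated weights,
biases, slack usage, diagnostics and a ``summary()`` table;
``fit_cv`` runs the cross-validated lambda grid search and returns
results carrying per-run weight uncertainty (median/MAD) alongside the
selected penalty.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_model import propagate_states
from .data import KnockdownDesign, ObservationMatrix, ReplicatedObservations
from .lp_infer import InferenceConfig, InferenceResult, infer_network
from .model_select import (
    DEFAULT_GRID,
    CVResult,
    EdgeSummary,
    select_lambda_cv,
    summarize_edges,
)
from .network import SignalingNetwork, Thresholds

__all__ = ["SignalingLPModel", "SignalingLPResults", "SignalingCVResults"]


class SignalingLPModel:
    """Network-inference model over a perturbation assay.

    Parameters
    ----------
    observations
        ``ObservationMatrix`` (or replicated observations, which are
        summarized by ``replicate_method``).
    design
        Binary knockdown design matching the observations.
    thresholds
        Per-gene activation thresholds: a ``Thresholds`` object, or
        ``"mean"`` / ``"median"`` to derive each gene's threshold from its
        own measurements across experiments (the data-driven convention
        for assays without calibration controls).
    config
        ``InferenceConfig`` with the LP margins, caps and solver options.
    """

    def __init__(
        self,
        observations: ObservationMatrix | ReplicatedObservations,
        design: KnockdownDesign,
        thresholds: Thresholds | str = "mean",
        config: InferenceConfig | None = None,
        known_activations: Sequence[tuple[str, str]] = (),
        known_inhibitions: Sequence[tuple[str, str]] = (),
        sources: Iterable[str] | None = None,
        sinks: Iterable[str] | None = None,
        replicate_method: str = "mean",
    ) -> None:
        if isinstance(observations, ReplicatedObservations):
            self.replicates: ReplicatedObservations | None = observations
            observations = observations.summarize(method=replicate_method)
        else:
            self.replicates = None
        observations.check_matches(design)
        self.observations = observations
        self.design = design
        self.config = config or InferenceConfig()
        self.thresholds = self._resolve_thresholds(thresholds)
        self.known_activations = tuple(known_activations)
        self.known_inhibitions = tuple(known_inhibitions)
        self.sources = None if sources is None else tuple(sources)
        self.sinks = None if sinks is None else tuple(sinks)

    def _resolve_thresholds(self, spec: Thresholds | str) -> Thresholds:
        if isinstance(spec, Thresholds):
            if len(spec) != self.observations.n:
                raise ValueError("threshold length does not match gene count")
            return spec
        if spec not in ("mean", "median"):
            raise ValueError("thresholds must be a Thresholds object, 'mean' or 'median'")
        agg = np.nanmean if spec == "mean" else np.nanmedian
        theta = agg(self.observations.D, axis=0)
        if np.isnan(theta).any():
            bad = [self.observations.genes[i] for i in np.nonzero(np.isnan(theta))[0]]
            raise ValueError(f"cannot derive thresholds for all-missing genes: {bad}")
        return Thresholds(theta)

    @classmethod
    def from_tables(
        cls, obs_path, design_path, thresholds: Thresholds | str = "mean", **kwargs
    ) -> "SignalingLPModel":
        """Build the model from observation/design TSV files (replicated
        observations in long format are accepted)."""
        from .io import read_design, read_observations

        obs = read_observations(obs_path)
        design = read_design(
            design_path, genes=obs.genes, experiment_ids=obs.experiment_ids
        )
        return cls(obs, design, thresholds=thresholds, **kwargs)

    def fit(self, lam: float | None = None) -> "SignalingLPResults":
        """Solve the inference LP at a fixed slack penalty."""
        result = infer_network(
            self.observations, self.design, self.thresholds, self.config, lam=lam,
            known_activations=self.known_activations,
            known_inhibitions=self.known_inhibitions,
            sources=self.sources, sinks=self.sinks,
        )
        return SignalingLPResults(self, result, lam=self.config.lam if lam is None else lam)

    def fit_cv(
        self,
        grid: Sequence[float] = DEFAULT_GRID,
        scheme: str = "loo_cells",
        k: int = 10,
        n_holdouts: int = 100,
        seed: int = 0,
    ) -> "SignalingCVResults":
        """Cross-validated lambda selection followed by edge summarization."""
        cv = select_lambda_cv(
            self.observations, self.design, self.thresholds,
            grid=grid, scheme=scheme, k=k, n_holdouts=n_holdouts, seed=seed,
            cfg=self.config,
            known_activations=self.known_activations,
            known_inhibitions=self.known_inhibitions,
            sources=self.sources, sinks=self.sinks,
        )
        summary = summarize_edges(cv.run_weights, nodes=list(self.design.genes))
        return SignalingCVResults(self, cv, summary)


@dataclass
class SignalingLPResults:
    """Point estimate from one LP solve."""

    model: SignalingLPModel
    result: InferenceResult
    lam: float

    @property
    def status(self) -> str:
        return self.result.status

    @property
    def weights(self) -> pd.DataFrame:
        genes = self.model.design.genes
        return pd.DataFrame(self.result.weights, index=genes, columns=genes)

    @property
    def bias(self) -> pd.Series:
        return pd.Series(self.result.bias, index=self.model.design.genes, name="bias")

    @property
    def objective_value(self) -> float:
        return self.result.objective_value

    def network(self) -> SignalingNetwork:
        return self.result.network(
            sources=self.model.sources or (), sinks=self.model.sinks or ()
        )

    def predict_states(self, Z: np.ndarray | None = None) -> np.ndarray:
        """Propagate states through the fitted network for each design row."""
        Z = self.model.design.Z if Z is None else np.asarray(Z)
        net = self.network()
        out = np.empty(Z.shape, dtype=float)
        for kk in range(Z.shape[0]):
            out[kk] = propagate_states(net, self.model.thresholds, Z[kk]).x
        return out

    def summary(self) -> str:
        res = self.result
        genes = self.model.design.genes
        n_edges = int(np.count_nonzero(np.abs(res.weights) > 1e-9))
        n_act = int(np.count_nonzero(res.weights > 1e-9))
        n_inh = n_edges - n_act
        used_slack = {c: v for c, v in res.slacks.items() if v > 1e-9}
        lines = [
            "Signaling network LP inference",
            "=" * 46,
            f"genes: {len(genes)}   experiments: {self.model.design.m}",
            f"lambda: {self.lam:g}   status: {res.status}",
            f"objective: {res.objective_value:.6g}",
            f"edges: {n_edges} ({n_act} activating, {n_inh} inhibiting)",
            f"slack variables > 0: {len(used_slack)} / {len(res.slacks)}",
            "-" * 46,
            f"{'source':>10} {'target':>10} {'weight':>10}",
        ]
        for j, src in enumerate(genes):
            for i, tgt in enumerate(genes):
                w = res.weights[j, i]
                if abs(w) > 1e-9:
                    lines.append(f"{src:>10} {tgt:>10} {w:>10.4f}")
        return "\n".join(lines)


@dataclass
class SignalingCVResults:
    """Cross-validated fit: selected lambda plus robust edge summary."""

    model: SignalingLPModel
    cv: CVResult
    edge_summary: EdgeSummary

    @property
    def best_lambda(self) -> float:
        return self.cv.best_lambda

    @property
    def weights(self) -> pd.DataFrame:
        genes = self.model.design.genes
        return pd.DataFrame(self.edge_summary.final_weight, index=genes, columns=genes)

    def network(self) -> SignalingNetwork:
        return SignalingNetwork(
            list(self.model.design.genes),
            self.edge_summary.final_weight,
            np.median(np.stack(self.cv.run_biases), axis=0)
            if self.cv.run_biases else np.zeros(len(self.model.design.genes)),
        )

    def summary(self) -> str:
        genes = self.model.design.genes
        es = self.edge_summary
        kept = int(es.keep_mask.sum())
        lines = [
            "Signaling network LP inference (cross-validated)",
            "=" * 52,
            f"genes: {len(genes)}   experiments: {self.model.design.m}",
            f"lambda grid: {list(self.cv.mse_table.index)}",
            f"selected lambda: {self.best_lambda:g}   folds: {self.cv.mse_table.shape[1]}",
            f"mean held-out MSE at best lambda: {self.cv.mean_mse().loc[self.best_lambda]:.6g}",
            f"edges kept (|median| > MAD): {kept}",
            "-" * 52,
            f"{'source':>10} {'target':>10} {'median_w':>10} {'MAD':>8}",
        ]
        for j, src in enumerate(genes):
            for i, tgt in enumerate(genes):
                if es.keep_mask[j, i]:
                    lines.append(
                        f"{src:>10} {tgt:>10} {es.median_weight[j, i]:>10.4f}"
                        f" {es.mad_weight[j, i]:>8.4f}"
                    )
        return "\n".join(lines)

    def plot_mse(self, ax=None):
        """Mean held-out MSE across the lambda grid (log-x when spread)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mm = self.cv.mean_mse()
        ax.plot(mm.index, mm.values, marker="o")
        ax.axvline(self.best_lambda, ls="--", color="grey")
        ax.set_xlabel("lambda")
        ax.set_ylabel("mean held-out MSE")
        if len(mm) > 1 and mm.index.max() / max(mm.index[mm.index > 0].min(), 1e-12) > 50:
            ax.set_xscale("symlog", linthresh=max(mm.index[mm.index > 0].min(), 1e-3))
        return ax
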