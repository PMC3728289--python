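"""Observation matrices, knockdown designs and replicate handling.

Conventions: matrices are experiment-major, shape ``(m, n)`` for ``m``
perturbation experiments over ``n`` genes.  ``D[k, i]`` is the measured
(continuous) activity of gene ``i`` in experiment ``k``; missing entries
are ``NaN``.  ``Z[k, i] = 1`` marks gene ``i`` as targeted (knocked down)
in experiment ``k``; combinatorial knockdowns (row sums > 1) are allowed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KnockdownDesign",
    "ObservationMatrix",
    "ReplicatedObservations",
    "summarize_replicates",
]


@dataclass
class KnockdownDesign:
    """Binary activation matrix Z: which genes each experiment targets."""

    Z: np.ndarray
    experiment_ids: list[str]
    genes: list[str]

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z)
        if self.Z.ndim != 2:
            raise ValueError("Z must be 2-d (experiments x genes)")
        if self.Z.shape[0] < 1:
            raise ValueError("need at least one experiment")
        if not np.isin(self.Z, (0, 1)).all():
            raise ValueError("design entries must be 0 or 1")
        self.Z = self.Z.astype(np.int8)
        self.experiment_ids = list(self.experiment_ids)
        self.genes = list(self.genes)
        if self.Z.shape != (len(self.experiment_ids), len(self.genes)):
            raise ValueError("Z shape does not match experiment/gene labels")

    @property
    def m(self) -> int:
        return self.Z.shape[0]

    @property
    def n(self) -> int:
        return self.Z.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Z, index=self.experiment_ids, columns=self.genes)


@dataclass
class ObservationMatrix:
    """Continuous activity measurements, one value per (experiment, gene).

    Missing measurements are NaN and stay distinguishable from any numeric
    value throughout the pipeline.
    """

    D: np.ndarray
    experiment_ids: list[str]
    genes: list[str]

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2:
            raise ValueError("D must be 2-d (experiments x genes)")
        self.experiment_ids = list(self.experiment_ids)
        self.genes = list(self.genes)
        if self.D.shape != (len(self.experiment_ids), len(self.genes)):
            raise ValueError("D shape does not match experiment/gene labels")

    @property
    def m(self) -> int:
        return self.D.shape[0]

    @property
    def n(self) -> int:
        return self.D.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.D)

    def check_matches(self, design: KnockdownDesign) -> None:
        if self.D.shape != design.Z.shape:
            raise ValueError(
                f"observation shape {self.D.shape} != design shape {design.Z.shape}"
            )
        if self.genes != design.genes or self.experiment_ids != design.experiment_ids:
            raise ValueError("observation and design labels do not match")

    def with_missing(self, cells: Sequence[tuple[int, int]]) -> "ObservationMatrix":
        """Copy with the given (experiment, gene) cells blanked to NaN."""
        D = self.D.copy()
        for k, i in cells:
            D[k, i] = np.nan
        return ObservationMatrix(D, self.experiment_ids, self.genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.experiment_ids, columns=self.genes)


@dataclass
class ReplicatedObservations:
    """Stack of replicate measurements, shape (n_replicates, m, n)."""

    values: np.ndarray
    experiment_ids: list[str]
    genes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("replicated values must be 3-d (replicate, experiment, gene)")
        if self.values.shape[0] < 1:
            raise ValueError("need at least one replicate")
        self.experiment_ids = list(self.experiment_ids)
        self.genes = list(self.genes)
        if self.values.shape[1:] != (len(self.experiment_ids), len(self.genes)):
            raise ValueError("replicate stack shape does not match labels")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    def summarize(self, method: str = "mean") -> ObservationMatrix:
        return summarize_replicates(self, method=method)

    def resample(self, rng: np.random.Generator) -> "ReplicatedObservations":
        """Bootstrap: per cell, resample replicate values with replacement.

        Cells whose replicates are partially missing resample among the
        non-missing values only; all-missing cells stay all-missing.
        """
        if self.n_replicates < 2:
            warnings.warn(
                "fewer than 2 replicates: bootstrap degenerates to repetition",
                stacklevel=2,
            )
        r, m, n = self.values.shape
        out = np.full_like(self.values, np.nan)
        for k in range(m):
            for i in range(n):
                vals = self.values[:, k, i]
                obs = vals[~np.isnan(vals)]
                if obs.size == 0:
                    continue
                out[:, k, i] = rng.choice(obs, size=r, replace=True)
        return ReplicatedObservations(out, self.experiment_ids, self.genes)


def summarize_replicates(
    replicates: ReplicatedObservations | Sequence[ObservationMatrix],
    method: str = "mean",
) -> ObservationMatrix:
    """Collapse the replicate axis to one value per (experiment, gene).

    ``method`` is ``"mean"`` (arithmetic average, the simulation-protocol
    default) or ``"median"``.  Missing replicates are ignored; a cell whose
    replicates are all missing stays missing.
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown summarization method: {method!r}")
    if isinstance(replicates, ReplicatedObservations):
        stack = replicates.values
        exp_ids, genes = replicates.experiment_ids, replicates.genes
    else:
        mats = list(replicates)
        if not mats:
            raise ValueError("need at least one replicate")
        exp_ids, genes = mats[0].experiment_ids, mats[0].genes
        for om in mats[1:]:
            if om.D.shape != mats[0].D.shape:
                raise ValueError("replicate shapes do not match")
        stack = np.stack([om.D for om in mats])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        if method == "mean":
            D = np.nanmean(stack, axis=0)
        else:
            D = np.nanmedian(stack, axis=0)
    return ObservationMatrix(D, exp_ids, genes)
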