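"""Signed, directed signaling-network container.

A network is a directed graph over proteins (or protein complexes) whose
edges carry real weights: ``w[j, i]`` is the influence of node ``j`` on
node ``i`` — positive for activation, negative for inhibition.  Each node
additionally carries a bias term ``b_i`` describing its baseline activity
in the absence of regulation, and a positive activation threshold
``theta_i`` above which the node counts as active.  Self-loops are
forbidden; cycles of length >= 2 are allowed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = ["SignalingNetwork", "Thresholds"]


@dataclass(frozen=True)
class Thresholds:
    """Per-gene activation thresholds theta_i (all strictly positive)."""

    theta: np.ndarray

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta, dtype=float)
        if theta.ndim != 1:
            raise ValueError("theta must be a 1-d vector")
        if not np.all(theta > 0):
            raise ValueError("activation thresholds must be strictly positive")
        object.__setattr__(self, "theta", theta)

    @classmethod
    def constant(cls, value: float, n: int) -> "Thresholds":
        return cls(np.full(n, float(value)))

    def __len__(self) -> int:
        return self.theta.size


@dataclass
class SignalingNetwork:
    """Node labels, signed weight matrix, biases and source/sink sets.

    Parameters
    ----------
    nodes
        Ordered protein labels, length ``n``.
    weights
        ``(n, n)`` real matrix; ``weights[j, i]`` is the weight of the edge
        ``j -> i``.  The diagonal must be exactly zero (no self-loops).
    bias
        Length-``n`` baseline activities ``b_i``.
    sources, sinks
        Receptor-like nodes exempt from the in-degree requirement, and
        terminal nodes exempt from the out-degree requirement.
    """

    nodes: list[str]
    weights: np.ndarray
    bias: np.ndarray
    sources: frozenset[str] = field(default_factory=frozenset)
    sinks: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.nodes = list(self.nodes)
        n = len(self.nodes)
        if n < 1:
            raise ValueError("network needs at least one node")
        if len(set(self.nodes)) != n:
            raise ValueError("node labels must be unique")
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n, n):
            raise ValueError(f"weights must be ({n}, {n}), got {self.weights.shape}")
        if np.any(np.diag(self.weights) != 0.0):
            raise ValueError("self-loops are forbidden: weight diagonal must be 0")
        self.bias = np.asarray(self.bias, dtype=float)
        if self.bias.shape != (n,):
            raise ValueError(f"bias must have length {n}")
        self.sources = frozenset(self.sources)
        self.sinks = frozenset(self.sinks)
        unknown = (self.sources | self.sinks) - set(self.nodes)
        if unknown:
            raise ValueError(f"source/sink labels not in node set: {sorted(unknown)}")
        self._index = {lab: i for i, lab in enumerate(self.nodes)}

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index(self, node: str) -> int:
        return self._index[node]

    def edges(self) -> list[tuple[str, str, float]]:
        """Nonzero edges as (source, target, weight), row-major order."""
        out = []
        for j, src in enumerate(self.nodes):
            for i, tgt in enumerate(self.nodes):
                w = self.weights[j, i]
                if w != 0.0:
                    out.append((src, tgt, float(w)))
        return out

    def edge_mask(self) -> np.ndarray:
        """Boolean (n, n) matrix of present edges (diagonal always False)."""
        return self.weights != 0.0

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(self.weights))

    @classmethod
    def from_edges(
        cls,
        nodes: Sequence[str],
        edges: Iterable[tuple[str, str, float]],
        bias: np.ndarray | dict[str, float] | None = None,
        sources: Iterable[str] = (),
        sinks: Iterable[str] = (),
    ) -> "SignalingNetwork":
        nodes = list(nodes)
        idx = {lab: i for i, lab in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for src, tgt, weight in edges:
            if src not in idx or tgt not in idx:
                raise ValueError(f"edge ({src}, {tgt}) references unknown node")
            if src == tgt:
                raise ValueError(f"self-loop on {src} is forbidden")
            w[idx[src], idx[tgt]] = weight
        if bias is None:
            b = np.zeros(len(nodes))
        elif isinstance(bias, dict):
            b = np.array([bias.get(lab, 0.0) for lab in nodes])
        else:
            b = np.asarray(bias, dtype=float)
        return cls(nodes, w, b, frozenset(sources), frozenset(sinks))

    def copy(self) -> "SignalingNetwork":
        return SignalingNetwork(
            list(self.nodes), self.weights.copy(), self.bias.copy(),
            self.sources, self.sinks,
        )
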