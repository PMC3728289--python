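"""Threshold activation model: discretization, propagation, prediction.

The model treats signal transduction as a deterministic information flow:
a gene ``i`` is active (``x_i = 1``) exactly when the weighted input from
its parents plus its baseline activity reaches its threshold,

    x_i = 1  iff  sum_j w_ji * x_j + b_i >= theta_i,

with knocked-down genes forced inactive and removed from regulation.
Incoming activations aggregate additively, i.e. a node fed by several
active parents behaves as an OR over sufficient inputs.  Measurement noise
enters only at the observation stage, via one Gaussian per activity state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ObservationMatrix
from .network import SignalingNetwork, Thresholds

__all__ = [
    "ActivityState",
    "GaussianObservationModel",
    "discretize_observations",
    "propagate_states",
    "predict_observations",
]

# Boundary convention used everywhere: ties count as active
# (d >= theta and  sum w x + b >= theta  both activate).


@dataclass
class ActivityState:
    """Binary activity vector/matrix with per-experiment convergence flags."""

    x: np.ndarray
    converged: np.ndarray | bool = True

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)


@dataclass(frozen=True)
class GaussianObservationModel:
    """Per-gene Gaussian measurement means for active/inactive states."""

    mu_active: np.ndarray
    mu_inactive: np.ndarray
    sigma: float = 0.01

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu_active", np.asarray(self.mu_active, dtype=float))
        object.__setattr__(self, "mu_inactive", np.asarray(self.mu_inactive, dtype=float))
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def discretize_observations(D: ObservationMatrix | np.ndarray, theta: Thresholds) -> np.ndarray:
    """Threshold continuous observations into binary states.

    Returns a float matrix with entries 1.0 (``d >= theta_i``), 0.0, or NaN
    where the observation is missing.
    """
    arr = D.D if isinstance(D, ObservationMatrix) else np.asarray(D, dtype=float)
    th = theta.theta
    if arr.ndim == 1:
        arr = arr[None, :]
        squeeze = True
    else:
        squeeze = False
    if arr.shape[1] != th.size:
        raise ValueError(
            f"observation columns ({arr.shape[1]}) != threshold length ({th.size})"
        )
    x = np.where(np.isnan(arr), np.nan, (arr >= th[None, :]).astype(float))
    return x[0] if squeeze else x


def propagate_states(
    net: SignalingNetwork,
    theta: Thresholds,
    knockdown: np.ndarray,
    max_iter: int | None = None,
) -> ActivityState:
    """Deterministic state propagation under a knockdown.

    Synchronous fixed-point iteration of the threshold activation rule.
    Initialization: ``x0_i = 1`` iff ``b_i >= theta_i`` and ``i`` is not
    knocked down.  Knocked-down genes are clamped to 0 and receive no
    regulation.  The iteration budget is ``2 n``; exact on acyclic
    networks, where it reduces to evaluation in topological order.  If no
    fixed point is reached (an oscillating cycle), the elementwise AND of
    the last two iterates is returned with ``converged=False``.
    """
    kd = np.asarray(knockdown).astype(bool)
    n = net.n
    if kd.shape != (n,):
        raise ValueError(f"knockdown vector must have length {n}")
    th = theta.theta
    if th.size != n:
        raise ValueError("threshold length does not match network size")
    budget = 2 * n if max_iter is None else max_iter

    free = ~kd
    x = ((net.bias >= th) & free).astype(float)
    prev = x
    for _ in range(budget):
        total = net.weights.T @ x + net.bias
        new = ((total >= th) & free).astype(float)
        if np.array_equal(new, x):
            return ActivityState(new, converged=True)
        prev, x = x, new
    return ActivityState(np.minimum(prev, x), converged=False)


def propagate_all(
    net: SignalingNetwork, theta: Thresholds, Z: np.ndarray
) -> ActivityState:
    """Propagate every experiment (row of Z); stacks states and flags."""
    Z = np.asarray(Z)
    states = np.empty(Z.shape, dtype=float)
    flags = np.empty(Z.shape[0], dtype=bool)
    for k in range(Z.shape[0]):
        st = propagate_states(net, theta, Z[k])
        states[k] = st.x
        flags[k] = bool(st.converged)
    return ActivityState(states, converged=flags)


def predict_observations(
    state: ActivityState | np.ndarray, model: GaussianObservationModel
) -> np.ndarray:
    """Map binary states to expected measurements (the per-state means)."""
    x = state.x if isinstance(state, ActivityState) else np.asarray(state, dtype=float)
    mu_a, mu_i = model.mu_active, model.mu_inactive
    bad = np.isnan(mu_a) | np.isnan(mu_i)
    if bad.any():
        which = np.nonzero(bad)[0]
        raise ValueError(f"no estimated Gaussian means for gene index(es) {which.tolist()}")
    return np.where(np.isnan(x), np.nan, np.where(x >= 0.5, mu_a, mu_i))
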