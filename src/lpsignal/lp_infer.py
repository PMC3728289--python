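"""Linear-program assembly and solution for network inference.

The inference problem: find sparse edge weights ``w`` and biases ``b``
consistent with discretized perturbation data.  For every non-targeted,
observed cell ``(i, k)`` the linear input to gene ``i`` must clear its
threshold by a margin ``epsilon`` when the gene was observed active, and
stay below it (up to a bounded, penalized slack ``xi_ik``) when observed
inactive:

    active:    sum_{j != i} w_ji a_jk + b_i >= theta_i + epsilon
    inactive:  sum_{j != i} w_ji a_jk + b_i <= theta_i - epsilon + xi_ik

The objective minimizes ``sum |w| + sum |b| + (lambda / N0) sum xi``, an
L1 (lasso-type) penalty that drives non-required edges to exactly zero;
``N0`` counts the inactive cells, i.e. the constraints that may be
violated.  Absolute values are linearized by the standard variable split
``w = w+ - w-``, ``b = b+ - b-`` with all parts non-negative.

Missing data heuristics: a constraint whose own observation ``x_ik`` is
missing is dropped; a missing parent value ``a_jk`` takes the worst case,
0 in active constraints and 1 in inactive ones.  Targeted cells
(``z_ik = 1``) never generate constraints — the knocked-down gene is no
longer subject to regulation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .core_model import discretize_observations
from .data import KnockdownDesign, ObservationMatrix
from .network import SignalingNetwork, Thresholds

__all__ = [
    "InferenceConfig",
    "LPSpec",
    "InferenceResult",
    "build_lp",
    "add_edge_priors",
    "add_source_sink_constraints",
    "solve_lp",
    "infer_network",
]


@dataclass(frozen=True)
class InferenceConfig:
    """Tunable parameters of the inference LP.

    epsilon
        Margin enforced between activated and non-activated linear inputs.
        Must be well below the separation of the active/inactive
        measurement means; default 0.1 on data scaled to roughly [0, 1].
    lam
        Non-negative slack penalty (the regularization parameter chosen by
        cross-validation).
    slack_cap_factor
        Slacks are bounded above by ``slack_cap_factor * Var(D)`` over all
        observed entries.
    parent_value_mode
        ``"discretized"`` uses binary parent states in the constraints;
        ``"continuous"`` uses the raw observations (sensitivity analysis).
    normalize_slack
        If True (default) the slack term in the objective is
        ``lam / N0 * sum(xi)``; if False, ``lam * sum(xi)``.
    """

    epsilon: float = 0.1
    lam: float = 1.0
    slack_cap_factor: float = 1.0
    parent_value_mode: str = "discretized"
    prior_edge_min: float = 1.0
    degree_delta: float = 0.1
    solver_tolerance: float = 1e-7
    normalize_slack: bool = True

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.slack_cap_factor <= 0 or self.prior_edge_min <= 0 or self.degree_delta <= 0:
            raise ValueError("caps and bounds must be positive")
        if self.parent_value_mode not in ("discretized", "continuous"):
            raise ValueError("parent_value_mode must be 'discretized' or 'continuous'")


@dataclass
class LPSpec:
    """An assembled linear program: min c'v  s.t.  A v <= rhs, lo <= v <= hi.

    Variables are ordered ``w+`` (all ordered pairs j != i, row-major),
    ``w-``, ``b+``, ``b-``, then one ``xi`` per inactive cell.  Every
    variable is non-negative.  Constraint rows carry a provenance tag in
    {"active", "inactive", "prior_edge", "degree"}.
    """

    nodes: list[str]
    var_names: list[str]
    objective: np.ndarray
    rows: list[dict[int, float]]
    rhs: list[float]
    tags: list[str]
    bounds: list[tuple[float, float | None]]
    n_inactive: int
    pair_index: dict[tuple[int, int], int]
    slack_index: dict[tuple[int, int], int]  # (gene, experiment) -> column
    slack_cap: float

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_variables(self) -> int:
        return len(self.var_names)

    @property
    def n_constraints(self) -> int:
        return len(self.rows)

    def wplus_col(self, j: int, i: int) -> int:
        return self.pair_index[(j, i)]

    def wminus_col(self, j: int, i: int) -> int:
        return len(self.pair_index) + self.pair_index[(j, i)]

    def bplus_col(self, i: int) -> int:
        return 2 * len(self.pair_index) + i

    def bminus_col(self, i: int) -> int:
        return 2 * len(self.pair_index) + self.n + i

    def add_constraint(self, coefs: dict[int, float], rhs: float, tag: str) -> None:
        self.rows.append(coefs)
        self.rhs.append(float(rhs))
        self.tags.append(tag)

    def to_matrices(self) -> tuple[np.ndarray, sparse.csr_matrix, np.ndarray]:
        """Objective vector, sparse A_ub and rhs for the solver."""
        nv = self.n_variables
        data, ri, ci = [], [], []
        for r, row in enumerate(self.rows):
            for c, v in row.items():
                ri.append(r)
                ci.append(c)
                data.append(v)
        A = sparse.csr_matrix(
            (data, (ri, ci)), shape=(len(self.rows), nv), dtype=float
        )
        return self.objective.copy(), A, np.asarray(self.rhs, dtype=float)

    def to_lp_format(self) -> str:
        """Serialize to CPLEX-LP text (debugging aid for small instances)."""
        def term(coef: float, name: str) -> str:
            sign = "+" if coef >= 0 else "-"
            return f" {sign} {abs(coef):g} {name}"

        lines = ["Minimize", " obj:" + "".join(
            term(c, self.var_names[idx])
            for idx, c in enumerate(self.objective) if c != 0
        ) or " obj: 0"]
        lines.append("Subject To")
        for r, (row, rhs, tag) in enumerate(zip(self.rows, self.rhs, self.tags)):
            expr = "".join(term(v, self.var_names[c]) for c, v in sorted(row.items()))
            lines.append(f" {tag}_{r}:{expr} <= {rhs:g}")
        lines.append("Bounds")
        for idx, (lo, hi) in enumerate(self.bounds):
            hi_s = "+inf" if hi is None else f"{hi:g}"
            lines.append(f" {lo:g} <= {self.var_names[idx]} <= {hi_s}")
        lines.append("End")
        return "\n".join(lines)


@dataclass
class InferenceResult:
    """Solved LP: recombined weights/biases, slacks, objective and status."""

    weights: np.ndarray
    bias: np.ndarray
    slacks: dict[tuple[int, int], float]
    objective_value: float
    status: str
    nodes: list[str]
    solution: np.ndarray | None = None
    spec: LPSpec | None = None

    def network(
        self, sources: Iterable[str] = (), sinks: Iterable[str] = ()
    ) -> SignalingNetwork:
        return SignalingNetwork(
            list(self.nodes), self.weights.copy(), self.bias.copy(),
            frozenset(sources), frozenset(sinks),
        )

    def max_violation(self) -> float:
        """Largest constraint violation of the stored solution (0 if none)."""
        if self.spec is None or self.solution is None:
            raise ValueError("result does not carry its LP spec/solution")
        _, A, rhs = self.spec.to_matrices()
        if A.shape[0] == 0:
            return 0.0
        return float(max(0.0, (A @ self.solution - rhs).max()))

    def to_json(self) -> str:
        edges = [
            {"source": self.nodes[j], "target": self.nodes[i],
             "weight": float(self.weights[j, i])}
            for j in range(len(self.nodes))
            for i in range(len(self.nodes))
            if self.weights[j, i] != 0.0
        ]
        return json.dumps({
            "status": self.status,
            "objective": self.objective_value,
            "edges": edges,
            "bias": {lab: float(b) for lab, b in zip(self.nodes, self.bias)},
            "slacks": {f"{self.nodes[i]}@{k}": float(v)
                       for (i, k), v in self.slacks.items() if v > 0},
        }, indent=2)


def _parent_value(x_or_d: np.ndarray, Z: np.ndarray, j: int, k: int) -> float | None:
    """Parent value a_jk, or None when missing (worst-case substitution)."""
    if Z[k, j] == 1:
        return 0.0
    v = x_or_d[k, j]
    if np.isnan(v):
        return None
    return float(v)


def build_lp(
    X: np.ndarray,
    D: ObservationMatrix | np.ndarray,
    Z: KnockdownDesign | np.ndarray,
    theta: Thresholds,
    cfg: InferenceConfig,
    lam: float | None = None,
) -> LPSpec:
    """Assemble the inference LP from discretized states and the design.

    Parameters
    ----------
    X
        Discretized activity states, shape (m, n), NaN = missing.
    D
        Continuous observations; used for the slack cap (its variance) and,
        in continuous parent mode, for the parent values.
    Z
        Knockdown design.
    lam
        Overrides ``cfg.lam`` when given.
    """
    Darr = D.D if isinstance(D, ObservationMatrix) else np.asarray(D, dtype=float)
    Zarr = Z.Z if isinstance(Z, KnockdownDesign) else np.asarray(Z)
    nodes = Z.genes if isinstance(Z, KnockdownDesign) else [
        f"g{i+1}" for i in range(Zarr.shape[1])
    ]
    X = np.asarray(X, dtype=float)
    m, n = Zarr.shape
    if X.shape != (m, n) or Darr.shape != (m, n) or len(theta) != n:
        raise ValueError("X, D, Z and theta are dimensionally inconsistent")
    lam = cfg.lam if lam is None else float(lam)
    if lam < 0:
        raise ValueError("lambda must be non-negative")

    observed = ~np.isnan(Darr)
    if not observed.any():
        warnings.warn("all observations missing: constraint set is empty", stacklevel=2)
    var_d = float(np.nanvar(Darr)) if observed.any() else 1.0
    slack_cap = cfg.slack_cap_factor * var_d
    parents = X if cfg.parent_value_mode == "discretized" else Darr

    pairs = [(j, i) for j in range(n) for i in range(n) if j != i]
    pair_index = {p: c for c, p in enumerate(pairs)}
    P = len(pairs)
    var_names = (
        [f"wp_{j}_{i}" for j, i in pairs]
        + [f"wm_{j}_{i}" for j, i in pairs]
        + [f"bp_{i}" for i in range(n)]
        + [f"bm_{i}" for i in range(n)]
    )
    bounds: list[tuple[float, float | None]] = [(0.0, None)] * (2 * P + 2 * n)

    # Slack variables: one per inactive, non-targeted, observed cell.
    slack_index: dict[tuple[int, int], int] = {}
    for k in range(m):
        for i in range(n):
            if Zarr[k, i] == 0 and not np.isnan(X[k, i]) and X[k, i] == 0.0:
                slack_index[(i, k)] = len(var_names)
                var_names.append(f"xi_{i}_{k}")
                bounds.append((0.0, slack_cap))
    n_inactive = len(slack_index)

    objective = np.zeros(len(var_names))
    objective[: 2 * P + 2 * n] = 1.0
    if n_inactive > 0 and lam > 0:
        slack_coef = lam / n_inactive if cfg.normalize_slack else lam
        objective[2 * P + 2 * n :] = slack_coef

    spec = LPSpec(
        nodes=list(nodes), var_names=var_names, objective=objective,
        rows=[], rhs=[], tags=[], bounds=bounds, n_inactive=n_inactive,
        pair_index=pair_index, slack_index=slack_index, slack_cap=slack_cap,
    )

    th = theta.theta
    for k in range(m):
        for i in range(n):
            if Zarr[k, i] == 1 or np.isnan(X[k, i]):
                continue
            active = X[k, i] >= 0.5
            coefs: dict[int, float] = {}
            for j in range(n):
                if j == i:
                    continue
                a = _parent_value(parents, Zarr, j, k)
                if a is None:
                    a = 0.0 if active else 1.0  # worst-case substitution
                if a == 0.0:
                    continue
                sgn = -a if active else a
                coefs[spec.wplus_col(j, i)] = sgn
                coefs[spec.wminus_col(j, i)] = -sgn
            if active:
                # -(sum w a + b) <= -(theta + eps)
                coefs[spec.bplus_col(i)] = -1.0
                coefs[spec.bminus_col(i)] = 1.0
                spec.add_constraint(coefs, -(th[i] + cfg.epsilon), "active")
            else:
                coefs[spec.bplus_col(i)] = 1.0
                coefs[spec.bminus_col(i)] = -1.0
                coefs[slack_index[(i, k)]] = -1.0
                spec.add_constraint(coefs, th[i] - cfg.epsilon, "inactive")
    return spec


def add_edge_priors(
    spec: LPSpec,
    known_activations: Sequence[tuple[str, str]] = (),
    known_inhibitions: Sequence[tuple[str, str]] = (),
    cfg: InferenceConfig = InferenceConfig(),
) -> LPSpec:
    """Force known interactions: w_ji >= prior_edge_min (activation) or
    w_ji <= -prior_edge_min (inhibition).  Returns the spec (modified in
    place); an empty prior set leaves it unchanged."""
    idx = {lab: i for i, lab in enumerate(spec.nodes)}
    for edges, sign in ((known_activations, +1), (known_inhibitions, -1)):
        for src, tgt in edges:
            if src not in idx or tgt not in idx:
                raise ValueError(f"prior edge ({src}, {tgt}) references unknown node")
            if src == tgt:
                raise ValueError(f"prior on self-loop {src} rejected")
            j, i = idx[src], idx[tgt]
            # sign * (w+ - w-) >= prior_edge_min  ->  -sign*(w+ - w-) <= -min
            spec.add_constraint(
                {spec.wplus_col(j, i): -float(sign), spec.wminus_col(j, i): float(sign)},
                -cfg.prior_edge_min, "prior_edge",
            )
    return spec


def add_source_sink_constraints(
    spec: LPSpec,
    sources: Iterable[str] = (),
    sinks: Iterable[str] = (),
    cfg: InferenceConfig = InferenceConfig(),
) -> LPSpec:
    """Require in-degree for non-sources and out-degree for non-sinks.

    Every node that is not a source must collect total incoming weight
    magnitude >= degree_delta; every non-sink analogously for outgoing.
    """
    idx = {lab: i for i, lab in enumerate(spec.nodes)}
    sources, sinks = set(sources), set(sinks)
    for unknown in (sources | sinks) - set(spec.nodes):
        raise ValueError(f"source/sink label {unknown!r} not in node set")
    n = spec.n
    for i, lab in enumerate(spec.nodes):
        if lab not in sources:  # needs an incoming edge
            coefs = {}
            for j in range(n):
                if j != i:
                    coefs[spec.wplus_col(j, i)] = -1.0
                    coefs[spec.wminus_col(j, i)] = -1.0
            spec.add_constraint(coefs, -cfg.degree_delta, "degree")
        if lab not in sinks:  # needs an outgoing edge
            coefs = {}
            for j in range(n):
                if j != i:
                    coefs[spec.wplus_col(i, j)] = -1.0
                    coefs[spec.wminus_col(i, j)] = -1.0
            spec.add_constraint(coefs, -cfg.degree_delta, "degree")
    return spec


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def solve_lp(spec: LPSpec, cfg: InferenceConfig = InferenceConfig()) -> InferenceResult:
    """Solve the assembled LP (HiGHS) and recombine the split variables."""
    n, P = spec.n, len(spec.pair_index)
    c, A, rhs = spec.to_matrices()
    if spec.n_constraints == 0:
        x = np.zeros(spec.n_variables)
        res_status, objective = "optimal", 0.0
    else:
        res = linprog(
            c, A_ub=A, b_ub=rhs, bounds=spec.bounds, method="highs",
            options={"primal_feasibility_tolerance": min(cfg.solver_tolerance, 1e-7)},
        )
        res_status = _STATUS.get(res.status, "numerical")
        if res_status != "optimal":
            return InferenceResult(
                weights=np.zeros((n, n)), bias=np.zeros(n), slacks={},
                objective_value=float("nan"), status=res_status,
                nodes=list(spec.nodes), solution=None, spec=spec,
            )
        x, objective = res.x, float(res.fun)

    weights = np.zeros((n, n))
    for (j, i), p in spec.pair_index.items():
        weights[j, i] = x[p] - x[P + p]
    bias = x[2 * P : 2 * P + n] - x[2 * P + n : 2 * P + 2 * n]
    slacks = {cell: float(x[col]) for cell, col in spec.slack_index.items()}
    result = InferenceResult(
        weights=weights, bias=bias, slacks=slacks,
        objective_value=objective, status=res_status,
        nodes=list(spec.nodes), solution=np.asarray(x), spec=spec,
    )
    if result.status == "optimal" and spec.n_constraints > 0:
        viol = result.max_violation()
        if viol > 10 * max(cfg.solver_tolerance, 1e-7):
            warnings.warn(f"solver reported optimal but violation {viol:.2e}", stacklevel=2)
    return result


def infer_network(
    D: ObservationMatrix,
    Z: KnockdownDesign,
    theta: Thresholds,
    cfg: InferenceConfig = InferenceConfig(),
    lam: float | None = None,
    known_activations: Sequence[tuple[str, str]] = (),
    known_inhibitions: Sequence[tuple[str, str]] = (),
    sources: Iterable[str] | None = None,
    sinks: Iterable[str] | None = None,
) -> InferenceResult:
    """Discretize, assemble (with optional priors) and solve in one call."""
    D.check_matches(Z)
    X = discretize_observations(D, theta)
    spec = build_lp(X, D, Z, theta, cfg, lam=lam)
    if known_activations or known_inhibitions:
        add_edge_priors(spec, known_activations, known_inhibitions, cfg)
    if sources is not None or sinks is not None:
        add_source_sink_constraints(spec, sources or (), sinks or (), cfg)
    return solve_lp(spec, cfg)
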