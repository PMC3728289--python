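# Methods

## Model

Signal transduction is treated as deterministic information flow
through a signed, directed graph.  Each protein `i` carries a binary
activity `x_i`, a baseline activity `b_i`, and a positive threshold
`theta_i`; each ordered pair `(j, i)`, `j != i`, may carry a weight
`w_ji` (activation if positive, inhibition if negative; self-loops
forbidden, longer cycles allowed).  The activation rule is

    x_i = 1   iff   sum_{j != i} w_ji x_j + b_i >= theta_i .

Ties (`= theta_i`) count as active; one convention, applied everywhere
(discretization of data and propagation of states).  Incoming edges
aggregate additively — a single sufficient active parent activates the
child, i.e. OR semantics.  An experimental knockdown clamps its target
genes to 0 and removes them from regulation.  Noise is purely
observational: an active gene is measured as `N(mu_active, sigma)`, an
inactive one as `N(mu_inactive, sigma)`.

### State propagation

Cyclic graphs make the activation rule a fixed-point problem.  States
are computed by synchronous iteration initialized at
`x0_i = [b_i >= theta_i and i not knocked down]`, with an iteration
budget of `2n`.  This is exact on acyclic graphs (it reduces to
evaluation in topological order) and deterministic everywhere.  If no
fixed point is reached the dynamics are oscillating between two
states; the elementwise AND of the two is returned with
`converged = False` — flagged, never raised, since unstable cycles are
a legitimate model outcome the inference must tolerate.

## The inference LP

For every cell `(i, k)` with gene `i` observed and not targeted in
experiment `k`:

    x_ik = 1:   sum_{j != i} w_ji a_jk + b_i >= theta_i + eps
    x_ik = 0:   sum_{j != i} w_ji a_jk + b_i <= theta_i - eps + xi_ik

minimizing `sum(|w|) + sum(|b|) + (lambda / N0) * sum(xi)` with
`0 <= xi_ik <= c * Var(D)` and `N0` the number of inactive cells.
Absolute values are linearized by the standard split `w = w+ - w-`,
`b = b+ - b-` (all parts non-negative); the program is solved with
HiGHS through `scipy.optimize.linprog`.  Feasibility of the returned
solution is checked against the assembled constraints; infeasible or
unbounded statuses are reported as such, never coerced.

Parent values `a_jk` default to the discretized states (`0/1` scale,
matching the worst-case substitutions below); the raw continuous
observations are selectable for sensitivity analysis.  Missing data:
a constraint whose own observation is missing is dropped; a missing
parent takes the worst case — 0 in active constraints, 1 in inactive
ones.  Targeted cells generate no constraints.

Prior knowledge enters as extra constraints: known activations
(inhibitions) force `w_ji >= prior_edge_min` (`<= -prior_edge_min`);
known source/sink annotations add degree constraints — every non-source
needs total incoming weight magnitude `>= degree_delta`, every non-sink
total outgoing magnitude `>= degree_delta`.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `epsilon` | 0.1 | margin between active and inactive linear inputs; must be well below the separation of the two measurement means (data on a roughly [0, 1] activity scale) |
| `lam` | CV-selected | slack penalty; grid default {0, 0.01, 0.1, 0.5, 1, 5, 10, 50} |
| `slack_cap_factor` (c) | 1.0 | slack bound `c * Var(D)` over observed entries |
| `prior_edge_min` | 1.0 | forced magnitude of prior edges |
| `degree_delta` | 0.1 | forced degree mass for non-source/non-sink nodes |
| `solver_tolerance` | 1e-7 | primal feasibility tolerance |
| `theta` | per-gene data mean | threshold heuristic for assays without calibration controls; per-gene median selectable |

A feasibility caveat that matters in practice: a label contradiction
(identical parent states, conflicting child labels) needs slack
`xi >= 2 * epsilon`.  With `epsilon = 0.1` and bimodal data on [0, 1]
(`Var(D) ~ 0.12`), the default cap `1 * Var(D)` cannot absorb even one
contradiction and the LP turns infeasible.  Under conditions where
contradictions are unavoidable — heavy missingness, high noise — use
`c * Var(D) > 2 * epsilon`; the built-in benchmark protocols use
`c = 2` for exactly this reason.

## Model selection

`lambda` is selected on a grid by hold-out prediction.  The hold-out
unit is a single (experiment, gene) cell; two schemes:

- `loo_cells`: `n_holdouts` random cells (default 100), one per fold —
  the protocol for small networks;
- `kfold`: all eligible cells partitioned into `k` folds, stratified by
  the cell's discretized activity state — the cheaper protocol for
  larger networks (default `k = 10`).

Per fold and grid value: held-out cells are marked missing, the LP is
solved, states are propagated through the inferred network for each
experiment, and held-out measurements are predicted by per-gene
Gaussian means estimated from the training cells split by state (a
gene seen in only one state borrows the global mean of the other
state).  The grid value minimizing mean MSE wins; ties break to the
smallest `lambda` (the more conservative regularization statement).
Fold assignment is a pure function of the seed.

The held-out MSE is a *ranking* criterion, not a small quantity: a
held-out cell whose constraint was the unique evidence for an edge is
necessarily mispredicted by the L1-minimal network (drop the only
experiment in which a chain's sink is active and the chain's last edge
has no reason to exist).  At `sigma = 0.01` on ten-node data roughly
3–4% of held-out states are mispredicted for this reason; the tests
accordingly assert that prediction beats the unconditional-mean null,
not that the MSE approaches `sigma^2`.

Edges are summarized across CV runs by median and unscaled MAD (no
1.4826 consistency factor); an edge is kept iff |median| > MAD, and its
final weight is the median.  For replicate-rich data,
`bootstrap_aggregate` resamples replicates per cell with replacement,
runs the full grid search per bootstrap sample, and takes the median
across samples.

## Synthetic data

The generator emulates an RNAi assay over a sparse signaling network:

- topology: `n_edges` ordered pairs drawn uniformly (no self-loops),
  weight +1, a configurable fraction flipped to -1.  Nodes without
  incoming edges are sources (receptors) and carry baseline activity
  `N(0.95, 0.01)`, redrawn per replicate and experiment unless
  targeted; all other biases are 0.  Connectivity and acyclicity are
  *not* enforced — callers approximate curated-pathway density with
  `n_edges ~ 1.3 * n_nodes`.  A draw may have no source at all, giving
  an entirely inactive (uninformative) study; this is left as-is.
- design: single knockdowns of every gene, `n_double` random double
  knockdowns, one unperturbed control.
- measurements: `mu_active = 0.95`, `mu_inactive = 0.245`,
  `theta = 0.6`, `sigma = 0.01`, 3 replicates (all configurable).
  The means sit on the [0, 1] activity scale consistent with the 0/1
  worst-case substitutions and the 0.95 source baseline.

What the generator does **not** emulate: partial knockdown efficiency,
gene-specific measurement variance, correlated antibody cross-talk,
temporal dynamics.  Passing tests therefore show correctness of the
inference machinery under the model's own assumptions, not performance
on real assays.

One consequence of the chosen means: after averaging 3 replicates even
`sigma = 0.2` misdiscretizes under 0.2% of cells, so the noise sweep's
AUC response is nearly flat — reconstruction error under these
conditions is identifiability-limited (multiple minimal networks
consistent with the same knockdown data), not noise-limited.

## Evaluation

Confusion metrics over ordered off-diagonal pairs (`directed`),
unordered pairs with either direction counting (`unsigned`), or the
relaxed `rep` mode in which a predicted edge `(a, b)` is correct when
the reference contains `(a, b)`, `(b, a)` or a directed path `a ~> b`,
and a reference edge is missed only when no predicted edge explains it
under the same rule.  Reported SP/SN/PR/AC are rounded to two decimals,
half away from zero (the convention that reproduces published
evaluation tables, including the 0.625 -> 0.63 tie).

Ranked-edge evaluation uses ROC AUC (trapezoid over the |weight|
threshold sweep; ties included simultaneously) and average precision
for the PR AUC — trapezoid interpolation of PR curves is biased, so
step-wise average precision is the default (a documented deviation,
configurable upstream via scikit-learn directly).  The three-class
evaluation (activation / none / inhibition) macro-averages
one-vs-rest AUCs with sign-specific scores (`w`, `-|w|`, `-w`);
classes absent from the reference are skipped.  Under this stand-in
the random-guessing expectation is 0.5 by symmetry of each
one-vs-rest sweep.

Random-guessing baselines relocate the reference's edges uniformly
among off-diagonal slots (edge count preserved); empirical p-values
are `(1 + #{null >= observed}) / (n_perm + 1)`.  A transitive-closure
utility supports comparisons against effects-propagation-style
equivalence classes; self-reachability on cycles is not materialized
as an edge (diagonal pairs are excluded everywhere).

## Benchmark protocols and problem sizes

The built-in benchmarks are sized for a single CPU:

- ten-node sweeps (noise, missingness, priors): the ten benchmark
  topologies with edge counts 5, 7, 7, 7, 7, 7, 8, 10, 12, 13;
  `loo_cells` CV with 20 holdouts over the reduced grid {0.1, 1};
  permutation baseline with 20 draws per network.
- size benchmark: networks of 16, 24, 32, 44, 52 nodes with
  ~1.3 edges/node, stratified 10-fold CV over the reduced grid;
  completes in well under a minute.

All randomness flows from explicit integer seeds; identical
configuration and seed give bit-identical outputs.

## Known limitations

- LP optima can be degenerate (several weight assignments with equal
  L1 cost); the deterministic simplex vertex returned by HiGHS is
  reproducible, but individual near-zero weights should be read
  through the median/MAD summary, not in isolation.
- The worst-case substitution for missing parents suppresses edges out
  of unobserved genes (they can never help an active constraint), so
  fully-unobserved genes are recovered at chance level; the method's
  value under missingness lies in keeping the *observed* subnetwork
  reliable.
- Propagation under inferred networks starts from the bias-driven
  baseline; activity sustained purely by a feedback cycle without a
  source path is not reproduced, which contributes to held-out
  prediction error on cyclic topologies.
- No time-course semantics: the model captures steady-state responses
  to persistent perturbations only.
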