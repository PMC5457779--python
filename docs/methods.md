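# Methods

## Model

An S-System describes `N` interacting biochemical components by power-law
production and degradation terms:

    dX_i/dt = alpha_i * prod_j X_j^g_ij  -  beta_i * prod_j X_j^h_ij

The real exponents (*kinetic orders*) `g_ij`, `h_ij` carry the network
topology — a zero exponent means no influence — and the positive rate
constants `alpha_i`, `beta_i` set the time scales.  The product may run
over additional independent variables (enzyme activities, uptake fluxes)
held at known constant values.  There are `N(2N+2)` parameters, which is
what makes naive least-squares fits of trajectories both expensive (every
candidate requires an ODE solve) and ill-posed (dense, overfitted
networks).

## Decoupled biobjective inference

Instead of fitting trajectories, each equation is fit independently to
estimated derivatives: given measured concentrations `X(t)` at `T`
uniform time points under `C` initial conditions, slopes `S_i` are
estimated by the five-point finite-difference formula (fourth order,
one-sided variants of the same order at the two points adjacent to each
boundary), and a candidate right-hand side is scored as

    err_i = sum_{c,t} ( S_i(c,t) - Shat_i(c,t) )^2

with `Shat_i` evaluated at the *observed* concentrations of all
components.  No candidate is ever integrated; this decoupling is what
makes population-based search affordable.

A candidate equation is encoded as a bit vector `bx` (2N connection
indicators) plus a real vector `rx` (2N kinetic-order candidates and the
two rate constants); kinetic orders decode as `g_j = bx_j * rx_j`.  The
two minimized objectives are `err_i` and the connection count
`L0 = sum(bx)`.  Because sparsity is counted through the bits, no
magnitude threshold is ever applied to prune connections — a structural
zero is an explicit decision of the optimizer, which is the central design
point of the whole approach.

### Independent variables

For the yeast fermentation benchmark the eight independent variables are
part of the experimental setup, not of the inference problem: their known
constant contribution to each equation (`K_prod_i`, `K_deg_i`, products
of the fixed values raised to their known exponents) multiplies the
candidate's rate constants during scoring.  Without this, the effective
rate constants (20–60 in model units) could not lie inside the search
range [0, 3], and recovered `alpha`, `beta` would not be comparable to
the published model.  The ground-truth simulator always keeps the
independent variables explicit.

## The mixed-variable evolutionary algorithm

Per equation, a population of `pop_size` (default 100) mixed solutions
evolves for `iterations` (default 2000) generations:

* **Binary variation** — three-parent recombination: where two reference
  parents agree, the offspring inherits the first parent's bit with
  probability 0.9 (else the agreed value); where they disagree, the first
  parent's bit is flipped with probability `0.5*CR`.  Parents come from
  the population and previous generation with probability `p1 = 0.8`,
  otherwise from the archive.
* **Real variation** — DE/rand/1 (`F = 0.5`) with binomial crossover
  (`CR = 0.9`) against the first parent, with the difference pair drawn
  from the parents with probability `p2 = 0.7` and otherwise from the
  slot's real-vector pool; out-of-bounds components are reflected back
  (clipping would concentrate mass on the bounds).
* **Survival** — parents and offspring are ranked by dominance depth;
  within a rank, ascending connection count, then lower error.  The best
  `pop_size` survive; the remainder update a fixed-size archive that
  evicts duplicated bit-strings first and otherwise the worst-error
  member.  A `gbest` individual is tracked (population with probability
  `p3 = 0.8`, else archive) for instrumentation; it does not enter
  variation.
* **Elite register and memetic polish** — the best solution ever seen at
  each connection count is kept in a side register.  This is required
  for a monotone front: ascending-L0 truncation drifts the population
  toward sparse duplicates while the error-only archive eviction discards
  sparse-but-imprecise members, so without the register the front at
  intermediate L0 degrades over long runs.  Every `polish_every`
  (default 250) generations each incumbent's reals are refined by bounded
  least squares with its topology fixed, and a pruned child (topology
  minus its weakest decoded connection) is refined too; improvements
  re-enter the register and the archive.  The pruning cascade is what
  lets exact sparse supports be discovered from easily-found dense ones —
  pure bit-flip variation locates an exact 5-of-10 support only slowly,
  and for the yeast system not at all within the default budget.

The returned front is the nondominated filter (best member per distinct
L0, strictly decreasing error) over the final population, archive and
elite register.  Independent restarts (`n_runs`, default 10) are merged
by the same filter.  All randomness flows through one seeded generator;
a root seed fans out to `(seed, equation, run)` child seeds so any run
reproduces bit-identically in isolation.

## Automatic selection (knee point)

Per front, both objectives are normalized by their maxima after dropping
the degenerate zero-connection member (its sparsity score of exactly 0
would make its aggregation product 0 for every `lambda < 1`, hijacking
the selection regardless of fit).  For each `lambda` on a uniform grid
(101 points) the member minimizing the aggregation product
`Score1^lambda * Score2^(1-lambda)` is selected per equation; the
selected scores sum to one vector per `lambda`.  The linear aggregation
sum is implemented for comparison but not used: it systematically picks
over-sparse networks.

Among the distinct nondominated sum vectors (sorted by summed fit score)
the knee is the point maximizing the tradeoff angle, computed as the
*bend* angle `pi - interior angle` at the point between its two
neighbours — zero on a straight segment, large at a sharp corner.
Endpoints have no two neighbours and are excluded; angle ties break
toward the sparser vector; with exactly two distinct vectors the
better-fitting one is chosen.  The final network is assembled from the
grid `lambda` closest to the midpoint of the interval of `lambda` values
that reach the knee vector (the interval itself is reported).

## Evaluation

Topology is scored structurally over the `2N^2` dependent kinetic-order
entries: TP/FP/TN/FN by nonzeroness, `TPR = TP/(TP+FN)`,
`FPR = FP/(TN+FP)` (0/0 := 0).  Sign agreement of true positives is
reported separately and does not enter the rates.  A lambda sweep yields
an ROC curve; dynamics of recovered vs. true networks are compared by
per-component trajectory RMSE over shared initial conditions.

## Synthetic data

`generate_dataset` draws initial concentrations i.i.d. uniformly per
component, integrates the ground truth with adaptive RK45
(`rtol 1e-8`, `atol 1e-10`), samples 15 uniform time points and attaches
five-point slopes.  Measurement noise is multiplicative Gaussian,
`X*(1+eps)`, `eps ~ N(0, rate^2)`, independent per observation, clipped
below at 1e-6, with slopes recomputed from the noisy series.  Defaults
follow the benchmark protocols: 4 conditions with initials in
U[0.5, 1.5] for the artificial network; 10 conditions with initials in
U[0.2, 2.0] for the yeast pathway.

**Sampling window.**  Neither benchmark's sampling interval is published.
The window bounds everything: the fifth derivative of the fast transients
(relaxation time ~0.1 in both systems) makes the five-point bias scale as
`dt^4 * f^(5)`, and a least-squares oracle at the true topology shows
that windows of 0.5 or longer shift the *optimum itself* by 10–70% —
incompatible with the published sub-2% recovery errors — while `[0, 0.2]`
(dt ~ 0.014, about two relaxation times) reproduces the published error
pattern, including the one equation that is known to be poorly
conditioned (its component reaches steady state almost immediately, so
its slope vector carries little information).  Both benchmarks therefore
default to `t in [0, 0.2]`, configurable.

What a green synthetic-data test establishes: that the estimator recovers
the generating structure under the stated noise model with known,
identical dynamics across conditions.  Real time-course data adds
unmodelled effects — correlated and heteroscedastic measurement error,
unobserved components, condition-to-condition parameter drift, irregular
sampling (unsupported by the five-point formula) — none of which the
generator emulates.

## Numerical choices and degenerate cases

* Candidate scoring clips observations at 1e-12 before taking logs, so EA
  evaluation is total even for pathological noise draws; the ground-truth
  simulator never clips and raises on positivity loss instead.
* `x^0 := 1` everywhere, including masked exponents and aggregation
  scores at `lambda` endpoints.
* Overflowing candidate errors become `+inf` (never NaN), which dominance
  handles naturally.
* Normalization of a degenerate front (all-equal objective) yields zero
  scores rather than dividing by zero.
* Assembled networks floor rate constants at 1e-12 (a decoded candidate
  with a zero rate would otherwise be unrepresentable as an S-System).
* Exact collinearity in the knee computation gives equal angles; the tie
  rule (sparser vector) decides.

## Known limitations

* Intrinsically weak connections (kinetic orders of magnitude ~0.01 at
  the observed concentration scales) are not identifiable from slope
  data: an exhaustive per-topology least-squares scan shows competing
  supports fit strictly better at every tested window.  The method then
  returns a sparser or substituted connection — the behaviour the L0
  objective is designed to prefer.
* Noise rates of 15% and above visibly corrupt the five-point slopes and
  recovery degrades to partially wrong, but still sparse, networks.
* Uniform time grids only; no stiff-solver heuristics; equations are fit
  independently, so a shared-parameter constraint across equations cannot
  be expressed.
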