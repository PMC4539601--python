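# Methods

## The modeling problem

`pertnet` infers cell-type-specific, executable models of signaling from
systematic drug-perturbation experiments. The data are a *response map*: a
matrix of log2(perturbed/unperturbed) changes in (phospho)protein levels and
cellular phenotypes measured across tens of perturbation conditions (single
targeted drugs at multiple doses, and drug pairs). The model is a network of
N nodes — proteomic, phenotypic, and unmeasured *activity* nodes through
which each drug's effect enters — coupled by nonlinear ODEs

    dx_i/dt = ε_i tanh( Σ_{j≠i} w_ij x_j + u_i ) − α_i x_i

where x_i is the relative response of node i, u_i the real-valued
perturbation input, w_ij the (discrete) strength of the influence of node j
on node i, ε_i the dynamic range and α_i the relaxation rate. Edge
strengths live on an 11-value grid {−1, −0.8, …, 0.8, 1}. Activity nodes
receive no in-edges; phenotype nodes, by default, emit none.

A network configuration W is scored by the cost

    C(W) = β Σ_{μ,i} (x_i^μ − x_i^μ*)² + λ Σ_{i,j} δ(w_ij) + Σ_{i,j} η(w_ij)

with predicted steady states x, measurements x*, an L0 complexity term
(δ(w) = 1 iff w ≠ 0) and the prior prize η. Defaults β = 2, λ = 5, κ = 5
(λ = 2.5 on edges into phenotype nodes when prior information is active)
follow the published parameter choice.

## Prior-knowledge restraints

Qualitative interactions from pathway databases arrive as SIF triples with
an activating / inhibitory / generic relation. The general form of the
prize treats the prior edge value as Gaussian with mean E[w^prior] and
spread σ^prior and applies an inverse-Boltzmann conversion,

    η(w) = −κ ln(1/(σ√2π)) + κ (w − E)² / (2σ²);

for binary database priors the value is uniform over the conforming
half-grid, the quadratic term vanishes, and η collapses to a step function:
−κ on the conforming values (w > 0 activating, w < 0 inhibitory, w ≠ 0
generic), 0 elsewhere. The prize is a *soft* restraint: an edge is realized
only when the prize outweighs the data misfit it introduces, so incorrect
priors can be rejected. Setting κ = 0 reproduces de novo inference exactly
(the prior network is ignored bit-for-bit). The rejection behavior is
testable by comparing accepted-prior counts under the database prior
against randomly generated pseudopriors of the same size.

## Belief propagation

Because the data constrain each target row of W independently (at steady
state the closure x_i* = tanh(Σ_j w_ij x_j* + u_i) involves only row i; the
inference assumes ε_i = α_i = 1, as the data are single-time-point steady
states), the Boltzmann distribution exp(−C(W)) factorizes over rows and BP
runs per target node. For every condition μ and candidate edge (i, k) a
cavity message ρ^μ(w_ik) is maintained; the cavity marginal excluding μ is

    P^μ(w_ij) ∝ e^{−λδ(w)} e^{−η(w)} Π_{ν≠μ} ρ^ν(w_ij)

and the message update sums the non-cavity parents out of the condition
constraint. Two routes implement that sum:

* **exact enumeration** over all 11^k configurations when the row has
  k ≤ `exact_cutoff` (default 3) non-cavity parents — the summation is
  cheap there and removes any approximation;
* **Gaussian mean-field** otherwise: the non-cavity input s = Σ w x* is
  treated as Gaussian with mean Σ w̄_ij x_j* + u_i and variance
  Σ Var[w_ij] (x_j*)², and the integral
  ∫ e^{−β(x_i* − tanh(s + ω x_k*))²} N(s) ds is evaluated by Gauss–Hermite
  quadrature (order 20).

Messages are initialized from seeded random distributions, updated with a
parallel (flooding) schedule in log space, and damped (default 0.5).
Convergence is declared when the largest absolute message change in a sweep
falls below 1e-3 (default), capped at 500 sweeps; non-convergence returns
the best marginals with a warning rather than raising. On tree-structured
factor graphs (single-parent rows; singles-only designs; single-condition
fixtures) the fixed point equals exhaustive Boltzmann enumeration; with
multiple overlapping pair conditions, loopy BP carries a small bias (a few
1e-3 on tiny dense fixtures), which is the expected behavior of the
algorithm, not an implementation artifact.

## BP-guided decimation

Distinct executable models are instantiated by decimation: repeatedly pick
a random unfixed edge, draw its value from the current marginal, clamp it
(its posterior becomes 1), and refresh the landscape by re-running BP from
the warm message state. The conditional-update heuristic skips the refresh
when the clamped value's pre-fix probability was ≥ 0.95, but forces one
after five consecutive skips so residual shifts cannot accumulate; clamps
at probability exactly 1 change nothing and are not counted as skips (this
makes decimation of already-deterministic marginals a pure read-out).
Because rows are independent, a refresh only recomputes rows with new
clamps — an exact optimization. Each of the n models restarts from freshly
randomized messages (seeded per model), sampling the solution degeneracy
of the cost landscape; ensembles are summarized by the average model
⟨W_ij⟩, edge frequencies f(|w_ij| > 0.2), and ensemble-mean predictions
with SEM.

## Model execution

Models are integrated with LSODA from the basal state x = 0 until
max_i |dx_i/dt| < 1e-6 (default) or t = 1000. The published record lists
ATOL = 1e-10 and RTOL = 1e-20; the latter is below double precision, so
the default is RTOL = 1e-10 with a `strict` flag that forwards the literal
value. A damped fixed-point iteration provides an independent route to the
same steady states on contractive models and is used as a cross-check.
Sustained oscillations (possible for high-gain inhibitory rings) are
reported as non-converged states, and excluded (and counted) from ensemble
predictions.

## Synthetic data and what a green test establishes

The generator emulates the structure of the experimental study — 89
conditions over 99 nodes (82 proteomic, 5 phenotypic, 12 activity) at full
scale: every drug pair plus two doses of each single agent. The published
count of 89 equals 66 pairs + 23 singles, one short of 12 × 2 singles, so
the full-scale design drops the last single-agent dose. Ground-truth
networks are sparse random draws over the structurally allowed edge slots
(each activity node wired to at least one proteomic target; values uniform
on the nonzero grid), responses are the true model's steady states, and
noise is additive Gaussian on the log2 scale (default sd 0.05, roughly the
replicate spread implied by a 15% CV ceiling on linear intensities) applied
to measured columns only — activity columns are design-derived inputs, not
measurements.

The parameter-recovery world used in the acceptance suite has 10 nodes
(4 proteomic, 1 phenotypic, 5 activity), 15 edges, and 40 noiseless
conditions (5 × 2 single doses + 10 pairs × 3 dose combinations, doses 1
and 2 in perturbation-strength units; inputs are inhibitory, u = −dose).
Five activity nodes are the smallest number whose pairs-plus-singles design
reaches 40 conditions; dose asymmetry in the pair conditions breaks source
collinearity. Under the default cost (λ = 5, β = 2), edges whose source
node carries little signal are *correctly* suppressed — the Boltzmann
optimum is sparser than the truth — so recovery is evaluated as sign
accuracy on strong (|w| ≥ 0.6) edges and correlation between truth and the
ensemble-average ⟨W⟩, not exact support recovery. Synthetic tests establish
algorithmic correctness and recovery in a well-excited noiseless regime;
they do not establish performance on real RPPA data (antibody
cross-reactivity, unmeasured nodes, non-steady-state effects are not
emulated).

## Numerical and design choices

* Activity-node response columns are not measured; they are synthesized
  from the design as tanh(−strength) ∈ [−1, 0] (0 when untargeted), the
  steady state an isolated activity node reaches under its input. This
  makes loaded data and simulated data consistent by construction.
* The 2.5σ signal filter recenters on the mean of the currently unflagged
  points each iteration and pools all data points across nodes; the CV
  filter uses the sample CV (ddof = 1) on the linear scale and drops nodes
  with undefined (zero-mean) CV with a warning.
* Map-estimate networks break exact marginal ties toward smaller |w|, then
  the lower grid index.
* Decimation draws edges uniformly at random among unfixed edges; sweep
  and draw randomness derive from one seed per model, making ensembles
  reproducible.
* Files with missing cells are rejected rather than imputed.
* Screen strengths are applied as inhibitory inputs (u = −strength), with
  four default levels standing in for the dose tags of the experimental
  protocol.

## Known limitations

* Loopy-BP bias on dense multi-condition fixtures (see above) is small but
  nonzero; the exact-enumeration route bounds it only for small parent
  sets.
* Steady-state data cannot distinguish collinear sources; the ensemble
  splits mass across near-equivalent wirings rather than resolving them.
* Phenotype out-edges and edges into activity nodes are structurally
  excluded by default; real feedback from phenotype-scale processes onto
  signaling is outside the model class.
* The inference closure fixes ε = α = 1; simulated predictions honor
  per-node ε, α, but no fitting of those constants is provided.
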