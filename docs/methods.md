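# Methods

`velotraj` infers differentiation trajectories by *simulating* the process
that RNA velocity describes, instead of fitting curves to the geometry of the
data. This note documents the model, the parameters that matter, the
synthetic data the package is validated on, and the numerical choices made
where the design was genuinely open.

## Model overview

A single-cell dataset with RNA velocity defines a vector field on the
expression manifold: each cell carries an estimate of d(expression)/dt. The
package turns this field into a Markov chain over observed cells and treats
differentiation paths as realizations of that chain.

**Transition model.** For each cell `c`, its `k` nearest neighbors (Euclidean
distance in PCA space, default `k = 30`, ties broken by cell index) are its
possible transition partners. The velocity graph stores
`γ(c, j) = cos(velocity(c), x_j − x_c)` — the agreement between the cell's
velocity and the displacement to neighbor `j`, computed in gene space by
default (PC space optional, projecting velocity through the component
loadings). Zero-norm vectors yield cosine 0. The transition matrix is an
exponential kernel on these cosines,

    P(c, j) ∝ exp(γ(c, j) / τ),     row-normalized over the k neighbors,

with scale `τ = 0.1` by default: a sharpened kernel that concentrates mass on
the best-aligned neighbors while keeping every neighbor reachable. The scale
is deliberately exposed as configuration; larger values approach a uniform
walk on the k-NN graph, smaller values approach a deterministic flow.

**Root and terminal states.** The terminal-state probability of a cell is the
stationary distribution of the forward chain `P`; the root-state probability
is the stationary distribution of the reversed chain (transpose of `P` with
rows re-normalized). Both are computed by power iteration (tolerance 1e-10,
at most 10,000 iterations, uniform start) and rescaled so the maximum is 1,
which gives them a per-cell probability reading. Cells at or above a
threshold (default **0.99**) form the root set `Cr` and terminal set `Ct`;
the cluster labels covering `Ct` are the terminal regions `St`. Both sets can
instead be supplied by the user — as cells or whole clusters — and this is
the expected mode for processes where the stationary analysis recovers only
the dominant terminal state (see *Known limitations*). When both root and
terminal states are supervised the stationary computation is skipped
entirely, which also covers cyclic processes whose oscillatory spectrum
prevents power-iteration convergence.

**Simulation.** Each simulation starts at a root cell chosen uniformly at
random and performs `i_max` transitions; a step draws `κ ~ U[0, 1)` and picks
the first neighbor whose cumulative row probability reaches `κ`. Defaults
scale with dataset size: `i_max = round(5·log10(n))` steps and
`m = round(500·log10(n))` unique terminating simulations required per
terminal region (five extra steps, and 500 extra simulations, per order of
magnitude). The sampler iterates batches (default `4·m` per terminal region
per iteration) and adjusts:

- if at most 10% of a batch terminates inside any terminal region, the step
  count doubles (the simulations are too short to traverse the manifold);
- otherwise, if the lagging region holds fewer than 60% of `m` unique
  simulations, the step count is incremented by
  `i_max · m / max(i_max, |lagging set|)`;
- sampling continues until every region holds `m` unique terminating
  simulations (uniqueness judged on the exact cell-index sequence; a region
  stops accumulating at `m`), or a bounded number of iterations (default 10)
  is exhausted, which returns with a warning rather than searching forever.

The two adjustment rules are applied mutually exclusively within an
iteration: when overall termination is poor the lagging-region statistic
carries no information. Step growth is capped at four times the cell count —
a chain that long has had every opportunity to traverse the manifold — so a
topology quirk cannot push the step count into pathological territory.

**Consensus trajectories.** Per terminal region, the retained simulations
(as sequences of PCA coordinates) are compared with the Euclidean Hausdorff
distance `H(A,B) = max(max_a min_b d(a,b), max_b min_a d(b,a))` and clustered
by Louvain community detection on an affinity graph
`exp(−H²/σ²)` with `σ` the median off-diagonal distance, sparsified to each
node's `min(15, n−1)` strongest edges. Each cluster is collapsed by
greedy-pairwise dynamic time warping: sequences are taken longest-first, each
next sequence is aligned to the running consensus, and both are expanded
along the warping path; the per-step mean is the sub-trajectory. A second
clustering + alignment round over the sub-trajectories yields the reported
trajectories. DTW uses the exact dynamic program (boundary, monotonicity and
continuity constraints; ties in the traceback prefer the diagonal) for
sequences up to 200 steps and a banded approximation beyond, both exposed in
configuration. Trajectories can optionally be anchored to observed cells
(each step snapped to the nearest cell state). The number of trajectories per
region is unconstrained by default; a user-requested count is enforced by
merging the closest sub-trajectory groups under Hausdorff distance (a
requested count *above* the unsupervised one warns instead — splitting a
consensus is not well defined).

**Cell scoring.** For each trajectory, step neighborhoods `M_i` (default 50
nearest cells per step, k-d tree in PCA space) define the *compositional
clusters*: clusters whose frequency in some `M_i` exceeds 0.3. Cells of
compositional clusters are scored against the trajectory's segments: with
transition partners `K` (the cell's neighbors in the transition model), the
score of segment `b` (step `i−1 → i`) is

    ξ_ib = (1/|K|) Σ_k cos(η_kb) · exp(γ_k),

where `η_kb` is the angle between the segment and the displacement to partner
`k` (PCA space) and `γ_k` is the stored velocity cosine. `exp` is taken with
natural base on the raw cosine, so partner weights span `[e⁻¹, e]`. The
per-step score `p_i = max(ξ_ib, ξ_if)` uses whichever of the backward/forward
segments agrees better (boundary steps use their single segment); negative
`p_i` is floored at 0. By default a cell is scored only at steps whose
neighborhood contains it; a flag lifts the restriction.

From the step scores follow:

- **pseudotime** — the score-weighted mean step index `Σ i·p_i / Σ p_i` per
  trajectory (invariant to rescaling a cell's scores; cells with no positive
  score stay NaN, never 0), plus a consensus pseudotime across trajectories
  as the fate-weighted mean;
- **summary alignment** `p` — the mean of `p_i` over positively scoring
  steps;
- **fate** — `p` row-normalized over trajectories (simplex rows);
- **differentiation potential** — Shannon entropy of the fate row, min-max
  rescaled over scored cells (degenerate all-equal case maps to 0 with a
  warning);
- **Euclidean pseudotime** — a non-velocity baseline: the end-step index of
  the nearest trajectory segment (point-to-segment distance in PCA space,
  ties to the lower index);
- **velocity cohesiveness** — the mean of a cell's velocity-graph row;
- **terminal-state frequency** (from 5000 undirected 30-step simulations)
  and **simulation step density** — `log1p` of per-cell termination/arrival
  counts, the former min-max rescaled. `log1p` handles zero counts; arrivals
  exclude the initial state.

Rolling pseudotime comparisons fit a least-squares line of one pseudotime
against another in a 50-cell window centered on each cell (clamped at the
boundaries).

## Synthetic data

The generator places cells on smooth curves in a 50-gene space: each gene is
one Gaussian bump along process time `t ∈ [0,1]` (sd 0.12 in time units;
periodic bumps for the cyclic topology so the curve closes). Branching
topologies assign half the genes to the trunk and half to branch-specific
programs whose bump centers sit ≥ 3 sd past the branch point, so expression
diverges smoothly after it; the convergent topology mirrors this with two
root programs merging into one trunk. Velocity is the analytic tangent
`d(expression)/dt`, optionally rescaled by a per-time magnitude profile.
Expression noise is iid Gaussian truncated at 0 (default sd 0.05, roughly 5%
of bump amplitude); velocity noise is isotropic Gaussian at the same default.
Cluster labels are equal-width bins of true time per branch (5 per branch,
8 for the cycle) — a stand-in for Louvain clustering with a known
correspondence to the planted structure. PCA (10 components, deterministic
full SVD) provides the low-dimensional representation, its first two
components the display embedding.

What the generator does *not* emulate: count noise and sparsity, the
spliced/unspliced estimation error structure of real RNA velocity (which is
strongly gene- and regime-dependent), doublets, batch effects, or uneven cell
density along the process. Passing the recovery suites therefore shows that
the inference machinery is correct and well-conditioned, not that every real
dataset will resolve equally cleanly — in particular, real velocity noise is
correlated across genes, which can bias (not just blur) the transition
directions.

Hand-written 4–8 state chains with analytically known stationary behavior
(`absorbing4`, `uniform3`, `twobranch6`, `cycle4`) serve as oracles for the
stationary and sampling code.

## Validation protocols and problem sizes

The test and acceptance runs use 500-cell datasets: large enough for stable
neighbor statistics at `k = 30` (where `m ≈ 1350` unique simulations per
region), small enough that a full pipeline run completes in well under a
minute per topology.

- *Linear*: everything inferred from the data; expected 1 terminal region,
  1 trajectory, pseudotime–truth Spearman ≥ 0.9 (observed ≈ 0.999).
- *Bifurcating / multifurcating*: terminal regions supervised with the
  planted terminal clusters — the protocol a practitioner uses when the
  stationary threshold recovers only the dominant fate (see below) — root
  inferred; one trajectory per fate, post-branch cells receive ≥ 0.8 fate for
  their own branch. Terminal-state *discovery* is validated separately: the
  cells with the highest undirected-simulation termination frequency
  concentrate in the planted terminal clusters.
- *Cyclic*: root and terminal supervision at adjacent phase checkpoints, one
  enforced trajectory, and the step count set by the first-passage
  calibration (median first arrival at the terminal region over a 500-path
  pilot). Without the calibration the doubling schedule tends to overshoot
  the single-lap step count on a noiseless cycle — the coherent probability
  packet laps the circle and only terminates once dispersion covers it —
  which yields a wrapped, multi-lap consensus. Expected: phase bins traversed
  in cyclic order, per-quarter-arc Spearman ≥ 0.8.
- *Convergent*: 1 terminal region described by 2 trajectories, one per
  origin — the package reports per-origin paths rather than averaging two
  unrelated prefixes into one.
- *Two-speed linear* (velocity magnitude halved on the second half, velocity
  noise 0.3): the slow half shows both lower cohesiveness·|velocity| and a
  lower local rate of geometric progress per pseudotime step. The geometric
  rate is measured as the rolling slope of the *arc-length* position of the
  nearest-segment assignment against pseudotime; raw segment indices share
  the trajectory's step density with pseudotime itself and would cancel the
  signal. The comparison is a sign test on the planted halves: per-cell
  cohesiveness on a one-dimensional manifold is a mean over symmetric
  forward/backward neighbors and is therefore near zero-centered, so only
  aggregate contrasts are meaningful.

## Numerical choices

- Stable softmax (row-max subtraction) for the transition kernel.
- k-NN by stable argsort of full distance rows: exact, deterministic,
  tie-broken by index. Fine for the 10³–10⁴ cells this package targets.
- Power iteration normalizes by L1 mass each step; reversed-chain rows with
  no in-edges hold their mass in place.
- Pairwise Hausdorff and the DTW dynamic program are numba-compiled; the
  Hausdorff inner loop abandons a point as soon as it cannot raise the
  directed maximum.
- All randomness flows from a single integer seed: NumPy generators for
  sampling, the igraph RNG (seeded and restored around each call) for
  Louvain. Identical seeds reproduce byte-identical outputs.
- Degenerate cases are explicit: empty root/terminal selections raise with
  the suggestion to lower the threshold or supervise; all-equal min-max
  rescales map to 0 with a warning; unaligned cells carry NaN, never a fake
  0.

## Known limitations

- The stationary threshold typically recovers only the strongest terminal
  state when several fates compete: quasi-stationary mass concentrates
  per-cell very unevenly across regions. This matches the behavior reported
  for real differentiation data; the remedy is terminal supervision or the
  undirected-simulation discovery statistic, both first-class here.
- Power iteration does not converge on strongly periodic chains; cyclic
  processes should be run fully supervised (which skips it).
- The transition kernel uses cosine direction only; velocity *magnitude*
  influences nothing directly, so progression speed is observable only
  through noise-mediated coherence (cohesiveness), not through step length.
- Greedy-pairwise DTW is order-dependent; longest-first is a fixed, sensible
  schedule but not an optimal multiple alignment.
- Fate scores are alignment-mass ratios, not absorption probabilities of the
  chain; the two agree qualitatively but are not the same quantity.
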