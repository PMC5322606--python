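# Methods

## Model

A single discrete character with ordered state alphabet of size s evolves
along a rooted phylogeny under a homogeneous continuous-time Markov chain
with instantaneous rate matrix Q (off-diagonals ≥ 0, rows summing to zero).
Branch lengths are in whatever units the input trees carry (time or expected
substitutions); all dwelling times inherit those units.  Three constraint
classes parameterize Q: ER (1 free rate), SYM (s(s−1)/2, q_ij = q_ji) and
ARD (s(s−1)).  ER and SYM matrices are symmetric, hence reversible with a
uniform stationary distribution; ARD matrices may be non-reversible.

Tip data are non-empty state subsets per taxon: singletons are observations,
proper subsets ambiguity, the full set missing data.  The likelihood of tip
data is computed by the pruning (postorder) recursion with per-node
rescaling, so trees with thousands of tips do not underflow.

## Analytic branch expectations

Let Q = U diag(λ) U⁻¹.  For a branch of length T define

    J_kl = ∫₀ᵀ e^{λ_k τ} e^{λ_l (T−τ)} dτ = (e^{λ_k T} − e^{λ_l T})/(λ_k − λ_l),

with the limit T·e^{λ_k T} when |λ_k − λ_l| < 1e-9·max(1, |λ|).  Conditional
on endpoint states (a, b), the expected time spent in state i is

    D_i(a,b) = [Σ_{k,l} U_{ak} U⁻¹_{ki} U_{il} U⁻¹_{lb} J_{kl}] / P_ab(T),

and the expected number of i→j jumps is

    N_ij(a,b) = q_ij · [Σ_{k,l} U_{ak} U⁻¹_{ki} U_{jl} U⁻¹_{lb} J_{kl}] / P_ab(T).

The per-branch posterior over endpoint pairs is W_ab ∝ g(a)·P_ab(T)·f(b),
where f is the child's pruning partial and g the "outside" vector of the
parent excluding the child's subtree (root prior included).  The reported
per-branch expectations are the W-weighted averages of D and N.  In the
implementation the endpoint sum collapses: with α = gU and β = U⁻¹f, the
matrix B = U⁻ᵀ (α ⊗ β ∘ J) Uᵀ holds every dwell numerator on its diagonal
and every pairwise numerator off it, normalized by g·P(T)·f.  This is one
O(s³) product chain per branch, which is what makes whole-posterior analyses
O(t·n·s³).

Away-from-state counts are always the row sums of the pairwise matrix, never
computed independently; pairwise i→j expectations are exposed as an
additional output.  Dwelling times are reported both in branch-length units
and as fractions of branch length; transition counts as absolute
expectations, with a per-unit-length rate available.

Degenerate cases: a zero-length branch gets zero dwell and zero transitions
with P(0) = I; endpoint pairs with P_ab(T) = 0 carry exactly zero posterior
weight, so the (undefined) conditional values never enter any sum — the
standalone endpoint-conditioned functions report them as NaN by design.

### Numerical regime

ER/SYM matrices are symmetric and use `eigh` (real orthogonal
decomposition).  ARD matrices use the general decomposition; complex
eigenvalues are tolerated, intermediates stay complex, and results are
accepted only if imaginary parts are below 1e-8, otherwise an error directs
the caller to the quadrature fallback (`method="quadrature"` in `map_tree`),
which integrates the defining integrals with adaptive quadrature on
`expm` and needs no diagonalizability.  An eigenvector condition number
above 1e12 triggers the same advice.  Transition-probability matrices are
clipped to [0, 1] after verifying negatives exceed −1e-12.

## Q estimation

The negative pruning log-likelihood is minimized in log-rate space with
L-BFGS-B, rates bounded to [1e-8, 1e3] divided by the mean branch length,
objective tolerance 1e-10.  Three multistarts by default: one at the
heuristic rate n_tips/tree_length, the rest log-uniform from a seeded
generator; the best converged optimum is kept, with its log-likelihood and
convergence flag attached to the returned model.  Several independent
characters can be fit jointly (the pruning pass is vectorized across
characters).  Over a tree set, Q is estimated per tree by default, with a
`pooled` mode (fit once on the first tree, reuse everywhere — the
"empirical" convention of simulation-based implementations) and a `user`
mode that takes Q as given.

The root prior defaults to uniform (1/s).  It is exposed as
{uniform, stationary-of-Q, explicit vector} and recorded in output metadata;
whether ancestral-state software should fix π at the stationary distribution
is a long-standing modelling choice, and this package treats it as exactly
that — an option, not a hidden default.

## Posterior summarization and painting

Branches are matched across rooted trees by descendant tip-label set.  This
is deliberately root-dependent; no rerooting or unrooted bipartition
matching is attempted.  Matching works on non-bifurcating trees too, since a
clade either occurs or not.

Dwelling fractions map to 21 tones at 5% steps by nearest-multiple rounding:
bin k covers ((k−0.5)·5%, (k+0.5)·5%], with bin 0 = [0, 2.5%] and
bin 20 = (97.5%, 100%].  The edge convention is a package choice (only the
step size is canonical) and is recorded in the legend metadata.  Transition
counts use 21 equal-width bins on [0, max observed across matched target
branches].  Every posterior tree carries weight 1/t (an equally weighted
MCMC sample is assumed).  Each target branch's binned distribution sums to
its matched fraction; the remainder is painted gray along the branch, and a
`renormalize` option rescales partially matched branches to total mass 1
instead — both behaviours are offered because only the fully-unmatched
(gray) case has a canonical answer.  Segment order along a branch is
gray first, then decreasing mass; a fixed rule keeps figures deterministic.
SVG output is written directly with per-segment `data-clade`/`data-share`
attributes so painted shares are machine-checkable; PNG/PDF render the same
geometry through matplotlib.

## Synthetic data

The generator produces the verification conditions used throughout the test
suite: an ultrametric pure-birth (Yule) tree and a binary character evolved
under an ER CTMC with rate 1.0 per unit branch length.

* **Pure-birth trees.**  The process starts at the root split with two
  lineages; with j lineages extant the next speciation arrives after
  Exp(j·λ) and a uniform lineage splits; after the n-th lineage appears a
  final Exp(n·λ) interval separates the last split from the present.  The
  expected root-to-tip depth is therefore Σ_{j=2..n} 1/(jλ), which the test
  suite checks by Monte Carlo.  With λ = 1 and n = 128 the tree spans ≈3.7
  time units, giving a binary character at rate 1 a few dozen expected
  transitions — informative but not saturated.
* **Character histories** are exact Gillespie realizations down the tree
  (root state from π), retaining every (state, duration) segment, so
  realized dwelling times and transition counts are known exactly.
* **Endpoint-conditioned paths** are drawn by uniformization: the jump count
  N given endpoints follows the conditioned Poisson mixture
  P(N=n|a,b) ∝ Pois(n; μT)·Rⁿ_ab with μ = max_i(−q_ii) and R = I + Q/μ; the
  uniformized chain is then sampled exactly by backward smoothing against
  powers of R, jump times are uniform order statistics, and virtual jumps
  collapse.  If μT would exceed 10⁴ expected auxiliary events, rejection
  sampling of forward paths replaces it.
* **Simulation-based stochastic mapping** samples all node states jointly
  from their conditional posterior (root from π·F_root, each child from
  P_ab(T)·F_child(b)) and fills branches with endpoint-conditioned paths.
  `simulate_mappings` returns full histories; `simulate_mapping_totals` is
  the identical sampler vectorized across replicates (grouped by branch,
  endpoint pair and jump count) returning only per-replicate tree totals,
  which makes 50,000-replicate comparisons run in under a second.

What the generator does **not** emulate: rate heterogeneity across the tree
or among branches, extinction (no birth–death trees), correlated characters,
sampling biases, and phylogenetic error in the input trees themselves.
Passing tests therefore demonstrate internal correctness of the expectations
and their Monte-Carlo consistency, not robustness of the CTMC model to
real-data violations.

## Verification design and problem sizes

Three independent routes to the same quantities are required to agree
(the "triangle"): the analytic expectations, adaptive quadrature of the
defining integrals on `expm` (no eigendecomposition), and endpoint-
conditioned path simulation.  Likelihoods are checked against exhaustive
enumeration over all ancestral assignments on trees small enough to
enumerate (≤ 6 tips, s ≤ 3).  Whole-pipeline Monte-Carlo agreement uses a
16-tip binary fixture with 50,000 mapping replicates and a 3-standard-error
band; rate recovery uses 100 characters on a 128-tip tree over 20 seeds.
The runtime-scaling check asserts only linearity (through-origin R² of time
vs. tree count), never absolute times.  These sizes keep the full suite and
the acceptance script each within a few minutes on one core while leaving
the Monte-Carlo bands tight enough to be meaningful.

The accuracy harness (`statemap verify`) defaults to 32 tips with a
replicate ladder {100, 250, 500, 1000, 2500} across 20 seeds, reporting
analytic, simulation-mean and true values per seed; a single-simulation
comparison is anecdotal, which is why the harness always spans seeds.

## Known limitations

* Expectations only: no sampled full histories are returned for downstream
  character-correlation analyses (the simulators can produce them, but they
  are verification tools, not the analysis product).
* The public per-branch summary reports transitions *away from* each state;
  pairwise i→j expectations are available as an extension output.
* No Bayesian sampling of Q, no gamma rate heterogeneity, no covarion-style
  models.
* Clade matching is strict rooted tip-set identity; a branch whose clade is
  absent from the posterior is reported gray rather than approximately
  matched.
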