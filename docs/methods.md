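# Methods

This note records the model, the sampler, the defaults and the numerical
choices in `acctrait`, together with what the built-in validation studies do
and do not demonstrate.

## Model

Data for one element are: a rooted bifurcating phylogeny **T** with L
leaves, N = 2L−1 nodes and E = N−1 edges (branch lengths t in expected
neutral substitutions per site); an L×S nucleotide alignment forming the
observed rows of the N×S matrix **X**; a length-L observed trait vector
forming the leading entries of the length-N vector **y**; and a neutral
substitution model (Q, π). Ancestral rows of **X**, ancestral entries of
**y**, the per-branch conservation states **z**, and all parameters are
latent.

Branch states follow the root-to-tips Markov chain Φ(a, b, c) with
structural zeros (no 2→1, 3→1 or 1→3 transitions) and root prior
(½, ½, 0). Sequence evolution on a branch is the neutral CTMC scaled by
r_{z_j} with r = (1, r₂, r₃); trait evolution is Brownian with variance
t_j·v_{z_j}, v = (σ², β₂σ², β₃σ²); y_root ∼ N(0, 1). The joint density is
the product of per-site per-edge nucleotide transition probabilities, the
per-edge trait displacement densities, the per-edge state transition
probabilities, the root terms (π per site, the root trait prior, the root
state prior) and the parameter priors.

Priors (all Normal second parameters are **variances**): r₂ ∼ Gamma(5,
0.04) and r₃ ∼ Gamma(10, 0.2) in shape–scale form, so E[r₂] = 0.2;
log σ² ∼ N(0, 2); log β₂, log β₃ ∼ N(0, 1) — equivalently
log(β₃/β₂) ∼ N(0, 2); a, b, c ∼ Beta(1, 1).

Because roughly half the nodes of a tree are unobserved, β₂ and β₃ are
poorly identified separately; inference and ranking therefore focus on the
ratio log(β₃/β₂).

## Sampler

One Gibbs sweep executes five blocks in order:

1. **Trait block.** `n_inner` (default 500) Metropolis iterations. Each
   iteration flips an independent Bernoulli(0.6) coin: parameter move
   (one of log σ², log β₂, log β₃ chosen uniformly; Gaussian random walk,
   default step s.d. 0.3) or latent-trait move (one latent node chosen
   uniformly; Gaussian step with s.d. 0.5·√(median branch length · current
   σ²), tying the proposal to the model's own diffusion scale). Per-state
   sufficient statistics (edge counts and Σd²/t) make parameter proposals
   O(1) and latent moves O(degree).
2. **Ancestral sequences.** Felsenstein pruning over the observed leaf rows
   (per-node per-site rescaling guards against underflow), then exact
   forward sampling root-to-tips. Leaves with gaps/ambiguity contribute
   all-ones partials (missing data); partial IUPAC information is
   deliberately not used.
3. **States.** Tips-to-root log messages combine, per candidate state, the
   branch's summed per-site log transition probabilities for the *current*
   filled-in X, the trait displacement density, and log-sum-exp mixing of
   child messages through Φ; then exact root-to-tips categorical draws.
   The root's nucleotide-π and trait-prior terms do not depend on the root
   state and cancel from its conditional.
4. **Rate multipliers.** One Metropolis step each on log r₂ and log r₃
   (default step s.d. 0.3) against the complete-data sequence likelihood
   of the edges currently in that state (grouped by distinct branch length
   so one matrix exponential serves many edges) plus the Gamma prior and
   the log-scale Jacobian. A state with no edges samples from its prior.
5. **Φ.** Conjugate draws c ∼ Beta(1+n₁₂, 1+n₁₁), a ∼ Beta(1+n₂₃, 1+n₂₂),
   b ∼ Beta(1+n₃₂, 1+n₃₃) from the parent→child state transition counts.

Matrix exponentials are cached per distinct scaled distance r_k·t_j and
recomputed only when (r₂, r₃) change. All tree recursions are scheduled by
level (nodes of equal height/depth processed as one vectorized batch).

Defaults: 10,000 sweeps × 3 chains, burn-in fraction 0.5, thinning 1,
convergence flagged when every monitored scalar's classic split-chain
Gelman–Rubin statistic is < 1.01 (a rank-normalized variant is reported
alongside but does not drive the flag). Chains start from independent prior
draws with re-initialized latent data (ancestral nucleotides from π, latent
traits at the mean of observed descendant leaves) so the diagnostic is
meaningful. No proposal adaptation is performed during sampling.

## Model selection

The null model pins β₂ = β₃ = 1. The Bayes factor in favour of the full
model is the Savage–Dickey density ratio at (log β₂, log β₃) = (0, 0):
prior density 1/2π exactly, posterior density from a bivariate Gaussian KDE
(Scott bandwidth, configurable) over the pooled post-burn-in draws of all
chains. At least 500 samples are required; degenerate (zero-variance)
samples raise an error rather than returning a misleading number. Evidence
labels are inclusive: BF ≥ 100 "overwhelming", BF ≥ 30 "very strong".
Rankings exclude non-converged elements to a side table by default.

## Simulator

`sim_z`, `sim_X`, `sim_y` draw states, alignments and traits from exactly
the generative model above, and `sim_study_replicate` composes them:
prior-draw mode samples every parameter from its prior before simulating;
null mode (`neutral_override`) applies one uniform rate multiplier to every
branch with β₂ = β₃ = 1 (the false-positive-rate scenarios: 1.0 neutral,
0.2 conserved, 0.5 barely conserved) and optionally fixes the leaf traits
to a supplied vector. Full ancestral truth is always retained. Whether the
reference experiments drew (a, b, c) from their priors was not stated; the
default draws them (any value can be fixed in `SimConfig`).

The simulator emulates gap-free, independently evolving sites under a
single per-branch rate and a homoskedastic Brownian trait. It does not
emulate alignment error, indels, site-rate heterogeneity, or correlated
traits, so passing validation studies demonstrates correctness of the
inference machinery under the model's own assumptions, not robustness to
their violation on real data.

## Validation studies and replication sizes

The ideal-tree studies use the 128-tip ultrametric tree (depth 7, all
branch lengths 0.1) with 80 bp elements and the Jukes–Cantor neutral model
(the neutral Q for the ideal-tree experiments is not dictated by the model;
JC is the neutral reference point and any `.mod` file can be substituted).

The packaged replications are scaled for a desk-class single-CPU run:

* **Parameter recovery / coverage**: 30 prior-drawn replicates (24 in
  `scripts/acceptance.py`), each fit with 2 chains × 1,000 sweeps.
* **False positive rates**: 50 null replicates per scenario (30 per
  scenario in the acceptance script), each fit with 2 chains × 600 sweeps.
* **Prior recovery**: 10,000 thinned draws (thin 22 after 4,000 burn-in
  sweeps) on a 4-leaf tree with an all-missing 2-column alignment and no
  observed traits, screened per parameter by Kolmogorov–Smirnov at
  p > 0.01. Thinning reflects the measured integrated autocorrelation time
  (~13 sweeps) of r₂, the slowest-mixing scalar, whose update is a single
  Metropolis step per sweep.

For the scaled studies the convergence screen uses a split-R̂ threshold of
1.1 rather than 1.01: with 500–1,000 post-burn-in draws per chain the
sampling noise of R̂ itself is of order 0.01–0.1, and the strict threshold
would reject mostly at random. MSE and interval coverage are aggregated
over every replicate; FPR — a decision about which fits one would report —
is computed over replicates passing the screen, with the screened-out count
reported separately.

## Numerical choices and edge cases

* Pruning uses per-node, per-site linear-space partials with running log
  scale factors; messages and state draws are entirely in log space with
  max-shifted log-sum-exp. Structural zeros of Φ enter as −∞ log entries.
* Transition-matrix rows are renormalized only when drift exceeds 1e-12;
  matrices are clipped at 0.
* Branch lengths of exactly 0 are rejected at parse time (the trait
  variance t·v degenerates); users must pre-collapse zero branches.
* All-missing alignment columns are retained (likelihood one) so S is
  stable; a fully missing element plus missing traits is valid input and
  samples from the prior.
* `update_phi` raises if the current states contain a transition with zero
  prior probability — that indicates internal corruption, never data.
* Ties in the element ranking break stably by element id.
* Every run is reproducible: one master seed drives per-chain and
  per-replicate `SeedSequence` children; identical seeds give bit-identical
  traces.

## Known limitations

* Single rate per branch and no within-branch state changes; branch length
  does not modulate the state-transition probabilities of Φ.
* No Ornstein–Uhlenbeck or jump trait models; no site-rate variation or
  indel model.
* β₂ and β₃ are reported individually but only their ratio is well
  identified; interpret marginal summaries of either alone with caution.
* The KDE-based Savage–Dickey estimate is noisy for very large BFs (tiny
  posterior density at the origin); ranking among extreme elements is
  approximate.
* The "barely conserved" null (uniform rate 0.5) conflates r₂ and r₃ and
  mixes slowly; expect more screened-out replicates there.
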