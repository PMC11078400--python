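# acctrait

Bayesian association of substitution-rate shifts in conserved non-coding
elements (CNEs) with the rate of evolution of a continuous trait.

Comparative genomics routinely finds CNEs that are accelerated on particular
branches of a phylogeny. `acctrait` asks a sharper question: *is the pace of
sequence evolution of an element linked to the pace of evolution of a trait
I care about?* It answers it with a latent-state phylogenetic model fit by
MCMC, and ranks candidate elements by a Bayes factor.

## The model

Each branch of a rooted phylogeny **T** (branch lengths in expected neutral
substitutions per site) carries a latent conservation state
z ∈ {background, conserved, accelerated}. States evolve root-to-tips by a
Markov chain with transition matrix

    Φ = [ 1−c   c    0  ]
        [  0   1−a   a  ]
        [  0    b   1−b ],   (a, b, c) ∈ (0,1)³,

whose structural zeros forbid returning to background and jumping straight
from background to accelerated. The root is background or conserved with
probability ½ each.

The state of a branch scales two processes at once:

* **Sequence.** Nucleotides evolve by the neutral CTMC (rate matrix **Q**,
  stationary distribution **π**, both inputs) scaled by rate multipliers
  **r** = (1, r₂, r₃): transition probabilities on branch *j* are
  expm(Q · r_{z_j} · t_j).
* **Trait.** A continuous trait evolves by Brownian motion with per-state
  variance multipliers **v** = (σ², β₂σ², β₃σ²):
  y_j | y_pa(j) ∼ N(y_pa(j), t_j · v_{z_j}), with y_root ∼ N(0, 1).

Priors: r₂ ∼ Gamma(5, 0.04) (shape–scale; mean 0.2), r₃ ∼ Gamma(10, 0.2);
log σ² ∼ N(0, 2); log β₂, log β₃ ∼ N(0, 1); a, b, c ∼ Beta(1, 1).

Inference is Gibbs sampling with Metropolis-within-Gibbs blocks: (1) a
Metropolis block on (σ², β₂, β₃) and latent trait values, (2) Felsenstein
pruning plus exact forward sampling of ancestral nucleotides, (3) exact
conditional resampling of the per-branch states, (4) Metropolis updates of
r₂, r₃, (5) conjugate Beta updates of (a, b, c).

The quantity of interest is **log(β₃/β₂)**: positive values mean faster
sequence evolution goes with faster trait evolution. Elements are ranked by
the Savage–Dickey Bayes factor for the full model against the nested null
β₂ = β₃ = 1, computed as the prior density of (log β₂, log β₃) at the
origin (exactly 1/2π) over a Gaussian-KDE estimate of the posterior density
there. BF ≥ 30 is reported as "very strong", BF ≥ 100 as "overwhelming".

## Worked example

Simulate one element on a 16-tip ultrametric tree and refit it:

```sh
acctrait simulate --tree tree.nwk --mod neutral.mod -S 80 --seed 11 --out el
acctrait fit --tree tree.nwk --mod neutral.mod \
    --align el.fa --trait el.trait.tsv \
    --iters 6000 --chains 3 --seed 1 --out fit
```

The `fit` command prints a one-line JSON and writes per-chain traces plus
`fit.summary.json`:

```
{"element_id": "fit", "bf": 0.7214785433773155, "converged": true}
```

with summary fields (this exact run):

```
bf                     0.721
median_log_beta_ratio -0.295      # truth for this element: -0.243
ci80                  [-1.848, 1.065]
rhat_max               1.001      # split Gelman-Rubin, threshold 1.01
medians: r2 0.205 (truth 0.259), r3 2.684, c 0.653, ...
```

The 80% credible interval covers the simulated value of log(β₃/β₂) and the
Bayes factor is near 1 — correct behaviour, since a single short element on
a small tree carries little evidence either way. The `study` subcommand
loops simulate → fit → summarize and reports MSE, 80%-interval coverage and
false-positive rates per BF cutoff.

Input formats: Newick tree (branch lengths required), phyloFit-style
`.mod` file (`BACKGROUND:` + `RATE_MAT:`) or a plain 5-row text fallback,
FASTA alignment, and a two-column tab-separated trait table keyed by the
tree's leaf names. Gaps and IUPAC ambiguity codes are treated as missing
data; species missing from the trait table get a latent trait value.

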