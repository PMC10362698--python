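# Methods

## Overview

`tvae` learns a generative model of an aligned homologous protein
family and uses it to search for new variants with a desired fitness.
Three pieces cooperate:

1. a **variational autoencoder** whose encoder is a temporal
   convolutional network (TCN) over alignment columns, giving each
   sequence a low-dimensional latent Gaussian;
2. a **Gaussian-process (GP) regression** from latent means to a scalar
   fitness label (for cytochrome P450 chimeras, T50 — the temperature
   at which half the protein is irreversibly inactivated);
3. a **latent-space generator** that samples around the posterior of a
   high-fitness reference sequence, decodes the samples, and screens
   them by predicted fitness.

A phylogenetic simulator provides fully synthetic study families so the
entire chain is testable on one CPU without any downloads.

## Input preparation

Aligned FASTA ('.' and '-' both read as gaps) is cleaned by (i)
removing sequences whose gap fraction exceeds 20% of the alignment
length, and (ii) deduplicating exact repeats (first occurrence kept).
The gap fraction is evaluated on the aligned sequences — after
stripping there would be no gaps left to count, so the rule is only
meaningful pre-stripping.  `strip_gap_sites` is provided for unaligned
output but the model itself consumes the aligned matrix.

Residues are coded 0–20: gap = 0, amino acids 1–20 in alphabetical
one-letter order `ACDEFGHIKLMNPQRSTVWY`.  Ambiguity codes (B, J, O, U,
X, Z) have no slot in the 21-letter model and are coerced to gap with a
warning.  Each sequence becomes a 21×L one-hot matrix.

Sequences are weighted with Henikoff & Henikoff (1994) position-based
weights: in a column with r distinct symbols a sequence carrying a
symbol of count m contributes 1/(r·m); the per-sequence mean over
columns is normalized to sum to N.  The gap counts as a 21st symbol.
Weights multiply each sequence's whole loss (reconstruction + KL),
re-balancing the effective data distribution.

## Encoder

The encoder stacks residual blocks of **dilated causal convolutions**:
output position t sees only alignment columns ≤ t (left padding of
(k−1)·d zeros), and block dilations double (1, 2, 4, …), so the
receptive field grows exponentially with depth.  Each block is
[conv → ReLU → dropout] ×2 with weight normalization on every kernel
and a 1×1 convolution on the skip path when channel counts change;
the block output is ReLU(skip(x) + F(x)).

Defaults: kernel 2, stride 1, dilation base 2, dropout 0.2, three
blocks, 100 output channels.  Receptive-field accounting exposes two
recursions: the stride-only textbook form RF_i = RF_{i−1} + (k_i−1)·S_i
and the dilation-aware form RF_i = RF_{i−1} + (k_i−1)·d_i·S_i.  Only
the latter matches an empirical sensitivity probe of the composed
convolutions (the probe is part of the test suite), so the encoder
reports it; the stride-only form is kept as a named alternative for
comparison.

The final feature map is averaged over positions (global average
pooling keeps the parameter count independent of L), passed through a
tanh fully connected layer, and two linear heads emit the posterior
mean and log-variance per latent dimension.

## Decoder and objective

The decoder is fully connected: z → tanh hidden layer (default 100
units) → linear logits → per-column softmax over the 21 tokens, i.e. an
independent categorical per alignment column given z.  Softmax is the
natural choice because each one-hot column has exactly one active
token.

Training maximizes the weighted ELBO

    ELBO(s) = E_q[log p(s|z)] − KL(q(z|s) ‖ N(0, I))

with the reparameterization trick (z = μ + σ⊙ε, one Monte-Carlo sample
per update — the standard estimator), the closed-form diagonal-Gaussian
KL, and Adam with L2 weight decay (default 1e-4).  Default learning
rate 1e-3, batch size 128, epochs counted as full passes.  All
randomness (initialization, batch order, posterior draws, dropout
masks) derives from one config seed; two runs with identical config
and data produce bit-identical checkpoints on one thread.

`elbo_components` can average the reconstruction term over several
posterior draws.  This matters when *checking* the variational bound:
the inequality ELBO ≤ log p(s) concerns the expectation E_q, and a
single draw exceeds a tight importance-sampling estimate of log p(s)
roughly 40% of the time when the posterior gap is near zero.  The
bound tests therefore average 64 draws; training keeps the single-draw
estimator.

The networks are built on a small reverse-mode automatic
differentiation engine over numpy float64 arrays written for this
package (broadcast arithmetic, matmul, causal dilated convolution, a
fused categorical log-likelihood, Adam).  Gradients are verified
against finite differences in the test suite.

## GP fitness regression

Latent means are the GP inputs.  The kernel is RBF,
k(z,z′) = σ_g²·exp(−‖z−z′‖²/(2λ²)), plus a fitted noise variance σ_n²
(floor 1e-8): exact interpolation of noisy T50 measurements is
ill-conditioned, and the noise term doubles as jitter.  The mean
function is the constant training mean of y.  Hyperparameters maximize
the log marginal likelihood by L-BFGS-B in log space from a data-driven
start (σ_g² = var(y), λ = median pairwise latent distance,
σ_n² = 0.1·var(y)) plus five seeded random restarts; the optimum is
never accepted if it scores below the start.  Predictions use a cached
Cholesky factorization; the posterior is validated against a direct
dense solve and against scikit-learn's GP at fixed hyperparameters.

Evaluation reports Pearson r and MAD = mean |pred − truth|.  The
train/test splitter rounds n·test_frac to the nearest integer, which
reproduces the 222/56 protocol for 278 labeled chimeras at
test_frac 0.2.

## Variant generation and screening

Given the fitted model and a reference (typically the labeled sequence
with the highest fitness), `sample_around` draws
z_i = μ_ref + scale·σ_ref⊙ε_i; scale 1 reproduces the reference
posterior, 0 collapses to its mean.  Samples are decoded to argmax
residue strings; gaps are retained in the aligned representation and
stripped for FASTA output.  Ids follow `Generate_<k>` with k counting
from 1.  Screening keeps variants with lower < predicted fitness <
upper, both bounds strict (the reference protocol screens above the
best natural T50, 69.7 °C, and below 72 °C).

**Identity scoring.** Global (Needleman–Wunsch) and local
(Smith–Waterman) identities use match = 1, mismatch = 0, gap
open/extend = 0.  Under all-zero penalties the optimal alignment is
not unique and co-optimal alignments differ in length, making
identity = matches/alignment-length ill-defined; the DP here maximizes
(matches, −length) lexicographically — the same optimal match count,
over the shortest alignment achieving it — so every reported identity
is reproducible bit-exactly.  Both DPs are validated against
exhaustive alignment enumeration for short sequences.  Local identity
of a pair with no common residue is reported as 0% (empty-alignment
convention).

## Synthetic families

`phylo_sim` grows a Yule tree (birth rate 1, death rate 0) to the
requested number of extant tips with dendropy, then appends the
Exp(n·λ) hanging time after the last speciation to every tip edge —
dendropy stops at the n-th split, which would otherwise leave that
cherry with zero-length tips.  A root sequence uniform over the 20
amino acids evolves along each branch of length t under a 20-state
Jukes–Cantor-style process: each site substitutes with probability
1 − exp(−rate·t), the replacement uniform over the other 19.  Clade
labels cut the tree at a fixed distance from the root.  Optional
fitness is one effect per clade (N(0, 4²)) plus a depth term
(1 °C per unit root distance) on a base of 60 °C, plus N(0, 0.5²)
noise — T50-like values with clade structure.

Desk-scale defaults, chosen once: 300 leaves (the full-scale reference
used 10,000), length 60, substitution rate 0.3 per site per unit
branch length, clade cut at 1.2 (roughly half the typical tree height,
yielding four clades at the default seed).  What the simulator does
**not** emulate: indels (families are gap-free), realistic exchange
matrices (WAG/LG), rate heterogeneity across sites, and alignment
error.  Tests passing on these families show that the machinery works
and the latent space organizes by evolutionary relatedness; they do
not certify performance on real Pfam-scale data.

## Problem sizes and numerical choices

All shipped experiments run on one CPU:

- memorization: 30 sequences × 40 columns, 2 blocks (24/32 channels),
  d = 3, 2000 epochs — mean argmax-reconstruction identity ≥ 95%;
- latent clade structure: 300 sequences × 60 columns, 2 blocks
  (32 channels), d = 2, dropout 0.2 — silhouette on clade labels
  positive and above every label permutation;
- GP: posterior equals the dense solve to 1e-8 at n = 50; length-scale
  recovery within ×1.5 (median of 10 seeded fits at n = 200); held-out
  Pearson ≥ 0.9 on the smooth landscape at n = 200.

Float64 throughout; categorical log-probabilities use the max-shifted
logsumexp; decoded probabilities are floored at 1e-300 before log.
Degenerate inputs: constant-y GP targets bypass optimization (tiny
signal variance, predictions return the constant); an all-gap sequence
stripped to empty triggers a warning; training aborts with a
diagnostic on non-finite loss.

## Known limitations

- The shipped configurations are orders of magnitude below the
  full-scale reference (57,356 sequences × 426 columns, 20,000
  epochs); headline numbers from that setting (e.g. Pearson 0.84 on
  chimeric T50) are not reproduced here.
- The decoder treats alignment columns as conditionally independent
  given z; epistasis is captured only through the latent variable.
- GP inputs are posterior means, ignoring posterior variance.
- Silhouette on simulated clades is sensitive to the training
  trajectory at desk scale; the shipped configuration was chosen for
  robustness (dropout on, moderate learning rate), not tuned per seed.
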