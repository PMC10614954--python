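# Methods

## Generative model and losses

A cell's raw UMI counts X (length G) with observed depth d = Σ_g x_g
are scored under a zero-inflated negative binomial per gene:

    P(x) = π·[x = 0] + (1 − π)·NB(x; m, r),   m = d·μ′,  π = sigmoid(p)

with NB parameterised by mean m and dispersion r (variance m + m²/r).
The decoder emits, per cell, the full triple (μ′, r, p) per gene:

* **μ′** through a softmax over genes, so Σ_g μ′_g = 1 exactly. The
  likelihood factorisation m = d·μ′ with the observed depth makes μ′ a
  depth-corrected relative rate, directly comparable to depth-normalized
  observed profiles and usable as the prediction itself.
* **r** through softplus plus ε = 1e-4, keeping dispersion strictly
  positive; r is emitted per gene *and* per cell (the most general
  parameterisation; a gene-wise-only r would be a special case the
  decoder can learn).
* **p** as a logit clamped to [−15, 15]. At the clamp the residual
  inflation mass is sigmoid(−15) ≈ 3e-7, numerically negligible but not
  exactly zero; exact NB behaviour is recovered only in the limit.

Likelihoods are computed in log space. At x = 0 the two mixture
branches combine as log σ(p) + softplus(log NB(0) − p), which is stable
for any logit; NB terms use log-gamma.

The KL term is the closed form for a diagonal Gaussian against N(0, I),
summed over latent dimensions and averaged over cells; the
reconstruction term is summed over genes and averaged over cells, and
the two are added unweighted. Encoder log-variances are clamped to
[−10, 10].

The encoder conditions on log1p of counts-per-10k by default
(`encoder_input="raw"` switches to raw counts); the likelihood always
scores raw counts. This is purely a conditioning choice: observed
depth never enters the decoder output except through m = d·μ′.

## Adversarial option

A single affine-softmax discriminator predicts species from sampled
embeddings z. Each minibatch runs one discriminator update (on its
cross-entropy) followed by one generator update on
loss_cVAE − w·loss_dis with the discriminator's weights treated as
constants (w = `adv_weight`, default 1; the discriminator receives a
sampled z, not the posterior mean). Updates are strictly
compartmentalised: generator steps never touch discriminator
parameters and vice versa (tested by parameter comparison).

## Training protocol

* Split: held-out stratum (a cell type or tissue in the target
  species) = test; of the rest, min(⌈10%⌉, 20,000) cells = validation,
  sampled without replacement from a seeded generator.
* Optimiser: Adam, learning rate 1e-3, minibatch 128 (256 in the
  larger test scenarios), maximum 500 epochs. These are conventional
  defaults for VAEs of this size; all are exposed in `TrainConfig`.
* Early stopping: training halts when validation loss_cVAE (always the
  unmodified cVAE loss, even with the adversary active; evaluated with
  z = posterior mean for determinism) has not reached a new minimum
  for 45 consecutive epochs; the parameters from the best epoch are
  returned.
* Grid search: {discriminator off/on} × {n_latent 25, 50, 100}, six
  fits; the candidate with the largest mean validation species-LISI is
  selected. Species-LISI only is used (not averaged with batch-LISI);
  the label set is configurable.
* Architecture: two ReLU hidden layers in encoder and decoder (depth
  fixed), hidden width 128 by default. Width is deliberately moderate:
  at the few-hundred-gene problem sizes this package targets, wider
  layers add cost without measurable accuracy gain; it is a config
  field for larger gene spaces.

## LISI

Per cell: squared Euclidean distances to the k = 3×perplexity nearest
neighbours (perplexity 30 by default, the cited method's convention),
Gaussian kernel bandwidth calibrated by bisection so the weight
entropy equals log(perplexity), label probabilities p_l = summed
normalized weights per label, LISI = 1/Σ_l p_l². When fewer than k+1
cells are available, k is reduced with a warning. The mean over cells
is reported.

## Prediction and evaluation

Prediction encodes each cell with its own factor codes using the
posterior mean (no sampling — predictions are deterministic and
bit-reproducible from a checkpoint) and decodes with the species code
replaced. Predicted pseudobulk averages μ′ linearly over cells;
baseline profiles (species, cell-type, donor) use depth-normalized,
log2(x+1)-transformed pseudobulk as their definitions require. The
log transform is applied after averaging cells; log2 with pseudocount
1 keeps all fold-change conventions in one base. Relative prediction
error |pred − target|/|source − target| is undefined where source and
target agree exactly; such genes are excluded from summaries and
counted rather than clipped. Quantile gene bins break ties by stable
rank so binning is deterministic under heavy ties.

## X-upregulation analysis

Cells of the source species are encoded once and decoded under each
species code of a pair; each cell's two predicted profiles are scaled
so summed housekeeping expression is 1, giving per-cell per-gene
log2((a + ε)/(b + ε)) with ε = 1e-6 on the normalized scale (small
enough to leave well-expressed genes untouched, large enough to cap
fold changes of near-zero predictions). The per-gene median across
cells is the gene's fold change. Groups:

* XAR — X-linked in the eutherian, autosomal in metatherian and bird;
* XCR — X-linked in both mammal clades, autosomal in the bird;
* autosomal — autosomal in all three; anything else excluded.

Group shifts are tested with one-sided one-sample Wilcoxon signed-rank
tests (exact null for n ≤ 25 after dropping exact ties, normal
approximation with continuity correction above; all-tied groups report
p = 1 with a flag), BH-corrected across the reported tests. The
stronger-in-mouse comparison is implemented exactly as specified (H0:
median ≥ 0, alternative less) with the direction exposed as a config
switch, since the stated null direction is in tension with the
biological reading and silently flipping it would be worse than
exposing it. GGACH motifs (H = A/C/T/U) are counted with overlaps via
regex lookahead and reported per kb; group motif-frequency deltas are
compared with one-sided rank-sum tests.

## Synthetic data

The generator draws, per cell: a cell-type program (log-normal gene
weights renormalized to a simplex, shared across species), per-gene
log2-additive species and batch effects, a log-normal depth (median
~450 UMIs, matching the sparse combinatorial-indexing regime; scale
configurable), then gamma-Poisson (NB) counts with dispersion 2 and
Bernoulli dropout (5% by default). Recorded truth includes programs
and effects, so recovery can be scored exactly.

For the XCU scenario, X-group genes receive effects centred at
−1 + u (halved dose plus upregulation u) with per-gene scatter
N(0, 0.5); autosomal genes are centred at 0 with the same scatter; a
separate housekeeping block has exactly zero species effect.
Housekeeping normalization assumes conserved housekeeping expression,
and simulating that block as strictly conserved makes the recovered
fold changes centred at the injected shifts — with noisy housekeeping
genes the anchor itself would drift by the (small, systematic) mean of
2^N(0, σ), which is a property of real data the simulation
deliberately idealises away.

What the generator does **not** emulate: gene–gene correlation within
programs, within-species doublets, ambient RNA, cell-type
composition differences between species, and batch-depth
interactions. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated generative assumptions,
not robustness to every artefact of real data.

## Problem sizes and seeds

The end-to-end recovery scenario uses 2 species × 2,000 cells × 200
genes × 3 cell types with species-effect sd 0.5 (log2), n_latent 25,
hidden width 128, batch 256, up to 100 epochs with patience 20, three
seeds — sizes chosen so the full suite runs comfortably on a laptop
core while leaving the recovery signal well above threshold. All
randomness flows from explicit seeds; sub-seeds are derived with
`numpy.random.SeedSequence`.

## Known limitations

* The likelihood assumes one dispersion regime per (cell, gene); no
  gene-wise shared dispersion shrinkage is implemented.
* The adversarial objective uses an unweighted loss difference by
  default; strong adversaries can destabilise small models (the grid
  search will then simply not select them).
* Ortholog reconciliation is greedy, not a global maximum-weight
  matching; this is the intended algorithm, and ties are broken
  lexicographically on gene IDs for determinism.
* The one-file checkpoint is a `.npz` archive; cross-version
  compatibility is guarded only by a format version field.
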