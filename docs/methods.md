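# Methods

## Problem and model

The package predicts the sensitivity of a cancer cell line to a drug —
the log-transformed IC50 of the pair — from pathway-level representations
of both the drug and the cell. The premise is that drugs act by
perturbing signaling pathways: if the pathways a drug engages are active
in a tumour, the tumour is more likely to respond. Rather than feeding
raw genomic features to a model, every data type is mapped onto a common
vocabulary of cancer signaling pathways, which keeps the feature space
small, comparable across data types, and interpretable at the level
oncologists reason about.

Five feature blocks are concatenated per (drug, cell) pair:

| block | entity | width (defaults) | content |
|---|---|---|---|
| CHEM | drug | 256 | Morgan fingerprint bits of the drug's SMILES |
| DG-Net | drug | one per pathway | NetPEA z-scores of the drug's expanded target genes |
| EXP | cell | one per pathway | ssGSEA NES of the cell's expression profile |
| MUT-Net | cell | one per pathway | expression-weighted NetPEA z of the cell's mutated genes |
| CNV-Net | cell | one per pathway | expression-weighted NetPEA z of the cell's non-diploid genes |

A fully connected neural network regresses the response on the z-scored
design matrix. Shapley values attribute each prediction back to pathways
and chemical bits.

## Network-based pathway enrichment (NetPEA)

Given a weighted, undirected protein–protein interaction network and a
seed gene set (a cell's mutated genes, its copy-number-altered genes, or
a drug's expanded targets), a random walk with restart computes the
stationary distribution

    p = (1 − c) · W · p + c · e

where `W` is the column-normalised weighted adjacency, `e` is uniform
over the seeds present in the network, and `c` is the restart
probability. `p[g]` measures the closeness of gene `g` to the seed set.
A pathway's raw score is the mean of `p` over its genes mapped to the
network — multiplied gene-wise by the cell's log-TPM expression for
MUT-Net and CNV-Net (coupling mutation status to transcriptional
context), unweighted for DG-Net. The raw score is normalised into a
z-score against `n_perm` random gene sets of the same mapped size drawn
from the network's node universe and scored against the same walk
vector.

Numerical choices:

- `c = 0.7` by default (a common propagation setting; the score is not
  sensitive to it in the ranges practitioners use), configurable.
- Networks under 500 nodes are solved exactly as the linear system
  `(I − (1−c)M)p = ce`; larger networks use power iteration to an L1
  tolerance of 1e−6 (max 1000 iterations). Columns of isolated nodes
  redistribute their mass to the restart vector, so `p` always sums to 1.
- Permutation nulls are cached per (entity, mapped set size); index sets
  are averaged in sorted order so that identical sets give bitwise-equal
  draws, and a null whose draws are all identical is treated as
  degenerate (z = 0 with a warning) rather than divided by a rounding
  artefact.
- Entities whose seeds all miss the network produce a zero row and are
  reported; pathways with no mapped genes score 0.
- The permutation universe is all network nodes, and the permutation size
  is the number of pathway genes mapped to the network, not the nominal
  pathway size.

## ssGSEA (EXP block)

For one cell, genes are ranked by descending expression (ties broken
lexicographically by symbol, making the score deterministic). The
enrichment score of a gene set is the sum over ranks of
`P_hit − P_miss`, where `P_hit` accumulates `|expression|^alpha`
(normalised over in-set genes) and `P_miss` accumulates uniformly over
out-of-set genes. The reported feature is `NES = ES / |mapped set|`.
`alpha = 0.25` by default (the standard ssGSEA weighting); at
`alpha = 0` the score is rank-only and invariant to monotone transforms
of expression. An optional permutation z-score against random same-size
gene sets is available as a diagnostic but is not the model feature.

## CHEM and DG-Net inputs

SMILES are folded into 256-bit binary Morgan fingerprints at radius 2
(ECFP4-equivalent; both knobs configurable). Invalid SMILES drop the
drug with a logged report. Drug target sets are expanded before DG-Net
enrichment: primary targets ∪ curated off-targets ∪ their first-order
PPI neighbours. Drugs with no targets, or whose targets all miss the
network, are dropped and reported.

## Normalisation and model

Features are z-scored column-wise with population standard deviation;
statistics are fit on training rows only and applied unchanged to
validation/test rows (the leak-free reading — published pipelines do not
always state where normalisation sits relative to the folds, so pooled
statistics could differ slightly). Zero-variance columns are dropped and
recorded.

The regressor is a plain multilayer perceptron: linear output head, MSE
loss, Adam, inverted dropout on hidden activations, and early stopping
on a validation split carved from the training rows (patience epochs
without improvement; best-validation weights restored). It is written in
numpy, CPU-only, and bit-reproducible given a seed. Library defaults are
hidden layers (1024, 512, 256), ReLU, dropout 0.1, learning rate 1e−4,
batch 32, up to 800 epochs, patience 30, validation fraction 0.1 — a
DeepDSC-style architecture. The test suite and the acceptance script use
a smaller configuration — hidden layers (128, 64), learning rate 1e−3,
batch 64, ≤150 epochs, patience 15 — sized to the synthetic study's 456
features and 2000 pairs, where the larger network adds nothing but
runtime.

## Evaluation

- k-fold cross-validation (default k = 10, optionally repeated with
  independent shuffles), leave-one-drug-out (every pair of one drug held
  out) and leave-one-cell-out. Splits are deterministic given a seed;
  normalisation and the early-stopping split are nested inside each
  training fold.
- Metrics: MAE, RMSE, R², Pearson correlation; per fold and pooled, with
  mean ± sd across folds (for repeated k-fold the per-repeat aggregation
  is available from the per-fold table).
- Residual diagnostic: a Laplace distribution is fit by median / mean
  absolute deviation and tested with the Kolmogorov–Smirnov statistic.
  Only the KS variant is implemented; Anderson–Darling and Watson
  statistics would serve the same diagnostic role.
- `theoretical_floor` computes the MAE/RMSE between two response tables
  on their shared (drug, cell) pairs — the irreducible error of any
  model trained on one screen and tested on another that disagrees with
  it.

## Shapley attribution

Model-agnostic permutation-sampling Shapley with background replacement:
"feature absent" means its value is taken from a background row
(default: 100 fixed-seed training rows). Each round draws a random
feature ordering and walks it, crediting each feature with the change in
model output as its value flips from background to the explained row;
rounds cycle deterministically through the background rows. The
telescoping sum per round equals `f(x) − f(b)`, so for linear models the
estimate is exactly `w_i (x_i − mean(b)_i)`; a final additive correction
distributes any residual evenly so local accuracy
(`base + Σφ = f(x)`) holds to machine precision at any sampling budget.

Global feature importance under `direction="positive"` ranks by the mean
positive part `E[max(φ, 0)]` rather than the signed mean: an informative
feature that pushes predictions up in half the samples and down in the
other half has a signed mean near zero, so the signed mean cannot
surface positive contributors; the positive-part mean does, and matches
the practice of reading positive contributions off a SHAP summary.
Under the convention that the response column increases with sensitivity
(−log IC50), positive attributions are sensitising; the package treats
the response sign as given and does not re-derive it from data.

## Synthetic study

The generator emits a complete, self-consistent dataset in the exact
file formats the readers consume. Latent per-cell pathway activities
`a[c, p] ~ N(0, 1)` organise every data type:

- expression: gene baseline + 1.0 × (sum of activities of the pathways
  containing the gene) + N(0, 0.5) noise, on a log-TPM-like scale;
- network: within-pathway gene pairs connect with probability 0.35 on a
  0.01-density background, weights U(0.5, 1);
- mutations: 5–50 genes per cell, sampled with probability tilted toward
  genes of active pathways (softmax with inverse temperature 0.8); CNV:
  10–30 non-diploid genes per cell, biased the same way, with signs
  following the activity direction;
- drugs: 20 molecules from a fixed panel of valid drug-like SMILES, with
  2–4 primary targets inside the driver pathway and 1–3 random
  off-targets;
- response: `effect_size × a[c, driver] + offset_d + N(0, noise_sd)` for
  every pair.

Defaults — 300 genes, 100 cells, 20 drugs, 50 pathways of 8–15 genes,
2000 pairs — are a desk-scale analogue of a GDSC-style screen (which has
~150 drugs × ~320 cells × 196 pathways); they keep a full pipeline run
around a minute on one CPU while leaving every mechanism (permutation
nulls, broadcasting, fold structure) at realistic sparsity. One driver
pathway is planted globally and shared by all drugs, so the planted
signal is identifiable both by the model and by the attribution step.
`effect_size = 2.0` against `noise_sd = 0.3` puts the signal sd more
than 5× above the noise; `drug_offset_sd` defaults to 0 so that setting
`effect_size = 0` yields a response genuinely independent of all
features (the null-control condition). Ground truth (driver pathway,
activities, offsets) is written to a sidecar file so recovery analyses
never touch generator internals.

What the generator does **not** emulate: cancer-type/tissue structure,
correlated pathway activities, realistic IC50 marginal distributions,
dose–response measurement artefacts, batch effects, and drug-specific
mechanisms beyond a single shared driver. Passing the recovery tests
therefore shows the pipeline recovers a pathway-mediated signal it is
pointed at under favourable signal-to-noise — not that it attains any
particular accuracy on real screens.

## Known limitations

- The permutation null assumes exchangeability of gene sets of equal
  size over the network universe; hub-heavy pathways can carry
  systematically broader nulls than degree-matched sampling would give.
- ssGSEA NES here is ES divided by set size; other implementations
  rank-normalise expression first, so absolute NES values are not
  comparable across implementations.
- The Shapley estimator's per-feature variance shrinks as 1/√rounds;
  local accuracy is exact by construction, but per-feature values at
  small budgets carry sampling noise (symmetric features agree only in
  expectation).
- LODO/LOCO error on the synthetic study is optimistic for LOCO-style
  extrapolation on real data, where unseen cells are farther from the
  training distribution than a fresh draw of the same generative model.
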