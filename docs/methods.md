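# Methods

## Input encoding

Peptides are at most 20 canonical residues. Sequences read through an amber
stop are truncated at the first `*`; truncation duplicates are merged (mean
score, modal label) and dropped on an exact label tie. Length-0 truncations
are kept through encoding and labeling — there is no evidence they harm
training and dropping them would silently shrink the stop-codon tail.

The model input is a 24-row × 20-channel matrix: two zero rows, the one-hot
residues, two zero rows, then rows of −1 to fill 24. Channels are the 20
amino acids in alphabetical one-letter order; this order is stored in every
checkpoint so weights are portable. Mask rows are fed to the network as-is
(no attention mask): the network learns that −1 blocks carry no signal.

## Architecture and the parameter budget

The hidden stack is convolution (100 filters × length 3, exponential
activation, no pooling) → single-head self-attention (key length 6) → dense
(64, ReLU) → sigmoid. The attention internals were fixed by an explicit
parameter budget of 17,491 trainable parameters, which pins down one
decomposition:

| block | shape | parameters |
|---|---|---|
| conv kernel + bias | 3×20×100 + 100 | 6,100 |
| input positional embedding | 22×100 | 2,200 |
| Q, K, V projections (+biases) | 3 × (100×6 + 6) | 1,818 |
| key-space positional encoding | 24×6 | 144 |
| output projection (+bias) | 6×100 + 100 | 700 |
| dense (+bias) | 100×64 + 64 | 6,464 |
| sigmoid head | 64 + 1 | 65 |
| **total** | | **17,491** |

Positions enter twice, which is deliberate: the 22×100 table gives the
attention *values* positional identity, and the 24×6 table (sized to the
padded input length; rows beyond the 22 convolution positions are unused at
the default filter length) biases the *keys* before the softmax so the
attention pattern itself can be position-aware. Attention uses scaled
dot-product weights (1/√6) and no residual connection or layer norm — the
budget excludes them. The bridge to the dense layer is mean pooling over
the 22 positions. No enumerated standard multi-head-attention variant
(with/without projection biases, valid/same convolution, learned/sinusoidal
positions, pool/flatten bridge) reproduces the budget; the decomposition
above does so exactly and is asserted in the tests.

## Training

Loss is binary cross-entropy; for hard 0/1 labels this equals the binary
KL divergence up to the (zero) label entropy, so the two are
interchangeable as objectives. Optimisation is Adam with standard defaults
(lr 10⁻³, β₁ 0.9, β₂ 0.999, ε 10⁻⁷), minibatch 128, up to 100 epochs.
Dropout: 0.1 after the convolution, 0.1 after the attention output, 0.4
after the dense layer. The elastic-net penalty on the dense kernel adds
0.01·(‖W‖₁ + ‖W‖₂²) to the loss; its gradient is added after the raw
backward pass so gradients stay numerically checkable against the
unpenalised loss.

The validation split is a stratified random 10%, derived from the fit seed;
validation AUPR (trapezoidal integration of the precision-recall curve) is
monitored for plateau learning-rate decay (×0.2 after 4 stale epochs) and
early stopping (after 10), and the best-AUPR weights are restored. All
randomness — initialisation, shuffling, dropout — derives from a single
seed via spawned generators, making fits bit-reproducible.

Numerical choices: pre-activations of the exponential convolution are
clipped at 30 before exponentiation (exp(30) ≈ 10¹³), with the gradient
masked in the clipped region; the attention softmax subtracts the row
maximum. Forward/backward passes run in float64.

Sequences longer than 20 residues are scored at every overlapping
length-20 window and summarised by the median (mean/min/max selectable);
the median is preferred for robustness to single extreme windows.

## Labeling

Per library: peptides with fewer than 100 input reads are removed; scores
are centered by subtracting the distribution mode, estimated by a Gaussian
KDE (Silverman bandwidth) evaluated on a 2,001-point grid. Because
non-aggregators dominate the library (~75–80%), the global mode coincides
with the non-aggregator mode; this avoids the circularity of needing labels
before centering, at the cost of a small bias if aggregators were ever the
majority. Each centered score is tested one-sided (z = score/error, upper
tail) with Benjamini–Hochberg adjustment across the library's scored
records; adjusted p ≤ 0.05 marks an aggregator. Records with missing
scores (no output reads) are non-aggregators by definition and are excluded
from the FDR adjustment.

## Synthetic libraries

The generator emulates the data-generating process at the amino-acid
level, not the sequencing level. Residues are drawn from the NNK
codon-count distribution (derived from the standard genetic code, 32
codons; leucine/arginine/serine 3/32 each, the amber stop 1/32, emitted as
`*` so the truncation logic is exercised — other stops cannot occur under
NNK). The latent score of a peptide is a sum over its 3-mer windows of
planted pattern effects scaled by an 18-entry positional weight vector,
plus optional pairwise interaction terms; the observed score adds Gaussian
noise and the error column reports that SD. Reads are negative binomial.

Defaults (fixed once, as study conditions): hydrophobic 3-mers
(I/L/V/F/W/Y/M) at +1.0 and charged-or-proline 3-mers (D/E/K/R/P) at −0.8;
positional weights declining linearly 1.5 → 0.5 from the N terminus
(N-terminal windows matter more); noise SD 0.3, i.e. a single unit-effect
motif sits ≈3.3 SE above zero, so single-motif aggregators are mostly but
not universally detected; reads NB(mean 500, dispersion 5), leaving a few
percent of peptides below the 100-read filter. What the generator does
*not* emulate: codon-level errors, selection-count noise structure
(errors are homoscedastic here), compositional biases beyond NNK, and any
real amyloid biology — passing tests show the pipeline recovers *planted*
structure, not that the planted grammar is biologically correct.

Structure fixtures plant β-strand segments as I/V/F stretches, disorder as
D/E/K/R/P stretches and coil as polar/small residues, giving ground truth
for enrichment AUROCs; real annotation tables (e.g. derived from solved
amyloid structures) use the same TSV schema (seq_id, 1-based position,
residue, label).

## Interpretability

**PWMs.** Activation energies of all 8,000 3-mers are computed analytically
from the filter weights (the convolution is linear in the one-hot input),
so selection is exhaustive, not sample-based. A filter's PWM uses at most
the 10 top-activating kmers, restricted to those within 75% of the maximum;
ties break by activation then lexicographically. The PWM is the unweighted
per-position residue frequency of the selected kmers.

**Clustering.** Each PWM is projected as PWM·BLOSUM62 (3×20, flattened to
60) and clustered with affinity propagation (damping 0.7, retried at 0.9 on
non-convergence, seeded). Within each cluster the member with the largest
|GIA importance| sets the sign; discordant members are pruned and recorded.

**GIA.** Effect sizes are causal, not correlational: a kmer is sampled from
a PWM with probability proportional to its activation ratio (for clusters:
filter first by |importance| ratio, then kmer), embedded into background
sequences (replacing three residues), and the importance is the mean paired
difference in pre-sigmoid score. Backgrounds are confidently predicted
full-length training sequences (aggregators with probability > 0.3,
non-aggregators < 0.2). Differences are taken on the pre-activation scale
so effects add where the model is additive; a probability-scale flag exists
for sensitivity checks. CIs are normal-approximation intervals of the mean
paired difference. The experiment designs: single feature (uniform or
fixed embedding position over starts 1..18), multiplicity (1–4
non-overlapping copies added incrementally, with the R² of importance
vs copy count), positional (18 fixed-position experiments, reported as
percent change against the position-averaged mean, undefined below |mean|
= 10⁻⁹), and interaction ([f(both) + f(bg)] − [f(A) + f(B)] at
non-overlapping positions, paired two-sided t test, Bonferroni-corrected by
the squared cluster count). Non-overlapping placement uses bounded
resampling (100 tries).

**Model selection.** Each training replicate is scored by the KL divergence
(natural log, 0.5 pseudocount per kmer bin) between the 3-mers at
top-attributed positions and all 3-mers of the test sequences. The
attribution is input-gradient saliency, mean-centered across channels at
each position (removing the off-simplex gradient component), read out at
the observed residue; the top position defines an edge-clipped 3-mer
window. The attribution function is pluggable. The selected replicate
maximises the interpretability score among those whose mean AUPR exceeds
the median of mean AUPRs (falling back to ≥ on degenerate ties). Note the
pseudocount floor: with n attributed kmers the smoothed P carries
4,000/(n + 4,000) uniform mass, so the score converges to its limits (0
for diffuse attribution, log 8000 for a point mass) only as n grows; the
tests verify both limits at large n.

**Enrichment.** A cluster's activation profile along a sequence is the
max over member filters at each kmer window, assigned to the window's
*center* residue (start/center/end being arbitrary, center keeps the
profile symmetric); terminal residues carry no value. Enrichment in a
structure class is the rank-based AUROC of profile values against the
binary class indicator, concatenated across sequences, with a percentile
bootstrap CI over residues.

## Evaluation

AUROC is rank-based, AUPR trapezoidal; CIs are percentile bootstrap (1,000
resamples, seeded). The hydrophobicity baseline sums Kyte–Doolittle values
(any scale can be supplied); the composition baseline is an L2-regularised
logistic regression on residue counts. The context-free task excises
annotated regions, concatenates the remainder, cuts consecutive
non-overlapping chunks of the region length from position 1 (discarding a
short tail), and downsamples negatives to exact class balance; the
length-filtered task keeps records of length ≥ 10 without whitespace.

## Problem sizes

The test suite runs everything at desk scale: libraries of 1,500–20,000
peptides, 1–2 training replicates at 1–8 epochs, GIA with 150–800
backgrounds, enrichment over 30–40 fixtures. These sizes were chosen so
the planted effects are estimated with comfortable margins (e.g. held-out
AUROC ≈ 0.95 against a 0.85 criterion); production analyses would scale the
same entry points up (100 epochs, 100 replicates, 25,000 backgrounds).

## Known limitations

- The attention parameterisation is one exact solution to the parameter
  budget; other internals could produce the same count and differ in
  behaviour.
- The saliency-based attribution in the interpretability score is one
  reasonable instantiation of attribution-map correction; the interface
  accepts alternatives.
- The global-mode centering is slightly optimistic when aggregators are
  common, and KDE mode estimation has grid-resolution error (~10⁻³ on unit
  scales).
- GIA importances are valid for the *model*; they transfer to biology only
  insofar as the model is right.
- Affinity propagation's cluster count is data-dependent; no attempt is
  made to force a particular number of clusters.
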