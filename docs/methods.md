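# Methods

`lncdra` predicts associations between long non-coding RNAs and anticancer
drug resistance by completing a sparse binary incidence matrix. The model
has four stages: Gaussian interaction-profile similarity graphs for each
node set, a two-layer graph-convolutional feature extractor, one or more
multi-head graph-attention layers, and a sigmoid inner-product decoder.
This note records the model, the choices made where its description was
genuinely open, the numerical conventions, and what the synthetic
benchmark does and does not show.

## Data model

The observed data is an m x n binary matrix A: A[i,j] = 1 when lncRNA i is
known to modulate resistance to drug j. Unlisted pairs are *unknown*
candidates, not confirmed negatives; rows explicitly labelled 0 in an edge
list are kept as known negatives and are preferred by the balanced
negative sampler. Identifier matching is case-sensitive exact match after
whitespace trimming, so distinct symbols are never silently merged.

## Similarity

Each lncRNA's interaction profile is its row of A; each drug's is its
column. Similarity on a side is the Gaussian interaction-profile (GIP)
kernel

    G(i,j) = exp(-alpha * ||p_i - p_j||^2),
    alpha  = 1 / mean_k ||p_k||^2,

so the bandwidth adapts to the side's mean interaction density. An
all-zero matrix has no defined bandwidth and is rejected; all-zero
*individual* profiles are allowed (the kernel is defined there). During
cross-validation the kernel is recomputed from the training fold's matrix
with test positives zeroed, so no test label can leak into the similarity
graph — a property asserted by a regression test (perturbing a held-out
entry leaves the epoch-1 training loss bit-identical).

## Encoder

Per side, node features are initialized to the rows of the similarity
matrix itself (X = G): the association profiles are the only node
attribute the method constructs, and this fixes the input width to the
node count. The GCN stage is

    X' = act( A_hat . ReLU( A_hat . X . W0 ) . W1 ),
    A_hat = D^{-1/2} (G + I) D^{-1/2},

with self-loops guaranteeing strictly positive degrees. The attention
stage computes, per head k, logits

    e_ij = LeakyReLU( a_k^T [ W_k x_i || W_k x_j ] ),

softmax-normalizes them over each node's neighborhood with
max-subtraction stabilization, and aggregates x_i' = sigma(sum_j alpha_ij
W_k x_j). Hidden attention layers concatenate head outputs (activation
applied per head before concatenation, output width K*c); the final layer
averages head aggregates before the activation (output width c). The node
activation sigma is ELU and the LeakyReLU slope is 0.2, the conventional
choices for this layer type; both are configurable. Scores are
A' = logistic(X_l' X_d'^T), always strictly inside (0, 1).

Total message-passing depth is the `layers` parameter: the GCN stage is
fixed at two layers by its two weight matrices, so `layers = 3` (the
default) means one attention layer, and deeper stacks add concat-fusion
attention layers before the final averaging layer. Ablation variants:
`gcn_only` replaces the attention stack with a learned linear projection
to the embedding width; `gat_only` applies the attention stack directly to
the similarity rows.

### Two defaults that deviate from the most literal reading

Both literal forms remain selectable; neither is the default because both
provably collapse the encoder.

**Attention neighborhoods** default to each node's 10 most-similar nodes
(ties broken toward smaller index, self always included; `knn=None`
restores the full graph). On the *complete* similarity graph this
attention form is query-independent: the logit decomposes as
e_ij = LeakyReLU(s_i + t_j), and wherever the LeakyReLU is sign-constant,
softmax_j(s_i + t_j) = softmax_j(t_j) does not depend on i. Every node
then aggregates the same convex mixture, all embeddings coincide, and
training converges to the constant base-rate predictor (held-out AUC 0.5
at every learning rate we measured). Distinct top-k neighborhoods restore
query dependence.

**GCN output activation** defaults to identity, the standard
graph-autoencoder choice, with `row_softmax` and `relu` selectable. A
row-softmax output squashes every row onto the probability simplex; at
width r = 200 the rows sit within ~1e-4 of the uniform point, and even the
GCN-only ablation cannot learn through it (held-out AUC 0.41 vs 0.74 with
identity under otherwise identical conditions).

## Loss and optimization

The decoder is trained by full-batch Adam (the graphs are small enough
that an epoch is one step) against mean binary cross-entropy over the
training entries, with probabilities clamped to [1e-7, 1 - 1e-7]; mean
squared error is selectable. The *signed residual sum* form of the
reconstruction objective is retained as a diagnostic only: it is unbounded
below and cannot be optimized. Averaging (rather than summing) over masked
entries keeps the learning-rate scale comparable between balanced and
unbalanced masks. All randomness — initialization (Glorot uniform),
negative sampling, dropout when enabled — derives from the single config
seed, and two runs with the same seed produce histories equal to 1e-6.
Weight decay and dropout are exposed but default to 0.

Defaults mirror the method's stated operating point: learning rate 1e-4,
3 layers, 8 heads, embedding size 200, 400 epochs, classification
threshold 0.5. The GCN hidden width (never pinned down by the method
description) defaults to the embedding size.

## Evaluation protocol

Cross-validation is edge-wise: positives are shuffled by seed and dealt
round-robin into k test sets (sizes differing by at most one). In
unbalanced mode every non-positive pair is used, appearing in exactly one
fold's test negatives; in balanced mode each fold samples as many
negatives as it has positives, without replacement, known negatives
first. Metrics are computed per fold and also pooled over all folds'
concatenated predictions, since a protocol may want either aggregation.

Conventions, fixed for bit-reproducibility: AUC is the Mann-Whitney rank
statistic with ties counted 1/2; AUPR is average precision over the
descending step curve (no trapezoidal interpolation, which is
optimistically biased); F1 and MCC come from the confusion matrix at the
threshold (default 0.5, the natural operating point of a sigmoid
decoder), with MCC defined 0 when its denominator vanishes. The
`average_metric` is the plain mean of the four.

## Synthetic benchmark

Real association collections at the scale this method targets (thousands
of lncRNAs by tens of drugs) are not redistributable here, so tests run
on a planted stochastic block model: rows and columns are partitioned
into contiguous near-equal blocks (remainder to the last block) and
A[i,j] ~ Bernoulli(p_in) within blocks, Bernoulli(p_out) outside. The
benchmark configuration is m=100, n=20, 4 blocks, p_in=0.5, p_out=0.02,
with 10% of positives held out and scored against all never-associated
pairs.

What this emulates: sparse bipartite structure with low-rank community
signal, the regime the similarity kernel assumes. What it does not:
scale-free degree distributions, correlated drug families, annotation
bias, or any chemistry — so passing tests show the pipeline recovers
planted structure, not that it matches real-data performance figures.

Two quantitative properties of this benchmark are worth recording
because they bound what any method can score on it. First, entries are
Bernoulli noise around block-level rates, so the best possible ranking is
the block oracle; its held-out AUC is 0.848-0.888 across seeds (mean
0.877), and a rank-4 SVD baseline reaches 0.836. Second, learning-rate
1e-4 with one full-batch Adam step per epoch moves each parameter by at
most ~1e-4 per step, so a 200-epoch run explores only a small
neighborhood of the initialization; at that budget the encoder remains
near its starting point (held-out AUC ~0.43-0.55), and with a tenfold
larger step budget it peaks around AUC 0.78-0.85 per seed before it
begins fitting within-block noise. The acceptance suite reports these
recovery numbers as computed; the ablation ordering (full encoder not
trailing its GCN-only variant on the 4-metric average) is consistently
reproduced at the same conditions.

## Problem sizes used in tests

Unit tests use matrices up to 20 x 10 nodes and oracle comparisons up to
10 nodes; the recovery benchmark is 100 x 20 over 5 seeds at 200 epochs;
cross-validation tests use 3-5 folds on 20-40 row matrices with reduced
epochs and widths. These sizes keep the full suite's runtime in the
low minutes while exercising every code path at full default widths
(200-dimensional embeddings, 8 heads) at least once.

## Known limitations

* Transductive only: embeddings exist for nodes present in the training
  matrix; unseen lncRNAs or drugs require retraining.
* The GIP kernel uses association profiles only — no sequence, structure
  or chemical similarity.
* On dense similarity graphs the attention weights are near
  query-independent even with top-k neighborhoods when profiles are
  nearly identical; strongly homogeneous inputs reduce the attention
  stage to weighted averaging.
* The literal signed-residual objective is reported but never optimized.
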