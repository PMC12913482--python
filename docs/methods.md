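# Methods

## The prediction task and the model

`siamphage` treats phage–host interaction prediction as binary classification
of genome pairs. A phage genome and a candidate bacterial host genome are
each encoded by their own *tower* with identical architecture but independent
parameters (a pseudo-Siamese design; `share_tower_weights=True` gives the
strictly-Siamese variant), and a fusion classifier decides match vs
non-match.

Per genome of length `N` bp:

1. **Segmentation.** The sequence is cut into `c = ceil(N / 2000)` windows of
   exactly 2000 bp; the last window is right-padded. Every k-mer window
   (k = 3) that touches a pad symbol or an IUPAC ambiguity code becomes the
   reserved UNK token, whose embedding row is pinned to the zero vector — so
   the padded region contributes exact zeros to the segment matrix while the
   row count stays fixed at `2000 − k + 1 = 1998`.
2. **k-mer embedding.** Overlapping 3-mers are embedded with vectors trained
   by skip-gram with negative sampling (SGNS) on the pooled tokenised corpus
   of all training genomes (one shared vocabulary and table for both towers).
   Each segment becomes an `X ∈ R^(1998×d)` matrix, `d = 64` by default. The
   table is pretrained and frozen; the `use_pretrained_embedding=False`
   ablation replaces it with a trainable, seeded random table of the same
   shape.
3. **Local features (CNN).** `X` is treated as a one-channel 2-D image and
   passed through three conv–batchnorm–ReLU blocks (channels 64/128/256,
   3×3 kernels, stride 1, same padding) with 2×2 max pooling after blocks
   one and two; global average pooling yields a 256-d vector per segment
   regardless of spatial extent.
4. **Global aggregation (Transformer).** A learnable CLS vector is prepended
   to the sequence of segment vectors and a stack of 6 post-norm encoder
   layers (4 heads, `d_k = d_v = 64`, residual + LayerNorm around both the
   attention and the position-wise FFN sub-layers, FFN width 1024) mixes the
   set; the final CLS row is the genome's global representation. No
   positional encoding is applied by default: segments form an unordered
   set, which makes the CLS output provably invariant to segment permutation
   and to appended masked padding segments — both are tested properties.
   Sinusoidal encodings are available behind `use_positional_encoding`. The
   `use_transformer=False` ablation replaces the encoder with a
   mask-weighted mean of segment vectors.
5. **Fusion classifier.** `z = [C_phage; C_host] ∈ R^512` goes through an
   MLP 512 → 4096 (ReLU) → 2 and a softmax; index 1 is the match
   probability, prediction is the argmax.

## Optimisation protocol

Cross-entropy loss with the L2 penalty *inside* the loss
(`+ λ Σ w²` over weight matrices only; biases and normalisation gains are
exempt), Adam (`lr 1e-4`, `β₁ 0.9`, `β₂ 0.999`), mini-batches of 32
seeded-shuffled pairs, global-norm gradient clipping at 5.0, 200 epochs, and
batch-norm moving statistics with decay 0.999. Probabilities are clamped at
1e-12 before the log; a non-finite loss or gradient aborts with the batch
index. All weight initialisation, shuffling and sampling flow from explicit
seeds; repeated runs are bit-identical on one machine.

Two numerical choices depart from the plain textbook recipe and matter at
small scale:

* **Debiased batch-norm statistics.** The moving accumulator follows
  `m ← 0.999·m + 0.001·batch` from a zero start, so after `n` updates it
  underestimates the population by the factor `1 − 0.999ⁿ`. Evaluation
  divides by that factor (the same correction Adam applies to its moments).
  At 10k+ updates this is a no-op; at the few hundred updates of a
  desk-scale run it is the difference between usable and garbage inference
  statistics.
* **Fusion-layer calibration.** Discriminative information in the CLS
  vectors lives in directions whose variance is orders of magnitude smaller
  than the LayerNorm-fixed O(1) coordinate scale. The optional
  `fusion_batchnorm` flag (off by default, on in the reduced profile)
  batch-standardises `z` before the MLP so the classifier sees those
  directions at O(1) scale. Because train-mode towers (batch statistics) and
  eval-mode towers (population statistics) produce slightly different `z`
  distributions — a difference of many standard deviations of the tiny
  informative coordinates — the fusion layer's population statistics are
  re-estimated after training from the training pairs with the towers in
  inference mode. Without this calibration, inference saturates to a
  constant class at desk scale while training accuracy is fine.

## Synthetic benchmark generator

Real data for this task couples hosts to a five-rank taxonomy (genus ⊂
family ⊂ order ⊂ class ⊂ phylum) whose clades differ in k-mer composition,
with phages partially mirroring their host's composition — the signal that
all alignment-free host-prediction methods exploit. The generator plants
exactly that structure and nothing else:

* Every phylum receives an order-2 Markov chain over {A,C,G,T} with
  Dirichlet-distributed transition rows (`profile_concentration`, default
  1.0). Child clades mix the parent's rows with fresh Dirichlet noise
  (`rank_inheritance`, default 0.75 weight on the parent), so compositional
  similarity decays with taxonomic distance — the reason host-prediction
  accuracy rises with rank.
* A clade's `CompositionProfile` is defined as the *stationary* 3-mer law of
  its chain. An arbitrary probability vector over the 64 trimers is
  generally not realisable as the 3-mer distribution of any stationary
  sequence (left- and right-marginal consistency), so defining the profile
  through the chain makes "empirical 3-mer frequency converges to the
  profile" exact in the long-sequence limit rather than approximate.
* A phage emits each base from `m·P_host(next | previous two) + (1−m)/4`
  with `m = mimicry_strength`: `m = 0` is an iid-uniform genome, `m = 1`
  reproduces the host clade's chain exactly. For intermediate `m` the
  realised 3-mer law is the stationary law of the mixed chain (not the
  literal profile mixture).
* Labelled pairs: one positive per phage (its true host) plus negatives
  drawn uniformly, without replacement, among hosts whose phylum differs
  from the true host's (the phylum-exclusion rule). A dataset whose hosts
  all share one phylum raises an error rather than silently degrading.

What the generator does **not** emulate: genes, GC skew, prophages, repeat
structure, strand asymmetry, horizontal transfer, or any protein-level
signal. Passing tests on this data demonstrates that the pipeline recovers a
planted compositional signal end to end; it says nothing about accuracy on
real genomes, where the signal is weaker and confounded.

An in-repo oracle guards learnability: a naive nearest-profile baseline
(cosine similarity of 3-mer frequency vectors) must assign >80% of phages to
the right phylum at `mimicry_strength ≥ 0.7` and 50-kb genomes before any
neural training is blamed for a failure.

## Desk-scale profile

The full-size protocol (thousands of genomes, 62k candidate hosts, 200
epochs of a 6-layer Transformer) is a GPU-scale computation. Tests and the
reproduction script therefore use a reduced profile chosen once:

* architecture: 2 Transformer layers, 2 heads, conv channels 16/32/64 into a
  64-d tower, `d_embed 8`, pooling (8×4) then (8×2), MLP width 256,
  `fusion_batchnorm` on, float32;
* study: 4 phyla (one genus each at branching 1, 2 hosts per genus), 20-kb
  genomes, mimicry 0.9, 20 training phages → 40 balanced training pairs,
  10 held-out phages → 20 balanced test pairs;
* optimisation: 30 epochs, lr 1e-3 decaying linearly to 1e-4, batch 4,
  λ = 1e-4, BN decay 0.9.

The learning rate, L2 coefficient and BN decay are rescaled from the
full-protocol defaults because those are calibrated for ~10k optimiser
steps: at a few hundred steps, λ = 1e-3 under Adam's normalised updates
shrinks the weights to zero before the data signal is learned, and a
0.999-decay BN memory (≈1000-step window) averages over the whole run while
the representations are still drifting. The linear lr decay lets the
optimiser settle; without it held-out accuracy fluctuates between epochs
instead of converging. The memorisation check uses the same architecture on
an 8-pair fixture with ~4-kb genomes.

## Evaluation

For host prediction, the binary classifier scores a phage against every
candidate host and predicts the top-1 by match probability (ties broken by
lexicographic host id). Host tower representations are computed once per
candidate and cached; a test asserts cache-equivalence with independent
single-pair forwards. Accuracy is reported at each of the five ranks: a
prediction is correct at rank L when the predicted host's lineage name at L
equals the true host's. With tree-consistent lineages the report is monotone
non-decreasing from genus to phylum; the implementation is tested against a
brute-force double-loop oracle on randomised instances.

## Known limitations

* The numpy implementation is memory-bandwidth-bound; the full-size
  architecture is practical for inference and shape-level verification but
  not for full-scale training.
* SGNS updates are mini-batched with per-token averaging rather than
  word2vec's strictly sequential updates; embeddings are equivalent in the
  properties tested (context similarity), not bit-compatible with any other
  implementation.
* Only the forward strand is tokenised by default; reverse-complement
  canonicalisation exists behind a flag but is untested against any
  biological claim.
* The desk-scale study has 20 test pairs; its accuracies carry
  correspondingly wide binomial uncertainty and are checked against
  statistical bounds, not point values.
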