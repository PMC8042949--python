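# Methods

## The SSC representation

A protein pair (A, B) is encoded as a `grid_side x grid_side x n_channels`
tensor (default 60 x 60 x 3). Each protein contributes up to `max_len`
(1800) residue slots; the invariant `2 * max_len = grid_side^2` makes a
maximum-length pair fill the grid exactly. Per slot, three values are
derived from the raw sequence:

| channel | formula | range | meaning |
|---------|---------|-------|---------|
| S1 | `((i*12)+20)/255`, `i` = alphabet index | {0.0784 … 0.9725} | residue identity |
| S2 | `num(i)/len` | (0, 1] | within-sequence frequency of the residue at this slot |
| C  | `(i*20+j)/400`, `j` = next residue | [0, 0.9975] | ordered bigram of this slot and its right neighbour |

The alphabet is the 20 one-letter codes in alphabetical order (A=0 … Y=19).
This ordering is forced by the worked bigram values M→E = 0.5075 and
E→M = 0.1750, which require M=10, E=3. The S1 multiplier/offset make the
twenty codes irregular so they never coincide with a C-channel value.

Layout: the flattened axis has `2*max_len` slots; A is written forward from
slot 0, B is written *reversed* ending at the last slot, zeros fill the gap.
Channels are computed on each sequence as laid out, so B's bigrams are
those of its reversed string. Each channel vector is reshaped row-major.
Consequences, all tested:

* swapping (A, B) reverses the flattened S1 and S2 vectors exactly
  (centrosymmetry), even with padding;
* the C channel breaks the symmetry for any pair that is not an all-'A'
  homopolymer — note that even a palindromic sequence breaks it, because
  ordered bigram codes are asymmetric and the terminal zero slot moves
  under reversal; the homopolymer works only because its A–A bigrams code
  to 0;
* the A–A bigram code equals the padding value 0. We follow the formula
  verbatim and document the collision rather than renormalising.

Degenerate inputs: sequences outside 20..1800 residues raise a length-filter
error naming the offending protein; residues outside the alphabet either
raise (`reject`, default) or encode as 0 with a logged warning
(`map_to_zero`). All codes are kept at full float precision internally;
4-decimal rounding is applied only for display and in tests.

A one-hot `L x 20` encoding (95% zeros) is retained as the baseline format
for the 1D CNN.

## Dataset construction

* **Length filter**: keep 20..1800 residues inclusive; rejection log states
  a reason per record.
* **Redundancy reduction**: greedy longest-first clustering; a record is
  dropped when its global identity (1 − edit distance / max length,
  Needleman–Wunsch via edlib) to an already-kept representative exceeds
  0.60. This is a deliberately simple stand-in for CD-HIT-style clustering
  with the same interface, deterministic under the sort order
  (length descending, then id).
* **Negative sampling** (all samplers exclude recorded positives and
  enforce global pair uniqueness across strategies):
  1. *random*: uniform over unordered non-recorded pairs;
  2. *location*: pairs of annotated proteins whose localization term sets
     are disjoint (unannotated proteins are ineligible — absence of
     annotation is not evidence of separation);
  3. *edited*: a sampled positive has one partner's sequence mutated at a
     uniformly drawn fraction f ∈ [0.2, 0.8] of positions (substitutions
     only, never to the original residue), yielding a synthetic variant
     record and a label-0 pair. The premise that a heavily mutated partner
     no longer interacts is an assumption inherited from the study design,
     not something the package verifies.
  The default mix follows the published composition (≈26.9% location,
  ≈26.9% edited, remainder random); strategies that cannot supply their
  share (e.g. no localization data) fall back to random pairs.
* **Degree-threshold filter**: a pair survives iff both proteins appear in
  at least `threshold` distinct pairs of the supplied positive set.
* **Splits**: stratified 80/20 train/test plus stratified 5-fold CV over
  the training portion (scikit-learn), seeded and reproducible.

Pairs are unordered for sampling and degree bookkeeping; the encoder
consumes the ordered (a, b) as given, since the two orientations yield
different context-channel features.

## The classifiers

2D CNN over the SSC tensor: conv(f1) → conv(f1) → pool 2x2 → conv(f2) →
conv(f2) → pool 3x3 → dropout 0.25 → dense(64) → dense(1, sigmoid), all
convolutions 3x3, stride 1, same-padded, leaky-ReLU (α = 0.3) activations.
The kernel-scale groups name (f1, f2): 32/64, 64/128, 128/256, 256/512;
smaller ad-hoc groups (e.g. 16/32) are accepted for scaled-down runs. The
pooling windows 2 then 3 realise the 60 → 30 → 10 reduction, so the pooled
feature map is 10 x 10 for every kernel group — this is pinned as an
architectural contract and tested. (A stride-based "fast shrinking"
reading of the design cannot produce 10 x 10 from 60 x 60 exactly; we keep
conv strides configurable but default them to 1 and let pooling do the
reduction.)

Training: uniform (Glorot) initialization, Adam (default lr 1e-3; the
scaled-down experiments use 3e-3 with batch 64), binary cross-entropy
computed stably from logits, per-epoch loss history, NaN loss aborts with
diagnostics. Decision rule: positive iff score > 0.5, strictly — a score
of exactly 0.5 is a negative call. Dropout is inverted and inference is
deterministic. All randomness (init, shuffling, dropout masks) derives
from the config seed; training is bit-reproducible on a fixed BLAS.

The layer library (`sscppi.nn`) is a compact numpy implementation —
im2col convolutions backed by BLAS matmul, argmax-routed max pooling,
float32 throughout. At the published data scale (half a million pairs) a
GPU framework is the right tool; the numpy stack trains the desk-scale
experiments below in minutes on one CPU core.

The 1D baseline mirrors the layer plan with 1D kernels over `L x 20`
one-hot input (for the published comparison of encoding formats).

Hyperparameters the design leaves open are pinned as: conv kernel 3x3,
α = 0.3, hidden dense width 64, batch size 128, Adam defaults, epochs 20 —
all overridable in `ModelConfig` and echoed into run manifests.

## Metrics

Closed forms over the thresholded confusion matrix (Acc, Sen, Spe, Pre,
F ≡ F1, MCC); "weighted mean of precision and recall" is taken as the
balanced F1. ROC/PR curves and trapezoidal areas delegate to scikit-learn.
Zero-denominator metrics are reported as 0 with a flag naming the
undefined quantity; AUROC/AUPRC on single-class inputs are NaN with a
flag. The F measure is computed from the (possibly zero-substituted)
precision and sensitivity. Loss is mean binary cross-entropy of the
probability scores (clipped at 1e-7).

## The synthetic interactome

`generate_interactome` emulates sequence-determined interaction: sequences
are i.i.d. uniform over the 20 residues; with probability 0.7 a protein
receives one motif — a random side of one of three planted 6-mer motif
pairs — written over a random position. A pair interacts iff some library
entry has its two motifs split across the two sequences (either
orientation). Interaction is thus motif *co-occurrence*, not similarity,
so the statistics and context channels carry signal beyond residue
identity — the ablation logic at desk scale. Localization terms (1–2 of 6)
are assigned so the location-disjoint sampler can run. Defaults
(160 proteins of 30–120 residues) yield on the order of 1,000 interacting
pairs, hence ≈1,600 training / 400 test pairs after 1:1 balancing — the
scale all scaled-down experiments use.

What the generator does **not** emulate: real degree distributions (its
interaction graph is a union of dense motif-compatibility blocks),
homology structure, compositional bias, disorder, or any physical binding
model. Passing the learning test therefore shows the pipeline can extract
a planted sequence-pair signal end to end — not that it reaches any
particular accuracy on curated interactomes.

## Scaled-down learning experiment

The published experiments (hundreds of thousands of pairs, 128/256
kernels, GPU) are out of desk-scale reach; the substituted, self-contained
property is: on a seeded planted-motif interactome (defaults above), a
16/32-kernel model trained with batch 64, lr 3e-3 must exceed 75% held-out
accuracy, while the same procedure on shuffled labels stays within
0.5 ± 0.05; and training must run without error under all four channel
variants ([S1], [S1,S2], [S1,C], [S1,S2,C]). Training pairs are augmented
with their swapped orientation (databases record both directions as
distinct interactions; the context channel makes the orientations
genuinely different inputs), which roughly doubles sample efficiency on
the compositional motif-matching task. The test set is never augmented.

## Known limitations

* The greedy identity clustering is coarser than CD-HIT (no word
  filtering, single-linkage-like greedy assignment); a hook allows
  delegating to an external tool.
* Bit-exact training reproducibility holds for a fixed numpy/BLAS build;
  across BLAS implementations results may differ in the last ulps.
* The edited-negative labelling assumption (mutation ⇒ non-interaction)
  is untestable within the package.
* The A–A bigram / padding collision means an all-'A' prefix is
  indistinguishable from padding in the C channel (S1/S2 still separate
  them).
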