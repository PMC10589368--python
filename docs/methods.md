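# Methods

## Problem setting

CRISPR-Cas9 cleaves where the 20-nt guide RNA (gRNA) plus a 3-nt NGG PAM
matches genomic DNA, but it also cleaves *off-target* sites that differ from
the intended target by base mismatches, RNA bulges (an unpaired base on the
gRNA side of the alignment) or DNA bulges (an unpaired base on the DNA
side).  Genome-wide assays (GUIDE-seq, CIRCLE-seq, SITE-seq, …) produce
tables of aligned gRNA–target pairs labelled active/inactive, with read
counts reflecting cleavage strength.  These tables are extremely imbalanced
— negatives outnumber positives by up to thousands to one — which is why the
package's primary metric is the area under the precision–recall curve
(PR-AUC) rather than accuracy or ROC-AUC.

`crisprhw` implements an indel-aware token encoding for such pairs and a
hybrid parallel neural network that classifies them, together with the
training/evaluation protocol, a synthetic-data generator, dataset analytics
and a thin CLI.

## Token encoding

Every sample is a pre-aligned pair of 23-symbol sequences (20-nt protospacer
+ PAM) over `{A, C, G, T, -}`, with `-` marking a bulge and never present in
both strands at one position.  Position *i* forms the ordered pair
(guide[i], target[i]); over five symbols there are 5 × 5 = 25 ordered pairs,
each mapped to a unique integer token in [0, 24].  The canonical layout puts
guide rows `A, T, C, G` against target columns `A, T, C, G, -` with
`token = 5·row + col`, and fills the gap row as `(-,-)→20, (-,A)→21,
(-,T)→22, (-,C)→23, (-,G)→24`.  This is the unique simple completion
consistent with the five anchor assignments the encoding is defined by
(`AA→0`, `TA→5`, `C-→14`, `GA→15`, `-A→21`).  `(-,-)` is kept for a dense
vocabulary although the pair invariant makes it unreachable.  The table is a
data object (exportable/importable as two-column text), so an alternative
layout can be substituted without code changes.

Unlike one-hot schemes that OR the two strands together, the token encoding
preserves both the identity and the orientation of every perturbation
(`TA` ≠ `AT`), and it covers bulges, which most one-hot encodings do not.

## Network architecture

Input: 23 integer tokens.  Four stages:

1. **Sequence encoding** — embedding 25 → 90 per position.
2. **Feature extraction** — two same-padded 1-D convolutions,
   kernel 4 with 70 filters then kernel 6 with 40 filters, each followed by
   batch normalisation then ReLU.  Same-padding preserves the 23-position
   axis, which the skip connections and positional attention require.
3. **Hybrid parallel layer** — three branches on the 23 × 40 features:
   * a modified 1-D residual block: two kernel-5 convolutions (40 filters,
     batch-normed) with a skip addition and final ReLU;
   * a bidirectional LSTM, 64 units per direction (the per-direction width
     is configurable; 64 gives capacity comparable to the 70/40-filter
     convolutional stages);
   * single-head scaled dot-product self-attention over the 23 positions,
     applied to a skip fusion: the embedding output projected to width 40
     and added element-wise to the feature-extraction output.  Attention can
     weight, e.g., mid-protospacer bulge positions and PAM-proximal
     mismatches more heavily.
   Branch outputs are flattened (no pooling) and concatenated
   (920 + 2944 + 920 = 4784 features).
4. **Dense head** — 300 → 100 → 2, ReLU and dropout 0.2 after the first two
   layers, softmax over the final two logits giving (inactive, active)
   probabilities.

### Ablation variants

`no_blstm`, `no_resnet`, `no_attention` drop one branch; `no_dense` feeds
the concatenated features to a single 2-unit softmax layer (it must still
emit probabilities); `serial` keeps all three components but chains them
residual block → BLSTM → attention (mirroring the parallel listing order)
before the dense head.  Every removal variant has strictly fewer parameters
than the full model, so ablation deltas measure the component, not
capacity.  Where the architecture's published description leaves details
open — BLSTM width, attention head count and width, padding scheme, the
exact fusion operator feeding attention, the serial ordering — the choices
above are this package's own and are configurable through `ModelSpec`.

## Numerical engine

The network runs on a small reverse-mode automatic-differentiation engine
over numpy arrays (`crisprhw.nn`): broadcasting arithmetic, batched matmul,
an embedding gather, a same-padded 1-D convolution via im2col, fused batch
normalisation, a fused LSTM recurrence with hand-derived backpropagation
through time, softmax, and a fused softmax-cross-entropy loss.  Everything
is float32; weights are Glorot-uniform from a seeded generator (LSTM forget
gates start at bias 1).  Every backward rule is checked against central
finite differences in float64 in the test suite; the checks randomise all
parameters, including biases, because zero-initialised biases can park
preactivations exactly on the ReLU kink where the finite-difference
quotient is not the subgradient.  Backward walks the graph in reverse
topological order and then breaks the closure cycles explicitly so graphs
free by reference counting; inference runs under a `no_grad` context that
skips graph construction entirely.

## Training protocol

Stratified, shuffled 5-fold cross-validation: each held-out fold serves both
as the plateau-monitoring validation set and the evaluation set, and the
encoder is applied identically to every fold.  Loss is categorical
cross-entropy on two-column one-hot targets (matching the 2-unit softmax
head).  The optimiser is Adam at initial learning rate 0.003 with a
reduce-on-plateau schedule: after 3 consecutive epochs without a *strictly*
lower validation loss (equality counts as no improvement), the rate is
multiplied by 0.2, floored at 1e-5.  Default epochs 30 and batch size 512
are package choices, overridable per run.  No class rebalancing is applied
— training sees the imbalanced data as-is.

`generalization_run` trains one model on concatenated training datasets and
evaluates once on a concatenated disjoint test pool (leave-technique-out
style); a stratified tenth of the training pool is carved out for plateau
monitoring, so the pool needs at least ten samples of each class.

## Metrics

* **ROC-AUC** — the Mann–Whitney rank statistic: the probability a random
  positive outscores a random negative, ties counting one half.
* **PR-AUC** — non-interpolated average precision,
  Σᵢ precisionᵢ·(recallᵢ − recallᵢ₋₁) over descending unique score
  thresholds (not trapezoidal interpolation).
* **Recall = TP/(TP+FN), precision = TP/(TP+FP)** — from the argmax of the
  softmax pair (equivalently threshold 0.5).  A printed variant of the
  recall formula with TN in the denominator circulates in the literature
  defining this metric suite; it contradicts recall's prose definition
  ("proportion of actual positive samples correctly identified") and is
  treated as a typographical error.
* Undefined cases (single-class AUC, empty denominators) raise or return
  `None` rather than silently returning a number.

Both AUCs are verified against deliberately naive oracles (exhaustive
pairwise comparison; full threshold sweep) and against scikit-learn on
random small instances.

## Synthetic data generator

The generator's job is structural fidelity to off-target screens, not
biological realism: it does not model substitution biases, chromatin
context, guide-specific activity, or multi-bulge alignments (bulges in real
screens are rare single events; at most one per pair is generated).
Defaults, chosen once:

| parameter | default | rationale |
|---|---|---|
| `n_pairs` | 10,000 | exercises training at minutes-scale on one CPU |
| `imbalance_ratio` | 78 | the skew of the largest published indel screen |
| mismatch count | weights over 0–6, mode at 1–3 | screens report up to 6 mismatches |
| `indel_prob` | 0.15 | far above the real bulge frequency (~430 of 585k pairs) so bulge code paths are exercised at test sizes |
| bulge position | triangular on 8–20, peak 14 | bulges concentrate mid-sequence, sparing the PAM and the 5′ start |
| penalties | mismatch 1.0, DNA bulge 0.6, RNA bulge 1.2, PAM-weighted | RNA bulge > DNA bulge at every position; scaled so mid-sequence bulges reduce but do not abolish activity — bulge-bearing actives must exist for the bulge–read analysis to have subject matter |
| reads | positives: 1 + Poisson–exponential heavy tail, scale boosted ×2.5 for RNA-bulge and ×1.5 for DNA-bulge pairs; negatives: 0 | reproduces the observation that RNA bulges carry more enrichment reads than DNA bulges |
| `noise_sd` | 0.5 | labels correlate with, but are not a function of, the penalty |

Labels are assigned by ranking the latent activity
`s = −Σᵢ w(i)·penalty(pairᵢ) + ε` and thresholding at exactly
`n_pairs // (1 + imbalance_ratio)` positives, so the requested skew holds by
construction.  Note the read model is deliberately *not* `exp(s)`: ranking
by `s` makes bulge-bearing positives the exception, and their read
magnitudes are governed by the bulge-type boost so the RNA > DNA read
ordering holds among the positives that do carry bulges.

`planted_signal_separable` is the controlled fixture for learning tests:
active pairs have ≤1 mismatch and no bulge, inactive pairs have 3–6
mismatches (15% also a bulge), so the label is a noiseless deterministic
function of the token sequence and a perfect classifier exists.  Shuffling
its labels destroys the signal entirely, giving the matching null control.

What passing tests on this generator do **not** show: performance on real
screens, where the decision boundary is far from separable, bulges are two
orders of magnitude rarer, and read noise is assay-specific.

## Problem sizes used in the checks

The end-to-end learning check cross-validates the full network on 10,000
planted pairs at 10:1 imbalance for 10 epochs (batch 512) and expects mean
PR-AUC ≥ 0.9; its permuted-label null control runs 3 epochs — a null has
nothing to learn, and three epochs are ample to show chance-level ROC-AUC.
The ablation check trains each of the six variants for one epoch on 1,000
synthetic pairs.  Metric oracles sweep 200 random instances of ≤ 20
samples.  These sizes are the package's own choices for a minutes-scale,
single-CPU check of correctness, not statements about real-data behaviour.

## Known limitations

* The engine is single-threaded numpy; it is meant for correctness and
  desk-scale experiments, not GPU-scale training on half-million-pair
  screens.
* `Dataset` holds pairs in memory as Python objects; hundreds of thousands
  of rows work but are not fast to construct.
* The encoder interface accepts an alternative `TokenTable`, but no
  alternative (one-hot) encoders ship with the package.
* Reported real-screen AUC values depend on external data and long
  stochastic training runs and are out of scope for the test suite.
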