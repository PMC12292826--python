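# Methods

`mvld` implements Stage-1 pre-training for a compact medical vision-language
model trained under a frozen, higher-capacity teacher.  This note records the
model, the training procedure, the synthetic data the package ships with, and
the numerical and design choices a maintainer would want to know about.

## Model

Both teacher and student are dual-stream transformers:

- **Image encoder** — a ViT: the image is cut into non-overlapping
  `p x p` patches (16 px at full scale, N = (S/p)^2 patches), linearly
  embedded, prefixed with a learnable summary token, given learned position
  embeddings, and passed through pre-norm self-attention blocks.
- **Text encoder** — token + position embeddings over a whitespace
  vocabulary (a pluggable hook can substitute a sub-word tokenizer at full
  scale) followed by pre-norm self-attention blocks.
- **Fusion module** — co-attention layers: each layer gives the image
  stream and the text stream a self-attention sublayer, a cross-attention
  sublayer attending to the other stream, and an MLP.  We chose the
  dual-stream design over a single stack on the concatenated token sequence
  because the published per-layer multi-modal parameter counts
  (9.45 M per layer per modality at width 768, i.e. 16 d^2) match exactly
  the self + cross + MLP layout and cannot be produced by a concatenated
  single stack (12 d^2 per layer).  It also gives the "text-influenced"
  N x N image attention map a natural home (below).
- **Heads** — a masked-language-modeling head whose output projection is
  weight-tied to the token embedding (the standard choice for this text
  encoder family); a 2-way image-text matching classifier on a pooled joint
  vector (mean of the two stream summary tokens through a tanh pooler); and
  a masked-autoencoder-style reconstruction decoder (default 8 layers at
  width 512, the canonical MAE decoder) that receives visible fused image
  tokens plus mask tokens at masked slots and predicts raw per-patch pixel
  vectors.

Every attention sublayer exposes its post-softmax probabilities and every
block its hidden state, captured in a `ForwardRecord`.

Parameter counts of the full-scale presets land at 102-106% of the published
341.4 M / 188.8 M / 141.6 M totals.  Exact reproduction is impossible from
the published table alone: the published image-encoder figure carries ~19 M
of parameters beyond a standard ViT-B/16 whose identity is not stated, and
head/decoder sizes are not given.  Tests therefore assert layer counts
exactly and totals within 10%.

## Pre-training objectives

- **MLM**: 15% of non-special tokens are selected (floor rule, uniform
  without replacement); of the selected, 80% are replaced by `[MASK]`, 10%
  by a random non-special token, 10% kept.  Loss: mean cross-entropy at
  selected positions (kept tokens included, standard practice).  A batch
  with no maskable tokens contributes 0 with a warning.
- **MIM**: 75% of patches masked; only visible patches (plus the summary
  token) enter the image encoder; loss is MSE between predicted and true
  pixel vectors over masked patches only, pixels in [0, 1], no per-patch
  normalization.  MSE follows the procedure prose (the loss formula's
  cross-entropy symbol is treated as generic notation).
- **ITM**: each pair flips to a negative with probability 0.5; a negative
  substitutes caption or image (equal odds) from another batch member.
  Loss: binary cross-entropy from 2-way logits.
- Sums are exact and unweighted: `pretrain = mlm + mim + itm`,
  `distill = hid + attn`, `total = pretrain + distill`.  Each task runs its
  own forward (masked text / masked image / negative pairs are mutually
  incompatible inputs); a sharing flag is deliberately not implemented —
  clarity over speed at toy scale.

## Distillation

Student layer i aligns to teacher layer `m(i) = ceil(i L / l)` (the last
teacher layer in the i-th of l equal intervals), applied per component
(image, text, fusion).  This reproduces the published 2:1, 3:1 and 6:1
ratios whenever L/l is integral; the non-integral cases (12->7, 12->5) fall
back to the same ceil rule.  Hidden loss: MSE summed over student layers.
Attention loss: MSE per head between post-softmax maps (pre-softmax scores
were rejected as contrary to the definition of the attention matrix),
summed over layers and heads, scaled by 1/h; teacher and student share h.
In the fusion module the self-attention of both streams is distilled; the
cross-attention maps are not (they are recorded and available).  Distillation
runs on the MLM-branch forward; the teacher pass is gradient-free and the
teacher's weights are verified unchanged by hash.

## Attention-guided progressive masking

Per step, a gradient-free forward of teacher and student on the *unmasked*
pair yields four N x N maps: each model's last image-encoder self-attention
(uni-modal) and each model's image-stream self-attention in the last fusion
layer (multi-modal — text influence reaches it through the cross-attention
sublayer).  Maps are head-averaged; the summary-token row/column is dropped
and rows renormalized, since only patch scores are ever ranked.  The four
maps are summed and min-max normalized to [0, 1] (a constant sum maps to the
uniform 0.5 matrix).  Per-patch salience is the column mean ("attention
received"); the reduction from matrix to vector is not specified anywhere,
and column means are the natural "importance to all queries" reading.

The high-attention group contains the `round((1-r) N)` most salient patches
with `r = r_start - (r_start - r_end) * step / max_steps`, r_start = 0.95,
r_end = 0.3, clamped beyond `max_steps` (= the run's total optimizer steps).
The whole high group is masked; the remaining budget is drawn uniformly from
the low group so the total is always `round(0.75 N)`.  The verbatim rule
"75% - r of the low group" is negative at r = 0.95; fixing the total budget
at 75% reproduces both printed endpoints (5% high + 70% low at the start,
70% high + 5% low at the end) and matches the random-masking ratio.  Ties in
salience break toward the lower patch index; all group sizes use
round-half-up.  Low-group sampling is defined over the patch indices in
ascending order, so an independent implementation of the written rule
reproduces the masks bit-for-bit given the same generator.  When no teacher
is configured, the student's maps are used alone (min-max normalization
makes doubling them a no-op), which mirrors the student-only ablation.

## Training loop

AdamW (decoupled weight decay 0.01), linear warm-up over 10% of steps then
linear decay to zero.  The full-scale default learning rate is 1e-5; toy
profiles use 1e-3, since 1e-5 cannot move a randomly initialized toy model
measurably within a few hundred steps.  Weights are initialized from a
truncated normal (sigma = 0.02, cut at 2 sigma) under a run-level seed;
initialization from published pre-trained encoders is an optional untested
hook.  The guided mask is recomputed every step from scratch (a caching
flag was considered and rejected for determinism clarity).  Every step logs
a JSONL row with all loss components and the current r; checkpoints embed
the architecture config (load refuses a hash mismatch), optimizer moments
and RNG states, so a resumed run is bit-identical to an uninterrupted one.
Runs are deterministic given the seed: all randomness flows from
`SeedSequence(seed)` spawns (data order, token masking, guided/random
masks, ITM negatives, init).

## Synthetic corpus

Each sample is an S x S grayscale image in [0, 1]: a low-contrast background
(0.35 plus three random low-frequency sinusoids of amplitude 0.02-0.06,
emulating the low-contrast, structurally similar character of radiographs)
with one bright ellipse planted fully inside a random quadrant.  Size word
(tiny/small/large) sets the semi-major axis (6-19% of the side), shape word
sets the axis ratio (1 / 0.6 / 0.35), intensity word sets the added
brightness (0.25 / 0.45 / 0.65).  The caption is generated from a fixed
template ("a <size> <shape> <intensity> opacity in the <position> region")
over a 64-token vocabulary, so captions mention exactly the words that
rendered the lesion and MLM has learnable structure at toy scale.  The patch
indices covered by the lesion are recorded, giving ground-truth salience for
guided-masking tests.  What the generator does **not** emulate: real
anatomy, multiple or diffuse findings, reporting language, inter-annotator
noise, compound figures.  Passing tests therefore demonstrate mechanism
correctness (masking, objectives, distillation, scheduling), not clinical
representation quality.

## Problem sizes used in tests

The toy geometry is 32 px images, 8 px patches (N = 16), width 32, 2 heads,
16-token captions, a 64-token vocabulary; the toy teacher is 4/4/2 layers
and the student 2/2/1.  The end-to-end check overfits the teacher for 300
steps on 8 pairs and trains the student for 500 steps with the full loss,
then repeats the student run to verify bit-reproducibility.  Statistical
checks use 10,000 sequences (selection rate), 100,000 selected positions
(action split), and 1,000 trials for the exhaustive guided-mask
equivalence.

## Known limitations

- The NumPy stack is single-threaded and unbatched across tasks; it is
  sized for correctness testing, not throughput.  Timing comparisons are
  labelled informational.
- Padding tokens are attended like regular tokens (toy captions nearly fill
  the window; a padding mask adds no information at this scale).
- The text-to-image "multi-modal" map is one defensible reading of an
  underspecified quantity; a literal text-query cross-attention is T x N
  and cannot be summed with N x N maps.
- Whether attention aggregation should average over layers rather than use
  the last layer is unspecified; the last layer is used.
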