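# Methods

## The pipeline model

An exam is a pair of grayscale views plus metadata. All three stages share
one representation: each view is resized to a square, scaled to [0, 1],
encoded to a d-vector, and the two view vectors are concatenated in fixed
(frontal, lateral) order. Stages never see pixels directly, only this
embedding, so the encoder is a pluggable contract (`embed(image) -> R^d`,
with `dim`, `name`, `input_size`).

**Default encoder.** A seeded random-filter convolutional feature
extractor: three blocks of 3×3 convolution (He-scaled Gaussian filters),
ReLU and 2×2 average pooling, then per-channel average pooling over a
coarse spatial grid, then a seeded linear projection to `dim`. Random
convolutional features preserve the two properties the pipeline needs —
locality (the pooling grid keeps *where* brightness structure sits) and
nonlinearity — while remaining deterministic, dependency-free and fast on
CPU. The filters are fixed by design: all task adaptation happens in the
trained heads. A learned backbone can be substituted wherever an
`ImageEncoder` is accepted. Defaults: input 64 px, 12 filters, 6×6 grid,
d = 96 (the grid is clamped to the post-pooling feature-map size, so very
small inputs degrade gracefully).

**Heads and optimization.** Both the abnormality head (1 output) and the
tagging head (A outputs) are dense sigmoid networks trained with mean
binary cross-entropy using seeded mini-batch Adam (batch 32, lr 1e-3) and
a reduce-on-plateau schedule: the learning rate halves after 2 epochs
without validation-loss improvement, floored at 1e-5. Inputs are z-scored
with training-split statistics stored inside the model; this is what makes
the heads robust to the per-exam exposure variation described below.
Training is full numpy, so identical seeds give bit-identical weights.
Defaults used at study scale: one 64-unit ReLU hidden layer, 1000 epochs
(a few seconds on one CPU). The library-level `TrainConfig` default is a
single dense layer, 300 epochs — the minimal head; the pipeline overrides
it with the study settings.

**Ranking.** Scores are sorted descending; equal scores order by ascending
exam_id so every ranking is a total, reproducible order. `top_k(k)` is the
prefix handed to tagging. The abnormality label is the manifest flag; in
synthetic data it equals "gold tag set non-empty".

**Tagging.** Trained on abnormal exams only — passing an exam with an
empty tag set is an error, since an all-negative row carries no
information the stage is designed to use. Thresholds: per-tag grid search
over {0.01, …, 0.99} on validation F1, keeping the *smallest* maximizer
(ties on the flat top of the F1 curve are common; smallest is the most
sensitive choice); tags absent from validation, or with no positive-F1
grid point, fall back to 0.5. Assignment uses strict `>`, so a
probability exactly at threshold is not assigned. A global-threshold mode
(`per_tag=False`) exists for comparison. k-NN voting: r = mean tag count
of the k retrieved exams, rounded half away from zero, floored at 1;
frequency ties prefer the tag whose best supporting neighbour is most
similar, then lexicographic order. The random tagger draws
round(mean tags/exam) distinct tags uniformly from the vocabulary.

**Captioning.** "Same tags" is strict set equality, including the empty
set (an empty prediction retrieves among normal-pattern exams). A
precomputed tag-set → entries hash map backs the filter; search within
the candidate set is an exhaustive cosine scan (index sizes here are
hundreds to thousands). Similarity ties break by lower exam_id. A
subset-match mode (`match="subset"`: entries whose tags contain all
predicted tags) is available for study. The index holds all training
exams by default; `abnormal_only=True` restricts it.

## Evaluation protocols

- **nDCG@k** uses binary gain (abnormal = 1) and the log2(i+1) discount;
  a ranking with no relevant item scores 0 (configurable alternative:
  exclude such bootstrap samples — not the default, to keep replicate
  counts fixed). The bootstrap curve samples `sample_size` exams with
  replacement per replicate, ranks them by the fixed scores (ties by
  exam_id), averages nDCG@k over replicates for each k, then applies a
  centered moving average along k with shrinking windows at the edges.
  Defaults: 1000 replicates of 100 exams, k = 10..80, window 5.
- **Exam-wise F1** is 2|P∩G|/(|P|+|G|), defined 1.0 when both sets are
  empty and 0.0 when exactly one is; F1@k macro-averages it over the
  top-k of a ranked list.
- **Text preprocessing** (shared by BLEU/ROUGE and the keyword labeler):
  lowercase, alphanumeric tokenization, drop all-digit tokens and
  single-character tokens.
- **BLEU** is corpus-level, n-grams up to 4, with brevity penalty. A
  corpus with zero unigram matches scores 0; higher-order zero-match
  counts use exponential (mteval-style) smoothing; orders longer than
  every candidate are dropped from the geometric mean. **ROUGE-L F** is
  the harmonic mean of LCS precision and recall per caption pair, 0 when
  either side is empty.
- **Clinical precision/recall** extract label sets from system and gold
  texts with a deterministic labeler and average per-exam overlap ratios;
  both-empty label sets count 1.0 (vacuous agreement), an empty
  denominator against a non-empty set counts 0. The bundled
  `KeywordLabeler` fires a label when a trigger phrase occurs without a
  negation cue ("no", "not", "without", …) ending within 3 tokens before
  it; uncertainty hedges ("possible", "cannot exclude") are deliberately
  not negations, so hedged mentions count positive.

## The synthetic generator

`SynthConfig` defines the study conditions. Each tag owns a geometric
motif (ellipse, disk, band, line) at a tag-specific location, rendered
into *both* views of every exam carrying that tag, over Gaussian noise
(mean 0.35, sd 0.08). Abnormal exams draw their tag set mostly
(probability 0.85) from a pool of 12 recurring tag-set "syndromes", so
identical tag sets recur across exams — as identical reports do in real
collections — keeping the exact-tag retrieval filter regularly non-empty;
the remainder are fresh random sets (size 1 + Poisson(mean−1), mean 3
tags). Captions concatenate per-tag template sentences plus boilerplate
shared with normal reports (recreating the common-phrase overlap that
inflates pure word-overlap metrics); by construction the bundled keyword
labeler recovers exactly the gold tags from every gold caption. Defaults:
600 exams, abnormal fraction 0.39, 64×64 images, 70/10/20 train/val/test
split.

Two features make the generated task realistically hard rather than
trivially separable:

- **Exposure jitter** — each exam's noise mean is shifted by N(0, 0.06),
  shared across its two views, emulating acquisition brightness
  variation.
- **Benign clutter** — six tag-independent bright disks at random
  positions per exam, present in normal and abnormal exams alike,
  emulating benign anatomy. Clutter and jitter dominate raw cosine
  similarity between embeddings, while the standardized trained heads
  learn to ignore them. This reproduces the regime in which retrieval
  baselines trail trained classifiers and in which constraining caption
  retrieval by predicted tags improves clinical correctness — the regime
  the pipeline is designed for. Motif intensities are tiered
  (conspicuous: nodule 0.70, pneumonia 0.55; subtle: edema 0.14,
  degenerative change 0.20) for the same reason: finding conspicuity
  varies in practice.

`degrade_signal(collection, s, out_dir)` re-renders a generated
collection with motif intensity scaled by `s` using the stored config and
seed, so `s=1` reproduces the bytes exactly and `s=0` removes the
abnormal signal entirely; it supports power-style tests of how pipeline
performance decays with separability.

What the generator does *not* emulate: anatomical texture and multi-view
projective geometry, inter-reader label noise, long-tailed tag
vocabularies (8 tags here vs. hundreds in practice), free-form report
language (captions are templated), and co-occurrence structure between
findings beyond the syndrome pool. Tests passing on this data show the
pipeline's logic and its expected orderings hold when tags are visually
grounded; they do not certify performance on clinical images.

## Numerical and design choices

- Tags are compared case-insensitively after whitespace normalization;
  vocabulary order (which fixes output-node indices) is first appearance
  in the training split. Out-of-vocabulary gold tags on val/test exams
  are kept for evaluation but can never be predicted.
- Manifests are JSONL (free text and tag lists without CSV escaping
  ambiguity); a CSV reader with ';'-joined tags is provided. Round-trips
  are lossless, including the vocabulary order.
- Embedding tables, encoder weights and retrieval indices persist as
  `.npz` (no pickle); reloads are bit-identical.
- All similarity search is cosine; zero-norm queries are an error rather
  than silently defined.
- Random draws use `numpy.random.default_rng` seeded per entry point; the
  mini-batch shuffler derives its stream from seed+1 so data order and
  weight initialization stay independent.
- The pipeline predicts tags only for the top-k ranked exams (the
  operational workflow); evaluation protocols may tag all abnormal test
  exams to build F1 curves. Default k = 100.

## Problem sizes

The bundled tests and the acceptance script run the full pipeline at 600
exams (64×64 px) and the multi-seed retrieval comparison at 300 exams ×
5 seeds — sizes chosen so every stage trains to its asymptotic ordering
(trained tagger above k-NN voting above random; constrained retrieval at
or above unconstrained on clinical precision/recall) while a complete run
stays in the tens of seconds on one CPU core.

## Known limitations

- The trained-vs-retrieval tagging margin narrows below ~400 exams, where
  threshold selection overfits the small validation split; the
  global-threshold mode is more stable there.
- Probabilities are not calibrated; ranking uses them only ordinally.
- Ranking ignores urgency/severity — an exam with a minor but certain
  finding can outrank a subtle critical one.
- The keyword labeler handles negation by a fixed 3-token window; scope
  constructions ("no evidence of X or Y") beyond that window, and
  mentions split across sentences, are not modeled.
- Joint fine-tuning of the convolutional filters with the heads is not
  implemented; the encoder is a fixed feature extractor by design, and a
  trainable backbone would be supplied as an external `ImageEncoder`.
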