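# Methods

## Model

A user is a sequence of posts `p_1 … p_n` (chronological when timestamps
exist, file order otherwise).  The model has four parts sharing one
trainable text encoder:

1. **Encoder.** The default ("tiny") encoder is a word-embedding table with
   mean pooling: whitespace/punctuation tokenization, lowercasing,
   corpus-built vocabulary (default cap 5,000 types, ids 0 = pad,
   1 = unknown), truncation at `max_tokens = 64` (social-media posts
   average a few tens of tokens), embedding dimension `d_h = 32`.  The
   encoder slot accepts any object mapping texts to fixed-length vectors;
   a pre-trained transformer adapter can be plugged in without changing
   any downstream interface, but the default path deliberately needs no
   download and no GPU.
2. **Post head.** One affine layer + 12-way softmax over the 11 distortion
   categories plus NORMAL.  Loss `l1` is the mean cross-entropy over posts
   that carry a distortion label (gold or pseudo); unlabeled posts are
   masked and contribute exactly zero, including to gradients.
3. **Aggregator.** A unidirectional LSTM (hidden size 32 by default;
   bidirectional available) over the post vectors, then additive attention
   `e_t = v·tanh(W ĥ_t + b)`, `α = softmax(e)`, `ĥ_all = Σ_t α_t ĥ_t`.
   Attention is applied to the LSTM outputs (the sequential architecture);
   a config switch `attend_over="raw"` instead attends over the raw post
   vectors, bypassing the LSTM, for comparison.  Histories longer than
   `max_posts_per_user = 128` keep the most recent posts.
4. **User head.** A one-hidden-layer (tanh, 16 units) FFN with 2-way
   softmax; the reported depression probability is the positive-class
   probability.  Loss `l2` is mean cross-entropy over labeled users.

Training minimizes `l = w1·l1 + w2·l2` (defaults `w1 = w2 = 1`; `w1 = 0`
is the single-task ablation).  Every optimization step mixes both
supervision sources: a batch of users (default 8) contributes `l2` and, via
its labeled posts, `l1`; a standalone labeled post corpus ("seed posts"),
when given, is spread evenly across each epoch's batches so it is covered
once per epoch.  The optimizer is Adam (lr 0.02).  All computation is
NumPy with hand-written backpropagation, verified against central finite
differences in the test suite (tolerance `1e-6 + 1e-4·|g|`).

**Checkpointing and early stopping.**  A stratified validation split
(default 20% of users) is held out.  Training stops when validation F1 has
not improved for `early_stopping_patience = 10` epochs; the restored
checkpoint is the epoch with minimum validation joint loss.  These two
roles are deliberately distinct: on small validation splits F1 is coarse
(a lucky early epoch can score 1.0 and never be beaten), while validation
loss moves smoothly and covers both tasks.

**Determinism.**  All randomness (init, shuffles, splits) flows from the
config seed through `numpy.random.default_rng`; repeated runs are
bit-identical on the same machine.

## Semi-supervised expansion

A post-level classifier (the same encoder + softmax head, trained alone)
is fitted on the gold seed set and applied to an unlabeled pool.  Pool
posts whose top-class probability clears `confidence_threshold = 0.9`
(a deliberate default; "high confidence" is otherwise unquantified) are
accepted with that pseudo label — including NORMAL predictions, which grow
the normal class.  Expansion is single-round; argmax ties resolve to the
lowest category index; an optional per-category cap keeps the
highest-confidence posts.  Quality is estimated by simple random sampling
without replacement (default 100 accepted posts) against an oracle — the
generator's withheld answers in synthetic runs, a human annotation file
otherwise — reported per category, with categories absent from the sample
reported as undefined rather than zero.  The estimator is unbiased over
sampling seeds, which the tests check by Monte Carlo against known true
precision.

## Evaluation modes

`standard` computes recall TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP), F1 = harmonic mean of precision and recall (positive class =
depressed).  `paper_literal` applies verbatim a nonstandard printed variant
in which the sensitivity formula is reported under the name "specificity",
precision is TP/(TP+TN), and F1 harmonic-means those two.  The two
conventions disagree in general and cannot be mapped onto each other after
the fact, so every report is stamped with its mode and the package never
silently "fixes" either; zero-denominator ratios are reported absent,
never 0.

## Synthetic corpus generator

The generator emulates the statistical structure that the analyses assume,
not real language:

* cohort: each user is depressed with probability `depressed_fraction`
  (default 0.3 — a clear minority class, between the roughly 15% and 35%
  depressed fractions typical of public screening corpora);
* volume: posts per user are gamma-Poisson with mean 50 (desk-scale;
  real histories run to hundreds or thousands and the model truncates to
  the most recent 128 anyway);
* distortion rates: each post is distorted with probability 0.30
  (depressed) vs 0.05 (control), scaled by an age-group factor
  `1 − slope·g` with `slope = 0.15` over groups a–d, encoding the higher
  prevalence among depressed users and the decline with age that the
  cohort analyses are designed to detect;
* categories: distorted posts draw a category from a per-cohort simplex
  defaulting to the relative category frequencies of the expanded seed
  corpus;
* text: template phrases with one marker token unique to each category
  ("should", "doomed", "thinks", …).  At `signal_strength = 1` every
  distorted post contains its category's marker and a keyword lookup is a
  perfect classifier (the separability oracle); at 0 the text is drawn
  from neutral templates regardless of label, so labels are independent of
  text and any classifier sits at chance (1/12 on balanced classes).
  `marker_variants = k` gives each category `k` distinct surface forms
  (base marker + digit suffix), emulating lexical diversity; the keyword
  oracle matches variants by prefix and stays exact;
* topics: adolescent depressed users talk about mom / friend / love /
  school, adult depressed users about work, controls about everyday
  subjects — giving the word-frequency analysis a known signal to find;
* every post carries its gold label; `generate_seed_and_pool` additionally
  emits an unlabeled pool whose true labels are withheld into an answers
  map keyed by post id, so pseudo-label precision can be scored exactly.

What passing tests on this generator shows: that the implementation
recovers structure that is genuinely present, at the stated sample sizes,
under a vocabulary of a few hundred types.  What it does not show:
robustness to real social-media language — misspellings, sarcasm, topic
drift, class imbalance in the wild, or distortions expressed without
marker words.

## Canonical experiments

Both experiments live in `cogdep.experiments` so tests, scripts and
documentation run identical conditions.

**Separable recovery.**  200 users × ~50 posts at `signal_strength = 1`,
160/40 train/test split, every post gold-labeled, 25 epochs.  A correct
implementation reaches ≥ 0.95 held-out accuracy on both tasks (typical
runs: 1.00 user-level, ≥ 0.99 post-level).

**Multi-task benefit.**  The ablation question — does post-level
distortion supervision improve user-level depression F1? — is only
meaningful away from ceiling, and only clean when the two arms differ in
nothing but the auxiliary loss.  With a single surface form per category,
or with category-specific template phrasing, the generator's text is easy
enough that the ablation matches the joint model and their difference is
optimization noise.  The experiment therefore makes the premise literal:
distorted posts are neutral sentences with a category marker token
embedded (`marker_only_text=True`), each category has 30 marker surface
forms (~330 in all), the depression corpus carries *no* post-level
labels, and distortion supervision comes only from a separate
expanded-scale labeled post corpus (1,644 distorted + 2,000 normal).
User supervision is scarce: 40 labeled users × ~15 posts (per-post
distortion rate 0.2 in the depressed cohort), evaluated on 80 held-out
users.  Both arms receive identical corpora and vocabulary; the ablation
sets `w1 = 0`.  The ablation can only learn the marker forms present in
its few dozen users' posts, while the joint model learns all of them from
the labeled post corpus and transfers them through the shared encoder.
Mean held-out F1 over 8 fixed seeds: joint ≈ 0.98 vs ablation ≈ 0.95;
the batch-mean gain was positive on five disjoint 8-seed batches
(+0.01 to +0.10).  The comparison is directional (joint ≥ ablation on
the mean); individual seeds vary.

## Numerical choices and degenerate inputs

* Softmax is max-shifted; cross-entropy clips probabilities at 1e-12.
* LSTM forget-gate bias initialized to 1; other weights
  Gaussian · 1/√fan-in.
* An all-masked `l1` batch yields exactly 0 with a logged warning; a batch
  with no labeled users is a training error.
* Attention over a single post yields weight [1.0]; an empty post sequence
  is a contract error.
* Argmax ties (post categories, pseudo-labels) resolve to the lowest
  category index; word-frequency top-k ties break lexicographically.
* Posts whose text is all punctuation tokenize to the unknown token rather
  than an empty sequence.
* The stopword list shipped for word-frequency analysis keeps modal and
  absolutist tokens ("should", "always", "never", "must"): they are
  distortion markers, and filtering them would erase the signal the
  analysis looks for.
* Age bins are fixed at 10–15 / 16–22 / 23–35 / 36+ (secondary school,
  university, post-college, stable middle age); ages below 10 are a
  contract error, and users without an age are excluded from age-group
  analyses with a logged count.

## Known limitations

* The tiny encoder cannot represent word order or negation; it is a test
  vehicle and a baseline, not a competitive text model.  The encoder slot
  exists so a pre-trained transformer can replace it where resources
  allow.
* Loss masking assumes pseudo-labels are as trustworthy as gold at equal
  weight; no confidence-weighted loss is implemented.
* The generator's cohort mixtures are identical for depressed and control
  users by default; analyses that depend on *which* categories differ
  between cohorts need custom mixtures.
* Single-round expansion only; iterative self-training is out of scope.
* No significance testing is attached to cohort differences; the analyses
  report point estimates and quartiles.
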