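# Methods

## Problem and data model

A discussion thread is a set of posts plus a reply map `R` (child → parent)
forming a tree rooted at the initial post `p_A`; `U(p)` denotes a post's
author. Threads are assumed to be *decision-making* threads — the initial
post asks for help with a health-care decision; selecting such threads is an
upstream concern outside this package.

A *relationship* is a triple `(p_A, p_B, p_C)` with `R(p_B) = p_A`,
`R(p_C) = p_B`, `U(p_C) = U(p_A)` and `U(p_B) ≠ U(p_A)`. It is an
*influence relationship* iff `p_B` is relevant to `p_A`, `p_C` is relevant
to `p_B`, and `p_C` contains a question or indicates a future action.
Classification of triples into these two classes (+1 / −1) is the package's
task.

### Reply-tree construction

Input posts arrive chronologically with an indent depth (tab count in forum
HTML dumps). A post at depth `d ≥ 1` attaches to the most recent preceding
post at depth `d − 1`. Degenerate inputs:

* empty thread or empty initial post → error;
* depth jumps with no plausible parent → error;
* posts empty after whitespace normalization → dropped with a warning, and
  their children re-attach to the most recent surviving shallower post. The
  source corpora say nothing about deleted posts; this re-attachment policy
  is our choice and keeps every surviving post reachable from the root.

Chronological order must be total; the reader supplies it (file order breaks
timestamp ties) so parsing is deterministic. Triple enumeration is ordered
by the reply's, then the counter-reply's, chronological rank.

## Linguistic signals

**Question probability** `Q(p)` is the max over the post's sentences of a
two-rule score: a sentence containing `?` scores `qmark_confidence`
(default 1.0); otherwise a sentence-initial 5W1H pattern — an interrogative
(what/who/when/where/why/how) followed by an auxiliary
(is/are/was/were/do/does/did/can/could/should/would/will) — scores
`pattern_confidence` (default 0.9); otherwise 0. The confidence values are
ordered by reliability of the cue (a question mark is near-definitive); both
are configurable, with the constraint `pattern < qmark`. The full 5W1H ×
auxiliary expansion table is ours; bare "how + adjective" forms ("how long
was it") are deliberately covered through the auxiliary pairings rather
than as free patterns.

**Action probability** `A(p)` is 1.0 when any sentence contains a modal
auxiliary (Penn Treebank MD lexicon: will, can, could, may, must, would,
should, might, shall) or a "going to + verb" construction, else 0.5. The
fallback absorbs informal writing and typos that hide tense; consequently
`A(p) ∈ {0.5, 1.0}` by design. Negation is ignored on purpose: a negated
plan still engages with the suggestion, and polarity is information the
relevance vectors carry. Detection is an explicit lexicon rule — the modal
class is closed, so a statistical tagger adds nothing here; the crude
"verb after *going to*" filter (reject determiners/pronouns) is the one
heuristic, and it only widens recall of an already-soft rule.

Sentence segmentation splits on terminal punctuation (`.`, `!`, `?`)
followed by whitespace; ellipses stay attached to their fragment. The exact
segmentation is frozen by a regression test.

## Text relevance

Relevance of a directional post pair is a binary classification (shared
topic vs not) emitting a score in [0, 1] and a penultimate-layer *relevance
vector*. Two architectures sit behind one estimator:

* **arc1** (representation-based): frozen embedding lookup → 1-D convolution
  (kernel 3, 32 filters) → masked global max-pooling per text →
  concatenation → dense+ReLU (the 64-wide relevance vector) → sigmoid score.
* **matchpyramid** (interaction-based): word-by-word dot-product matrix →
  2-D convolution (3×3, 32 filters) → adaptive max-pooling onto a 4×4 grid →
  dense+ReLU (relevance vector) → sigmoid score.

Choices worth stating:

* The *relevance vector* is the last hidden layer before scoring — the
  richest pair representation available.
* Padding/OOV tokens map to the zero embedding row; padded positions are
  masked out of arc1's max-pooling. Embeddings are **not** L2-normalized
  before the interaction dot products.
* Texts longer than `max_len` (default 128 tokens) are truncated with a log
  message, never an error. The padded length also shrinks to the longest
  training text, which only removes all-pad columns.
* The scoring layer is zero-initialized so training starts at score 0.5;
  pooled conv features have unbounded magnitude and a random scoring layer
  starts the sigmoid saturated.
* The embedding layer is pluggable (anything with `token_ids` /
  `padded_matrix` / `dim`); a contextual-embedding variant could be slotted
  in without touching the matchers.

### Word embeddings

Skip-gram with negative sampling (window 4, 5 negatives, unigram^0.75 noise
distribution), trained on the tokenized sentences of the training-split
posts. The SGD runs in chunks for speed; within a chunk the accumulated
gradient of each row is **averaged** over how often the row was touched, so
the per-word step is bounded by the learning rate regardless of word
frequency (a summed chunk update diverges on small vocabularies). Defaults:
dim 50, lr 0.2 decaying linearly, 10 epochs, single-threaded and seeded —
identical seeds give identical matrices.

## Influence combination

With `Q = Q(p_C)`, `A = A(p_C)`:

* **Baseline**: score `P_AB · P_BC · max(Q, A)`; label +1 iff
  `P_AB ≥ 0.5`, `P_BC ≥ 0.5`, `max(Q, A) ≥ 0.9`. The thresholds are the
  conventional operating point for this rule and are configurable.
* **Deep combiner**: four inputs `V_AB ⊗ Q`, `V_AB ⊗ A`, `V_BC ⊗ Q`,
  `V_BC ⊗ A` where `⊗` is `cat` (append the scalar; input width = vector
  width + 1) or `dot` (elementwise scaling). Each passes a dense+ReLU layer
  (32 units) producing `S_1..S_4`; their concatenation passes a merge
  dense+ReLU (32) and a 2-class softmax. Loss is binary cross-entropy on the
  softmax positive-class probability (functionally identical to a single
  sigmoid unit; the 2-way softmax matches the architecture as designed),
  optimized by Adam (lr 1e-3, batch 32, 30 epochs, no early stopping —
  fixed epochs keep runs reproducible). Decision threshold on the positive
  probability: 0.5, configurable. `Q` and `A` enter unscaled — in
  particular `A`'s 0.5 floor is not recentered, since the combiner consumes
  probabilities as-is. No class reweighting by default; a positive-class
  weight flag exists for imbalanced corpora.

The relevance matcher and the combiner are trained separately (pair labels,
then triple labels); gradients do not flow from the combiner into the
matcher or embeddings.

## Synthetic corpus

The generator emulates the statistical skeleton the analysis relies on, not
natural language:

* Each topic owns a disjoint synthetic vocabulary; a shared pool supplies
  generic tokens. A post's text is drawn from its topic's vocabulary mixed
  with generic tokens; the generic-token rate is drawn **per post** from
  `U(noise_rate − noise_spread, noise_rate + noise_spread)` (defaults
  0.6 ± 0.35), so posts range from strongly topical to almost purely
  generic chatter. This per-post variability is what gives the relevance
  labels an irreducible text ambiguity, putting the trained matcher at a
  realistic operating point (high-80s ROC AUC, ~0.8 accuracy) instead of
  ceiling performance.
* A thread is a root (which always asks a question, as decision-making
  threads do), 1–3 replies by other authors, and, with probability 0.8, a
  counter-reply by the initial author under each. A reply shares its
  parent's topic with probability `p_reply_relevant` (default 0.7 —
  matching the ~71% relevant-pair rate observed in labeled OHC data);
  `p_question`/`p_action` (defaults 0.4/0.4) insert a templated question /
  future-action sentence into the counter-reply, giving an expected
  positive-triple fraction of `0.7² · (0.4 + 0.4 − 0.16) ≈ 0.31`, matching
  the ~31% influence rate of labeled OHC relationships.
* Pair labels are exact topic identity; triple labels re-derive the
  influence definition from the drawn booleans. Question templates always
  end in `?` and contain no modals; action templates always contain a modal
  or going-to construction — so the rule modules recover the inserted
  signals exactly, mirroring the perfect question-module result reported on
  real data at fixture scale.

What the generator does **not** model: natural-language syntax and
paraphrase, post-length and author-activity distributions, sarcasm or
rhetorical questions, relevance that is not topical-vocabulary overlap.
Passing tests therefore demonstrate that the machinery recovers structure
it was designed to recover — not performance on real clinical text.

## Evaluation protocol

Triples split 90/10 (deterministic shuffle; train side is ⌈0.9·n⌉). Pair
labels ride with their triple's split assignment, so relevance training
never sees test-triple text. Metrics: precision, recall, F1, accuracy, ROC
AUC, PR AUC (computed as average precision, i.e. step-wise interpolation).
Zero-denominator ratios report 0 and are flagged in the report's
`undefined` list. For the baseline, confusion counts use the rule's own
labels while the AUCs rank its product score.

Default experiment sizes: 200 threads (~400 triples, ~800 pairs — the same
order as the 853 labeled triples of the reference corpus), ARC-I relevance
matcher trained 30 epochs (the ~650-pair training set needs more passes
than the estimator's quick 10-epoch default), combiners 30 epochs. The full
pipeline runs in well under a minute on one CPU; unit suites use smaller
corpora throughout.

## Known limitations

* Only triples anchored at the initial post are considered; influence among
  arbitrary reply chains is out of scope.
* Action detection has no notion of action *relevance* — "I will tell you
  though..." style false positives survive, as the rule is recall-oriented
  with the relevance vectors expected to compensate.
* The sentence segmenter and tokenizer are regex-based and English-centric.
* The numpy networks are CPU-only and sized for corpora of thousands of
  pairs, not millions.
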