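# Methods

## Model and objective

The embedding is skip-gram with negative sampling over a joint vocabulary
of note words *W* and grouped diagnosis codes *C*. Two dense matrices
*V*, *U* ∈ ℝ^((|W|+|C|)×T) hold input (target) and context
representations; word ids occupy `[0, |W|)` and code ids
`[|W|, |W|+|C|)`, with an internal `ICD9:` prefix on code tokens so no
code string can collide with a word string.

Per visit (*D*, *N*):

* every code in *D* is a target whose contexts are the other codes of *D*
  and **every word occurrence** of *N* — note length therefore weights
  code–word pairs, which is the definition implemented, not an
  approximation (an optional cap is deliberately not provided; nothing in
  the task needed it);
* every word of *N* is a target whose contexts are the words within ±q
  positions of the same note and all codes of *D*. Windows never cross
  note boundaries: notes are kept as separate token sequences rather than
  concatenated, which prevents spurious co-occurrence between the end of
  one note and the start of the next.

Each observed pair is scored `log σ(V_t·U_c) + Σ_k log(1 − σ(V_t·U_{n_k}))`
with K negatives drawn i.i.d. from the unigram distribution of the
*context's* namespace raised to `noise_power`. Negatives are not
deduplicated and may occasionally coincide with the positive context (the
word2vec convention); at the default K = 5 this bias is negligible.

## Training procedure

* **Initialization** — V rows uniform in [−0.5/T, +0.5/T], U zero, from a
  single seeded generator that also drives shuffling, pretraining
  sampling and negative draws; two runs with the same config are
  byte-identical.
* **Updates** — per pair, the classic in-place sweep: each context or
  negative U row is updated immediately with the pre-update V row, while
  the V row accumulates its full gradient and is applied once at the end.
  The hot loop is a numba-compiled kernel over a precomputed per-epoch
  pair stream; the pure-Python `sgd_pair_update` implements the identical
  arithmetic and the tests assert the two paths agree to 1e-12.
* **Learning rate** — linear decay from `initial_lr` (default 0.025) to
  1% of it over a phase's scheduled updates, or constant. The words-only
  pretraining phase and the joint phase each get their own schedule; the
  configured epoch count covers the joint phase only, with pretraining
  epochs counted separately (`pretrain_epochs`, default 5 over a seeded
  10% sample of visits). Pretraining touches only word rows, so code rows
  enter joint training at their initialization.
* **Numerical safety** — σ and log σ are computed in branchless/stable
  forms (`logaddexp`), finite for dot products of magnitude 10⁴ and
  beyond; non-finite matrix entries abort training with a pointer at the
  learning rate.

Defaults (T = 200, 40 epochs, q = 5, K = 5) follow the standard setting
for this model family. `noise_power` defaults to the SGNS convention of
0.75; 1.0 gives the raw marginal distribution for users who want the
literal unigram.

## Preprocessing

Tokenization splits on any non-alphanumeric character, lowercases, drops
every token containing a digit, then drops stopwords (a standard English
list ships as a data file and is replaceable per run). An optional
dictionary word list, when supplied, drops out-of-dictionary tokens —
this reproduces the spell-checked vocabulary regime; leaving it off keeps
all frequent tokens, the regime that surfaces treatment terms like drug
names. ICD-9 codes are grouped by their first three characters after
stripping dots and whitespace; V- and E-codes get the same uniform rule
(the alternative — special-casing E-codes to four characters — was
considered and rejected for uniformity, since grouping granularity is a
user-visible convention, not a correctness issue). Codes shorter than
three characters are kept whole with a warning. Frequency thresholds are
inclusive-keep: count ≥ 50 for words, ≥ 5 for codes, by default.

## Next-visit prediction

Consecutive-visit pairs per patient (sorted by admission time, ties by
visit id) form the labeled set; pairs whose later visit has no
in-vocabulary codes are skipped since the label set must be nonempty. The
predictor is a single softmax layer Z ∈ ℝ^(|C|×F) trained by per-example
SGD (constant lr, default 0.5, 100 epochs) on categorical cross-entropy;
the multi-code label is encoded as a uniform target distribution over the
true codes — the natural maximum-likelihood reading of a set-valued
label. No regularization is applied. Top-k recall is macro-averaged over
examples and reported with the standard error (sample sd / √n). The CLI
splits patients (not examples) 80/20 so no patient leaks across the
split.

## Synthetic cohorts

The generator plants `n_topics` latent conditions, each owning
`codes_per_topic` three-digit codes and `words_per_topic` alphabetic
words, plus a shared noise-word pool. A patient's first-visit topic is
uniform; each later visit keeps the topic with probability
`topic_transition_stickiness` (default 0.8) and otherwise redraws
uniformly. A visit samples `codes_per_visit` codes without replacement
from its topic pool and a `note_length`-word note mixing topic words with
noise words. Defaults — 500 patients with 2–4 visits, 5 topics, 8 codes
and 40 words per topic, 40 noise words, 30-word notes, 20% noise — are
sized so every planted token clears the default frequency thresholds and
the sticky chain gives the next-visit task learnable but non-trivial
signal.

What the generator does **not** emulate: clinical language (tokens are
synthetic strings), realistic note-length and code-frequency tails,
multi-morbidity (one topic per visit), or coding noise. Passing tests
therefore demonstrate that the implementation recovers structure that is
present; they say nothing about how much structure real EHR corpora
contain.

End-to-end checks train at T = 50 for 30 epochs on the default cohort —
dimension 50 is ample for 5 planted topics and keeps the full suite
fast — and measure macro retrieval precision at k = 15 (fraction of a
code's nearest words sharing its topic) and top-k recall of `concat_avg`
features against the 20/40 = 0.5 chance level.

## Numerical and design notes

* Vocabulary ids are assigned by descending count with lexicographic
  tie-break, making indexing a pure function of the corpus.
* Neighbor ranking breaks similarity ties lexicographically; queries use
  V rows only, and zero-norm rows are excluded from candidate sets.
* Persistence uses the word2vec text format (full `repr` precision, so
  cosines survive a round trip bit-for-bit); the vocabulary travels as a
  TSV of token, id, count, and loading revalidates ids against the
  rebuild.
* The trainer is single-threaded by design; determinism is considered
  more valuable here than asynchronous speed, and the kernel already
  trains the default synthetic cohort in tens of seconds.
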