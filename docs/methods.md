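# Methods

## The semantic space

The unit of analysis is the *context*: documents are cut into consecutive,
non-overlapping blocks of `chunk_size` tokens (default 150; a final
remainder block of any positive length is kept as its own context, so
chunking is lossless). Contexts, not documents, are the columns of the
count matrix so that very long documents contribute many comparable units
instead of one dominant one.

Vocabulary filtering removes types occurring fewer than `min_count` times
(default 5), then the `ceil(top_fraction × n)` most frequent remaining
types (default 3%), which strips closed-class/function words without a
stoplist. The order matters and is fixed: min-count first, then the top
cut; frequency ties are broken lexicographically (earlier string counts as
more frequent) so the cut is deterministic. One consequence worth knowing:
because the top cut is a fraction of the *remaining* list, raising
`min_count` can occasionally re-admit a type that sat just below the old
cut — each filter is individually sensible but the pair is not jointly
monotone. Token-class filtering before chunking drops numerals, bare
alphabetic strings, markup tags, punctuation and symbol tokens by
Unicode-category rules; named entities cannot be recognized from surface
strings alone, so the `name` class is driven by an optional user stoplist.

Counts are damped entrywise with ln(1 + c) (zeros stay zero, preserving
sparsity), and the matrix is reduced by truncated SVD to `svd_dim`
dimensions (default 300, automatically capped at min(n_words, n_contexts)
for small corpora). Context vectors are rows of V·S and word vectors rows
of U·S. Scaling by the singular values is a deliberate choice: at full
rank it makes cosines between context vectors exactly equal to cosines
between the raw weighted columns, which gives the reduction an independent
oracle that the test suite checks to 1e-8. Matrices up to 600 on their
longer side are decomposed exactly (LAPACK); larger ones use scikit-learn's
randomized SVD with a fixed `random_state`, so results are reproducible
either way.

## The measures

**CD** counts contexts containing the word at least once and is never
capped. **SemD** is −log(mean pairwise cosine) over the word's context
vectors, base 10 by default (`log_base` is configurable; base 10 puts
scores in the familiar 0–1.2 range). When a word occurs in more than
`context_cap` contexts (default 2,000), SemD and SemVar use the contexts
where the word occurs most often — a tractability cap, since the pairwise
computation is quadratic. A non-positive mean cosine (possible in reduced
spaces) yields a missing value with a logged warning rather than a complex
logarithm.

**SemVar** clusters the word's unit-normalized context vectors with
k-means (k-means++ seeding, best of `n_restarts` by SSE; scikit-learn's
Euclidean Lloyd — for unit vectors ‖u−v‖² = 2(1−cosθ), so the Euclidean
and cosine objectives agree up to a constant). Reported centroids are
re-normalized cluster means and all reported distances are cosine
distances (1 − cos), which puts within-group scores in [0, 2]. The SSE
profile is computed for k = 1..`k_max` and monotone-repaired
(sse[k] ← min(sse[k], sse[k−1])) because restart noise can leave a worse
optimum at larger k. The cluster count is the smallest k achieving
`sse_threshold` (default 90%) of the *attainable* reduction
sse[1] − sse[k_max]; the relative reading is chosen because an absolute
90% drop need not exist, and it yields the small selected counts one
expects from natural context sets. A flat profile (within float tolerance)
selects k = 1; since a between-group distance then does not exist, the
search restarts at k = 2, and the result records that re-selection. Words
with fewer than `min_contexts` contexts (default 10) get a missing SemVar
with a reason code — clustering a handful of points is not meaningful.
SemVar = pooled mean member-to-centroid distance divided by the unweighted
mean pairwise centroid distance; "pooled" means large clusters weight the
numerator by size, while the denominator treats clusters equally.

**SemVarRes** is the per-word residual of a simple OLS of SemVar on log CD
across the measured lexicon (closed-form two-parameter fit). Residuals sum
to zero and are uncorrelated with log CD to machine precision; both
properties are asserted in the tests. SemVar is strongly and positively
tied to log CD — mechanically, more contexts at a fixed cluster budget
mean larger within-cluster spread — so the residual isolates the
substructure signal.

Per-word clustering seeds are derived as crc32(word) mixed with the run
seed, so a word's score does not depend on which other words were
requested, and identical runs are byte-identical.

## The synthetic corpus generator

Real corpora of the relevant scale are licensed, so validation uses a
generative model that plants the geometry the measures are meant to
detect. Topics are unigram distributions over disjoint vocabularies of
`vocab_per_topic` types with a mildly skewed (power-law, exponent 0.8)
within-topic profile, giving the corpus a realistic frequency spread for
the vocabulary filters and CD to act on. Topics come in *families*
(default: 8 topics, 2 families of 4); a document's token distribution
mixes its base topic with its family siblings at total weight
`topic_correlation` (default 0.4) — related topics share substantial
context, unrelated families share none.

Planted words: *unambiguous* words are emitted in documents of one topic;
*polysemes* in several topics of one family (a broad but connected
region — related senses); *homonyms* in two topics from different families
(two unrelated regions). The default planted lexicon is deliberately
heterogeneous, as real lexicons are: homonyms vary in meaning dominance
(50/50 to 80/20) and polysemes in number of senses (2 to 4), so
within-class score variance reflects lexical variety, not just sampling
noise. Per-topic emission rates are solved so that every planted word's
expected per-context hit mass equals the balanced two-topic baseline
(target_rate 0.005 per token, i.e. about 60 expected contexts at the
default corpus size): homonyms and polysemes are matched on expected CD by
construction, so SemVar differences between the classes are attributable
to cluster geometry alone. A generated corpus is checked against
`min_contexts` for every planted word and regenerated (bounded retries)
if sampling fell short; genuinely infeasible specs raise a diagnostic.

Default study sizes are 240 documents × 300 tokens (480 contexts,
~850 vocabulary types) analyzed with `svd_dim` 100, `k_max` 12 and
2 restarts — a corpus small enough to replicate fifty times in minutes
while keeping every stage of the method non-trivial. The full-scale
defaults (300 dimensions, k up to 200, 10 restarts) remain the library
defaults for real corpora.

What the generator does *not* emulate: Zipfian frequency structure across
the whole vocabulary, syntax and word order (contexts are bags of tokens),
multi-character word formation, and graded sense hierarchies. Passing
tests therefore show that the measures recover planted distributional
geometry under the stated model, not that they capture every property of
natural text.

## Separation analysis

`evaluate_separation` compares planted homonyms and polysemes with a
one-sided Mann–Whitney rank-sum test on SemVar (hypothesis: homonyms
lower), a two-sided test on SemD, and standardized group differences
(Cohen's d with pooled variance) for both measures. On the default
generator the replicated pattern is: SemVar(homonym) < SemVar(polyseme)
with p ≪ .01 in essentially every corpus, while SemD — high for both
classes — shows the smaller standardized difference; unambiguous words,
whose contexts form one topic-shaped cloud with no substructure, score the
highest SemVar of all, underscoring that low SemVar specifically signals
*split* context structure rather than ambiguity per se. Across a
frequency-stratified sample of corpus words SemVar correlates strongly and
positively with log CD, which is why SemVarRes exists.

## Numerical and degenerate-input choices

- Cosine of a zero-norm vector, clustering of zero vectors: errors, not
  silent NaNs.
- Cosine distances are clamped below at 0 against rounding (a unit vector's
  self-similarity can exceed 1 by ~1e-16).
- Empty k-means clusters (possible only with duplicated points) are
  repaired deterministically by donating a member from the largest cluster.
- Duplicated context sets give coincident centroids and a zero
  between-group distance; SemVar is then missing with reason
  "degenerate between-group distance" rather than infinite.
- Missing values are `None`/`NA` end to end, with a reason column in the
  output table.

## Known limitations

- The k-means objective on unit vectors approximates spherical k-means;
  assignment boundaries can differ marginally from a max-cosine rule when
  centroid norms differ. The package treats the clustering as a means to a
  distance ratio, not as the quantity of interest.
- SemVar's strong coupling to CD means raw SemVar comparisons across words
  of very different frequency mostly reflect context counts; use SemVarRes
  for that comparison.
- The 2,000-context cap makes extremely frequent words' scores depend on
  the occurrence-count ranking of their contexts; with ties the earliest
  contexts win, which is deterministic but arbitrary.
- Measures on corpora much smaller than a few hundred contexts are
  dominated by the SVD dimension cap and should be interpreted with care.
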