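# Methods

This note documents the statistical models implemented in `pulsecube`,
the parameter defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical conventions used
throughout.

## Stream model

A stream is an ordered collection of posts at **day resolution** (the
canonical time grain of all temporal analysis here; finer timestamps are
truncated on ingest), in two languages (`en`, `es`), with retweet and
reply links. Retweets are split off before any text analysis and used
only to resolve audiences; duplicate texts (exact match after lowercasing,
URL stripping and whitespace collapsing) can be collapsed to their
earliest occurrence, with a map from every copy to its canonical post.
Near-duplicate detection (edit distance, shingling) is deliberately out of
scope: keyword streams are dominated by *verbatim* copies, which exact
normalized matching already captures.

## User quality metrics

**Vocabulary diversity (Yule's I).** For a user's pooled original posts,
with frequency spectrum `V_i` (number of word types occurring exactly `i`
times), `M1 = Σ V_i` and `M2 = Σ i²·V_i`:

    I = M1² / (M2 − M1)

This is the inverse of Yule's characteristic K. The statistic is
undefined when every type is a hapax (`M2 = M1`); it is then reported at a
configurable cap (default 10 000). `I` is computed per user over pooled
posts, not averaged per post, so that one value describes one account.
Low `I` (default threshold 30) with high posting volume is the signature
of template-generated text.

**Domain coherence.** The user's maximum-likelihood unigram model is
compared with a domain unigram model by their inner product
`Σ_w P_user(w)·P_domain(w)` — the probability that two independent draws
coincide. This operationalization needs no smoothing, is symmetric, zero
exactly when the vocabularies are disjoint, and bounded by
`√(Σ P_user² · Σ P_domain²)` (Cauchy–Schwarz). Unigram rather than bigram
models are used; the bigram alternative is noted as a sensitivity
question, but unigrams are far denser at per-user sample sizes. The
domain model is read from any `term → weight` TSV; multiword terms donate
their weight to each constituent word so that either word of a two-word
condition name raises coherence. **The absolute scale of coherence is
inversely proportional to the lexicon size**: against a full medical
metathesaurus (millions of entries) typical in-domain users score ~10⁻⁴,
against the compact built-in lexicon (44 terms) they score ~10⁻²⁻³. The
off-domain cutoff (default 0.5 × 10⁻⁴) is calibrated for a large lexicon
and is configurable; with the built-in lexicon it effectively requires
vocabulary disjointness, which is exactly the planted off-domain
behaviour.

**Quality bands.** A user is *filtered* when high-volume and low-quality
on either axis:

    (n ≥ 100 and I < 30)  or  (n ≥ 100 and coherence < 0.5e-4)

Users caught only when every boundary is relaxed by a multiplicative
margin (default ±20%) are banded *inspect* for manual review — precisely
the band meant for ambiguous high-diversity low-coherence accounts such
as single-topic influencers. All five numbers are configurable
(`QualityThresholds`); the volume prong prevents small accounts, whose
metrics are noisy, from ever being auto-filtered.

## Event and topic detection

Candidate terms are adjacent word pairs after tokenization (URLs removed,
`@mentions` preserved as tokens but excluded from pairs, hashtag symbols
stripped, stopword-adjacent pairs excluded), plus a configurable whitelist
of single-word themes whose semantics need no second word. Each term's
daily occurrence series over the full analysis window — **zeros
included** — is summarized by total, peak (max daily count), span (first
to last occurrence, inclusive) and population excess kurtosis
`g2 = m4/m2² − 3` (biased central moments; zero-variance series score 0 by
convention). Including the zero days is what makes an isolated burst
high-kurtosis (a single-spike series of length n is a scaled
Bernoulli(1/n), `g2 = (1−6pq)/pq ≈ 95` at n = 100) and a sustained theme
low-kurtosis; computing kurtosis only over occurrence days would invert
that ordering.

Selection rules (defaults in `EventThresholds`):

* **event**: `kurtosis ≥ 10` and `peak ≥ 20` and `span ≤ 10` days;
* **topic**: `total ≥ 20` and *not* (`kurtosis ≥ 10` and `span ≤ 10`).

The peak threshold is a *minimum* burst height: events of interest carry
tens of occurrences per day at their peak. Topics are not required to be
disjoint from events — a tall burst inside a sustained series (an event
embedded in its topic) stays a topic, so topic groups contain their
events. The `total ≥ 20` pre-filter stands in for whatever
minimum-frequency cut a production deployment would apply before
clustering.

Selected terms are clustered on their weighted co-occurrence graph (edge
weight = number of posts containing both terms) by Louvain-style greedy
modularity maximization, with `Q = Σ_c [e_c/m − (d_c/2m)²]`. Events and
topics are clustered separately, on their own graphs, mirroring their
separate selection. The clustering is deterministic for a fixed seed;
isolated terms become singleton groups; group ids are stable (ordered by
size, then lexicographically). A post belongs to every group owning at
least one term it contains (one-term membership; a quorum rule was
considered and rejected as it would leave most posts of small groups
unassigned).

## Profile classification

Account self-descriptions are featurized as counts of unigrams plus
adjacent bigrams and fed to a single-hidden-layer (64 ReLU units)
feed-forward classifier over eleven roles; a multinomial-logistic backend
is selectable. This is the smallest architecture that fits the task —
descriptions are short and the per-role vocabularies nearly disjoint, so
depth buys nothing. One multilingual vocabulary is used rather than
per-language models (role vocabulary crosses languages, e.g. emergency-care
terms). Training requires ≥ 2 classes and ≥ 5 examples per class and is
reproducible under a seed; empty descriptions bypass the model and map to
`others` with certainty. Per-role unigram language models over pooled
descriptions provide the top-words report.

## The synthetic generator

`synthgen` emulates the statistical shape of a keyword-collected health
stream; its defaults define the standard study conditions used by the
tests and the reproduction script:

* 90 days, 50 accounts in 10 archetypes (18 lay, 6 concerned,
  4 professional, 5 organization, 5 journalist, 3 alternative-therapy,
  2 student, 2 bot, 2 spammer, 3 off-domain);
* **10 planted events**: truncated discrete-Gaussian bursts of width 5
  (≤ the 10-day span cap), 3 co-occurring name bigrams each, with a
  construction guarantee that the peak-day count reaches the event peak
  threshold; 60% of event posts also carry an associated topic term, so
  event groups overlap their topics;
* **20 planted topics** (18 medical bigrams + 2 single-word themes) at a
  uniform ~1.1 posts/day;
* **100 noise bigrams** planted in 2–10 posts each — too rare and too flat
  for either selector;
* human text is a mixture of one collection keyword per post, common
  words drawn Zipf-weighted (exponent 0.8) from a 4 000-word pool, and a
  30% share of rare words from a 20 000-word tail. The exponent and rare
  share were set so that genuine accounts land in the realistic Yule's I
  band (~55–120) at their stream volumes, well clear of the bot cutoff;
* bots draw from 10-word vocabularies (I ≪ 30), spammers repeat one
  template text, off-domain accounts draw from a disjoint background pool
  (coherence exactly 0); each posts ≥ 100 times so the volume prong
  engages;
* ~60% of human posts are verbatim same-day copies of earlier posts
  (mirroring the heavy redundancy of real keyword streams), retweets at
  0.35 per original resolve the audience, replies at 15% (45% for one
  designated discussion topic), and first-person markers are injected per
  archetype in the post's language.

Everything is seeded; identical configs give byte-identical JSONL.
`small_fixture()` is a 190-post, 10-user, 30-day instance of the same
machinery used by unit tests and documentation.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: natural language (texts are bags of real
keywords plus pseudo-words, so tokenization robustness to real-world
orthography is only covered by targeted unit tests); the long tail of
one-post users (real streams have ~77% single-post accounts, the compact
50-user stream has none, which inflates OnDom values); follower-graph
structure; sub-day burst dynamics; code-switching within a post; and
adversarial bots that randomize vocabulary to evade the diversity metric.
Planted events are near-ideal bursts, so detector precision/recall on the
generator is an upper bound on real-stream performance. Topic coverage in
the generated stream (~69%) exceeds the planted share because incidental
domain-word pairs also qualify as sustained topics — a realistic property
of bigram selection, worth remembering when reading coverage figures.

## Numerical conventions and degenerate inputs

* Yule's I: `M2 = M1` → +∞ sentinel, reported at the cap; empty token
  pool → error (undefined).
* Kurtosis: population (biased) moments; zero variance → 0; series
  shorter than 2 days → error.
* Modularity: errors on an edgeless graph or a non-covering partition;
  `cluster_terms` on an edgeless graph returns singletons with Q = 0.
* Coherence: empty user model → 0 with a warning.
* Empty stream: undefined window (`None`), flagged on ingest.
* Users with only retweets have undefined metrics and no quality band;
  they are never auto-filtered.
* Group report author averages are over distinct authors, not posts;
  %replies and %first-person are over original posts only (retweets enter
  only the audience columns).
* Duplicate canonicalization breaks ties by `(day, post_id)`.

## Problem sizes

The standard study stream is ~15k posts / 50 users; the reproduction
script (`scripts/acceptance.py`) analyses one such stream end-to-end,
checks clustering recovery on ten 40-node planted graphs and trains the
profile classifier on 1 100 synthetic descriptions — a few seconds in
total. The test suite additionally sweeps 20 generator seeds for the
quality-band recovery check.

## Known limitations

* The event/topic thresholds are tuned for day-level bigram counts in
  streams of this order of magnitude; much larger streams would need a
  volume-dependent peak threshold.
* Coherence depends on lexicon coverage; a lexicon missing lay synonyms
  under-scores genuine patients (the inspect band exists for this).
* Louvain is non-hierarchical: one resolution, no nested topics.
* Sentiment/polarity, geolocation and demographic attributes are out of
  scope by design.
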