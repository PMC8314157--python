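# Methods

This note documents the models and procedures implemented in `forumvigil`,
the parameters that matter, what the synthetic-data generator does and does
not emulate, and the design decisions taken where the problem was genuinely
open.

## Corpus model

A post is the atom of every analysis: `(post_id, user_id, forum_id,
timestamp, text)` in line-delimited JSON. Forum scrapers normalise per-site
HTML into explicit `[quote]…[/quote]` and `[signature]…[/signature]`
blocks; cleaning removes these (innermost first, iterated, so nested
quoting unwinds), normalises whitespace, and discards posts left empty.
Deduplication is deliberately conservative: a duplicate is *the same user
posting the identical cleaned text*, and the earliest copy by timestamp
survives. Scoping the rule per user avoids deleting short formulaic posts
("merci !") that different users legitimately share. The language filter
trusts an upstream tag when present and otherwise uses a pluggable
detector (default: a French/English stopword vote); a detector failure
lets the post through with a warning — a flaky backend must never silently
shrink the corpus.

Group assignment matches a product keyword table (keyword → category →
canonical brand) with whole-word, case- and diacritic-folded,
leftmost-longest matching, so "dol" can never fire inside an unrelated
word and a combination brand ("dafalgan codeine", an opioid combination)
shadows its base brand at the same position. A post joins the group of
every category it matches plus the Aggregate union; a post matching
nothing leaves the analysis corpus. The bundled 20-keyword table is an
illustrative stand-in with the same shape as a study keyword list.

## Demographics

French gendered morphology (past participles, adjectives) is
near-deterministic for first-person text, so a lexicon of gendered forms
decides first whenever its votes are unanimous; only marker-free users
fall through to a linear SVM (cost C = 1, token unigrams of the user's
concatenated posts). A decision margin below 0.5 returns `unknown` rather
than a guess. In the pipeline the classifier self-trains on the users the
rule layer labels — the rule layer is the annotator — which is the natural
bootstrap when no labelled demographic data exist. Age comes only from
first-person statements (`j'ai NN ans`); third-person ages ("ma fille a
5 ans") are out of pattern scope, and when a user states different ages
over time the most recent post wins (people age). Age bins follow the
report convention 0–20, 21–30, …, 51–60, 60+; the last two are resolved as
[51, 60] and [61, ∞) so every age falls in exactly one bin.

## Concept tagging

Concept mentions are found by leftmost-longest, non-overlapping dictionary
matching over length-preserving folded text (per-character lowercasing and
diacritic stripping, so spans on the folded string are valid spans on the
original). Longest-match is the standard dictionary-NER convention and is
deterministic; a brute-force all-substrings oracle in the test suite
checks exact equivalence. The dictionary format mirrors a
preferred-term terminology enriched with a consumer layer; every consumer
surface form must map to a concept that also has a standard form. The
licensed terminology itself is not distributed; a 20-entry demo dictionary
ships for tests and the generator.

## Topic model

Latent Dirichlet allocation fitted by batch variational EM
(scikit-learn), seeded and deterministic; K is configurable (default 6 for
the desk-scale corpus). Tokens are folded unigrams and bigrams with a
small French stoplist and a corpus-count floor (`min_count = 2`).
Characteristic tokens: the study procedure weights each topic's token
probabilities by the inverse of the token's probability in the *other*
topics; the exact formula is not published, so this package adopts

    score(k, w) = β[k, w] / (mean over k' ≠ k of β[k', w] + ε),  ε = 1e-12

with ties broken lexicographically and the top 15 reported. This is
documented as an interpretation; its invariances (rescaling a β row leaves
that topic's ranking unchanged; an exclusive token outranks a shared token
of equal in-topic probability) are tested. The correlated-topic-model
variant (logistic-normal prior) is out of scope: the ranking stage, which
is what downstream reporting consumes, is prior-agnostic.

## Intake classification

Messages are split into sentences (terminal punctuation with an
abbreviation and decimal-number guard; sentence spans partition the text
exactly). Features per sentence: intake and non-intake lexical-field hit
counts, exclamation proportion (over non-whitespace characters), pronoun
proportion, token length, and the relative position of the first drug
mention. Features are standardized *within each user* (zero s.d. → 0), so
a prolific poster's volume cannot dominate the feature scale; the
transformation is idempotent and volume-invariant by construction. A
seeded random forest (500 trees, threshold 0.5) predicts per sentence and
a post is an intake post iff any sentence is positive — one credible
intake assertion is what the downstream misuse definitions need.
Supervision comes from sentence labels; on synthetic corpora these are
derived from the generator's post-level truth localized by a first-person
intake rule. Co-consumption then runs dictionary NER with the product
list over intake posts only; spans covered by a paracetamol-product
keyword are not co-mentions, and the denominator is the count of
paracetamol-intake posts.

## Misuse detectors

All misuse analyses run on the adult, intake-positive slice: posts
describing use in a subject younger than 15 (child-noun patterns with age
< 15, or infant nouns) are excluded from these analyses only — concept
counts and the other tables are unaffected.

**Dependence.** Candidate sentences contain a drug name and at least one
term of the dependency lexical field. Each is scored with Okapi BM25
against a reference pattern — the token sequence of the whole lexical
field, one query pseudo-document — and the message score is the sum over
its candidate sentences; a message scoring ≥ 40 (inclusive) is flagged.
Parameters are the classical k1 = 1.2, b = 0.75. Document frequency is
taken over *all* sentences of the corpus while the length normalization
uses the mean *candidate*-sentence length; the idf is the non-negative
form `ln(1 + (N − df + 0.5)/(df + 0.5))`, because the classical Okapi idf
goes negative for terms in more than half the documents, which would break
the guarantee that adding a candidate sentence never lowers a message
score. The scorer is checked against a from-scratch BM25 computation to
1e-9.

**Overdose.** Dose expressions are parsed from folded text: masses
(`10 g`, `500 mg`), unit counts with explicit or product-table strengths
(`2 comprimés de 1000 mg`; the product's mg-per-unit is looked up when no
strength is written, and the higher strength is assumed when a product is
listed ambiguously), and per-day multipliers (`3 fois par jour`). Among
several expressions the highest daily dose is assumed. A dose strictly
greater than the configurable adult threshold (default 4000 mg/day
paracetamol) flags the post and the excess is reported as
`(dose − threshold)/threshold × 100`; independently, any overdose-lexicon
term flags the post lexically. Unknown units are skipped with a warning,
never silently. Per-drug user counts pool both modes and count each user
once.

**Potential adverse events.** For each (post, concept-mention) pair on
the slice, three features: token distance from the concept to the closest
drug mention (adjacent tokens → 1), message token length, and the
concept's occurrence count in the message. A class-weighted radial-kernel
SVM (cost 100, gamma 0.1) classifies the pair; the published gold-standard
annotations are unavailable, so training labels come from the synthetic
ground truth.

**Unapproved indications.** Intake posts whose stated concepts all fall
outside the approved-indication set of every product category the post
matched become candidates, grouped by concept; a post with any approved
concept is on-label and excluded. A seeded simple random sample (default
10%) is drawn for manual review — the review itself, and its published
confirmation percentages, are human outcomes outside computational scope.

## Activity monitoring

The monthly count series (zero months included) is deseasonalized with
STL, i.e. iterated LOESS on each of the 12 seasonal subseries with period
12. The trend window is deliberately short (13 months): with the default
slow trend, an abrupt regime shift leaks into the seasonal component and
produces spurious within-regime swings; a responsive trend absorbs the
step. Requires ≥ 24 months.

Segmentation: a 3-state Gaussian HMM (diagonal covariance, log1p-
transformed values for variance stabilization) is fitted by EM with
multiple seeded restarts (best converged likelihood kept; a global
failure raises an error carrying per-restart diagnostics). K-means (k = 3)
then clusters per-month feature vectors — standardized trend,
standardized deseasonalized value, and the HMM posterior state
probabilities with columns canonicalized by ascending emission mean, so
a permutation of HMM state indices cannot change the outcome. Clusters
are relabelled weak/moderate/high by ascending mean volume. Two
post-processing steps make the three-centroid machinery honest about
series with fewer regimes: clusters are merged when their members
interleave in time (> 3 alternating runs — regimes are temporal blocks by
definition) or when their mean gap is within 3.5 robust noise standard
deviations (noise estimated from median successive differences, which a
cluster split cannot deflate); then runs shorter than `min_run = 2`
months are absorbed into the flanking state with the nearer mean. The
monitor therefore targets marked regime shifts (severalfold volume
changes); a subtle shift below the noise-gap criterion is deliberately
not split.

## Reporting conventions

Every percentage is `100·n/d` rounded **half-up** to two decimals, the
rule consistent with the published pairs (71.3355 → 71.34, 74.9611 →
74.96, 16.6595 → 16.66). Aggregate distinct users are the union of the
subgroup user sets, never the sum. A concept counts once per post.
Denominators differ by table (users, posts, posts-with-concepts,
intake posts) and each table carries its denominator explicitly.

## Synthetic corpus generator

The generator is first-class, tested code, not a fixture. It emulates the
statistical structure the pipeline assumes: Poisson monthly volumes around
a seasonal rate `base × (1 + A·cos(2π(month−1)/12)) × regime multiplier`
phased to peak in December–February (default amplitude 0.3), a
female/male/unknown user mix of 0.71/0.12/0.17, an age mixture following
the aggregate age-bin distribution of the emulated study population,
and per-post planted signals: product keywords (groups), first-person
intake vs non-intake phrasing, concept mentions, adjacent drug–symptom
contexts (adverse events), dependence blocks rich in dependency-lexicon
terms, dose expressions above or below threshold, child-use contexts,
English posts, exact duplicates, quote/signature blocks. Defaults: 200
users, 2000 expected posts over 2003–2006; intake 0.55, dependence 0.05,
overdose 0.05, adverse-event 0.10 per intake post — rates chosen once as
plausible for a drug-misuse forum screen and held fixed. Every post's
labels are recorded in a ground-truth table, and generation is
byte-identical per (config, seed).

Because generation is template-based, planted signals are *recoverable by
construction* when the detectors run with the same lexicons: the
dependence block, for instance, is worded so its BM25 message score
clears the threshold at the default rates (scores ≈ 56–58 against 40 at a
5% dependence rate). A `noise` knob injects typo corruption to exercise
the classifier (not rule) paths; default 0. Passing round-trip tests on
this corpus therefore demonstrates that the pipeline's machinery is
correct and internally consistent — not that the classifiers would reach
the same accuracy on real forum language, with its paraphrase, slang,
negation and irony. That gap is exactly what the published manual-review
percentages quantify, and it is out of computational scope here.

## Problem sizes

The bundled study conditions (2000-post corpus, 48-month series,
120-document topic corpora) are sized for complete desk-scale runs: the
full test suite and the acceptance script each finish in well under a
minute of compute per pipeline pass on a single CPU, which keeps the
round-trip experiments easy to rerun while leaving every statistical
check comfortably powered (≈ 50+ planted posts per misuse class, ≈ 170
known-gender users).

## Known limitations

- The language detector is a stopword vote — adequate for tagged or
  clearly bilingual synthetic corpora, not for production language ID.
- Dose parsing covers the common French dosage constructions, not free
  arithmetic ("deux fois la dose de mon mari").
- The gender classifier inherits whatever bias its (self-)training data
  carry; the margin threshold trades coverage for precision.
- Sentence splitting guards common abbreviations only.
- With k = 3 centroids the activity monitor cannot represent more than
  three volume regimes, and its merge criterion hides shifts smaller than
  ~3.5 noise standard deviations by design.
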