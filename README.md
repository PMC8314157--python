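# forumvigil

Social-media pharmacovigilance for paracetamol-containing products:
a tested, desk-scale pipeline that mines French health-forum posts for what
patients say about a drug — who is talking (gender, age), what they discuss
(medical concepts, topics), whether they actually took the product, what
they take it with, and the misuse signals that matter to drug safety:
dependence phrasing, daily doses above the recommended maximum, and
candidate off-label uses.

It is written for pharmacoepidemiologists and text-mining researchers who
want an end-to-end, reproducible reference implementation of this kind of
surveillance study. Real forum data cannot be redistributed, so the package
ships a seeded synthetic-corpus generator whose posts carry complete
ground-truth labels; every detector is validated by round-trip recovery of
the planted signals and, where a closed form exists, against independent
oracles.

## What the pipeline computes

Posts `(post_id, user_id, forum_id, timestamp, text)` flow through:

1. **corpus** — quote/signature removal, whitespace normalization,
   per-user exact deduplication, French-language filtering; posts are
   assigned to analysis groups by a product keyword table
   (*Paracetamol Only*, *Paracetamol and Opioids*, *Paracetamol and
   Others*, and the *Aggregate* union; multi-product posts join several
   groups).
2. **demographics** — gender from French gendered morphology
   ("je suis allée" vs "allé"), with a linear SVM (cost C = 1) over token
   unigrams for marker-free users and an `unknown` verdict below a decision
   margin; age from first-person statements ("j'ai 34 ans"), binned
   0–20 / 21–30 / 31–40 / 41–50 / 51–60 / 60+.
3. **concepts** — leftmost-longest dictionary tagging of medical concepts
   (preferred terms enriched with a consumer-vocabulary layer).
4. **topics** — latent Dirichlet allocation fitted by batch variational EM;
   each topic is summarized by its 15 *characteristic tokens*, ranked by

   `score(k, w) = β_kw / (mean_{k'≠k} β_k'w + ε)`,

   the per-topic token probability weighted by the inverse of its mean
   probability in the other topics.
5. **intake** — sentence-level drug-intake classification (seeded random
   forest over lexical, stylistic and syntactic features, standardized
   within each user), aggregated per post by any-positive; co-consumption
   counts other drugs mentioned in paracetamol-intake posts.
6. **safety** — on the adult, intake-positive slice:
   - *dependence*: candidate sentences (drug name + dependency-lexicon
     term) scored with Okapi BM25 (k1 = 1.2, b = 0.75) against a reference
     pattern built from the dependency lexical field; a message whose
     sentence-score sum reaches 40 is flagged;
   - *overdose*: dose expressions parsed to mg/day ("2 comprimés de
     1000 mg, 3 fois par jour" → 6000 mg) and compared with the 4000 mg
     adult daily threshold (strictly greater flags, and the excess is
     reported as a percent above the threshold), plus an overdose lexical
     field; users counted once per drug;
   - *potential adverse events*: a class-weighted radial SVM (cost 100,
     gamma 0.1) over concept–drug token distance, message length and
     concept count;
   - *unapproved indications*: intake posts whose stated concepts all fall
     outside the product category's approved-indication index, with a
     seeded 10% sample drawn for manual review.
7. **activity** — monthly post-volume series, seasonality removed by STL
   (LOESS on each of the 12 seasonal subseries), then weak/moderate/high
   regime segmentation: a 3-state Gaussian HMM fitted by EM, K-means over
   (trend, deseasonalized value, HMM posteriors), ascending-mean
   relabelling, merging of indistinct clusters and short-run smoothing.
8. **reporting** — the aggregate tables (group sizes, demographics, top-10
   concepts/PAEs, co-consumption shares, misuse prevalence), every
   percentage computed as `100·n/d` rounded half-up to 2 decimals.

## Worked example

Generate a synthetic corpus (2000 expected posts, 200 users, 2003–2006,
winter-peaked seasonality, 71/12/17% female/male/unknown) and run the whole
pipeline:

```bash
forumvigil generate --seed 1 --out-posts posts.jsonl --out-truth truth.tsv
# wrote 2022 posts to posts.jsonl

cat > config.yaml <<EOF
corpus_path: posts.jsonl
truth_path: truth.tsv
seed: 7
EOF
forumvigil run-all --config config.yaml --outdir out
# pipeline complete: {'raw': 2022, 'kept': 1919, 'grouped': 1919,
#  'concept_mentions': 1118, 'intake_posts': 1053, 'adult_posts': 1861}
```

Of 2022 raw posts, 1919 survive cleaning (duplicates, non-French and
empty-after-cleaning posts are discarded), all of them match a product
keyword, 1053 assert an actual intake, and 1861 remain after excluding
child-use contexts. `out/` then contains the report tables, e.g.
`misuse.tsv`:

```
group               kind        posts  post_pct  users  user_pct
ParacetamolOnly     dependence  18     2.41      17     8.63
ParacetamolOnly     overdose    17     2.28      15     7.61
ParacetamolOpioids  dependence  26     3.63      26     13.61
ParacetamolOpioids  overdose    24     3.35      23     12.04
```

— 18 posts (2.41% of the Paracetamol Only group) from 17 distinct users
carry dependence phrasing whose BM25 message score reaches the threshold
of 40, and `coconsumption.tsv` reports, per co-mentioned drug, the share of
the 1053 paracetamol-intake posts that also mention it (caffeine 43/1053 =
4.08%, ibuprofen 4.08%, tramadol 3.80% under this generator
configuration). `activity.tsv` holds the monthly series with its
deseasonalized values and weak/moderate/high state per month.

Every subcommand (`generate`, `clean`, `demographics`, `concepts`,
`topics`, `intake`, `safety`, `activity`, `report`, `run-all`) is also
available individually; the library API mirrors the CLI one-to-one.

## Limitations

The bundled keyword table, concept dictionary, drug list and SmPC index
are small illustrative stand-ins: the study-scale resources (the full
product keyword list, the licensed medical terminology, a ~2500-entry
product list) are not redistributable. Corpus-dependent results from the
original study population (absolute post counts, topic labels, top-10
rankings) are therefore not reproduction targets; the detectors, their
decision rules and their arithmetic are. See `docs/methods.md` for the
modelling assumptions and design decisions.
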