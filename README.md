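# vinculo

Record linkage toolkit for Brazilian-style administrative registries.

Population-scale epidemiology in Brazil is built by linking a social-programme
population base (CadUnico-like registries, keyed by the NIS social
identification number) against health registries — live births (SINASC),
mortality (SIM), disease notification (SINAN) — which carry no shared key.
`vinculo` implements the full linkage stack such cohorts need, testable end to
end without access to any real data:

- **synthetic registries** with configurable overlap, field corruption
  (single-character edits, accent loss, date-digit swaps, missingness) and a
  gold standard of true pairs known by construction;
- **preprocessing**: name normalization (uppercase, accent folding, particle
  handling for DA/DE/DOS), date standardization to ISO-8601, 7-digit
  municipality and 11-digit NIS validation, exact-key deduplication;
- **Bloom-filter probabilistic linkage**: predicate blocking, bigram
  Bloom-filter encoding of name fields, Dice similarity, weighted composite
  scores, greedy one-to-one resolution;
- **TF-IDF inverted-index linkage**: exact / semi-exact / fuzzy query modes
  over an inverted index, with a cheapest-first fall-through schedule;
- **deterministic linkage** by unique key, plus the two-stage mother–child
  strategy for birth records (newborns may be unnamed, so children attach
  through their probabilistically linked mothers);
- **accuracy assessment**: review-sample labeling, sensitivity/specificity/
  ROC-AUC over a cut-off grid, and Youden-J cut-off selection.

## The methods in brief

**Bloom-filter similarity.** Each normalized name field is split into padded
character bigrams; every bigram sets *k* = 3 bits of an *m* = 128-bit vector
via double hashing with a per-field salt. Two encodings A, B are compared with
the Dice coefficient

    D(A, B) = 2·|A ∧ B| / (|A| + |B|),

and the record-pair score is a weighted mean of per-field similarities (names
by Dice; birth date, sex and municipality by exact agreement), renormalized
over the fields present in both records. Comparison needs only the bit
vectors, never the plaintext names.

**TF-IDF retrieval.** The right-hand registry is indexed by word tokens
(mother-name tokens prefixed, one token per categorical attribute); a probe is
scored against candidates by the cosine of L2-normalized vectors with weights

    w(t) = (1 + ln tf(t)) · ln(1 + N / df(t)).

Queries run in one of three modes — exact agreement on all attributes the
probe carries, exact birth-date+municipality with names ranked by TF-IDF, or
fully fuzzy over shared postings — and a schedule falls through from the
strictest mode to the loosest.

**Calibration.** Candidate pairs are sampled (default n = 2000, optionally
stratified by score decile), labeled (by the gold standard in simulation, by
reviewers via a CSV round-trip in real use), and swept over a cut-off grid.
The final cut-off maximizes Youden J = sensitivity + specificity − 1; the ROC
AUC is reported by the trapezoidal rule.

## Worked example

```python
from vinculo import (
    CorruptionConfig, generate_population, derive_linked_registry,
    clean_registry, deduplicate, BloomParams, build_blocks, default_predicates,
    score_candidates, classify, make_review_sample, cutoff_report,
)

base = generate_population(1000, seed=7, id_prefix="L")
derived, gold = derive_linked_registry(base, 0.5, CorruptionConfig.benchmark(seed=8))
left, _ = deduplicate(clean_registry(base))
right, _ = deduplicate(clean_registry(derived))

candidates = build_blocks(left, right, default_predicates())
scored = score_candidates(left, right, candidates, BloomParams())
sample = make_review_sample(scored, gold, n=2000, seed=9)
report = cutoff_report(sample)
result = classify(scored, report.selected_cutoff)
```

prints, with the summary lines shown in the source:

```
candidate pairs: 39079
review sample:   2000 pairs, AUC 0.999
selected cutoff: 0.57
links: 596  true-positive rate: 100.0%  precision: 83.9%
```

Read: blocking reduced 1000×1000 comparisons to 39,079 candidate pairs; the
calibrated cut-off 0.57 recovers all 500 true pairs (true-positive rate 100%)
at the cost of 96 false links (precision 83.9%) — at this small scale the
Youden criterion favors sensitivity; the score-sorted pair list and the
cut-off report let you choose a stricter operating point.

The same pipeline is available from the shell:

```sh
vinculo generate --n 1000 --seed 7 --out data/
vinculo link config.yaml
vinculo benchmark --linker bloom --seed 42
```

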