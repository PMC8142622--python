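# Methods

## Problem setting

Cohorts built from administrative data link a population base registry (each
person carrying a unique social identification number, NIS) to health
registries that share no key with it. Where a key exists, linkage is
deterministic; where it does not, it relies on quasi-identifiers common to
both sides: full name, sex, mother's name, date of birth, municipality code.
`vinculo` implements both regimes plus the machinery around them —
preprocessing, blocking, scoring, cut-off calibration — and a synthetic-data
generator that stands in for the confidential registries.

## Synthetic registries

`generate_population` composes names as *given name + 0–2 particles + 1–2
surnames* from bundled pools of common Brazilian given names and surnames
(with accents and mixed case, so the normalizer is genuinely exercised), and
draws municipality codes from a bundled list of ~100 IBGE-style 7-digit
codes. Mothers share their child's final surname 75% of the time, which
reproduces the surname clustering that makes real registries hard to
discriminate. Dates are emitted as DD/MM/YYYY text to force the date
standardizer to run; every record gets a unique 11-digit NIS.

`derive_linked_registry` copies a known fraction of the base into a second
registry under a configurable error model and records exactly the copied
pairs as the gold standard — bookkeeping, never re-matching. The error model
(`CorruptionConfig`) applies, independently per record and field:

| knob | meaning | benchmark value |
| --- | --- | --- |
| `field_probability` | chance of 1..`max_edits_per_field` single-character edits (substitute/delete/insert/transpose) | 0.2 on full_name, mother_name, municipality_code |
| `accent_loss_probability` | accents stripped from name fields | 0.2 |
| `date_digit_swap_probability` | two adjacent differing digits of the date transposed | 0.2 |
| `missingness` | field blanked | 0.05 on mother_name, birth_date, municipality_code |

Edits are guaranteed to change the raw string whenever a changing edit
exists, so configured rates are observable as binomial counts. Accent loss is
deliberately neutralized by preprocessing — it exists to prove the cleaner
handles it. Municipality edits are restricted to substitutions and
transpositions, the keying errors numeric codes actually suffer.

What the generator does **not** model: household structure beyond
mother–child, nickname/abbreviation variation, realistic demographic
marginals, correlated errors between fields, and duplicate registrations
within one registry. Passing benchmarks here therefore demonstrate the
machinery under a declared, plausible error model — not performance on any
real registry, whose error structure is unknown.

`generate_birth_scenario` emits birth records carrying the mother's name and
municipality plus the child's own birth date and sex; a configurable fraction
of children are unnamed, as newborns may not yet have a registered name.

## Preprocessing

Names are uppercased, accent-folded (NFKD strip), cleared of punctuation and
digits, and whitespace-collapsed; linking particles (DA, DE, DO, DAS, DOS, E)
are retained by default because they contribute bigrams that carry signal,
with `strip_particles` available as a switch. Dates parse under a dialect
declared per file (DMY or ISO) — never sniffed, because silently misparsed
dates are the worst linkage failure mode; impossible dates become missing
values with an `invalid_date` flag rather than errors. Municipality codes
must be exactly 7 digits and NIS exactly 11; violations are cleared and
flagged. Deduplication is exact on the full linkage key, keeping the first
record in stable input order.

## Bloom-filter linkage

Blocking unions the within-block cross pairs of three predicates:
municipality code, birth year, and first-two-letters-of-name + sex. A record
missing a predicate's input gets no label from it (no catch-all block). An
empty predicate list is rejected rather than silently comparing all pairs.

Each name field is encoded as a Bloom filter over padded bigrams: *k* bits
per bigram via double hashing, `index_i = (h1 + i·h2) mod m`, with the two
base hashes taken from a keyed BLAKE2b digest salted per field (so the same
value in different fields sets different bits). Defaults *m* = 128, *k* = 3
follow common privacy-preserving record-linkage practice: ~20 distinct
bigrams per name field set ≤ 60 of 128 bits, keeping the filter below half
full so Dice similarity retains discrimination.

Per-field scores are Dice coefficients for the two name fields and 0/1 exact
agreement for birth date, sex and municipality. The composite is a weighted
mean with weights renormalized over the fields present in both records;
defaults favor names — full_name 0.40, mother_name 0.25, birth_date 0.15,
municipality 0.15, sex 0.05 — because bigram similarity degrades gracefully
under typos while categorical indicators fail hard under digit errors.
Classification thresholds the composite, then resolves one-to-one greedily in
descending score order (ties broken lexicographically by record ids, as are
all ties in the package, for bit-for-bit reproducibility).

## TF-IDF inverted-index linkage

Records tokenize to name words (mother-name words prefixed `M:` to keep the
fields distinct) plus one token each for birth date, sex and municipality.
Token weights are `(1 + ln tf) · ln(1 + N/df)` — the `1 +` inside the
logarithm keeps corpus-wide tokens at a small positive weight instead of
zero — and scores are cosines of L2-normalized vectors, so identical token
multisets score exactly 1. Probe tokens absent from the index drop out of the
probe vector.

Three query modes, from strictest to loosest:

- **exact** — candidates agreeing on every attribute the probe carries
  (candidate missing such an attribute does not agree); returned at score 1.
- **semi-exact** — candidates agreeing exactly on birth date and municipality
  code, ranked by TF-IDF over name tokens only. A block member sharing *no*
  name token is a coincidence of date and municipality, not a result; such
  rank-zero hits are dropped so the schedule can fall through.
- **fuzzy** — candidates sharing at least one token, gathered through the
  postings and ranked by TF-IDF over all tokens.

All modes drop hits below the query cut-off and keep the top `top_n`
(default 10). Registry linkage probes each left record through the schedule
(default `[exact, semi_exact, fuzzy]`), stopping at the first mode with any
surviving hit and keeping its best candidate; one-to-one resolution is the
same greedy pass as the Bloom linker. Because sub-cut-off hits are dropped
*inside* each query, calibration uses an uncensored gathering pass (cut-off
0) to observe the full score distribution, and the production pass re-runs
the schedule with the calibrated cut-off active — a mode whose hits all fall
below the cut-off then falls through instead of blocking the schedule.

## Deterministic and two-stage linkage

`link_by_key` joins on exact key agreement, pairing only keys unique on both
sides. A key occurring more than once on either side is reported as
ambiguous and produces no pairs: a "unique" identifier that repeats is a
data-quality event to surface, not to resolve silently.

`link_births_two_stage` first links each birth record's mother attributes
(her name and the municipality — the attributes a birth record actually
carries) probabilistically to the target registry, using either linker.
Stage 1 is deliberately many-to-one: several births may share one mother, so
each probe independently keeps its best target at or above the stage-1
cut-off (default 0.8). Stage 2 attaches the child deterministically through
the linked target identifier plus the child's birth date and sex — never the
child's name, so unnamed newborns are linkable. Same-mother children
indistinguishable on (birth date, sex) — twins of the same sex — are reported
ambiguous and left unlinked.

## Calibration

A review sample (default n = 2000) is drawn without replacement, either
uniformly or stratified equally across score deciles (thin deciles donate
unmet quota to a uniform draw from the remainder); labels come from the gold
standard in simulation or from a labeling CSV round-trip in real use.
Sensitivity and specificity are computed on a grid of 101 equally spaced
cut-offs; zero-denominator ratios are reported as missing, never as zero.
The ROC over the grid, augmented with (0,0) and (1,1), gives the AUC by the
trapezoidal rule; the selected cut-off maximizes Youden J (smallest grid
point on ties), with distance-to-(0,1) available as an alternative
criterion. Selection is invariant to grid ordering and duplicated points.

## Benchmark conditions and problem sizes

The declared benchmark (`vinculo.benchmark`) uses two registries of 5,000
records with 2,500 true shared individuals and the corruption profile in the
table above; the review sample is score-stratified with n = 2000. Unit and
property tests run on 200–400-record registries, large enough to populate
every block and score stratum while keeping the full suite fast. The
acceptance script reports the true-positive rate — the fraction of gold
pairs present in the final one-to-one linked set — in percent, after
calibrated classification.

## Pipeline, provenance and extraction

`run_pipeline` executes preprocess → link → calibrate → classify from a
single config (YAML or dict; unknown keys rejected before any computation)
and writes linked pairs, the cut-off report, preprocessing reports, a
JSON-lines log with per-stage record counts, and a provenance sidecar echoing
every parameter and the package version — a run directory is
self-describing. Extraction replaces record ids with keyed BLAKE2b hashes
(deterministic per salt, so tables remain joinable; no reversible key
management needed), refuses to pass identifying fields (names, NIS) through,
and supports aggregation rules such as birth date → year.

## Known limitations

- Within-registry deduplication is exact-key only; probabilistic dedup is out
  of scope.
- The fuzzy mode gathers candidates by whole-word postings; a single edit
  removes that word's token entirely, and a corrupted birth date removes a
  high-IDF token, so heavily corrupted records lean on the remaining tokens.
  Character-bigram tokenization would soften this and is a natural extension.
- Greedy one-to-one resolution is order-optimal per score but not globally
  optimal (no assignment-problem solve).
- Bloom encodings here are not hardened against cryptanalytic
  re-identification attacks; they provide encoding, not provable privacy.
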