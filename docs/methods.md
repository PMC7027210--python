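# Methods

## The classification model

The health classifier is a dictionary matcher, not a statistical model.
Its single modelling assumption is the *first-mention hypothesis*: the
primary disease focus of a grant is the disease mentioned closest to the
beginning of the title or, failing a title mention, the abstract. Under
that assumption the correct decision rule is: take the synonym occurrence
with the minimal start offset in the title; consult the abstract only when
the title has no occurrence; assign the single disease behind that synonym.
The rule is deliberately not multi-label — a grant genuinely spanning two
diseases is labelled with the first-mentioned one, and that failure mode is
quantified by the sensitivity audit rather than patched in the matcher.

### Normalisation

The field being scanned and every lexicon synonym pass through the same
normalisation: Unicode NFKD with combining marks stripped, case-folding,
dash variants folded to ASCII hyphen, every other punctuation character
replaced by a space, hyphens kept only between two alphanumerics, and
whitespace runs collapsed. Offsets are 0-based character indices into this
normalised text; "closer to the beginning" is therefore measured in
characters. Normalisation is idempotent, so offsets are well defined.

### Matching and tie-breaks

A match must respect word boundaries: it may not be flanked by a letter or
digit on either side. This blocks substring false positives ("flu" inside
"fluid") at the cost of agglutinated mentions, which for grant prose is
the right trade. Hyphens do not block a boundary ("flu-like" matches
"flu"). Ties at one offset are broken by longest synonym — preferring the
more specific "breast cancer" over "cancer" — then lexicographically, so
classification is a total, deterministic function of (text, lexicon).

The compiled index is a single regular-expression alternation whose
branch order encodes the tie-break (longest, then lexicographic), wrapped
in boundary lookarounds; leftmost-first alternation semantics then yield
exactly the documented rule. The test suite never trusts this: it checks
exact agreement with two independent brute-force matchers (a
find()-based scan over all synonyms and occurrences, and a fully naive
every-synonym-at-every-offset scan) on thousands of random instances.

An absent abstract is an empty abstract: the search trivially fails and
the grant is reported unclassified, never dropped.

### Grant types

Type assignment reuses the same scanning discipline over a separate,
much smaller synonym list for five types: core institutional funding,
training, capacity strengthening, meetings, networking. Research carries
no synonyms and is assigned exactly when nothing matches; consequently an
empty type lexicon classifies 100% of grants as research. When two type
synonyms of equal length tie at one offset, a fixed priority
(core_funding > training > capacity_strengthening > meetings > networking)
decides. Health and type passes are independent: a training grant can
still carry a disease label, because portfolio tables report the two
dimensions separately. The shipped type-synonym list is a reconstruction
from the category names and their canonical examples (postgraduate
degrees, fellowships, prizes, conferences); real deployments should
extend it iteratively the way any such list is built — snowballing over
observed titles until no new synonyms appear.

## Geography and income

Regions come from a country-metadata table using the closed six-value WHO
regional grouping; lookups canonicalise (trim, collapse whitespace,
case-fold) but never fuzzy-match, so a misspelt country is an explicit
"unspecified" with a log entry, not a guess. Income groups use the World
Bank classification when the country is listed. For unlisted territories
the fallback places a per-capita income figure into one of the four groups
by three ascending thresholds; the shipped defaults (1025 / 4035 / 12475
currency units) are the FY2016/17 Atlas boundaries and are configuration
(YAML key `income_cutoffs`, CLI `--cutoffs`), not constants. The Atlas
thresholds are defined on GNI per capita while a desk search typically
yields GDP per capita; the fallback treats the supplied figure
generically, and that approximation is acceptable precisely because it
only ever touches the ~2% of records in unlisted territories.

## Analytics conventions

- **Denominator policy is explicit.** Category tables are conventionally
  quoted out of classified grants; cross-cutting flags (neglected tropical
  diseases, blueprint pathogens) out of all grants. Every
  `DistributionTable` records which policy produced it and reports the
  unclassified count alongside, so `Σcounts = denominator` is a checkable
  invariant for full partitions.
- **Rounding is half-up**, computed in exact decimal arithmetic on the
  integer ratio, because that is the convention that reproduces
  hand-computed report tables; banker's rounding does not.
- **Durations** are measured in days and converted at 30.4375 days/month
  (365.25/12), because month arithmetic across calendars is ill-defined.
  Display splits months_total into years and half-up-rounded months,
  carrying a rounded 12 into the next year.
- **The collaboration cross-tab** counts each collaboration record once in
  its (recipient group, collaborator group) cell and each direct grant
  once in its recipient group's direct count, however many collaborations
  it spawned. Row marginals therefore equal per-group collaboration
  totals — an invariant the tests assert. Unresolved collaborations
  (direct-grant id not in the grants table) are excluded from the
  cross-tab and counted, mirroring the reality that funders cannot always
  account for all collaborations.

## The sensitivity-audit protocol

Sampling weights the audit by funder contribution: with `n_f` grants from
funder `f` out of `N` in total and a target of `base_n` records, each
funder's stratum is `ceil(base_n · n_f / N)` — the ceiling guarantees
every contributing funder at least one record, at the price of a realised
total slightly above target (107 for a target of 100 over the ten 2016
funders). Ceilings exceeding a tiny funder's stock are capped at the
stock, and the cap is reported. Strata are drawn by seeded simple random
sampling without replacement over grant-id-sorted strata, so a draw is
reproducible bit-for-bit.

Reviewer coding is consumed post-consensus (the human adjudication
process is data, not code). Each record says whether the grant was
classified, whether the label was accurate (only when classified), which
field produced it, and — for misclassified or unclassified records — one
failure reason from a closed list: unspecific/technical language, general
topic with no disease, new synonym discovered, disease not first
mentioned, multiple diseases, or abstract unavailable. The summary quotes
classification out of the whole sample, accuracy out of classified
records, per-field accuracy out of each field's records, and reason
shares out of the pooled misclassified-or-unclassified records; its
internal identities (classified = title + abstract counts; pool =
unclassified + inaccurate; reasons sum to pool) are validated.

## The synthetic-data generator

The generator emulates a World RePORT-style export at the 2016 study
conditions, which are its defaults: funder weights proportional to the
observed per-funder grant counts (NIH 52,928 … EDCTP 21); per-funder mean
durations from the observed averages (NIH 82 months … Institut Pasteur 18)
with a 9-month normal spread, floored at 6 months; the four-way category
mixture proportional to 40,035/11,123/3,056/1,127; income groups
proportional to 68,660/309/285/165/1 (the single "unspecified" record is a
synthetic unlisted territory); a 10% collaboration rate with 1–6 partners
per collaborating grant (mean ≈ 2.8) and same-income-group preference
(strength 0.6, high-income pull otherwise) mirroring observed collaboration
homophily; and a type mixture of research .704, training .187, meetings
.042, with the remaining 6.7% split .030/.020/.017 over capacity
strengthening, core funding and networking as a realistic completion of
the three minor types. `p_abstract = 0.8` and `p_title_mention = 0.5`
reflect that roughly half of classified grants are classified from the
abstract and that abstracts are sometimes unavailable; the unclassifiable
rate defaults to 0.2, the complement of the observed 81% classification
rate.

Text is templated, not prose: a filler clause, the planted disease
synonym, a filler clause, with an optional type-synonym prefix. Every
filler is screened against both lexicons at build time and each finished
grant is verified — the planted synonym must be the earliest hit in its
designated field, unclassifiable grants must contain no hit, and the type
must be recoverable — so ground truth is a checked property of the emitted
text, not an assumption. A config flag plants a second, later disease
mention to exercise the single-label rule. Generation is a pure function
of (config, seed).

What the generator does *not* emulate: real grant prose (no misspellings,
no ambiguous phrasing, no agglutinated disease mentions), lexicon
incompleteness (the planted synonym is by construction in the lexicon),
and reviewer disagreement. Perfect recovery on synthetic corpora therefore
validates the matching and bookkeeping machinery — that the implementation
computes the first-match rule exactly — not the real-world accuracy of the
first-mention hypothesis, which only a human audit of real grants (the
sensitivity protocol above) can measure.

## Problem sizes

The test suite and the acceptance script run the oracle-equivalence check
on randomly sized instances up to 200 grants × 100 synonyms (1000
instances in the suite, 300 in the script) and the recovery benchmarks on
5000-grant corpora; these sizes give the binomial checks ±3σ bands of
about ±0.017 on a rate of 0.2 while keeping a full run in well under a
minute on one core.

## Known limitations

- Word-boundary matching misses agglutinated mentions; it is toggled off
  only by editing the lexicon (add the agglutinated form as a synonym),
  which is the maintained-list workflow the method presumes.
- The demonstration lexicon (~60 synonyms, every category and subcategory
  represented, NTD and blueprint exemplars) is illustrative; portfolio
  shares computed with it on real data would be meaningless. The schema
  accepts a full list in flat CSV or nested JSON.
- Funding amounts are out of scope; the analytics count grants.
- The bundled country table is a small extract sufficient for the
  generator and examples, not a complete classification.
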