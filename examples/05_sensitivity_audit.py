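"""The funder-weighted accuracy audit, end to end.

First the sampling design: a target sample of 100 records allocated over
the ten 2016 funders by ceiling allocation — every funder's stratum is
its exact proportional share rounded up, so even the smallest funder
contributes one record and the realised total is 107. Then the audit
arithmetic on the published reviewer tallies: percentage classified,
accuracy overall and per source field, and failure-reason shares over
the pooled misclassified-or-unclassified records.
"""

from grantminer import accuracy_summary, allocate_sample, reviews_from_tallies
from grantminer.synthetic import FUNDER_GRANT_COUNTS

alloc = allocate_sample(FUNDER_GRANT_COUNTS, base_n=100)
print("Per-funder sample sizes (ceiling allocation over 69,420 grants):")
for funder, size in alloc.per_funder.items():
    print(f"  {funder:<16} {FUNDER_GRANT_COUNTS[funder]:>6} grants -> {size:>2} sampled")
print(f"  realised total: {alloc.total} (target {alloc.base_n})")

reviews = reviews_from_tallies(
    n_total=107,
    title_reviewed=43,
    title_accurate=42,
    abstract_reviewed=44,
    abstract_accurate=37,
    reason_tallies={
        "unspecific_technical_language": 11,
        "general_topic_no_disease": 7,
        "new_synonym_discovered": 9,
        "disease_not_first_mentioned": 1,
    },
)
s = accuracy_summary(reviews)
print(f"\nClassified: {s.n_classified}/{s.n_total} = {s.pct_classified:.0f}%")
print(f"Accurate (of classified): {s.n_accurate}/{s.n_classified} = {s.pct_accurate:.0f}%")
print(f"  via title:    {s.title_accurate}/{s.title_reviewed} = {s.pct_title:.0f}%")
print(f"  via abstract: {s.abstract_accurate}/{s.abstract_reviewed} = {s.pct_abstract:.0f}%")
print(f"Failure reasons over the {s.pool_size} misclassified/unclassified records:")
for reason, pct in s.reason_pcts.items():
    print(f"  {reason:<32} {s.reason_counts[reason]:>2} ({pct:.0f}%)")
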