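"""Assign grant types with research as the fallback.

Grant types (core funding, training, capacity strengthening, meetings,
networking) are matched from their own synonym list under the same
earliest-occurrence rule as the disease classifier; anything that
matches nothing is research — the type defined by exclusion.
"""

from grantminer import GrantRecord, classify_types_corpus, resources

grants = [
    GrantRecord(grant_id="T1", funder="EC", title="International conference on antimicrobial resistance"),
    GrantRecord(grant_id="T2", funder="MRC", title="PhD studentship in computational neuroscience"),
    GrantRecord(grant_id="T3", funder="NIH", title="Molecular mechanisms of synaptic plasticity"),
    GrantRecord(grant_id="T4", funder="Wellcome Trust", title="Early career award: imaging tumour metabolism"),
]

types = classify_types_corpus(grants, resources.demo_type_lexicon())
print(types.to_string(index=False))
print()
print("T3 matched no type synonym, so it is research by fallback —")
print("exactly one type per grant, always.")
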