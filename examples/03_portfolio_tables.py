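"""Portfolio tables: category distribution, top recipients, duration.

Generates a synthetic 2000-grant corpus mirroring the 2016 ten-funder
portfolio, classifies it, and prints the three staple portfolio tables.
Note the two denominators: category shares are quoted out of classified
grants, while the corpus-wide share of any one key uses all grants.
"""

from grantminer import (
    SynthConfig,
    average_duration,
    classify_corpus,
    distribution,
    generate_corpus,
    resources,
    top_recipients,
)

corpus = generate_corpus(SynthConfig(n_grants=2000, seed=42))
labels = classify_corpus(corpus.grants, resources.demo_lexicon())

table = distribution(labels, "category", policy="classified_grants")
print(f"Health categories (denominator = {table.denominator} classified grants,")
print(f"{table.n_unclassified} unclassified reported separately):")
print(table.as_frame().to_string(index=False))

print("\nTop 5 recipient countries (ties alphabetical), with each country's")
print("most frequent recipient institution:")
print(top_recipients(corpus.grants, "country", 5).to_string(index=False))

duration = average_duration(corpus.grants)
print(f"\nAverage grant duration: {duration.display}")
print("(mean of per-grant day counts, converted at 30.4375 days/month)")
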