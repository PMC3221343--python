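"""Reproduce the full five-product evidence profile from the packaged spec.

Runs the whole pipeline — generate, merge per product, classify, bin by
currency, match across products — and prints the four indicators.
"""

import evicite as ev

spec = ev.study_fixture(seed=1)
merged = ev.combine_corpora(ev.generate_corpora(spec))
classified = [c for corpus in merged for c in ev.classify_corpus(corpus)]

print("== Citation distribution ==")
shares = ev.distribution_by_product_topic(classified).counts.sum(axis=1)
grand = shares.sum()
for product, n in shares.items():
    print(f"  {product:18s} {n:5d}  ({100 * n / grand:.1f}%)")

print("\n== Evidence types (percent of each product's citations) ==")
print(ev.publication_type_table(classified).percents().to_string())

print("\n== Currency (percent of dated citations per product) ==")
print(ev.currency_table(classified).percents().to_string())

print("\n== Overlap across the five products ==")
dist = ev.overlap_distribution(ev.match_citations(merged), n_products=5)
print(ev.overlap_summary(dist).to_string(index=False))

n_syn, n_rev, pct = ev.synopsis_audit(classified)
print(f"\nsynopsis sources among reviews: {n_syn}/{n_rev} ({pct}%)")
print(
    f"\nReading: of {grand} citation instances, {dist.total_distinct} are"
    "\ndistinct; the product with the fewest citations has the highest share"
    "\nof systematic reviews + randomized trials, and overlap between"
    "\nproducts is minimal (>90% of citations appear in a single product)."
)
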