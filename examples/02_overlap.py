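"""Measure citation overlap between two simulated products.

Generates two product corpora that share a controlled number of citations,
clusters all records, and prints the overlap-multiplicity distribution under
both percentage conventions.
"""

import evicite as ev

spec = ev.CorpusSpec(
    products=["ProductA", "ProductB"],
    topics=["asthma"],
    category_counts={
        "ProductA": {"randomized_controlled_trial": 12, "review": 8},
        "ProductB": {"randomized_controlled_trial": 10, "review": 5},
    },
    year_bin_counts={
        "ProductA": {"pre_2001": 10, "2004_2006": 10},
        "ProductB": {"pre_2001": 8, "2004_2006": 7},
    },
    overlap_multiplicities={2: 6, 1: 23},  # 6 citations shared, 23 unique
    pmid_less_fraction=0.2,
    seed=42,
)

merged = ev.combine_corpora(ev.generate_corpora(spec))
clusters = ev.match_citations(merged, ev.MatchConfig(fuzzy_enabled=True))
dist = ev.overlap_distribution(clusters, n_products=2)

print(f"instances: {dist.total_instances}, distinct citations: {dist.total_distinct}")
print(ev.overlap_summary(dist).to_string(index=False))
print(
    "\npct_of_distinct divides by distinct citations (the 'unique' convention);"
    "\npct_of_instances divides by the total citation pool. The 6 shared"
    "\ncitations are recovered even though a fifth of records carry no PMID:"
    "\ncontent keys and fuzzy title matching close the gap."
)
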