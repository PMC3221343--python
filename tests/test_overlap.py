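"""Citation matching across products and the overlap distribution."""

import random
from difflib import SequenceMatcher

import pytest

import evicite as ev
from evicite._text import normalize_text

from conftest import make_record


def brute_force_clusters(records, config):
    """Independent oracle: exhaustive pairwise matching + transitive closure
    by repeated set merging (no union-find, no blocking)."""

    def pair_match(a, b):
        if ev.make_key(a) == ev.make_key(b):
            return True
        if not config.fuzzy_enabled or not a.title or not b.title:
            return False
        if config.require_year_match:
            if a.year is None or b.year is None:
                if not (a.year is None and b.year is None):
                    return False
            elif abs(a.year - b.year) > config.year_tolerance:
                return False
        ratio = SequenceMatcher(
            None, normalize_text(a.title), normalize_text(b.title), autojunk=False
        ).ratio()
        return ratio >= config.title_similarity_threshold

    groups = [{i} for i in range(len(records))]
    changed = True
    while changed:
        changed = False
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                if any(
                    pair_match(records[i], records[j])
                    for i in groups[gi]
                    for j in groups[gj]
                ):
                    groups[gi] |= groups[gj]
                    del groups[gj]
                    changed = True
                    break
            if changed:
                break
    return {frozenset(g) for g in groups}


def as_index_sets(clusters, records):
    pos = {id(r): i for i, r in enumerate(records)}
    return {frozenset(pos[id(r)] for r in cluster) for cluster in clusters}


class TestMakeKey:
    def test_pmid_identity(self):
        a, b = make_record(pmid="999"), make_record(pmid="999", title="Other title.")
        assert ev.make_key(a) == ev.make_key(b)

    def test_trailing_period_normalized_away(self):
        a = make_record(pmid=None, title="Airway responses to ozone.")
        b = make_record(pmid=None, title="Airway responses to ozone")
        assert ev.make_key(a) == ev.make_key(b)

    def test_different_years_differ(self):
        a = make_record(pmid=None, year=2003)
        b = make_record(pmid=None, year=2004)
        assert ev.make_key(a) != ev.make_key(b)


def corpus_of(product, records):
    for r in records:
        r.product = product
    return ev.Corpus(product=product, topic="asthma", records=records)


class TestMatchCitations:
    def test_shared_pmid_spans_all_products(self):
        corpora = [
            corpus_of(f"P{i}", [make_record(pmid="42", local_id="PMID:42")])
            for i in range(5)
        ]
        clusters = ev.match_citations(corpora)
        assert len(clusters) == 1
        assert len({r.product for r in clusters[0]}) == 5

    def test_disjoint_pmids_all_unique(self):
        corpora = [
            corpus_of(f"P{i}", [make_record(pmid=str(10 * i + j)) for j in range(1, 4)])
            for i in range(3)
        ]
        dist = ev.overlap_distribution(ev.match_citations(corpora), 3)
        assert dist.multiplicity_counts == {1: 9}

    def test_two_identical_corpora(self):
        def records():
            return [make_record(pmid=str(i)) for i in (1, 2, 3)]

        corpora = [corpus_of("A", records()), corpus_of("B", records())]
        dist = ev.overlap_distribution(ev.match_citations(corpora), 2)
        assert dist.multiplicity_counts == {2: 3}
        assert dist.total_distinct == 3
        assert dist.total_instances == 6

    def test_duplicate_product_labels_rejected(self):
        corpora = [corpus_of("A", [make_record()]), corpus_of("A", [make_record(pmid="2")])]
        with pytest.raises(ValueError, match="duplicate product"):
            ev.match_citations(corpora)

    def test_fuzzy_merges_near_duplicate_titles(self):
        a = make_record(pmid=None, title="Inhaled corticosteroids for persistent asthma in adults")
        b = make_record(pmid=None, title="Inhaled corticosteroids for persistent asthma in adult")
        sim = SequenceMatcher(
            None, normalize_text(a.title), normalize_text(b.title)
        ).ratio()
        assert sim >= 0.95
        corpora = [corpus_of("A", [a]), corpus_of("B", [b])]
        off = ev.match_citations(corpora, ev.MatchConfig(fuzzy_enabled=False))
        on = ev.match_citations(corpora, ev.MatchConfig(fuzzy_enabled=True))
        assert len(off) == 2
        assert len(on) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        spec = ev.random_corpus_spec(seed, mean_citations=15)
        corpora = ev.combine_corpora(ev.generate_corpora(spec))
        records = [r for c in corpora for r in c.records]
        config = ev.MatchConfig(fuzzy_enabled=True)
        impl = as_index_sets(ev.match_citations(corpora, config), records)
        oracle = brute_force_clusters(records, config)
        assert impl == oracle

    def test_threshold_monotonicity(self):
        rng = random.Random(4)
        base = "Inhaled corticosteroids for persistent asthma in adults"
        corpora = []
        for p in range(3):
            records = []
            for i in range(8):
                title = base[: len(base) - rng.randint(0, 10)] + f" cohort {p}{i}"
                records.append(make_record(pmid=None, title=title, year=2005))
            corpora.append(corpus_of(f"P{p}", records))
        counts = []
        for threshold in (0.70, 0.85, 0.95):
            cfg = ev.MatchConfig(fuzzy_enabled=True, title_similarity_threshold=threshold)
            dist = ev.overlap_distribution(ev.match_citations(corpora, cfg), 3)
            counts.append(sum(n for k, n in dist.multiplicity_counts.items() if k >= 2))
        assert counts[0] >= counts[1] >= counts[2]

    @pytest.mark.parametrize("seed", [2, 8])
    def test_corpus_order_invariance(self, seed):
        corpora = ev.combine_corpora(ev.generate_corpora(ev.random_corpus_spec(seed)))
        n = len(corpora)
        forward = ev.overlap_distribution(ev.match_citations(corpora), n)
        backward = ev.overlap_distribution(ev.match_citations(corpora[::-1]), n)
        assert forward.multiplicity_counts == backward.multiplicity_counts


class TestOverlapDistribution:
    def test_published_shape_identities(self):
        dist = ev.OverlapDistribution(
            multiplicity_counts={1: 1907, 2: 161, 3: 25, 4: 4, 5: 2},
            n_products=5,
            total_instances=2330,
            total_distinct=2099,
        )
        dist.validate()
        assert dist.weighted_instance_sum == 2330

    def test_inconsistent_counts_rejected(self):
        dist = ev.OverlapDistribution(
            multiplicity_counts={1: 5}, n_products=2, total_instances=5, total_distinct=4
        )
        with pytest.raises(ValueError):
            dist.validate()

    def test_multiplicity_beyond_products_rejected(self):
        dist = ev.OverlapDistribution(
            multiplicity_counts={3: 1}, n_products=2, total_instances=3, total_distinct=1
        )
        with pytest.raises(ValueError):
            dist.validate()


class TestOverlapSummary:
    @pytest.fixture
    def published_dist(self):
        return ev.OverlapDistribution(
            multiplicity_counts={1: 1907, 2: 161, 3: 25, 4: 4, 5: 2},
            n_products=5,
            total_instances=2330,
            total_distinct=2099,
        )

    def test_unique_percent_of_distinct(self, published_dist):
        table = ev.overlap_summary(published_dist)
        row = table[table.multiplicity == 1].iloc[0]
        assert row.pct_of_distinct == 90.9

    def test_all_products_percent_of_instances(self, published_dist):
        table = ev.overlap_summary(published_dist)
        row = table[table.multiplicity == 5].iloc[0]
        assert row.pct_of_instances == 0.09  # two decimals for the smallest cell

    def test_all_unique(self):
        dist = ev.OverlapDistribution({1: 10}, 3, 10, 10)
        table = ev.overlap_summary(dist)
        assert table.iloc[0].pct_of_distinct == 100.0

    def test_empty_distribution(self):
        dist = ev.OverlapDistribution({}, 3, 0, 0)
        assert ev.overlap_summary(dist).empty
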