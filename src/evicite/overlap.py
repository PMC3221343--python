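"""Cross-product citation matching and overlap-multiplicity distribution.

Two monographs citing the same article should be recognized as one distinct
citation. Matching is tiered:

1. **PMID-exact** — records sharing a PMID are the same citation.
2. **Content-key exact** — PMID-less records match on a normalized
   title | year | first-author key (URL for title-less web citations).
3. **Fuzzy (optional)** — pairs whose normalized titles are similar above a
   threshold, with years within tolerance, are merged. Off by default.

Clustering is the transitive closure of pairwise matches (union-find). The
multiplicity of a cluster is the number of *distinct products* citing it;
the overlap distribution counts distinct citations per multiplicity, from
which both summary conventions are computed: percent of distinct citations
(the "unique" convention) and percent of total citation instances (the
"found in all products" convention).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from difflib import SequenceMatcher

import pandas as pd

from ._text import author_surname, normalize_text, normalize_url
from .records import CitationRecord, Corpus
from .summarize import round_half_up


@dataclass(frozen=True)
class CitationKey:
    """Identity key of a citation: ``pmid`` kind or normalized ``content`` kind."""

    kind: str  # "pmid" | "content"
    value: str


@dataclass
class MatchConfig:
    """Matching behaviour. Fuzzy matching is an opt-in third tier."""

    fuzzy_enabled: bool = False
    title_similarity_threshold: float = 0.90
    require_year_match: bool = True
    year_tolerance: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.title_similarity_threshold <= 1.0):
            raise ValueError("title_similarity_threshold must lie in [0, 1]")
        if self.year_tolerance < 0:
            raise ValueError("year_tolerance must be >= 0")


def make_key(record: CitationRecord) -> CitationKey:
    """Identity key for a record: PMID when present, else a content key.

    The content key is a pure function of normalized title, year and
    first-author surname; a title-less web citation keys on its normalized
    URL, and a record with none of these keys on its own local_id (so it
    never merges with anything else).
    """
    if record.pmid:
        return CitationKey("pmid", record.pmid)
    if record.title:
        year = str(record.year) if record.year is not None else ""
        value = "|".join(
            [normalize_text(record.title), year, author_surname(record.first_author)]
        )
        return CitationKey("content", value)
    if record.url:
        return CitationKey("content", "url:" + normalize_url(record.url))
    return CitationKey("content", "local:" + record.local_id)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # deterministic: smaller root wins
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


def _years_compatible(a: int | None, b: int | None, config: MatchConfig) -> bool:
    if not config.require_year_match:
        return True
    if a is None or b is None:
        return a is None and b is None
    return abs(a - b) <= config.year_tolerance


def fuzzy_pair_match(a: CitationRecord, b: CitationRecord, config: MatchConfig) -> bool:
    """True if two records match under the fuzzy tier (titles similar, years
    compatible). Empty titles never fuzzy-match."""
    if not a.title or not b.title:
        return False
    if not _years_compatible(a.year, b.year, config):
        return False
    ta, tb = normalize_text(a.title), normalize_text(b.title)
    if not ta or not tb:
        return False
    matcher = SequenceMatcher(None, ta, tb, autojunk=False)
    threshold = config.title_similarity_threshold
    if matcher.real_quick_ratio() < threshold or matcher.quick_ratio() < threshold:
        return False
    return matcher.ratio() >= threshold


def match_citations(
    corpora: list[Corpus], config: MatchConfig | None = None
) -> list[list[CitationRecord]]:
    """Partition all records of per-product corpora into citation clusters.

    Each input corpus must carry a distinct product label (aggregate one
    corpus per product first; see
    :func:`evicite.citation_io.combine_corpora`). Returns clusters in first-
    appearance order; record order within a cluster follows input order.
    """
    config = config or MatchConfig()
    config.validate()
    products = [c.product for c in corpora]
    if len(set(products)) != len(products):
        raise ValueError(f"duplicate product labels in corpora: {products}")
    if not corpora:
        raise ValueError("at least one corpus is required")

    records: list[CitationRecord] = [rec for corpus in corpora for rec in corpus.records]
    uf = _UnionFind(len(records))

    # Tiers 1 + 2: exact key identity.
    first_seen: dict[CitationKey, int] = {}
    for i, rec in enumerate(records):
        key = make_key(rec)
        if key in first_seen:
            uf.union(first_seen[key], i)
        else:
            first_seen[key] = i

    # Tier 3: fuzzy title similarity, blocked by year for tractability.
    if config.fuzzy_enabled:
        buckets: dict[int | None, list[int]] = {}
        for i, rec in enumerate(records):
            buckets.setdefault(rec.year, []).append(i)
        bucket_years = sorted((y for y in buckets if y is not None))
        pairs_of_buckets: list[tuple[list[int], list[int]]] = []
        if config.require_year_match:
            for yi, ya in enumerate(bucket_years):
                for yb in bucket_years[yi:]:
                    if yb - ya > config.year_tolerance:
                        break
                    pairs_of_buckets.append((buckets[ya], buckets[yb]))
            if None in buckets:
                pairs_of_buckets.append((buckets[None], buckets[None]))
        else:
            everything = list(range(len(records)))
            pairs_of_buckets.append((everything, everything))
        for left, right in pairs_of_buckets:
            same = left is right
            for ai, i in enumerate(left):
                js = right[ai + 1 :] if same else right
                for j in js:
                    if uf.find(i) == uf.find(j):
                        continue
                    if fuzzy_pair_match(records[i], records[j], config):
                        uf.union(i, j)

    clusters: dict[int, list[CitationRecord]] = {}
    order: list[int] = []
    for i, rec in enumerate(records):
        root = uf.find(i)
        if root not in clusters:
            clusters[root] = []
            order.append(root)
        clusters[root].append(rec)
    return [clusters[root] for root in order]


@dataclass
class OverlapDistribution:
    """Counts of distinct citations by the number of products citing them.

    ``total_instances`` is the total number of record instances across all
    corpora. When no product cites the same work twice within one corpus,
    the conservation identity Σ k·n_k == total_instances holds.
    """

    multiplicity_counts: dict[int, int]
    n_products: int
    total_instances: int
    total_distinct: int

    def validate(self) -> None:
        if sum(self.multiplicity_counts.values()) != self.total_distinct:
            raise ValueError("multiplicity counts do not sum to total_distinct")
        for k in self.multiplicity_counts:
            if not (1 <= k <= self.n_products):
                raise ValueError(f"multiplicity {k} outside [1, {self.n_products}]")

    @property
    def weighted_instance_sum(self) -> int:
        """Σ k·n_k — equals total_instances absent within-product duplicates."""
        return sum(k * n for k, n in self.multiplicity_counts.items())


def overlap_distribution(
    clusters: list[list[CitationRecord]], n_products: int
) -> OverlapDistribution:
    """Tally clusters by the number of distinct products represented."""
    counts: Counter[int] = Counter()
    total_instances = 0
    for cluster in clusters:
        total_instances += len(cluster)
        counts[len({rec.product for rec in cluster})] += 1
    dist = OverlapDistribution(
        multiplicity_counts=dict(sorted(counts.items())),
        n_products=n_products,
        total_instances=total_instances,
        total_distinct=len(clusters),
    )
    dist.validate()
    return dist


def overlap_summary(dist: OverlapDistribution) -> pd.DataFrame:
    """Summary table of the overlap distribution, both denominators labeled.

    ``pct_of_distinct`` divides by the number of distinct citations (the
    convention behind "X% of citations were unique"); ``pct_of_instances``
    divides by the total citation pool (the convention behind "found in all
    products"). One-decimal rounding, except the all-products row of
    ``pct_of_instances`` at two decimals, matching the precision such small
    proportions need.
    """
    if dist.total_distinct == 0:
        return pd.DataFrame(
            columns=["multiplicity", "n_citations", "pct_of_distinct", "pct_of_instances"]
        )
    rows = []
    for k in sorted(dist.multiplicity_counts, reverse=True):
        n = dist.multiplicity_counts[k]
        pct_distinct = round_half_up(100.0 * n / dist.total_distinct, 1)
        decimals = 2 if k == dist.n_products else 1
        pct_instances = round_half_up(100.0 * n / dist.total_instances, decimals)
        rows.append(
            {
                "multiplicity": k,
                "n_citations": n,
                "pct_of_distinct": pct_distinct,
                "pct_of_instances": pct_instances,
            }
        )
    return pd.DataFrame(rows)
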