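"""Core record and corpus containers.

A :class:`CitationRecord` is one bibliographic reference retrieved from a
point-of-care (POC) product monograph, carrying the MEDLINE indexing metadata
(publication types, MeSH terms) used downstream to grade the type of evidence,
plus provenance: which product and which disease topic cited it.

A :class:`Corpus` is the ordered reference list for one (product, topic) pair.
The reserved topic label :data:`ALL_TOPICS` marks a corpus aggregated across
topics of a single product (see :func:`evicite.citation_io.combine_corpora`).
"""

from __future__ import annotations

import datetime
import re
from dataclasses import dataclass, field

#: Reserved aggregate topic label for per-product corpora merged across topics.
ALL_TOPICS = "all"

_PMID_RE = re.compile(r"^\d{1,8}$")


def _year_ceiling() -> int:
    return datetime.date.today().year + 1


@dataclass
class CitationRecord:
    """One citation with indexing metadata and provenance.

    ``verified`` mirrors the data-collection step of confirming citation
    details: a record is considered verified when it has a title and either a
    publication year or a PMID. Web citations that could not be confirmed
    stay unverified and are later graded ``unknown``.
    """

    local_id: str
    product: str
    topic: str
    title: str = ""
    first_author: str = ""
    source: str = ""
    year: int | None = None
    pmid: str | None = None
    pub_types: list[str] = field(default_factory=list)
    mesh_terms: list[str] = field(default_factory=list)
    abstract: str | None = None
    url: str | None = None
    verified: bool = True

    def validate(self) -> None:
        if not self.local_id:
            raise ValueError("local_id must be non-empty")
        if not self.product or not self.topic:
            raise ValueError("product and topic labels must be non-empty")
        if self.pmid is not None and not _PMID_RE.match(self.pmid):
            raise ValueError(f"pmid must be 1-8 decimal digits, got {self.pmid!r}")
        if self.year is not None and not (1800 <= self.year <= _year_ceiling()):
            raise ValueError(f"year {self.year} outside [1800, current year + 1]")


@dataclass
class Corpus:
    """Ordered reference list of one product/topic monograph."""

    product: str
    topic: str
    records: list[CitationRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def validate(self) -> None:
        if not self.product or not self.topic:
            raise ValueError("corpus product and topic labels must be non-empty")
        seen: set[tuple[str, str]] = set()
        for rec in self.records:
            rec.validate()
            if rec.product != self.product:
                raise ValueError(
                    f"record {rec.local_id} product {rec.product!r} != corpus {self.product!r}"
                )
            if self.topic != ALL_TOPICS and rec.topic != self.topic:
                raise ValueError(
                    f"record {rec.local_id} topic {rec.topic!r} != corpus {self.topic!r}"
                )
            # In an aggregate corpus the same citation may recur under
            # different topics; within one monograph local_id is unique.
            key = (rec.local_id, rec.topic if self.topic == ALL_TOPICS else "")
            if key in seen:
                raise ValueError(f"duplicate local_id {rec.local_id!r} in corpus")
            seen.add(key)
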