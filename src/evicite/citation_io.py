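"""Reading, writing and identifying citation records.

Two flat bibliographic formats are supported:

* **MEDLINE/nbib** — the PubMed export format of ``TAG - value`` lines
  (``PMID``, ``TI``, ``AU``, ``SO``, ``DP``, ``PT``, ``MH``, ``AB``), with
  continuation lines indented by whitespace. Two dialect tags extend it so a
  corpus round-trips exactly: ``UR`` carries a URL and ``VF`` (Y/N) carries
  the verification flag.
* **RIS** — ``TY``-to-``ER`` records. RIS has no MEDLINE publication-type
  vocabulary, so ``TY`` values are mapped through :data:`RIS_TYPE_MAP`;
  ``KW`` keywords are carried as MeSH-slot terms.

Identity: records with a PMID are identified as ``PMID:<digits>``. Records
without one get a deterministic content-addressed identifier (a digest of
normalized title | year | first-author surname), so the same bibliographic
content always maps to the same identifier — the role the study's structured
identifier guide played for PMID-less citations.
"""

from __future__ import annotations

import hashlib
import logging
import re
from pathlib import Path

from ._text import author_surname, first_year, normalize_text, normalize_url
from .records import ALL_TOPICS, CitationRecord, Corpus

logger = logging.getLogger(__name__)

#: Version of the PMID-less identifier scheme; bump if the digest recipe changes.
LOCAL_ID_SCHEME = "v1"

#: RIS reference-type → MEDLINE publication-type mapping. RIS types with no
#: MEDLINE counterpart map to the closest descriptive term; an unmapped TY is
#: kept verbatim so no type string is ever invented by the reader.
RIS_TYPE_MAP: dict[str, str] = {
    "JOUR": "Journal Article",
    "ABST": "Abstract",
    "BOOK": "Book",
    "CHAP": "Book Chapter",
    "RPRT": "Technical Report",
    "GOVDOC": "Government Publication",
    "THES": "Thesis",
    "CONF": "Congress",
    "ELEC": "Electronic Resource",
    "ICOMM": "Electronic Resource",
    "NEWS": "Newspaper Article",
    "GEN": "Journal Article",
}

_NBIB_TAG = re.compile(r"^([A-Z][A-Z0-9]{1,3})\s*- (.*)$")
_RIS_TAG = re.compile(r"^([A-Z][A-Z0-9])  - ?(.*)$")
_PMID_DIGITS = re.compile(r"^\d{1,8}$")


def _digest(payload: str) -> str:
    return hashlib.sha1(payload.encode("utf-8")).hexdigest()[:16]


def assign_local_id(record: CitationRecord, ordinal: int | None = None) -> str:
    """Deterministic identifier for a record.

    PMID-bearing records pass through as ``PMID:<pmid>``. Otherwise the
    identifier is content-addressed: a digest of the normalized
    title | year | first-author surname. A record with only a URL is
    identified by the normalized URL; a record with none of these falls back
    to source + product + ordinal (and such records should carry
    ``verified=False``).
    """
    if record.pmid:
        return f"PMID:{record.pmid}"
    if record.title:
        payload = "|".join(
            [
                normalize_text(record.title),
                str(record.year) if record.year is not None else "",
                author_surname(record.first_author),
            ]
        )
        return f"LOC:{LOCAL_ID_SCHEME}:{_digest(payload)}"
    if record.url:
        return f"URL:{LOCAL_ID_SCHEME}:{_digest(normalize_url(record.url))}"
    payload = "|".join(
        [normalize_text(record.source), record.product, str(ordinal or 0)]
    )
    return f"ANON:{LOCAL_ID_SCHEME}:{_digest(payload)}"


def _default_verified(record: CitationRecord) -> bool:
    return bool(record.title and (record.year is not None or record.pmid))


def _read_text(path: str | Path) -> str:
    raw = Path(path).read_bytes()
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        logger.warning("%s is not valid UTF-8; decoding with replacement", path)
        return raw.decode("utf-8", errors="replace")


def _parse_tagged_blocks(text: str, tag_re: re.Pattern) -> list[list[tuple[str, str]]]:
    """Split tag-value flat text into blocks of (tag, value) pairs.

    Blocks are separated by blank lines; indented lines continue the previous
    value (MEDLINE wraps long fields this way).
    """
    blocks: list[list[tuple[str, str]]] = []
    current: list[tuple[str, str]] = []
    for line in text.splitlines():
        if not line.strip():
            if current:
                blocks.append(current)
                current = []
            continue
        m = tag_re.match(line)
        if m:
            current.append((m.group(1), m.group(2).strip()))
        elif current and line[:1].isspace():
            tag, value = current[-1]
            current[-1] = (tag, f"{value} {line.strip()}")
        else:
            current.append(("??", line.strip()))
    if current:
        blocks.append(current)
    return blocks


def _record_from_nbib_block(
    fields: list[tuple[str, str]], product: str, topic: str, ordinal: int
) -> CitationRecord:
    rec = CitationRecord(local_id="pending", product=product, topic=topic)
    authors: list[str] = []
    verified_tag: bool | None = None
    recognized = 0
    for tag, value in fields:
        recognized += 1
        if tag == "PMID" and _PMID_DIGITS.match(value):
            rec.pmid = value
        elif tag == "TI":
            rec.title = value
        elif tag == "AU":
            authors.append(value)
        elif tag == "SO":
            rec.source = value
        elif tag == "DP":
            rec.year = first_year(value)
        elif tag == "PT":
            rec.pub_types.append(value)
        elif tag == "MH":
            rec.mesh_terms.append(value)
        elif tag == "AB":
            rec.abstract = value
        elif tag == "UR":
            rec.url = value
        elif tag == "VF":
            verified_tag = value.upper().startswith("Y")
        else:
            recognized -= 1
    if recognized == 0:
        raise ValueError("no recognized MEDLINE tags in block")
    rec.first_author = authors[0] if authors else ""
    rec.verified = verified_tag if verified_tag is not None else _default_verified(rec)
    rec.local_id = assign_local_id(rec, ordinal=ordinal)
    if not rec.verified and rec.local_id.startswith("ANON:"):
        rec.verified = False
    return rec


def _disambiguate(corpus: Corpus, rec: CitationRecord) -> None:
    """Keep within-file duplicates (deduplication is the overlap stage's
    job) by suffixing repeated identifiers deterministically."""
    existing = {r.local_id for r in corpus.records}
    if rec.local_id in existing:
        n = 2
        while f"{rec.local_id}#{n}" in existing:
            n += 1
        rec.local_id = f"{rec.local_id}#{n}"


def read_nbib(path: str | Path, product: str, topic: str) -> Corpus:
    """Parse a MEDLINE/nbib file into a :class:`Corpus`.

    Malformed record blocks are skipped with a logged warning; the corpus
    keeps source order for the rest.
    """
    corpus = Corpus(product=product, topic=topic)
    skipped = 0
    for ordinal, fields in enumerate(_parse_tagged_blocks(_read_text(path), _NBIB_TAG)):
        try:
            rec = _record_from_nbib_block(fields, product, topic, ordinal)
            rec.validate()
            _disambiguate(corpus, rec)
            corpus.records.append(rec)
        except ValueError as exc:
            skipped += 1
            logger.warning("skipping malformed nbib block %d in %s: %s", ordinal, path, exc)
    if skipped:
        logger.warning("%s: skipped %d malformed block(s)", path, skipped)
    corpus.validate()
    return corpus


def read_ris(path: str | Path, product: str, topic: str) -> Corpus:
    """Parse a RIS file into a :class:`Corpus`.

    ``TY`` values pass through :data:`RIS_TYPE_MAP`; ``M3`` (type of work)
    values are appended verbatim as additional publication types, which lets
    RIS exports carry MEDLINE terms such as ``Randomized Controlled Trial``.
    """
    corpus = Corpus(product=product, topic=topic)
    text = _read_text(path)
    blocks: list[list[tuple[str, str]]] = []
    current: list[tuple[str, str]] = []
    for line in text.splitlines():
        m = _RIS_TAG.match(line)
        if not m:
            if line.strip() and current:
                tag, value = current[-1]
                current[-1] = (tag, f"{value} {line.strip()}")
            continue
        tag, value = m.group(1), m.group(2).strip()
        if tag == "ER":
            if current:
                blocks.append(current)
            current = []
        else:
            current.append((tag, value))
    if current:
        blocks.append(current)

    skipped = 0
    for ordinal, fields in enumerate(blocks):
        try:
            rec = _record_from_ris_block(fields, product, topic, ordinal)
            rec.validate()
            _disambiguate(corpus, rec)
            corpus.records.append(rec)
        except ValueError as exc:
            skipped += 1
            logger.warning("skipping malformed RIS record %d in %s: %s", ordinal, path, exc)
    if skipped:
        logger.warning("%s: skipped %d malformed record(s)", path, skipped)
    corpus.validate()
    return corpus


def _record_from_ris_block(
    fields: list[tuple[str, str]], product: str, topic: str, ordinal: int
) -> CitationRecord:
    rec = CitationRecord(local_id="pending", product=product, topic=topic)
    authors: list[str] = []
    for tag, value in fields:
        if tag == "TY":
            rec.pub_types.append(RIS_TYPE_MAP.get(value, value))
        elif tag in ("TI", "T1"):
            rec.title = value
        elif tag in ("AU", "A1"):
            authors.append(value)
        elif tag in ("JO", "JF", "JA", "T2"):
            rec.source = rec.source or value
        elif tag in ("PY", "Y1"):
            rec.year = first_year(value)
        elif tag in ("AB", "N2"):
            rec.abstract = value
        elif tag == "KW":
            rec.mesh_terms.append(value)
        elif tag == "UR":
            rec.url = value
        elif tag in ("AN", "ID"):
            candidate = value.removeprefix("PMID:").strip()
            if _PMID_DIGITS.match(candidate):
                rec.pmid = candidate
        elif tag == "M3":
            rec.pub_types.append(value)
    if not rec.pub_types and not rec.title and not authors:
        raise ValueError("empty RIS record")
    rec.first_author = authors[0] if authors else ""
    rec.verified = _default_verified(rec)
    rec.local_id = assign_local_id(rec, ordinal=ordinal)
    return rec


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Serialize a corpus to the nbib dialect; ``read_nbib`` round-trips it."""
    corpus.validate()
    lines: list[str] = []
    for rec in corpus.records:
        if rec.pmid:
            lines.append(f"PMID- {rec.pmid}")
        if rec.title:
            lines.append(f"TI  - {rec.title}")
        if rec.first_author:
            lines.append(f"AU  - {rec.first_author}")
        if rec.source:
            lines.append(f"SO  - {rec.source}")
        if rec.year is not None:
            lines.append(f"DP  - {rec.year}")
        for pt in rec.pub_types:
            lines.append(f"PT  - {pt}")
        for mh in rec.mesh_terms:
            lines.append(f"MH  - {mh}")
        if rec.abstract:
            lines.append(f"AB  - {rec.abstract}")
        if rec.url:
            lines.append(f"UR  - {rec.url}")
        lines.append(f"VF  - {'Y' if rec.verified else 'N'}")
        lines.append("")
    Path(path).write_text("\n".join(lines), encoding="utf-8")


def combine_corpora(corpora: list[Corpus]) -> list[Corpus]:
    """Merge per-(product, topic) corpora into one corpus per product.

    The merged corpus carries the reserved topic label ``"all"``; individual
    records keep their own topic labels, so per-topic summaries still work
    downstream. Input order decides product order and record order.
    """
    by_product: dict[str, Corpus] = {}
    for corpus in corpora:
        merged = by_product.setdefault(corpus.product, Corpus(corpus.product, ALL_TOPICS))
        merged.records.extend(corpus.records)
    out = list(by_product.values())
    for corpus in out:
        corpus.validate()
    return out
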