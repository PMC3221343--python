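"""Text normalization shared by identifier generation and citation matching."""

from __future__ import annotations

import re

_PUNCT = re.compile(r"[^\w\s]", re.UNICODE)
_WS = re.compile(r"\s+")
_YEAR = re.compile(r"\b(1[89]\d{2}|20\d{2})\b")


def normalize_text(text: str | None) -> str:
    """Lowercase, strip punctuation, collapse whitespace.

    This is the canonical normalization applied to titles, author names and
    sources before hashing or comparing them, so that trivial typographic
    variants (trailing period, double spaces, case) never split a citation
    into two identities.
    """
    if not text:
        return ""
    text = _PUNCT.sub(" ", text.lower())
    return _WS.sub(" ", text).strip()


def normalize_url(url: str | None) -> str:
    """Normalize a URL for identity purposes: lowercase scheme/host, strip
    trailing slash and a leading ``www.``."""
    if not url:
        return ""
    url = url.strip().lower()
    url = re.sub(r"^https?://", "", url)
    url = re.sub(r"^www\.", "", url)
    return url.rstrip("/")


def author_surname(author: str | None) -> str:
    """Extract a normalized surname from a ``Surname AB`` / ``Surname, A. B.``
    style author string (MEDLINE AU convention puts the surname first)."""
    if not author:
        return ""
    head = author.split(",")[0].strip()
    parts = head.split()
    return normalize_text(parts[0]) if parts else ""


def first_year(date_string: str | None) -> int | None:
    """First 4-digit year found in a free-form date string.

    MEDLINE DP fields can read ``2008 Jan-Feb`` or ``2007 Dec 15``; the first
    plausible year (1800–2099) is taken as the publication year.
    """
    if not date_string:
        return None
    m = _YEAR.search(date_string)
    return int(m.group(0)) if m else None
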