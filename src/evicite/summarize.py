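"""Indicator tables: citation distribution, currency, publication types.

Four indicators characterize the evidence behind a set of point-of-care
products: how citations are distributed across products and topics, what
types of evidence they are, how current they are, and (in
:mod:`evicite.overlap`) how much products overlap.

Every table here stores raw counts; percentages are always recomputed from
the counts with explicit denominators, never stored independently. Rounding
is half-up, to one decimal by default — which is why a percent column may
legitimately sum to 99.9 or 100.1.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum

import pandas as pd

from .classify import ClassifiedCitation, PublicationCategory


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at the given decimal precision (the
    convention of printed clinical tables, unlike banker's rounding)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class YearBin(str, Enum):
    """Currency bins: pre-2001 lumped (clinicians rarely request evidence
    more than a decade old), then 3-year bins, plus post-2009 and missing."""

    PRE_2001 = "pre_2001"
    Y2001_2003 = "2001_2003"
    Y2004_2006 = "2004_2006"
    Y2007_2009 = "2007_2009"
    POST_2009 = "post_2009"
    MISSING = "missing"


def year_bin(year: int | None) -> YearBin:
    """Map a publication year (or absence) to exactly one currency bin."""
    if year is None:
        return YearBin.MISSING
    if year <= 2000:
        return YearBin.PRE_2001
    if year <= 2003:
        return YearBin.Y2001_2003
    if year <= 2006:
        return YearBin.Y2004_2006
    if year <= 2009:
        return YearBin.Y2007_2009
    return YearBin.POST_2009


@dataclass
class DistributionTable:
    """A counts table plus the convention for deriving percents from it.

    ``counts`` is integer-valued; ``percent_denominator`` selects the
    denominator: ``"grand"`` (grand total), ``"column"`` or ``"row"``.
    Percentages are computed on demand by :meth:`percents`, never stored.
    """

    counts: pd.DataFrame
    percent_denominator: str = "grand"
    exclude_from_denominator: list[str] | None = None

    def percents(self, decimals: int = 1) -> pd.DataFrame:
        counts = self.counts
        if self.percent_denominator == "grand":
            denom = counts.to_numpy().sum()
            pct = counts / denom * 100.0 if denom else counts * 0.0
        elif self.percent_denominator == "column":
            pct = counts.div(counts.sum(axis=0).replace(0, pd.NA), axis=1) * 100.0
        elif self.percent_denominator == "row":
            base = counts
            if self.exclude_from_denominator:
                base = counts.drop(columns=self.exclude_from_denominator, errors="ignore")
            denom = base.sum(axis=1).replace(0, pd.NA)
            pct = counts.div(denom, axis=0) * 100.0
        else:
            raise ValueError(f"unknown denominator convention {self.percent_denominator!r}")
        return pct.map(lambda v: round_half_up(v, decimals) if pd.notna(v) else v)


CATEGORY_ORDER = [
    PublicationCategory.SYSTEMATIC_REVIEW,
    PublicationCategory.RANDOMIZED_CONTROLLED_TRIAL,
    PublicationCategory.PRIMARY_RESEARCH_OTHER,
    PublicationCategory.GUIDELINE,
    PublicationCategory.REPORT,
    PublicationCategory.REVIEW,
    PublicationCategory.ANIMAL_STUDY,
    PublicationCategory.OTHER,
    PublicationCategory.UNKNOWN,
]

_BIN_ORDER = [
    YearBin.PRE_2001,
    YearBin.Y2001_2003,
    YearBin.Y2004_2006,
    YearBin.Y2007_2009,
    YearBin.POST_2009,
    YearBin.MISSING,
]


def _frame(classified: list[ClassifiedCitation]) -> pd.DataFrame:
    if not classified:
        raise ValueError("no classified citations given")
    return pd.DataFrame(
        {
            "product": [c.record.product for c in classified],
            "topic": [c.record.topic for c in classified],
            "category": [c.category.value for c in classified],
            "year_bin": [year_bin(c.record.year).value for c in classified],
            "synopsis": [c.synopsis_flag for c in classified],
        }
    )


def distribution_by_product_topic(
    classified: list[ClassifiedCitation],
) -> DistributionTable:
    """Citation counts per (product, topic); percents of the grand total."""
    df = _frame(classified)
    counts = (
        df.groupby(["product", "topic"], sort=True).size().unstack(fill_value=0)
    )
    return DistributionTable(counts=counts, percent_denominator="grand")


def currency_table(
    classified: list[ClassifiedCitation], include_missing_in_denominator: bool = False
) -> DistributionTable:
    """Per-product citation counts by currency bin.

    Missing-year citations are reported in their own column but excluded
    from the percent denominators by default (they are observations missing
    from the currency analysis, not a currency).
    """
    df = _frame(classified)
    counts = df.groupby(["product", "year_bin"], sort=True).size().unstack(fill_value=0)
    for b in _BIN_ORDER:
        if b.value not in counts.columns:
            counts[b.value] = 0
    counts = counts[[b.value for b in _BIN_ORDER]]
    exclude = None if include_missing_in_denominator else [YearBin.MISSING.value]
    return DistributionTable(
        counts=counts, percent_denominator="row", exclude_from_denominator=exclude
    )


def publication_type_table(classified: list[ClassifiedCitation]) -> DistributionTable:
    """Evidence-type category counts per product, plus a Total column.

    Percents are per column (each product sums to ~100%, within rounding
    tolerance [99.0, 101.0]).
    """
    df = _frame(classified)
    counts = df.groupby(["category", "product"], sort=True).size().unstack(fill_value=0)
    counts = counts.reindex([c.value for c in CATEGORY_ORDER], fill_value=0)
    counts["Total"] = counts.sum(axis=1)
    return DistributionTable(counts=counts, percent_denominator="column")


def higher_evidence_proportion(
    classified: list[ClassifiedCitation], product: str
) -> float:
    """Percent of a product's citations with higher-evidence publication
    types (systematic review + randomized controlled trial), one decimal."""
    df = _frame(classified)
    mine = df[df["product"] == product]
    if mine.empty:
        raise KeyError(f"product {product!r} not present")
    high = mine["category"].isin(
        [
            PublicationCategory.SYSTEMATIC_REVIEW.value,
            PublicationCategory.RANDOMIZED_CONTROLLED_TRIAL.value,
        ]
    ).sum()
    return round_half_up(100.0 * high / len(mine), 1)


def synopsis_audit(
    classified: list[ClassifiedCitation],
) -> tuple[int, int, int | None]:
    """Count synopsis-source citations among review-category citations.

    Returns (synopsis count, review count, integer percent); the percent is
    None when there are no reviews. Synopses (ACP Journal Club, FPIN items)
    are MEDLINE-indexed as reviews but are a distinct tier of preappraised
    evidence, so their share of the review category is worth auditing.
    """
    reviews = [c for c in classified if c.category is PublicationCategory.REVIEW]
    synopses = [c for c in reviews if c.synopsis_flag]
    if not reviews:
        return 0, 0, None
    pct = int(round_half_up(100.0 * len(synopses) / len(reviews), 0))
    return len(synopses), len(reviews), pct


def export_tables(
    tables: dict[str, DistributionTable],
    out_dir,
    tool_version: str = "0.1.0",
    rules_version: str = "1.0",
) -> None:
    """Write one CSV per indicator table with a metadata header line."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, table in tables.items():
        path = out / f"{name}.csv"
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(
                f"# evicite {tool_version}; rules {rules_version}; "
                f"denominator={table.percent_denominator}\n"
            )
            table.counts.to_csv(fh)
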