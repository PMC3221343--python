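"""Evidence-type classification of citations.

Each citation is assigned exactly one of nine publication-type categories,
ordered loosely by the evidence hierarchy (systematic reviews and randomized
controlled trials near the top, narrative reviews and opinion pieces lower):

``guideline``, ``systematic_review``, ``review``, ``primary_research_other``,
``randomized_controlled_trial``, ``report``, ``animal_study``, ``other``,
``unknown``.

Assignment is a deterministic precedence protocol over the MEDLINE
publication types, MeSH terms, source string and abstract text:

1. **unknown-check** — unverified citations (no confirmable details) grade
   ``unknown``.
2. **guideline** — practice-guideline / consensus publication types; kept
   distinct from systematic reviews because not all guidelines are
   evidence-based.
3. **systematic_review** — the Meta-Analysis publication type, or a
   review-family type whose abstract/title evidences systematic-review
   conduct (see :func:`is_systematic_review`); MEDLINE has no legacy
   "systematic review" publication type, hence the promotion step.
4. **randomized_controlled_trial**.
5. **animal_study** — MeSH ``Animals`` without ``Humans`` on a study-design
   record.
6. **report** — government publications, statistical reports, technology
   assessments, MMWR, task-force/working-group reports (source patterns and
   report publication types).
7. **review** — remaining review-family records (narrative reviews and
   synopses; synopsis sources such as ACP Journal Club and FPIN are flagged).
8. **letter/comment/editorial** — promoted to ``primary_research_other``
   when they report study data (see :func:`reports_study_data`), else
   ``other``.
9. **primary_research_other** — remaining study designs (case-control,
   cross-sectional, cohort, case series, unclear or combined designs).
10. **other** — books, abstracts, and remaining non-research items.

The rule set is data (a :class:`RuleSet`, serializable to YAML) so term
lists can be tightened or loosened without touching code.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, asdict
from enum import Enum
from pathlib import Path

import yaml

from ._text import normalize_text
from .records import CitationRecord, Corpus

logger = logging.getLogger(__name__)


class PublicationCategory(str, Enum):
    """The nine admissible evidence-type categories."""

    GUIDELINE = "guideline"
    SYSTEMATIC_REVIEW = "systematic_review"
    REVIEW = "review"
    PRIMARY_RESEARCH_OTHER = "primary_research_other"
    RANDOMIZED_CONTROLLED_TRIAL = "randomized_controlled_trial"
    REPORT = "report"
    ANIMAL_STUDY = "animal_study"
    OTHER = "other"
    UNKNOWN = "unknown"


@dataclass
class ClassifiedCitation:
    record: CitationRecord
    category: PublicationCategory
    rationale: list[str]
    sr_flag: bool = False
    study_data_flag: bool | None = None
    synopsis_flag: bool = False


@dataclass
class RuleSet:
    """Declarative precedence rules and term lists.

    Term lists are matched case-insensitively. ``study_data_requires_structure``
    controls whether letters/comments/editorials need a structured-abstract
    outline *in addition to* a described sample to count as reporting study
    data (default: both required).
    """

    version: str = "1.0"
    guideline_types: list[str] = field(default_factory=lambda: [
        "Guideline",
        "Practice Guideline",
        "Consensus Development Conference",
        "Consensus Development Conference, NIH",
    ])
    meta_analysis_types: list[str] = field(default_factory=lambda: [
        "Meta-Analysis",
        "Systematic Review",
    ])
    review_types: list[str] = field(default_factory=lambda: [
        "Review",
        "Review Literature",
        "Review, Tutorial",
        "Review, Academic",
    ])
    rct_types: list[str] = field(default_factory=lambda: [
        "Randomized Controlled Trial",
    ])
    letter_types: list[str] = field(default_factory=lambda: [
        "Letter",
        "Comment",
        "Editorial",
    ])
    book_types: list[str] = field(default_factory=lambda: [
        "Book",
        "Book Chapter",
        "Abstract",
        "Congress",
        "Thesis",
        "Newspaper Article",
    ])
    report_types: list[str] = field(default_factory=lambda: [
        "Technical Report",
        "Government Publication",
        "Government Publications",
    ])
    study_design_types: list[str] = field(default_factory=lambda: [
        "Journal Article",
        "Clinical Trial",
        "Controlled Clinical Trial",
        "Clinical Trial, Phase I",
        "Clinical Trial, Phase II",
        "Clinical Trial, Phase III",
        "Clinical Trial, Phase IV",
        "Comparative Study",
        "Evaluation Study",
        "Evaluation Studies",
        "Multicenter Study",
        "Observational Study",
        "Case Reports",
        "Twin Study",
        "Validation Study",
    ])
    report_source_patterns: list[str] = field(default_factory=lambda: [
        "mmwr",
        "morb mortal wkly",
        "morbidity and mortality weekly",
        "technology assessment",
        "task force",
        "working group",
        "government printing office",
        "statistical data report",
        "office for national statistics",
        "office of national statistics",
        "agency for healthcare research",
        "department of health",
    ])
    synopsis_source_patterns: list[str] = field(default_factory=lambda: [
        "acp j club",
        "acp journal club",
        "fpin",
        "family physicians inquiries network",
        "clin inq",
    ])
    # Systematic-review evidence: all three term groups must be present in
    # the title+abstract text (comprehensive search; explicit selection
    # criteria; synthesis of multiple primary studies).
    sr_search_terms: list[str] = field(default_factory=lambda: [
        "we searched",
        "literature search",
        "systematic search",
        "comprehensive search",
        "medline",
        "embase",
        "cochrane",
        "database search",
        "databases were searched",
    ])
    sr_selection_terms: list[str] = field(default_factory=lambda: [
        "inclusion criteria",
        "exclusion criteria",
        "eligibility criteria",
        "selection criteria",
        "studies were included",
        "trials were included",
        "studies were selected",
        "met criteria",
    ])
    sr_synthesis_terms: list[str] = field(default_factory=lambda: [
        "pooled",
        "meta-analysis",
        "meta analysis",
        "data were synthesized",
        "data were combined",
        "quantitative synthesis",
        "random-effects",
        "random effects",
        "fixed-effects",
        "summary estimate",
    ])
    study_data_requires_structure: bool = True

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleSet":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    @classmethod
    def default(cls) -> "RuleSet":
        return cls()


def _has_type(record: CitationRecord, types: list[str]) -> bool:
    have = {normalize_text(t) for t in record.pub_types}
    return any(normalize_text(t) in have for t in types)


def _matched_types(record: CitationRecord, types: list[str]) -> list[str]:
    wanted = {normalize_text(t) for t in types}
    return [t for t in record.pub_types if normalize_text(t) in wanted]


def _source_matches(record: CitationRecord, patterns: list[str]) -> bool:
    src = normalize_text(record.source)
    if not src:
        return False
    return any(normalize_text(p) in src for p in patterns)


_N_EQUALS = re.compile(r"\bn\s*=\s*\d+", re.IGNORECASE)
_COUNTED_SUBJECTS = re.compile(
    r"\b\d+\s+(?:consecutive\s+)?"
    r"(?:patients|subjects|participants|cases|adults|children|infants|"
    r"women|men|volunteers|individuals|enrollees)\b",
    re.IGNORECASE,
)
_COHORT_DESCRIPTOR = re.compile(
    r"\b(?:cohort of|sample of|were enrolled|was enrolled|were recruited|"
    r"consecutive patients|study population)\b",
    re.IGNORECASE,
)

#: Structured-abstract section cue groups; a heading counts once per group.
SECTION_CUE_GROUPS: list[list[str]] = [
    ["objective", "objectives", "introduction", "problem", "background", "aim", "aims"],
    ["methods", "method", "subjects", "patients and methods", "design", "materials and methods"],
    ["results", "findings"],
    ["discussion", "conclusion", "conclusions", "interpretation"],
]


def is_systematic_review(record: CitationRecord, rules: RuleSet | None = None) -> bool:
    """Decide whether a review-family citation is a systematic review.

    A systematic review has preplanned methods and original studies as its
    subjects; operationally, the title/abstract must evidence all three of:
    a comprehensive search, explicit selection criteria, and synthesis of
    multiple primary studies. A Meta-Analysis (or modern Systematic Review)
    publication type short-circuits to True.

    Raises ``ValueError`` if the record carries no review-family type
    (contract: callers pre-filter on the review family).
    """
    rules = rules or RuleSet.default()
    if _has_type(record, rules.meta_analysis_types):
        return True
    if not _has_type(record, rules.review_types):
        raise ValueError(
            f"record {record.local_id} has no review-family publication type"
        )
    text = " ".join(filter(None, [record.title, record.abstract or ""])).lower()
    if not text.strip():
        return False
    groups = (rules.sr_search_terms, rules.sr_selection_terms, rules.sr_synthesis_terms)
    return all(any(term.lower() in text for term in group) for group in groups)


def reports_study_data(
    record: CitationRecord, rules: RuleSet | None = None
) -> bool:
    """Decide whether a letter/comment/editorial reports study data.

    Criterion 1 (always required): the sample or subjects are described
    characteristically or in quantity — an explicit ``n = ...``, a counted
    subject phrase ("45 patients"), or an enrollment/cohort descriptor.
    Criterion 2 (required unless ``rules.study_data_requires_structure`` is
    False): a traditional structured-abstract outline is present, i.e. at
    least two distinct section cues (Objective/Introduction/Problem,
    Methods/Subjects, Results, Discussion/Conclusion) appear as headings.

    Raises ``ValueError`` for records outside the letter/comment/editorial
    family.
    """
    rules = rules or RuleSet.default()
    if not _has_type(record, rules.letter_types):
        raise ValueError(
            f"record {record.local_id} is not a letter, comment or editorial"
        )
    text = record.abstract or ""
    if not text.strip():
        return False
    criterion1 = bool(
        _N_EQUALS.search(text)
        or _COUNTED_SUBJECTS.search(text)
        or _COHORT_DESCRIPTOR.search(text)
    )
    if not criterion1:
        return False
    if not rules.study_data_requires_structure:
        return True
    hit_groups = 0
    for group in SECTION_CUE_GROUPS:
        if any(re.search(rf"\b{re.escape(cue)}\s*:", text, re.IGNORECASE) for cue in group):
            hit_groups += 1
    return hit_groups >= 2


def classify_citation(
    record: CitationRecord, rules: RuleSet | None = None
) -> ClassifiedCitation:
    """Assign exactly one evidence-type category by first-match precedence.

    Total function: every record lands in a category, with ``unknown`` the
    fallback for unverifiable citations. The rationale lists every rule that
    fired, in order, so multi-type conflicts remain auditable.
    """
    rules = rules or RuleSet.default()
    rationale: list[str] = []
    sr_flag = False
    study_data_flag: bool | None = None
    synopsis_flag = False

    def done(category: PublicationCategory) -> ClassifiedCitation:
        return ClassifiedCitation(
            record=record,
            category=category,
            rationale=rationale,
            sr_flag=sr_flag,
            study_data_flag=study_data_flag,
            synopsis_flag=synopsis_flag,
        )

    if not record.verified:
        rationale.append("unverified")
        return done(PublicationCategory.UNKNOWN)

    if _has_type(record, rules.guideline_types):
        rationale.append(
            "guideline-type:" + ",".join(_matched_types(record, rules.guideline_types))
        )
        return done(PublicationCategory.GUIDELINE)

    if _has_type(record, rules.meta_analysis_types):
        rationale.append(
            "meta-analysis-type:"
            + ",".join(_matched_types(record, rules.meta_analysis_types))
        )
        sr_flag = True
        return done(PublicationCategory.SYSTEMATIC_REVIEW)
    is_review_family = _has_type(record, rules.review_types)
    if is_review_family and is_systematic_review(record, rules):
        rationale.append("review-type-with-systematic-review-evidence")
        sr_flag = True
        return done(PublicationCategory.SYSTEMATIC_REVIEW)

    if _has_type(record, rules.rct_types):
        rationale.append("rct-type")
        return done(PublicationCategory.RANDOMIZED_CONTROLLED_TRIAL)

    mesh = {normalize_text(m.split("/")[0]) for m in record.mesh_terms}
    if (
        "animals" in mesh
        and "humans" not in mesh
        and _has_type(record, rules.study_design_types)
    ):
        rationale.append("mesh-animals-without-humans")
        return done(PublicationCategory.ANIMAL_STUDY)

    if _has_type(record, rules.report_types) or _source_matches(
        record, rules.report_source_patterns
    ):
        rationale.append("report-source-or-type")
        return done(PublicationCategory.REPORT)

    if is_review_family:
        rationale.append("review-type-narrative")
        synopsis_flag = _source_matches(record, rules.synopsis_source_patterns)
        if synopsis_flag:
            rationale.append("synopsis-source")
        return done(PublicationCategory.REVIEW)

    if _has_type(record, rules.letter_types):
        study_data_flag = reports_study_data(record, rules)
        if study_data_flag:
            rationale.append("letter-family-with-study-data")
            return done(PublicationCategory.PRIMARY_RESEARCH_OTHER)
        rationale.append("letter-family-no-study-data")
        return done(PublicationCategory.OTHER)

    if _has_type(record, rules.book_types):
        rationale.append("book-or-abstract-type")
        return done(PublicationCategory.OTHER)

    if _has_type(record, rules.study_design_types):
        rationale.append("remaining-study-design")
        return done(PublicationCategory.PRIMARY_RESEARCH_OTHER)

    if record.pub_types:
        rationale.append("nonresearch-publication-type")
        return done(PublicationCategory.OTHER)

    rationale.append("verified-but-unindexed")
    return done(PublicationCategory.OTHER)


def classify_corpus(
    corpus: Corpus, rules: RuleSet | None = None
) -> list[ClassifiedCitation]:
    """Classify every record of a corpus, preserving order."""
    rules = rules or RuleSet.default()
    out = [classify_citation(rec, rules) for rec in corpus.records]
    counts: dict[str, int] = {}
    for c in out:
        counts[c.category.value] = counts.get(c.category.value, 0) + 1
    logger.info(
        "classified %d records of %s/%s: %s", len(out), corpus.product, corpus.topic, counts
    )
    return out
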