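"""Synthetic citation corpora with controlled composition.

The generator builds per-(product, topic) corpora whose evidence-type
composition, currency profile and cross-product overlap structure are fixed
exactly by a :class:`CorpusSpec`. Records carry publication types, MeSH
terms, sources and template-generated abstracts engineered so that the
classifier recovers the intended category (at zero noise), and shared
citations carry identical PMIDs or identical content across the products
citing them, so the overlap stage recovers the specified multiplicity
distribution.

Everything is driven by one seeded :class:`random.Random`; the same spec and
seed always yield byte-identical corpora.

:func:`study_fixture` returns the packaged spec mirroring the published
five-product study: the per-product evidence-type counts, the overlap
multiplicities (2/4/25/161/1907 distinct citations cited by 5/4/3/2/1
products), the two documented currency constraints and the synopsis-source
counts. Year-bin values beyond the documented constraints are deterministic
fills chosen to match the reported qualitative currency pattern; they are
not published values.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .citation_io import assign_local_id
from .classify import PublicationCategory
from .records import CitationRecord, Corpus
from .summarize import YearBin

_CAT = PublicationCategory  # local alias

#: Vocabulary for template titles; samples of several words keep titles
#: mutually dissimilar so fuzzy matching never merges distinct citations.
_TITLE_VOCAB = [
    "airway", "albumin", "aldosterone", "ambulatory", "angiotensin", "antagonist",
    "arterial", "aspirin", "assessment", "atenolol", "atorvastatin", "baseline",
    "benazepril", "bronchial", "bronchodilator", "budesonide", "calcium", "carbon",
    "cardiac", "cardiovascular", "carotid", "cessation", "chamber", "cholesterol",
    "chronic", "clinical", "combination", "community", "compliance", "consequence",
    "coronary", "corticosteroid", "counseling", "diastolic", "dietary", "diffusion",
    "diltiazem", "disease", "diuretic", "dosing", "duration", "dyspnea",
    "education", "elderly", "emergency", "enalapril", "endothelial", "exacerbation",
    "exercise", "exhaled", "exposure", "ezetimibe", "fenofibrate", "fluticasone",
    "formoterol", "framingham", "frequency", "function", "gemfibrozil", "glucose",
    "guideline", "headache", "hemoglobin", "hospital", "hydrochlorothiazide",
    "hyperbaric", "hypoxia", "impairment", "incidence", "indoor", "inflammation",
    "inhaled", "inhalation", "intervention", "intoxication", "irbesartan",
    "ischemia", "kinetics", "lifestyle", "lipoprotein", "lisinopril", "losartan",
    "lovastatin", "management", "mechanism", "medication", "metoprolol",
    "monitoring", "montelukast", "morbidity", "mortality", "myocardial",
    "nebulized", "nedocromil", "neurological", "niacin", "nifedipine", "nitric",
    "obstruction", "occupational", "outcome", "outpatient", "oximetry", "oxygen",
    "particulate", "pediatric", "perception", "perfusion", "peripheral",
    "persistent", "pharmacist", "plasma", "poisoning", "pollution", "population",
    "pravastatin", "prediction", "pressure", "prevalence", "prevention",
    "prognosis", "propranolol", "pulmonary", "ramipril", "reduction", "referral",
    "regression", "rehabilitation", "remission", "renal", "residential",
    "resistance", "respiratory", "response", "risk", "rosuvastatin", "salmeterol",
    "screening", "seasonal", "secondary", "sequelae", "severity", "simvastatin",
    "smoking", "sodium", "spirometry", "stenosis", "stratification", "stroke",
    "surveillance", "survival", "symptom", "systolic", "telmisartan", "terbutaline",
    "theophylline", "therapy", "threshold", "tobacco", "tolerance", "toxicity",
    "treatment", "triglyceride", "urban", "valsartan", "variability", "vascular",
    "ventilation", "verapamil", "wheeze", "workplace", "zafirlukast",
]

_SURNAMES = [
    "Adler", "Barnes", "Carver", "Delgado", "Ekstrom", "Ferris", "Grantham",
    "Holloway", "Ibarra", "Jensen", "Kovacs", "Lindqvist", "Moreau", "Nakata",
    "Oyelaran", "Petrov", "Quon", "Rastogi", "Soto", "Tanaka", "Ulmer",
    "Vasquez", "Whitfield", "Xu", "Yamamoto", "Zielinski", "Okafor", "Bhatt",
    "Cresswell", "Duran", "Eriksen", "Fontaine", "Gallo", "Haddad", "Iqbal",
    "Jimenez", "Keller", "Larsen", "Mehta", "Novak",
]

_JOURNALS = [
    "J Intern Med", "Chest", "Eur Respir J", "Am J Cardiol", "Circulation",
    "J Hypertens", "Thorax", "Ann Emerg Med", "Arch Intern Med", "Lancet",
    "N Engl J Med", "BMJ", "JAMA", "Am J Respir Crit Care Med", "Clin Ther",
]

_REPORT_SOURCES = [
    "MMWR Morb Mortal Wkly Rep",
    "Health Technology Assessment Programme",
    "National Heart Lung and Blood Institute Working Group Report",
    "US Preventive Services Task Force Report",
]

_SYNOPSIS_SOURCES = ["ACP J Club", "FPIN Clinical Inquiries"]

_WEB_SOURCES = [
    "Office for National Statistics",
    "Centers for Disease Control and Prevention",
    "World Health Organization",
]


@dataclass
class CorpusSpec:
    """Parameters from which corpora are generated.

    ``category_counts`` and ``year_bin_counts`` are per-product 9-vectors /
    bin-vectors that must sum to the same per-product total;
    ``overlap_multiplicities`` maps k (number of products citing) to the
    number of distinct citations shared by exactly k products, and its
    k-weighted sum must equal the sum of product totals.
    """

    products: list[str]
    topics: list[str]
    category_counts: dict[str, dict[str, int]]
    year_bin_counts: dict[str, dict[str, int]]
    overlap_multiplicities: dict[int, int]
    synopsis_counts: dict[str, int] = field(default_factory=dict)
    pmid_less_fraction: float = 0.1
    classification_noise: float = 0.0
    seed: int = 0

    def product_total(self, product: str) -> int:
        return sum(self.category_counts[product].values())

    def validate(self) -> None:
        problems: list[str] = []
        if not self.products:
            problems.append("no products")
        if not self.topics:
            problems.append("no topics")
        for frac_name in ("pmid_less_fraction", "classification_noise"):
            v = getattr(self, frac_name)
            if not (0.0 <= v <= 1.0):
                problems.append(f"{frac_name} {v} outside [0, 1]")
        valid_cats = {c.value for c in PublicationCategory}
        valid_bins = {b.value for b in YearBin}
        for p in self.products:
            cats = self.category_counts.get(p)
            bins = self.year_bin_counts.get(p)
            if cats is None or bins is None:
                problems.append(f"missing counts for product {p!r}")
                continue
            bad = set(cats) - valid_cats
            if bad:
                problems.append(f"{p}: unknown categories {sorted(bad)}")
            bad = set(bins) - valid_bins
            if bad:
                problems.append(f"{p}: unknown year bins {sorted(bad)}")
            if any(n < 0 for n in cats.values()) or any(n < 0 for n in bins.values()):
                problems.append(f"{p}: negative counts")
            if sum(cats.values()) != sum(bins.values()):
                problems.append(
                    f"{p}: category total {sum(cats.values())} != "
                    f"year-bin total {sum(bins.values())}"
                )
        grand = sum(self.product_total(p) for p in self.products if p in self.category_counts)
        weighted = sum(k * n for k, n in self.overlap_multiplicities.items())
        if weighted != grand:
            problems.append(
                f"k-weighted overlap sum {weighted} != sum of product totals {grand}"
            )
        for k, n in self.overlap_multiplicities.items():
            if not (1 <= k <= len(self.products)):
                problems.append(f"multiplicity {k} outside [1, {len(self.products)}]")
            if n < 0:
                problems.append(f"negative count for multiplicity {k}")
        if problems:
            raise ValueError("invalid CorpusSpec: " + "; ".join(problems))

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["overlap_multiplicities"] = {
            str(k): v for k, v in self.overlap_multiplicities.items()
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CorpusSpec":
        data = yaml.safe_load(Path(path).read_text())
        data["overlap_multiplicities"] = {
            int(k): v for k, v in data["overlap_multiplicities"].items()
        }
        return cls(**data)


@dataclass
class _Cluster:
    """One distinct citation during generation."""

    members: list[str]           # product labels citing it
    category: str = ""
    year_bin: str = ""
    topic: str = ""
    synopsis: bool = False


def _assign_members(spec: CorpusSpec, rng: random.Random) -> list[_Cluster]:
    """Assign product sets to clusters, largest multiplicity first, always
    drawing the products with most remaining capacity (feasible whenever the
    spec's conservation identity can be realized)."""
    remaining = {p: spec.product_total(p) for p in spec.products}
    clusters: list[_Cluster] = []
    for k in sorted(spec.overlap_multiplicities, reverse=True):
        for _ in range(spec.overlap_multiplicities[k]):
            tiebreak = {p: rng.random() for p in spec.products}
            order = sorted(spec.products, key=lambda p: (-remaining[p], tiebreak[p]))
            chosen = order[:k]
            if any(remaining[p] <= 0 for p in chosen):
                raise ValueError(
                    "overlap multiplicities infeasible: not enough remaining "
                    f"capacity for a {k}-product citation"
                )
            for p in chosen:
                remaining[p] -= 1
            clusters.append(_Cluster(members=chosen))
    if any(v != 0 for v in remaining.values()):
        raise ValueError(f"capacity left over after assignment: {remaining}")
    return clusters


def _assign_shared_attributes(spec: CorpusSpec, clusters: list[_Cluster]) -> tuple[
    dict[str, dict[str, int]], dict[str, dict[str, int]]
]:
    """Give each shared (k>=2) cluster a category and year bin consistent
    with every member product's remaining counts; greedy max-min-remaining,
    avoiding unknown/missing for shared citations when possible."""
    rem_cat = {p: dict(spec.category_counts[p]) for p in spec.products}
    rem_bin = {p: dict(spec.year_bin_counts[p]) for p in spec.products}

    def pick(rem: dict[str, dict[str, int]], members: list[str], avoid: str, what: str) -> str:
        valid = [
            v
            for v in sorted(set().union(*(rem[p] for p in members)))
            if all(rem[p].get(v, 0) >= 1 for p in members)
        ]
        preferred = [v for v in valid if v != avoid] or valid
        if not preferred:
            raise ValueError(
                f"cannot assign a common {what} to citation shared by {members}"
            )
        return max(preferred, key=lambda v: min(rem[p][v] for p in members))

    for cluster in clusters:
        if len(cluster.members) < 2:
            continue
        cluster.category = pick(rem_cat, cluster.members, _CAT.UNKNOWN.value, "category")
        cluster.year_bin = pick(rem_bin, cluster.members, YearBin.MISSING.value, "year bin")
        for p in cluster.members:
            rem_cat[p][cluster.category] -= 1
            rem_bin[p][cluster.year_bin] -= 1
    return rem_cat, rem_bin


def _assign_unique_attributes(
    spec: CorpusSpec,
    clusters: list[_Cluster],
    rem_cat: dict[str, dict[str, int]],
    rem_bin: dict[str, dict[str, int]],
    rng: random.Random,
) -> None:
    """Fill single-product clusters with the remaining per-product category
    and year-bin counts; missing years pair with unknown citations first
    (unverifiable web citations are exactly the undatable ones)."""
    by_product: dict[str, list[_Cluster]] = {p: [] for p in spec.products}
    for cluster in clusters:
        if len(cluster.members) == 1:
            by_product[cluster.members[0]].append(cluster)
    for p in spec.products:
        cats = [c for c, n in sorted(rem_cat[p].items()) for _ in range(n)]
        bins = [b for b, n in sorted(rem_bin[p].items()) for _ in range(n)]
        mine = by_product[p]
        if len(cats) != len(mine) or len(bins) != len(mine):
            raise ValueError(
                f"{p}: {len(mine)} unique citations but {len(cats)} categories "
                f"and {len(bins)} year bins remain"
            )
        pairs: list[tuple[str, str]] = []
        n_pair = min(
            cats.count(_CAT.UNKNOWN.value), bins.count(YearBin.MISSING.value)
        )
        for _ in range(n_pair):
            cats.remove(_CAT.UNKNOWN.value)
            bins.remove(YearBin.MISSING.value)
            pairs.append((_CAT.UNKNOWN.value, YearBin.MISSING.value))
        rng.shuffle(cats)
        rng.shuffle(bins)
        pairs.extend(zip(cats, bins))
        for cluster, (cat, ybin) in zip(mine, pairs):
            cluster.category = cat
            cluster.year_bin = ybin


def _mark_synopses(spec: CorpusSpec, clusters: list[_Cluster]) -> None:
    todo = dict(spec.synopsis_counts)
    for cluster in clusters:
        if len(cluster.members) != 1:
            continue
        p = cluster.members[0]
        if todo.get(p, 0) > 0 and cluster.category == _CAT.REVIEW.value:
            cluster.synopsis = True
            todo[p] -= 1
    leftover = {p: n for p, n in todo.items() if n > 0}
    if leftover:
        raise ValueError(
            f"not enough single-product review citations for synopsis counts: {leftover}"
        )


_BIN_YEARS = {
    YearBin.PRE_2001.value: (1980, 2000),
    YearBin.Y2001_2003.value: (2001, 2003),
    YearBin.Y2004_2006.value: (2004, 2006),
    YearBin.Y2007_2009.value: (2007, 2009),
    YearBin.POST_2009.value: (2010, 2015),
}


def _unique_title(rng: random.Random, seen: set[frozenset[str]]) -> str:
    for _ in range(100):
        words = rng.sample(_TITLE_VOCAB, 7)
        key = frozenset(words)
        if key not in seen:
            seen.add(key)
            return (" ".join(words)).capitalize() + "."
    raise RuntimeError("could not draw a fresh title; vocabulary exhausted")


def _structured_study_abstract(rng: random.Random, n_subjects: int) -> str:
    return (
        "OBJECTIVE: To evaluate the intervention in routine care. "
        f"METHODS: {n_subjects} patients were enrolled and followed prospectively. "
        "RESULTS: The primary endpoint differed between groups. "
        "CONCLUSIONS: The findings support further evaluation."
    )


def _systematic_review_abstract(rng: random.Random, n_trials: int) -> str:
    return (
        "BACKGROUND: The comparative benefit remains uncertain. "
        "METHODS: We searched MEDLINE, EMBASE and the Cochrane Library; "
        "inclusion criteria were specified in advance. "
        f"RESULTS: Data from {n_trials} trials were pooled using a "
        "random-effects model. "
        "CONCLUSIONS: The summary estimate favours treatment."
    )


def _narrative_review_abstract(topic: str) -> str:
    return (
        f"This overview discusses the contemporary management of {topic}, "
        "summarising pathophysiology, diagnosis and therapeutic options, and "
        "highlights areas of ongoing debate for the practising clinician."
    )


def _opinion_abstract(topic: str) -> str:
    return (
        f"We read with interest the recent article on {topic}. The authors' "
        "conclusions deserve caution, and we offer an alternative "
        "interpretation for discussion by the readership."
    )


def _build_cluster_record(
    cluster: _Cluster,
    index: int,
    rng: random.Random,
    seen_titles: set[frozenset[str]],
    pmid_less: bool,
    noisy: bool,
) -> CitationRecord:
    """Build the shared bibliographic content of one distinct citation (as a
    prototype record; per-product copies differ only in provenance)."""
    cat = cluster.category
    year: int | None
    if cluster.year_bin == YearBin.MISSING.value:
        year = None
    else:
        lo, hi = _BIN_YEARS[cluster.year_bin]
        year = rng.randint(lo, hi)
    if year is None and cat != _CAT.UNKNOWN.value:
        # an undatable citation stays verifiable only through its PMID
        pmid_less = False

    author = f"{rng.choice(_SURNAMES)} {rng.choice('ABCDEFGHJKLMPRST')}{rng.choice('ABCDEFGHJKLMPRST')}"
    source = rng.choice(_JOURNALS)
    title: str | None = _unique_title(rng, seen_titles)
    url = None
    abstract: str | None = None
    mesh = ["Humans"]
    pts: list[str]

    if cat == _CAT.GUIDELINE.value:
        pts = ["Practice Guideline", "Guideline", "Journal Article"]
    elif cat == _CAT.SYSTEMATIC_REVIEW.value:
        if rng.random() < 0.5:
            pts = ["Meta-Analysis", "Journal Article"]
        else:
            pts = ["Review", "Journal Article"]
        abstract = _systematic_review_abstract(rng, rng.randint(5, 40))
    elif cat == _CAT.RANDOMIZED_CONTROLLED_TRIAL.value:
        pts = ["Randomized Controlled Trial", "Clinical Trial", "Journal Article"]
        abstract = _structured_study_abstract(rng, rng.randint(40, 2000))
    elif cat == _CAT.ANIMAL_STUDY.value:
        pts = ["Journal Article", "Comparative Study"]
        mesh = ["Animals", "Rats"]
        abstract = (
            "Exposure was induced under controlled conditions and physiological "
            "responses were recorded in the laboratory model."
        )
    elif cat == _CAT.REPORT.value:
        pts = ["Journal Article"]
        source = rng.choice(_REPORT_SOURCES)
    elif cat == _CAT.REVIEW.value:
        pts = ["Review", "Journal Article"]
        abstract = _narrative_review_abstract(cluster.topic)
        if cluster.synopsis:
            source = rng.choice(_SYNOPSIS_SOURCES)
    elif cat == _CAT.PRIMARY_RESEARCH_OTHER.value:
        style = rng.random()
        if style < 0.15:
            # letter reporting study data
            pts = [rng.choice(["Letter", "Comment"])]
            abstract = _structured_study_abstract(rng, rng.randint(10, 120))
        else:
            pts = ["Journal Article", rng.choice(["Comparative Study", "Multicenter Study"])]
            mesh = ["Humans", rng.choice(["Cohort Studies", "Case-Control Studies", "Cross-Sectional Studies"])]
            abstract = _structured_study_abstract(rng, rng.randint(20, 800))
    elif cat == _CAT.OTHER.value:
        style = rng.random()
        if style < 0.75:
            pts = [rng.choice(["Letter", "Comment", "Editorial"])]
            abstract = _opinion_abstract(cluster.topic)
        else:
            pts = ["Book"]
            if year is not None:
                pmid_less = True
    elif cat == _CAT.UNKNOWN.value:
        pts = []
        mesh = []
        title = None
        source = rng.choice(_WEB_SOURCES)
        url = f"http://example.org/resource/{index}"
        author = ""
        pmid_less = True
    else:  # pragma: no cover - spec validation excludes this
        raise ValueError(f"unhandled category {cat}")

    pmid = None if pmid_less else str(10000000 + index)
    if noisy and cat != _CAT.UNKNOWN.value:
        # ambiguity injection: strip the texts the heuristics rely on
        abstract = None
        mesh = []

    rec = CitationRecord(
        local_id="pending",
        product=cluster.members[0],
        topic=cluster.topic,
        title=title or "",
        first_author=author,
        source=source,
        year=year,
        pmid=pmid,
        pub_types=pts,
        mesh_terms=mesh,
        abstract=abstract,
        url=url,
        verified=bool(title and (year is not None or pmid)),
    )
    rec.local_id = assign_local_id(rec, ordinal=index)
    return rec


def generate_corpora(
    spec: CorpusSpec, return_truth: bool = False
) -> list[Corpus] | tuple[list[Corpus], dict[str, PublicationCategory]]:
    """Generate per-(product, topic) corpora realizing the spec exactly.

    With ``return_truth=True`` also returns the generator-intended category
    per local_id, for round-trip evaluation of the classifier.
    """
    spec.validate()
    rng = random.Random(spec.seed)

    clusters = _assign_members(spec, rng)
    rem_cat, rem_bin = _assign_shared_attributes(spec, clusters)
    _assign_unique_attributes(spec, clusters, rem_cat, rem_bin, rng)
    for cluster in clusters:
        cluster.topic = rng.choice(spec.topics)
    _mark_synopses(spec, clusters)

    seen_titles: set[frozenset[str]] = set()
    truth: dict[str, PublicationCategory] = {}
    corpora: dict[tuple[str, str], Corpus] = {
        (p, t): Corpus(product=p, topic=t) for p in spec.products for t in spec.topics
    }
    for index, cluster in enumerate(clusters):
        pmid_less = rng.random() < spec.pmid_less_fraction
        noisy = spec.classification_noise > 0 and rng.random() < spec.classification_noise
        proto = _build_cluster_record(cluster, index, rng, seen_titles, pmid_less, noisy)
        truth[proto.local_id] = PublicationCategory(cluster.category)
        for p in cluster.members:
            rec = CitationRecord(**{**proto.__dict__, "product": p})
            corpora[(p, cluster.topic)].records.append(rec)

    out = [corpora[(p, t)] for p in spec.products for t in spec.topics if corpora[(p, t)].records]
    for corpus in out:
        corpus.validate()
    return (out, truth) if return_truth else out


def random_corpus_spec(
    seed: int,
    n_products: int | None = None,
    mean_citations: int = 40,
) -> CorpusSpec:
    """A feasible random spec for property testing: random product totals,
    category/year mixes and modest overlap structure, all seeded."""
    rng = random.Random(seed)
    n_products = n_products or rng.randint(2, 5)
    products = [f"Product{i}" for i in range(n_products)]
    topics = ["asthma", "hypertension"]
    categories = [c.value for c in PublicationCategory]
    bins = [b.value for b in YearBin]

    totals = {p: rng.randint(mean_citations // 2, mean_citations * 2) for p in products}
    # Shared clusters: keep the shared load well under the smallest product total
    # so the greedy assignment always finds distinct products.
    min_total = min(totals.values())
    multiplicities: dict[int, int] = {}
    for k in range(2, n_products + 1):
        multiplicities[k] = rng.randint(0, max(1, min_total // (2 * n_products)))
    shared_weight = sum(k * n for k, n in multiplicities.items())
    grand = sum(totals.values())
    if shared_weight > grand:
        multiplicities = {}
        shared_weight = 0
    multiplicities[1] = grand - shared_weight

    category_counts: dict[str, dict[str, int]] = {}
    year_bin_counts: dict[str, dict[str, int]] = {}
    for p in products:
        cat_vec = {c: 0 for c in categories}
        # weight common categories so shared clusters always find room
        weights = [5 if c in ("review", "randomized_controlled_trial",
                              "primary_research_other") else 1 for c in categories]
        for _ in range(totals[p]):
            cat_vec[rng.choices(categories, weights=weights)[0]] += 1
        bin_vec = {b: 0 for b in bins}
        bin_weights = [6, 3, 3, 2, 1, 1]
        for _ in range(totals[p]):
            bin_vec[rng.choices(bins, weights=bin_weights)[0]] += 1
        category_counts[p] = cat_vec
        year_bin_counts[p] = bin_vec

    return CorpusSpec(
        products=products,
        topics=topics,
        category_counts=category_counts,
        year_bin_counts=year_bin_counts,
        overlap_multiplicities=multiplicities,
        pmid_less_fraction=rng.choice([0.0, 0.1, 0.2]),
        classification_noise=0.0,
        seed=rng.randrange(2**31),
    )


#: Five-product study composition (evidence-type counts per product).
_STUDY_CATEGORY_COUNTS: dict[str, dict[str, int]] = {
    "ACP PIER": {
        "systematic_review": 37, "randomized_controlled_trial": 171,
        "primary_research_other": 196, "guideline": 24, "report": 7,
        "review": 73, "animal_study": 0, "other": 23, "unknown": 0,
    },
    "Clinical Evidence": {
        "systematic_review": 51, "randomized_controlled_trial": 94,
        "primary_research_other": 61, "guideline": 6, "report": 10,
        "review": 15, "animal_study": 2, "other": 13, "unknown": 2,
    },
    "DynaMed": {
        "systematic_review": 164, "randomized_controlled_trial": 263,
        "primary_research_other": 444, "guideline": 33, "report": 23,
        "review": 147, "animal_study": 0, "other": 57, "unknown": 0,
    },
    "FirstCONSULT": {
        "systematic_review": 64, "randomized_controlled_trial": 73,
        "primary_research_other": 0, "guideline": 6, "report": 1,
        "review": 6, "animal_study": 0, "other": 3, "unknown": 0,
    },
    "UpToDate": {
        "systematic_review": 18, "randomized_controlled_trial": 64,
        "primary_research_other": 92, "guideline": 17, "report": 9,
        "review": 45, "animal_study": 7, "other": 8, "unknown": 1,
    },
}

#: Currency profile. Documented constraints: DynaMed 170 citations in
#: 2007–2009; Clinical Evidence none in 2007–2009; one undatable web citation
#: each in Clinical Evidence and UpToDate. All other values are deterministic
#: fills matching the qualitative pattern (pre-2001 largest everywhere except
#: FirstCONSULT, where 2001–2003 leads; 2007–2009 smallest).
_STUDY_YEAR_BINS: dict[str, dict[str, int]] = {
    "ACP PIER": {"pre_2001": 270, "2001_2003": 130, "2004_2006": 91, "2007_2009": 40, "missing": 0},
    "Clinical Evidence": {"pre_2001": 130, "2001_2003": 70, "2004_2006": 53, "2007_2009": 0, "missing": 1},
    "DynaMed": {"pre_2001": 500, "2001_2003": 250, "2004_2006": 211, "2007_2009": 170, "missing": 0},
    "FirstCONSULT": {"pre_2001": 50, "2001_2003": 60, "2004_2006": 30, "2007_2009": 13, "missing": 0},
    "UpToDate": {"pre_2001": 135, "2001_2003": 65, "2004_2006": 45, "2007_2009": 15, "missing": 1},
}


def study_fixture(seed: int = 20110218) -> CorpusSpec:
    """The packaged five-product study spec (2330 citation instances, 2099
    distinct citations, overlap multiplicities 2/4/25/161/1907, synopsis
    sources 18+1+1)."""
    return CorpusSpec(
        products=list(_STUDY_CATEGORY_COUNTS),
        topics=["asthma", "hypertension", "hyperlipidemia", "carbon monoxide poisoning"],
        category_counts={p: dict(v) for p, v in _STUDY_CATEGORY_COUNTS.items()},
        year_bin_counts={p: dict(v) for p, v in _STUDY_YEAR_BINS.items()},
        overlap_multiplicities={5: 2, 4: 4, 3: 25, 2: 161, 1: 1907},
        synopsis_counts={"DynaMed": 18, "FirstCONSULT": 1, "Clinical Evidence": 1},
        pmid_less_fraction=0.1,
        classification_noise=0.0,
        seed=seed,
    )
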