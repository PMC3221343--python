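import pytest
from hypothesis import settings

import evicite as ev

settings.register_profile("suite", derandomize=True, max_examples=200)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def study_pipeline():
    """The packaged five-product study composition run through the whole
    pipeline once: generate -> combine -> classify -> match -> distribute."""
    spec = ev.study_fixture(seed=101)
    corpora = ev.generate_corpora(spec)
    merged = ev.combine_corpora(corpora)
    classified = [c for corpus in merged for c in ev.classify_corpus(corpus)]
    clusters = ev.match_citations(merged)
    dist = ev.overlap_distribution(clusters, n_products=len(spec.products))
    return {
        "spec": spec,
        "corpora": corpora,
        "merged": merged,
        "classified": classified,
        "clusters": clusters,
        "dist": dist,
    }


NBIB_THREE_RECORDS = """\
PMID- 12345
TI  - Inhaled corticosteroids in persistent asthma: a randomized trial.
AU  - Jensen KL
SO  - Eur Respir J
DP  - 2004 Jan-Feb
PT  - Randomized Controlled Trial
PT  - Journal Article
MH  - Humans
MH  - Asthma/drug therapy
AB  - OBJECTIVE: To compare inhaled corticosteroids. METHODS: 120 patients
      were enrolled. RESULTS: Symptoms improved.

TI  - Management of chronic hypertension in primary care.
AU  - Moreau D
SO  - J Hypertens
DP  - 2002
PT  - Review

PMID- 67890
TI  - Statin therapy and cardiovascular outcomes.
AU  - Rastogi P
SO  - Lancet
DP  - 2006
PT  - Meta-Analysis
MH  - Humans
"""


@pytest.fixture
def nbib_file(tmp_path):
    path = tmp_path / "three.nbib"
    path.write_text(NBIB_THREE_RECORDS)
    return path


RIS_TWO_RECORDS = """\
TY  - JOUR
TI  - Ambient carbon monoxide exposure and emergency admissions.
AU  - Tanaka H
JO  - Ann Emerg Med
PY  - 2003
KW  - Carbon Monoxide Poisoning
AN  - PMID:555
ER  -
TY  - RPRT
TI  - Surveillance summary of unintentional poisoning.
AU  - Whitfield S
T2  - MMWR Morb Mortal Wkly Rep
PY  - 2005
ER  -
"""


@pytest.fixture
def ris_file(tmp_path):
    path = tmp_path / "two.ris"
    path.write_text(RIS_TWO_RECORDS)
    return path


def make_record(**kwargs) -> ev.CitationRecord:
    """A valid record with overridable fields, for terse test construction."""
    defaults = dict(
        local_id="PMID:1",
        product="ProductA",
        topic="asthma",
        title="A study of airway inflammation and treatment response.",
        first_author="Jensen KL",
        source="Eur Respir J",
        year=2005,
        pmid="1",
        pub_types=["Journal Article"],
        mesh_terms=["Humans"],
        verified=True,
    )
    defaults.update(kwargs)
    rec = ev.CitationRecord(**defaults)
    if "local_id" not in kwargs:
        rec.local_id = ev.assign_local_id(rec)
    return rec
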