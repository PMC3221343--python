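"""Reading, writing and identifying citation records."""

import pytest
from hypothesis import given, strategies as st

import evicite as ev
from evicite.citation_io import RIS_TYPE_MAP

from conftest import make_record


class TestReadNbib:
    def test_three_record_fixture(self, nbib_file):
        corpus = ev.read_nbib(nbib_file, product="P", topic="asthma")
        assert len(corpus) == 3
        pmids = [r.pmid for r in corpus]
        assert pmids == ["12345", None, "67890"]
        no_pmid = [r for r in corpus if r.pmid is None]
        assert len(no_pmid) == 1
        assert no_pmid[0].local_id.startswith("LOC:")

    def test_fields_carried_verbatim(self, nbib_file):
        corpus = ev.read_nbib(nbib_file, product="P", topic="asthma")
        first = corpus.records[0]
        assert first.pub_types == ["Randomized Controlled Trial", "Journal Article"]
        assert first.mesh_terms == ["Humans", "Asthma/drug therapy"]
        assert first.year == 2004  # first year of "2004 Jan-Feb"
        assert first.first_author == "Jensen KL"
        # wrapped AB continuation line is joined
        assert "120 patients were enrolled" in first.abstract

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.nbib"
        path.write_text("")
        corpus = ev.read_nbib(path, product="P", topic="t")
        assert len(corpus) == 0

    def test_malformed_block_skipped(self, tmp_path, caplog):
        path = tmp_path / "mixed.nbib"
        path.write_text(
            "just some prose, not a record\n\nPMID- 99\nTI  - Valid title.\nDP  - 2001\nPT  - Review\n"
        )
        with caplog.at_level("WARNING"):
            corpus = ev.read_nbib(path, product="P", topic="t")
        assert len(corpus) == 1
        assert corpus.records[0].pmid == "99"
        assert "skip" in caplog.text.lower()

    def test_non_utf8_decoded_with_replacement(self, tmp_path):
        path = tmp_path / "latin.nbib"
        path.write_bytes("PMID- 7\nTI  - Caf\xe9 exposure study.\nDP  - 2001\nPT  - Review\n".encode("latin-1"))
        corpus = ev.read_nbib(path, product="P", topic="t")
        assert len(corpus) == 1

    def test_reader_never_invents_pub_types(self, nbib_file):
        text = nbib_file.read_text()
        corpus = ev.read_nbib(nbib_file, product="P", topic="asthma")
        for rec in corpus:
            for pt in rec.pub_types:
                assert pt in text


class TestReadRis:
    def test_jour_maps_to_journal_article(self, ris_file):
        corpus = ev.read_ris(ris_file, product="P", topic="co")
        assert corpus.records[0].pub_types == ["Journal Article"]

    def test_two_records(self, ris_file):
        corpus = ev.read_ris(ris_file, product="P", topic="co")
        assert len(corpus) == 2
        assert corpus.records[0].pmid == "555"
        assert corpus.records[1].pub_types == ["Technical Report"]
        assert corpus.records[1].source == "MMWR Morb Mortal Wkly Rep"

    def test_keywords_fill_mesh_slot(self, ris_file):
        corpus = ev.read_ris(ris_file, product="P", topic="co")
        assert corpus.records[0].mesh_terms == ["Carbon Monoxide Poisoning"]

    def test_duplicate_records_both_kept(self, tmp_path):
        block = "TY  - JOUR\nTI  - Same article twice.\nAU  - Xu L\nPY  - 2004\nER  -\n"
        path = tmp_path / "dup.ris"
        path.write_text(block + block)
        corpus = ev.read_ris(path, product="P", topic="t")
        assert len(corpus) == 2  # dedup is the overlap stage's job

    def test_mapped_types_come_from_documented_table(self, ris_file):
        corpus = ev.read_ris(ris_file, product="P", topic="co")
        for rec in corpus:
            for pt in rec.pub_types:
                assert pt in RIS_TYPE_MAP.values()


class TestAssignLocalId:
    def test_pmid_passthrough(self):
        rec = make_record(pmid="12345", local_id="x")
        assert ev.assign_local_id(rec) == "PMID:12345"

    def test_content_determinism(self):
        a = make_record(pmid=None, title="Airway responses to ozone.", year=2003)
        b = make_record(pmid=None, title="Airway responses to ozone.", year=2003)
        assert ev.assign_local_id(a) == ev.assign_local_id(b)

    def test_normalization_insensitive_to_punctuation_and_case(self):
        a = make_record(pmid=None, title="Airway responses to ozone.")
        b = make_record(pmid=None, title="airway  responses to ozone")
        assert ev.assign_local_id(a) == ev.assign_local_id(b)

    def test_url_only_record(self):
        a = make_record(pmid=None, title="", url="http://www.example.org/stats/", verified=False)
        b = make_record(pmid=None, title="", url="http://example.org/stats", verified=False)
        ida, idb = ev.assign_local_id(a), ev.assign_local_id(b)
        assert ida == idb
        assert ida.startswith("URL:")

    def test_bare_record_uses_source_and_ordinal(self):
        rec = make_record(pmid=None, title="", url=None, source="Some Office", verified=False)
        first = ev.assign_local_id(rec, ordinal=3)
        assert first.startswith("ANON:")
        assert first != ev.assign_local_id(rec, ordinal=4)

    @given(
        title=st.text(min_size=1, max_size=80),
        year=st.one_of(st.none(), st.integers(1900, 2020)),
        author=st.text(max_size=20),
    )
    def test_identifier_is_pure_function_of_content(self, title, year, author):
        a = make_record(pmid=None, title=title, year=year, first_author=author)
        b = make_record(pmid=None, title=title, year=year, first_author=author)
        assert ev.assign_local_id(a) == ev.assign_local_id(b)


class TestWriteCorpus:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_identity(self, tmp_path, seed):
        spec = ev.random_corpus_spec(seed)
        for corpus in ev.generate_corpora(spec)[:3]:
            path = tmp_path / f"{seed}_{corpus.product}_{corpus.topic}.nbib"
            ev.write_corpus(corpus, path)
            back = ev.read_nbib(path, corpus.product, corpus.topic)
            assert back == corpus

    def test_empty_corpus(self, tmp_path):
        path = tmp_path / "empty.nbib"
        ev.write_corpus(ev.Corpus(product="P", topic="t"), path)
        assert len(ev.read_nbib(path, "P", "t")) == 0

    def test_byte_stable_across_writes(self, tmp_path):
        corpus = ev.generate_corpora(ev.random_corpus_spec(5))[0]
        p1, p2 = tmp_path / "a.nbib", tmp_path / "b.nbib"
        ev.write_corpus(corpus, p1)
        ev.write_corpus(corpus, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestCombineCorpora:
    def test_merges_per_product(self):
        corpora = ev.generate_corpora(ev.random_corpus_spec(9))
        merged = ev.combine_corpora(corpora)
        assert len({c.product for c in merged}) == len(merged)
        assert sum(len(c) for c in merged) == sum(len(c) for c in corpora)
        for c in merged:
            assert c.topic == ev.ALL_TOPICS


class TestValidation:
    def test_bad_pmid_rejected(self):
        with pytest.raises(ValueError, match="pmid"):
            make_record(pmid="123456789", local_id="x").validate()

    def test_year_range_enforced(self):
        with pytest.raises(ValueError, match="year"):
            make_record(year=1750).validate()

    def test_duplicate_local_id_rejected(self):
        rec = make_record()
        corpus = ev.Corpus(product="ProductA", topic="asthma", records=[rec, rec])
        with pytest.raises(ValueError, match="duplicate"):
            corpus.validate()
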