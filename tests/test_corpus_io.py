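import pytest
from lxml import etree

from pkddi import corpus_io, synthetic
from pkddi.corpus_io import (DDIPairAnnotation, Document, Sentence,
                             corpus_stats, read_corpus_xml,
                             read_pubmed_xml, render_html, split_sentences,
                             split_spans, to_unified_xml, write_corpus_xml)
from pkddi.tagger import KeyTerm, Span


def make_sentence(index, text, terms, label="NONE", pairs=()):
    key_terms = [KeyTerm(Span(index, s, e, text[s:e]), cat, norm)
                 for s, e, cat, norm in terms]
    return Sentence(index, text, key_terms, label, list(pairs))


class TestSplitSentences:
    def test_basic_split(self):
        assert split_sentences("A is B. C is D.") == ["A is B.", "C is D."]

    def test_decimal_point_not_boundary(self):
        out = split_sentences("The dose (0.05 mg/kg) was given. Next day "
                              "it was repeated.")
        assert len(out) == 2
        assert out[0].endswith("was given.")

    def test_abbreviation_guard(self):
        text = "Cmax was 9.0 ng/mL (P≤0.05) vs. control."
        assert split_sentences(text) == [text]

    def test_spans_reconstruct_input(self):
        text = "First sentence. Second one! And a third? Done."
        spans = split_spans(text)
        assert "".join(text[s:e] for s, e in spans) == text

    def test_empty(self):
        assert split_sentences("") == []


PUBMED_XML = """<?xml version="1.0"?>
<PubmedArticleSet>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>101</PMID>
      <Article>
        <ArticleTitle>Interaction study.</ArticleTitle>
        <Abstract>
          <AbstractText>Verapamil was given. The AUC increased.</AbstractText>
        </Abstract>
      </Article>
    </MedlineCitation>
  </PubmedArticle>
  <PubmedArticle>
    <MedlineCitation>
      <PMID>102</PMID>
      <Article><ArticleTitle>No abstract here.</ArticleTitle></Article>
    </MedlineCitation>
  </PubmedArticle>
</PubmedArticleSet>
"""


class TestPubmedXML:
    def test_single_record_with_pmid(self, tmp_path):
        path = tmp_path / "pm.xml"
        path.write_text(PUBMED_XML)
        docs, warnings = read_pubmed_xml(path)
        assert [d.pmid for d in docs] == ["101"]
        assert len(warnings) == 1 and "102" in warnings[0]

    def test_title_prepended_and_split(self, tmp_path):
        path = tmp_path / "pm.xml"
        path.write_text(PUBMED_XML)
        docs, _ = read_pubmed_xml(path)
        texts = [s.text for s in docs[0].sentences]
        assert texts == ["Interaction study.", "Verapamil was given.",
                         "The AUC increased."]

    def test_malformed_xml_raises(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<PubmedArticleSet><oops>")
        with pytest.raises(etree.XMLSyntaxError):
            read_pubmed_xml(path)


class TestCorpusRoundTrip:
    def test_synthetic_corpus_round_trip(self, tmp_path, small_corpus):
        docs, _ = small_corpus
        path = tmp_path / "c.xml"
        write_corpus_xml(docs, path)
        assert read_corpus_xml(path) == docs

    def test_round_trip_includes_vddis_context_pairs(self, tmp_path):
        docs, _ = synthetic.generate_corpus(
            synthetic.GenConfig(n_documents=40, seed=3))
        labels = [s.ddi_label for d in docs for s in d.sentences]
        assert "VDDIS" in labels  # the fixture must exercise the case
        path = tmp_path / "v.xml"
        write_corpus_xml(docs, path)
        assert read_corpus_xml(path) == docs

    def test_overlapping_spans_rejected(self, tmp_path):
        text = "verapamil inhibited CYP3A4"
        sent = make_sentence(0, text, [(0, 9, "DRUG", "verapamil"),
                                       (5, 14, "MECHANISM", "inhibit")])
        doc = Document("1", "t", [sent])
        with pytest.raises(ValueError, match="overlap"):
            write_corpus_xml([doc], tmp_path / "x.xml")

    def test_hand_written_minimal_file(self, tmp_path):
        xml = """<?xml version="1.0" encoding="utf-8"?>
<pkcorpus version="1.0">
  <document pmid="7" study_class="in_vivo_ddi">
    <title>t</title>
    <sentence index="0" ddi_label="CDDIS">
      <text>verapamil altered lovastatin</text>
      <term id="t0" category="DRUG" start="0" end="9" normal="verapamil"/>
      <term id="t1" category="DRUG" start="18" end="28" normal="lovastatin"/>
      <pair a="t0" b="t1" relation="DDI"/>
    </sentence>
  </document>
</pkcorpus>
"""
        path = tmp_path / "m.xml"
        path.write_text(xml)
        (doc,) = read_corpus_xml(path)
        assert doc.pmid == "7"
        (sent,) = doc.sentences
        assert sent.ddi_label == "CDDIS"
        assert [t.normal_form for t in sent.key_terms] == ["verapamil",
                                                           "lovastatin"]
        assert sent.pairs == [DDIPairAnnotation("t0", "t1", "DDI")]

    def test_schema_violation_reports_location(self, tmp_path):
        xml = """<pkcorpus version="1.0">
  <document pmid="7">
    <title>t</title>
    <sentence index="0" ddi_label="NONE">
      <text>short</text>
      <term id="t0" category="DRUG" start="0" end="99" normal="x"/>
    </sentence>
  </document>
</pkcorpus>
"""
        path = tmp_path / "bad.xml"
        path.write_text(xml)
        with pytest.raises(ValueError, match="sentence"):
            read_corpus_xml(path)


class TestUnifiedXML:
    def _unified(self, tmp_path, sentences):
        doc = Document("1", "t", sentences, study_class="in_vivo_ddi")
        path = tmp_path / "u.xml"
        to_unified_xml([doc], path)
        return etree.parse(str(path))

    def test_annotated_pair_is_true(self, tmp_path):
        text = "verapamil significantly altered lovastatin"
        sent = make_sentence(
            0, text,
            [(0, 9, "DRUG", "verapamil"), (32, 42, "DRUG", "lovastatin")],
            "CDDIS", [DDIPairAnnotation("t0", "t1", "DDI")])
        tree = self._unified(tmp_path, [sent])
        pairs = tree.findall(".//pair")
        assert len(pairs) == 1
        assert pairs[0].get("interaction") == "true"

    def test_single_entity_no_pairs(self, tmp_path):
        sent = make_sentence(0, "verapamil alone",
                             [(0, 9, "DRUG", "verapamil")])
        tree = self._unified(tmp_path, [sent])
        assert tree.findall(".//pair") == []

    def test_three_unannotated_entities_three_false_pairs(self, tmp_path):
        text = "verapamil midazolam lovastatin"
        sent = make_sentence(0, text,
                             [(0, 9, "DRUG", "verapamil"),
                              (10, 19, "DRUG", "midazolam"),
                              (20, 30, "DRUG", "lovastatin")])
        tree = self._unified(tmp_path, [sent])
        pairs = tree.findall(".//pair")
        assert len(pairs) == 3
        assert {p.get("interaction") for p in pairs} == {"false"}

    def test_char_offsets_half_open(self, tmp_path):
        text = "verapamil altered lovastatin"
        sent = make_sentence(
            0, text,
            [(0, 9, "DRUG", "verapamil"), (18, 28, "DRUG", "lovastatin")],
            "CDDIS", [DDIPairAnnotation("t0", "t1", "DDI")])
        tree = self._unified(tmp_path, [sent])
        ent = tree.findall(".//entity")[0]
        assert ent.get("charOffset") == "0-9"
        assert ent.get("text") == "verapamil"


class TestRenderHTML:
    def test_all_categories_styled(self, tmp_path, small_corpus):
        docs, _ = small_corpus
        path = tmp_path / "view.html"
        render_html(docs, path)
        html = path.read_text()
        for category in ("drug", "enzyme", "pk_parameter", "number",
                         "mechanism", "change"):
            assert f"kt-{category}" in html
        assert "sent-cddis" in html

    def test_empty_document_valid(self, tmp_path):
        path = tmp_path / "empty.html"
        render_html([], path)
        text = path.read_text()
        assert text.startswith("<!DOCTYPE html>") and "</html>" in text


class TestStats:
    def test_counts_match_generator_tally(self, small_corpus):
        docs, tally = small_corpus
        assert corpus_stats(docs) == tally

    def test_additive_over_concatenation(self, small_corpus):
        docs, _ = small_corpus
        half = len(docs) // 2
        a = corpus_stats(docs[:half])
        b = corpus_stats(docs[half:])
        combined = corpus_stats(docs)

        def add(x, y):
            if isinstance(x, dict):
                return {k: add(x.get(k, 0), y.get(k, 0))
                        for k in set(x) | set(y)}
            return x + y

        assert add(a, b) == combined

    def test_drug_term_count(self):
        text = "verapamil midazolam lovastatin"
        sent = make_sentence(0, text,
                             [(0, 9, "DRUG", "verapamil"),
                              (10, 19, "DRUG", "midazolam"),
                              (20, 30, "DRUG", "lovastatin")])
        stats = corpus_stats([Document("1", "t", [sent])])
        assert stats["terms"]["DRUG"] == 3
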