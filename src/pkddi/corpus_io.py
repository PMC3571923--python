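"""Corpus documents, three-level annotations, and their file formats.

The annotation hierarchy has three levels: key terms inside sentences,
sentence-level interaction labels (NONE / CDDIS / VDDIS), and relation
labels on entity pairs.  This module reads raw PubMed abstract XML, reads
and writes the annotated-corpus XML dialect (a versioned schema with the
same document -> sentence -> term/pair structure used by GENIA-style
corpora), converts to the unified relation-extraction XML layout
(document/sentence/entity/pair with character offsets), renders a colored
HTML view, and computes frequency statistics.

Character offsets are 0-based half-open within each sentence, everywhere.
"""

from __future__ import annotations

import html as _html
import re
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from ._tokenize import token_texts
from .tagger import KeyTerm, Span, select_entities

__all__ = [
    "Sentence", "Document", "DDIPairAnnotation",
    "SENTENCE_LABELS", "STUDY_CLASSES",
    "read_pubmed_xml", "split_sentences", "split_spans",
    "write_corpus_xml", "read_corpus_xml", "to_unified_xml",
    "render_html", "corpus_stats",
]

SENTENCE_LABELS = ("NONE", "CDDIS", "VDDIS")
STUDY_CLASSES = ("in_vivo_pk", "in_vivo_pg", "in_vivo_ddi", "in_vitro_ddi")

# context partner reference for VDDIS pairs: "ctx:<sentence index>:<term id>"
_CTX_RE = re.compile(r"^ctx:\d+:t\d+$")
_TERM_RE = re.compile(r"^t\d+$")


@dataclass
class DDIPairAnnotation:
    """A relation label on a pair of entities.

    ``entity_a``/``entity_b`` name key terms of the owning sentence by id
    ("t3"), or — for vague-DDI sentences whose partner lives elsewhere in
    the abstract — a context marker "ctx:<sentence>:<term>".
    """

    entity_a: str
    entity_b: str
    relation: str
    evidence: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        from .relation_rules import RelationLabel
        if self.relation not in RelationLabel.ALL[:-1]:
            raise ValueError(f"bad pair relation {self.relation!r}")
        for ref in (self.entity_a, self.entity_b):
            if not (_TERM_RE.match(ref) or _CTX_RE.match(ref)):
                raise ValueError(f"bad entity reference {ref!r}")


@dataclass
class Sentence:
    index: int
    text: str
    key_terms: list[KeyTerm] = field(default_factory=list)
    ddi_label: str = "NONE"
    pairs: list[DDIPairAnnotation] = field(default_factory=list)

    def term_id(self, term: KeyTerm) -> str:
        return f"t{self.key_terms.index(term)}"

    def term(self, ref: str) -> KeyTerm:
        return self.key_terms[int(ref[1:])]

    def validate(self) -> None:
        if self.ddi_label not in SENTENCE_LABELS:
            raise ValueError(f"bad sentence label {self.ddi_label!r}")
        if self.pairs and self.ddi_label == "NONE":
            raise ValueError(
                f"sentence {self.index}: pairs on an unlabeled sentence")
        n = len(self.text)
        prev_end = -1
        for t in sorted(self.key_terms, key=lambda t: t.span.start):
            if t.span.end > n:
                raise ValueError(
                    f"sentence {self.index}: span beyond sentence end")
            if t.span.text != self.text[t.span.start:t.span.end]:
                raise ValueError(
                    f"sentence {self.index}: span text mismatch at "
                    f"{t.span.start}")
            if t.span.start < prev_end:
                raise ValueError(
                    f"sentence {self.index}: overlapping spans")
            prev_end = t.span.end
        for p in self.pairs:
            for ref in (p.entity_a, p.entity_b):
                if _TERM_RE.match(ref) and int(ref[1:]) >= len(self.key_terms):
                    raise ValueError(
                        f"sentence {self.index}: dangling term ref {ref}")


@dataclass
class Document:
    pmid: str
    title: str
    sentences: list[Sentence] = field(default_factory=list)
    study_class: str | None = None

    def validate(self) -> None:
        if not self.pmid:
            raise ValueError("document without pmid")
        if self.study_class is not None and \
                self.study_class not in STUDY_CLASSES:
            raise ValueError(f"bad study class {self.study_class!r}")
        for i, s in enumerate(self.sentences):
            if s.index != i:
                raise ValueError(
                    f"pmid {self.pmid}: sentence indices not consecutive")
            s.validate()


# ---------------------------------------------------------------------------
# Sentence splitting
# ---------------------------------------------------------------------------

# tokens before a period that do not end a sentence
_ABBREVIATIONS = {
    "e.g", "i.e", "vs", "etc", "cf", "ca", "approx", "al", "fig", "figs",
    "dr", "prof", "st", "no", "resp",
    # dosing-route and unit abbreviations common in PK abstracts
    "i.p", "i.v", "p.o", "s.c", "b.i.d", "t.i.d", "q.d", "h", "hr", "min",
    "sec", "mg", "kg", "ml", "ml/min", "wk", "mo",
}

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")


def _is_boundary(text: str, match_start: int, match_end: int) -> bool:
    before = text[:match_start]
    m = re.search(r"([\w./-]+)$", before)
    if m:
        word = m.group(1).lower().rstrip(".")
        if word in _ABBREVIATIONS or word.rstrip(".") in _ABBREVIATIONS:
            return False
    after = text[match_end:].lstrip()
    if after and not re.match(r"[A-Z0-9(\[\"']", after):
        return False
    return True


def split_spans(text: str) -> list[tuple[int, int]]:
    """Sentence spans covering all of ``text``; joining the slices
    reconstructs the input exactly."""
    if not text:
        return []
    bounds = [m.end() for m in _BOUNDARY_RE.finditer(text)
              if _is_boundary(text, m.start(), m.end())]
    spans = []
    start = 0
    for b in bounds:
        spans.append((start, b))
        start = b
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def split_sentences(text: str) -> list[str]:
    """Deterministic sentence splitting with an abbreviation guard list.

    Decimal points, p-values ("P=.26"), dosing abbreviations ("i.p.") and
    similar are not boundaries.
    """
    return [text[s:e].strip() for s, e in split_spans(text)
            if text[s:e].strip()]


# ---------------------------------------------------------------------------
# PubMed abstract XML
# ---------------------------------------------------------------------------

def read_pubmed_xml(path: str | Path) -> tuple[list[Document], list[str]]:
    """Read a PubmedArticleSet file into unannotated documents.

    Title and abstract are concatenated into the sentence source text.
    Records without an abstract are skipped; their pmids are returned in
    the warning list.
    """
    tree = etree.parse(str(path))
    documents: list[Document] = []
    warnings: list[str] = []
    for article in tree.iter("PubmedArticle"):
        pmid_el = article.find(".//PMID")
        pmid = pmid_el.text.strip() if pmid_el is not None and pmid_el.text \
            else ""
        title_el = article.find(".//ArticleTitle")
        title = "".join(title_el.itertext()).strip() \
            if title_el is not None else ""
        abstract_parts = ["".join(el.itertext()).strip()
                          for el in article.findall(".//AbstractText")]
        abstract = " ".join(p for p in abstract_parts if p)
        if not abstract:
            warnings.append(f"record {pmid or '<no pmid>'} has no abstract; "
                            "skipped")
            continue
        source = (title + " " + abstract).strip() if title else abstract
        sentences = [Sentence(i, s)
                     for i, s in enumerate(split_sentences(source))]
        documents.append(Document(pmid=pmid, title=title,
                                  sentences=sentences))
    return documents, warnings


# ---------------------------------------------------------------------------
# Corpus XML (versioned schema, three annotation levels)
# ---------------------------------------------------------------------------

_SCHEMA_VERSION = "1.0"


def _term_to_xml(parent: etree._Element, tid: str, t: KeyTerm) -> None:
    el = etree.SubElement(parent, "term", id=tid, category=t.category,
                          start=str(t.span.start), end=str(t.span.end))
    el.set("normal", t.normal_form)
    if t.unit is not None:
        el.set("unit", t.unit)
    if t.value is not None:
        el.set("value", repr(t.value))
    if t.is_pvalue:
        el.set("pvalue", "true")
    if t.p_relation is not None:
        el.set("prelation", t.p_relation)
    if t.parent is not None:
        el.set("parent", t.parent)


def _term_from_xml(el: etree._Element, sent_index: int, text: str) -> KeyTerm:
    start, end = int(el.get("start")), int(el.get("end"))
    value = el.get("value")
    return KeyTerm(
        span=Span(sent_index, start, end, text[start:end]),
        category=el.get("category"),
        normal_form=el.get("normal"),
        unit=el.get("unit"),
        value=float(value) if value is not None else None,
        is_pvalue=el.get("pvalue") == "true",
        p_relation=el.get("prelation"),
        parent=el.get("parent"),
    )


def write_corpus_xml(documents: list[Document], path: str | Path) -> None:
    """Write annotated documents; :func:`read_corpus_xml` round-trips them
    losslessly."""
    root = etree.Element("pkcorpus", version=_SCHEMA_VERSION)
    for doc in documents:
        doc.validate()
        del_ = etree.SubElement(root, "document", pmid=doc.pmid)
        if doc.study_class:
            del_.set("study_class", doc.study_class)
        etree.SubElement(del_, "title").text = doc.title
        for sent in doc.sentences:
            sel = etree.SubElement(del_, "sentence", index=str(sent.index),
                                   ddi_label=sent.ddi_label)
            etree.SubElement(sel, "text").text = sent.text
            for i, t in enumerate(sent.key_terms):
                _term_to_xml(sel, f"t{i}", t)
            for p in sent.pairs:
                pel = etree.SubElement(sel, "pair", a=p.entity_a,
                                       b=p.entity_b, relation=p.relation)
                if p.evidence:
                    pel.set("evidence", " ".join(p.evidence))
    etree.ElementTree(root).write(str(path), encoding="utf-8",
                                  xml_declaration=True, pretty_print=True)


def read_corpus_xml(path: str | Path) -> list[Document]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != "pkcorpus":
        raise ValueError(f"{path}: not a pkcorpus file (root <{root.tag}>)")
    documents = []
    for del_ in root.iter("document"):
        doc = Document(pmid=del_.get("pmid", ""),
                       title=(del_.findtext("title") or ""),
                       study_class=del_.get("study_class"))
        for sel in del_.iter("sentence"):
            idx = int(sel.get("index"))
            text = sel.findtext("text") or ""
            sent = Sentence(idx, text, ddi_label=sel.get("ddi_label", "NONE"))
            try:
                for tel in sel.iter("term"):
                    sent.key_terms.append(_term_from_xml(tel, idx, text))
                for pel in sel.iter("pair"):
                    ev = tuple((pel.get("evidence") or "").split()) or ()
                    sent.pairs.append(DDIPairAnnotation(
                        pel.get("a"), pel.get("b"), pel.get("relation"), ev))
                sent.validate()
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{sel.sourceline}: <sentence>: {exc}") from exc
            doc.sentences.append(sent)
        try:
            doc.validate()
        except ValueError as exc:
            raise ValueError(
                f"{path}:{del_.sourceline}: <document>: {exc}") from exc
        documents.append(doc)
    return documents


# ---------------------------------------------------------------------------
# Unified relation-extraction XML
# ---------------------------------------------------------------------------

def to_unified_xml(documents: list[Document], path: str | Path,
                   collapse=None) -> None:
    """Convert to the unified entity/pair layout used by relation
    extraction systems.

    Every sentence with at least two pairable entities (metabolites
    removed, enzymes kept, synonym mentions collapsed) emits all unordered
    entity pairs; ``collapse`` maps a relation label to the binary
    ``interaction`` attribute (default: DDI and DEI are true, everything
    else false).
    """
    if collapse is None:
        from .extractor import collapse_labels as collapse
    root = etree.Element("corpus", source="pkddi")
    for d_i, doc in enumerate(documents):
        del_ = etree.SubElement(root, "document", id=f"d{d_i}",
                                origId=doc.pmid)
        for sent in doc.sentences:
            sid = f"d{d_i}.s{sent.index}"
            sel = etree.SubElement(del_, "sentence", id=sid, text=sent.text)
            entities = select_entities(sent.key_terms)
            ids = {}
            for e_i, t in enumerate(entities):
                eid = f"{sid}.e{e_i}"
                ids[sent.term_id(t)] = eid
                etree.SubElement(
                    sel, "entity", id=eid,
                    charOffset=f"{t.span.start}-{t.span.end}",
                    type="enzyme" if t.category == "ENZYME" else "drug",
                    text=t.span.text)
            if len(entities) < 2:
                continue
            # relations annotated on this sentence, by unordered normal pair
            annotated = {}
            for p in sent.pairs:
                refs = (p.entity_a, p.entity_b)
                if all(_TERM_RE.match(r) for r in refs):
                    key = frozenset(sent.term(r).normal_form for r in refs)
                    annotated[key] = p.relation
            p_i = 0
            for i in range(len(entities)):
                for j in range(i + 1, len(entities)):
                    key = frozenset({entities[i].normal_form,
                                     entities[j].normal_form})
                    rel = annotated.get(key, "NONE")
                    etree.SubElement(
                        sel, "pair", id=f"{sid}.p{p_i}",
                        e1=ids[sent.term_id(entities[i])],
                        e2=ids[sent.term_id(entities[j])],
                        interaction="true" if collapse(rel) else "false")
                    p_i += 1
    etree.ElementTree(root).write(str(path), encoding="utf-8",
                                  xml_declaration=True, pretty_print=True)


# ---------------------------------------------------------------------------
# HTML rendering
# ---------------------------------------------------------------------------

_CSS = """
body { font-family: sans-serif; max-width: 60em; margin: 2em auto; }
.kt-drug { background: #cce5ff; }
.kt-metabolite { background: #e2d9f3; }
.kt-enzyme { background: #d4edda; }
.kt-pk_parameter { background: #fff3cd; }
.kt-number { background: #f8d7da; }
.kt-mechanism { background: #ffe5d0; }
.kt-change { background: #d1ecf1; }
.sent-cddis { border-left: 4px solid #28a745; padding-left: .5em; }
.sent-vddis { border-left: 4px solid #ffc107; padding-left: .5em; }
.sent-none { padding-left: calc(.5em + 4px); }
"""


def render_html(documents: list[Document], path: str | Path) -> None:
    """Render the corpus with one color class per key-term category and a
    sentence-level highlight for DDI sentences."""
    parts = ["<!DOCTYPE html>", "<html><head><meta charset='utf-8'>",
             f"<style>{_CSS}</style></head><body>"]
    for doc in documents:
        parts.append(f"<h2>PMID {_html.escape(doc.pmid)}</h2>")
        for sent in doc.sentences:
            cls = f"sent-{sent.ddi_label.lower()}"
            chunks = [f"<p class='{cls}'>"]
            pos = 0
            for t in sorted(sent.key_terms, key=lambda t: t.span.start):
                chunks.append(_html.escape(sent.text[pos:t.span.start]))
                chunks.append(
                    f"<span class='kt-{t.category.lower()}' "
                    f"title='{_html.escape(t.normal_form)}'>"
                    f"{_html.escape(t.span.text)}</span>")
                pos = t.span.end
            chunks.append(_html.escape(sent.text[pos:]))
            chunks.append("</p>")
            parts.append("".join(chunks))
    parts.append("</body></html>")
    Path(path).write_text("\n".join(parts), encoding="utf-8")


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def corpus_stats(documents: list[Document]) -> dict:
    """Frequency table over the three annotation levels.

    Word totals are reported both as whitespace tokens and as tokenizer
    tokens.  ``total_pairs`` counts all unordered pairable-entity pairs
    within DDI sentences (CDDIS or VDDIS).
    """
    stats = {
        "terms": {c: 0 for c in ("DRUG", "METABOLITE", "ENZYME",
                                 "PK_PARAMETER", "NUMBER", "MECHANISM",
                                 "CHANGE")},
        "sentences": {label: 0 for label in SENTENCE_LABELS},
        "relations": {},
        "total_documents": len(documents),
        "total_sentences": 0,
        "total_words_whitespace": 0,
        "total_words_tokens": 0,
        "total_pairs": 0,
    }
    for doc in documents:
        for sent in doc.sentences:
            stats["total_sentences"] += 1
            stats["total_words_whitespace"] += len(sent.text.split())
            stats["total_words_tokens"] += len(token_texts(sent.text))
            stats["sentences"][sent.ddi_label] += 1
            for t in sent.key_terms:
                stats["terms"][t.category] += 1
            for p in sent.pairs:
                stats["relations"][p.relation] = \
                    stats["relations"].get(p.relation, 0) + 1
            if sent.ddi_label != "NONE":
                n = len(select_entities(sent.key_terms))
                stats["total_pairs"] += n * (n - 1) // 2
    return stats
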