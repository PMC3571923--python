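"""Inter-annotator reliability via Krippendorff's alpha (nominal metric).

alpha = 1 - Do/De, where Do is the observed disagreement taken from the
coincidence matrix of pairable values and De the disagreement expected by
chance.  Units annotated by a single annotator are not pairable and are
excluded; missing labels are permitted.  Three unit sets are derived from
annotated corpora: token-level key-term categories, sentence-level DDI
labels, and pair-level relation labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable

import numpy as np

from ._tokenize import tokenize
from .corpus_io import Document
from .tagger import select_entities

__all__ = ["AnnotationUnit", "ReliabilityResult", "krippendorff_alpha",
           "units_from_corpus"]


@dataclass(frozen=True)
class AnnotationUnit:
    unit_id: Hashable
    annotator_id: str
    label: Hashable


@dataclass
class ReliabilityResult:
    alpha: float
    observed_disagreement: float
    expected_disagreement: float
    n_pairable: int


def krippendorff_alpha(units: Iterable[AnnotationUnit], *,
                       degenerate: str = "one") -> ReliabilityResult:
    """Nominal-metric Krippendorff's alpha from a flat unit list.

    ``degenerate`` controls the zero-expected-disagreement case (every
    pairable value carries one common label): "one" defines alpha = 1.0,
    "error" raises.
    """
    by_unit: dict[Hashable, list[Hashable]] = {}
    seen: set[tuple[Hashable, str]] = set()
    for u in units:
        key = (u.unit_id, u.annotator_id)
        if key in seen:
            raise ValueError(f"duplicate (unit, annotator) {key!r}")
        seen.add(key)
        by_unit.setdefault(u.unit_id, []).append(u.label)

    pairable = {uid: labels for uid, labels in by_unit.items()
                if len(labels) >= 2}
    if not pairable:
        raise ValueError("insufficient overlap: no unit has two annotators")

    values = sorted({lab for labels in pairable.values() for lab in labels},
                    key=repr)
    index = {v: i for i, v in enumerate(values)}
    k = len(values)
    coincidence = np.zeros((k, k))
    for labels in pairable.values():
        m = len(labels)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i != j:
                    coincidence[index[a], index[b]] += 1.0 / (m - 1)

    n = coincidence.sum()
    n_c = coincidence.sum(axis=1)
    observed = (n - np.trace(coincidence)) / n
    expected = (n * n - (n_c ** 2).sum()) / (n * (n - 1))

    if expected == 0.0:
        if degenerate == "error":
            raise ValueError("expected disagreement is zero (single label)")
        return ReliabilityResult(1.0, float(observed), 0.0, int(round(n)))
    alpha = 1.0 - observed / expected
    return ReliabilityResult(float(alpha), float(observed), float(expected),
                             int(round(n)))


def units_from_corpus(
        corpora: dict[str, list[Document]],
) -> tuple[list[AnnotationUnit], list[AnnotationUnit],
           list[AnnotationUnit]]:
    """Derive the three unit sets from per-annotator corpora.

    * term level: one unit per token, labeled with the covering key-term
      category or "O";
    * sentence level: one unit per sentence, labeled NONE/CDDIS/VDDIS;
    * pair level: one unit per candidate entity pair in any sentence some
      annotator marked CDDIS/VDDIS; annotators who did not annotate the
      pair contribute the label NONE.

    Annotators may lack documents (those units are simply absent for
    them), but shared documents must have identical sentence texts —
    tokenization is shared, so diverging text means diverging units.
    """
    by_annotator = {ann: {d.pmid: d for d in docs}
                    for ann, docs in corpora.items()}
    all_pmids = sorted({p for docs in by_annotator.values() for p in docs})

    # alignment check
    for pmid in all_pmids:
        texts = {}
        for ann, docs in by_annotator.items():
            if pmid in docs:
                texts[ann] = [s.text for s in docs[pmid].sentences]
        ref_ann = next(iter(texts))
        for ann, sent_texts in texts.items():
            if sent_texts != texts[ref_ann]:
                diverge = next(
                    (i for i, (a, b) in enumerate(
                        zip(sent_texts, texts[ref_ann])) if a != b),
                    min(len(sent_texts), len(texts[ref_ann])))
                raise ValueError(
                    f"tokenization mismatch: pmid {pmid}, sentence "
                    f"{diverge} differs between annotators "
                    f"{ann!r} and {ref_ann!r}")

    term_units: list[AnnotationUnit] = []
    sentence_units: list[AnnotationUnit] = []
    pair_units: list[AnnotationUnit] = []

    # sentence-level DDI flags across annotators, for the pair universe
    ddi_sentences: set[tuple[str, int]] = set()
    for ann, docs in by_annotator.items():
        for pmid, doc in docs.items():
            for sent in doc.sentences:
                if sent.ddi_label != "NONE":
                    ddi_sentences.add((pmid, sent.index))

    # candidate pair universe per DDI sentence: union over annotators of
    # unordered canonical entity pairs
    universe: dict[tuple[str, int], set[frozenset]] = {}
    for ann, docs in by_annotator.items():
        for pmid, doc in docs.items():
            for sent in doc.sentences:
                if (pmid, sent.index) not in ddi_sentences:
                    continue
                ents = [t.normal_form
                        for t in select_entities(sent.key_terms)]
                pairs = universe.setdefault((pmid, sent.index), set())
                for i in range(len(ents)):
                    for j in range(i + 1, len(ents)):
                        if ents[i] != ents[j]:
                            pairs.add(frozenset({ents[i], ents[j]}))

    for ann, docs in by_annotator.items():
        for pmid, doc in docs.items():
            for sent in doc.sentences:
                for tok_idx, tok in enumerate(tokenize(sent.text)):
                    label = "O"
                    for t in sent.key_terms:
                        if t.span.start < tok.end and tok.start < t.span.end:
                            label = t.category
                            break
                    term_units.append(AnnotationUnit(
                        (pmid, sent.index, tok_idx), ann, label))
                sentence_units.append(AnnotationUnit(
                    (pmid, sent.index), ann, sent.ddi_label))
                key = (pmid, sent.index)
                if key in universe:
                    annotated = {}
                    for p in sent.pairs:
                        try:
                            ents = frozenset({
                                sent.term(p.entity_a).normal_form,
                                sent.term(p.entity_b).normal_form})
                        except (IndexError, ValueError):
                            continue  # context pairs have no in-sentence key
                        annotated[ents] = p.relation
                    for pair_key in universe[key]:
                        pair_units.append(AnnotationUnit(
                            (pmid, sent.index, tuple(sorted(pair_key))),
                            ann, annotated.get(pair_key, "NONE")))

    return term_units, sentence_units, pair_units
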