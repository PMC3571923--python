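"""Synthetic, fully ground-truthed corpora and the worked-example fixtures.

Two things live here:

* :func:`table9` — the eight published worked examples of the relation
  definitions, as structured candidates with their printed labels (the
  primary validation surface of the rule classifier);
* :func:`generate_corpus` — a seeded generator producing annotated
  abstracts from templates modeled on those examples, with evidence drawn
  to land in chosen rule bands, so every annotation is correct by
  construction and every count is known.  It covers the four study classes
  (clinical PK, clinical pharmacogenetics, in vivo DDI, in vitro DDI).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .corpus_io import DDIPairAnnotation, Document, Sentence
from .relation_rules import (CueEvidence, InteractionCandidate,
                             QuantEvidence, RelationLabel)
from .tagger import KeyTerm, Span

__all__ = [
    "GenConfig", "generate_corpus", "candidates_from_corpus",
    "Table9Fixture", "Table9Pair", "table9",
    "write_evidence_file", "read_evidence_file",
]


# ---------------------------------------------------------------------------
# Worked examples
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table9Pair:
    candidate: InteractionCandidate
    label: str
    note: str = ""


@dataclass(frozen=True)
class Table9Fixture:
    pmid: str
    sentence: str
    pairs: tuple[Table9Pair, ...]


def table9() -> list[Table9Fixture]:
    """The eight published worked examples, with structured evidence.

    The seventh example prints the pair (YM758, CYP1A2) twice; both printed
    pairs are kept and a corrected (YM758, CYP3A4) variant is added, all
    NDEI.
    """
    Q, C, Cue = QuantEvidence, InteractionCandidate, CueEvidence
    rows = [
        Table9Fixture(
            "20012601",
            "The pharmacokinetic parameters of verapamil were significantly "
            "altered by the co-administration of lovastatin compared to the "
            "control.",
            (Table9Pair(
                C("verapamil", "lovastatin",
                  cues=(Cue("definite", "significantly"),)),
                RelationLabel.DDI),)),
        Table9Fixture(
            "20209646",
            "The clearance of mitoxantrone and etoposide was decreased by "
            "64% and 60%, respectively, when combined with valspodar.",
            (Table9Pair(
                C("mitoxantrone", "valspodar",
                  quant=(Q("CL", "percent_change", 64.0,
                           direction="decrease"),)),
                RelationLabel.DDI),
             Table9Pair(
                C("etoposide", "valspodar",
                  quant=(Q("CL", "percent_change", 60.0,
                           direction="decrease"),)),
                RelationLabel.DDI))),
        Table9Fixture(
            "20012601",
            "The (AUC (0-infinity)) of norverapamil and the terminal "
            "half-life of verapamil did not significantly changed with "
            "lovastatin coadministration.",
            (Table9Pair(
                C("verapamil", "lovastatin",
                  cues=(Cue("negative", "not significantly changed"),)),
                RelationLabel.NDDI),)),
        Table9Fixture(
            "17304149",
            "Compared with placebo, itraconazole treatment significantly "
            "increase the peak plasma concentration (Cmax) of paroxetine by "
            "1.3 fold (6.7 2.5 versus 9.0 3.3 ng/mL, P≤0.05) and the area "
            "under the plasma concentration-time curve from zero to 48 "
            "hours [AUC(0-48)] of paroxetine by 1.5 fold (137 73 versus "
            "199 91 ng*h/mL, P≤0.01).",
            (Table9Pair(
                C("itraconazole", "paroxetine",
                  quant=(Q("Cmax", "fold_change", 1.3, 0.05, "le"),
                         Q("AUC", "fold_change", 1.5, 0.01, "le")),
                  cues=(Cue("definite", "significantly increase"),)),
                RelationLabel.DDI,
                note="AUC outranks Cmax; the printed 1.5-fold value sits "
                     "on the band boundary and the definite cue decides"),)),
        Table9Fixture(
            "13129991",
            "The mean (SD) urinary ratio of dextromethorphan to its "
            "metabolite was 0.006 (0.010) at baseline and 0.014 (0.025) "
            "after St John's wort administration (P=.26)",
            (Table9Pair(
                C("dextromethorphan", "st john's wort",
                  quant=(Q("MR", "fold_change", 0.014 / 0.006,
                           0.26, "eq"),)),
                RelationLabel.ADDI,
                note="metabolic ratio is unranked; >1.5-fold change with "
                     "p > 0.05"),)),
        Table9Fixture(
            "19904008",
            "The obtained results show that perazine at its therapeutic "
            "concentrations is a potent inhibitor of human CYP1A2.",
            (Table9Pair(
                C("perazine", "CYP1A2", setting="in_vitro",
                  pair_type="drug_enzyme",
                  cues=(Cue("definite", "potent inhibitor"),)),
                RelationLabel.DEI),)),
        Table9Fixture(
            "19230594",
            "After human hepatocytes were exposed to 10 microM YM758, "
            "microsomal activity and mRNA level for CYP1A2 were not "
            "induced while those for CYP3A4 were slightly induced.",
            (Table9Pair(
                C("ym758", "CYP1A2", setting="in_vitro",
                  pair_type="drug_enzyme",
                  cues=(Cue("negative", "not induced"),)),
                RelationLabel.NDEI),
             Table9Pair(
                C("ym758", "CYP1A2", setting="in_vitro",
                  pair_type="drug_enzyme",
                  cues=(Cue("negative", "slightly induced"),)),
                RelationLabel.NDEI,
                note="second pair as printed (duplicate of the first)"),
             Table9Pair(
                C("ym758", "CYP3A4", setting="in_vitro",
                  pair_type="drug_enzyme",
                  cues=(Cue("negative", "slightly induced"),)),
                RelationLabel.NDEI,
                note="corrected variant: the sentence attributes the "
                     "second observation to CYP3A4"))),
        Table9Fixture(
            "19960413",
            "From these results, DPT was characterized to be a competitive "
            "inhibitor of CYP2C9 and CYP3A4, with K(i) values of 3.5 and "
            "10.8 microM in HLM and 24.9 and 3.5 microM in "
            "baculovirus-insect cell-expressed human CYPs, respectively.",
            (Table9Pair(
                C("dpt", "CYP2C9", setting="in_vitro",
                  pair_type="drug_enzyme",
                  quant=(Q("Ki", "ki", 3.5), Q("Ki", "ki", 24.9))),
                RelationLabel.ADEI,
                note="Ki values from the two systems straddle 10 microM"),
             Table9Pair(
                C("dpt", "CYP3A4", setting="in_vitro",
                  pair_type="drug_enzyme",
                  quant=(Q("Ki", "ki", 10.8), Q("Ki", "ki", 3.5))),
                RelationLabel.ADEI))),
    ]
    return rows


# ---------------------------------------------------------------------------
# Evidence files (pipe-delimited; the `classify` command reads these)
# ---------------------------------------------------------------------------

def write_evidence_file(records, path: str | Path) -> None:
    """Write (record id, candidate, label) triples as delimited text.

    Columns: id|entity_a|entity_b|setting|pair_type|quant|cues|label with
    quant items "param:kind:value:p_rel:p_value:direction" (empty fields
    allowed) and cue items "polarity~phrase", both semicolon-joined.
    """
    lines = ["#id|entity_a|entity_b|setting|pair_type|quant|cues|label"]
    for rec_id, cand, label in records:
        quant = ";".join(
            f"{q.parameter}:{q.kind}:{q.value!r}:"
            f"{q.p_relation or ''}:"
            f"{'' if q.p_value is None else repr(q.p_value)}:"
            f"{q.direction}"
            for q in cand.quant)
        cues = ";".join(f"{c.polarity}~{c.phrase}" for c in cand.cues)
        lines.append("|".join([rec_id, cand.entity_a, cand.entity_b,
                               cand.setting, cand.pair_type, quant, cues,
                               label or ""]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_evidence_file(path: str | Path):
    """Inverse of :func:`write_evidence_file`."""
    records = []
    for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            (rec_id, a, b, setting, pair_type, quant_s, cues_s,
             label) = line.split("|")
            quant = []
            for item in filter(None, quant_s.split(";")):
                param, kind, value, prel, pval, direction = item.split(":")
                quant.append(QuantEvidence(
                    param, kind, float(value),
                    float(pval) if pval else None, prel or None,
                    direction or "increase"))
            cues = tuple(CueEvidence(*c.split("~", 1))
                         for c in filter(None, cues_s.split(";")))
            records.append((rec_id, InteractionCandidate(
                a, b, setting, pair_type, quant=tuple(quant), cues=cues),
                label or None))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad evidence row: {exc}") \
                from exc
    return records


def table9_records():
    """The worked examples in evidence-record form (id, candidate, label)."""
    records = []
    for fx in table9():
        for i, pair in enumerate(fx.pairs):
            records.append((f"{fx.pmid}.{i}", pair.candidate, pair.label))
    return records


# ---------------------------------------------------------------------------
# Corpus generator
# ---------------------------------------------------------------------------

_DRUGS = [
    "midazolam", "ketoconazole", "verapamil", "rifampin", "itraconazole",
    "fluconazole", "caffeine", "theophylline", "digoxin", "quinidine",
    "warfarin", "omeprazole", "paroxetine", "fluoxetine", "simvastatin",
    "lovastatin", "erythromycin", "clarithromycin", "diltiazem",
    "cimetidine", "repaglinide", "celecoxib", "bupropion", "metoprolol",
]
_ENZYMES = ["CYP3A4", "CYP2D6", "CYP2C9", "CYP2C19", "CYP1A2", "CYP2C8",
            "CYP2B6"]


@dataclass
class GenConfig:
    """Generator settings.

    ``class_mix`` gives the proportions of the four study classes
    (clinical PK, clinical PG, in vivo DDI, in vitro DDI); the default
    follows the published corpus composition (56/57/218/210 abstracts).
    ``positive_rate`` is the probability that a DDI-study sentence plants
    a definite interaction (DDI/DEI) rather than a negative, ambiguous, or
    no-statement sentence.
    """

    n_documents: int = 50
    seed: int = 0
    class_mix: tuple[float, float, float, float] = (0.10, 0.11, 0.40, 0.39)
    positive_rate: float = 0.2
    sentences_per_document: int = 4
    drugs: list[str] = field(default_factory=lambda: list(_DRUGS))
    enzymes: list[str] = field(default_factory=lambda: list(_ENZYMES))

    def __post_init__(self) -> None:
        if self.n_documents < 0:
            raise ValueError("n_documents must be >= 0")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if not 0.0 <= self.positive_rate <= 1.0:
            raise ValueError("positive_rate must be in [0, 1]")


class _SentenceBuilder:
    """Accumulates text and offset-anchored key terms."""

    def __init__(self, index: int):
        self.index = index
        self.parts: list[str] = []
        self.pos = 0
        self.terms: list[KeyTerm] = []

    def add(self, text: str) -> None:
        self.parts.append(text)
        self.pos += len(text)

    def add_term(self, text: str, category: str, normal: str,
                 **kw) -> int:
        start = self.pos
        self.add(text)
        self.terms.append(KeyTerm(
            Span(self.index, start, self.pos, text), category, normal,
            **kw))
        return len(self.terms) - 1

    def build(self, label: str = "NONE",
              pairs: list[DDIPairAnnotation] | None = None) -> Sentence:
        return Sentence(self.index, "".join(self.parts), self.terms,
                        label, pairs or [])


def _tid(i: int) -> str:
    return f"t{i}"


def generate_corpus(config: GenConfig | None = None
                    ) -> tuple[list[Document], dict]:
    """Generate an annotated corpus plus its ground-truth tally.

    The tally mirrors the structure of
    :func:`~pkddi.corpus_io.corpus_stats` and is counted independently as
    sentences are planted.
    """
    config = config or GenConfig()
    rng = random.Random(config.seed)
    tally = {
        "terms": {c: 0 for c in ("DRUG", "METABOLITE", "ENZYME",
                                 "PK_PARAMETER", "NUMBER", "MECHANISM",
                                 "CHANGE")},
        "sentences": {"NONE": 0, "CDDIS": 0, "VDDIS": 0},
        "relations": {},
        "total_documents": config.n_documents,
        "total_sentences": 0,
        "total_words_whitespace": 0,
        "total_words_tokens": 0,
        "total_pairs": 0,
    }
    documents = []
    for d in range(config.n_documents):
        study_class = rng.choices(
            ("in_vivo_pk", "in_vivo_pg", "in_vivo_ddi", "in_vitro_ddi"),
            weights=config.class_mix)[0]
        doc = _generate_document(d, study_class, config, rng, tally)
        documents.append(doc)
    return documents, tally


def _count_sentence(sent: Sentence, tally: dict) -> None:
    from ._tokenize import token_texts
    from .tagger import select_entities
    tally["total_sentences"] += 1
    tally["total_words_whitespace"] += len(sent.text.split())
    tally["total_words_tokens"] += len(token_texts(sent.text))
    tally["sentences"][sent.ddi_label] += 1
    for t in sent.key_terms:
        tally["terms"][t.category] += 1
    for p in sent.pairs:
        tally["relations"][p.relation] = \
            tally["relations"].get(p.relation, 0) + 1
    if sent.ddi_label != "NONE":
        n = len(select_entities(sent.key_terms))
        tally["total_pairs"] += n * (n - 1) // 2


def _generate_document(d: int, study_class: str, config: GenConfig,
                       rng: random.Random, tally: dict) -> Document:
    doc = Document(pmid=f"9{d:06d}", title=f"Synthetic abstract {d}",
                   study_class=study_class)
    n = config.sentences_per_document
    # the vague-DDI tail plants a definite interaction, so it only occurs
    # when positives are being planted at all
    vddis_tail = (study_class == "in_vivo_ddi" and n >= 2
                  and config.positive_rate > 0 and rng.random() < 0.25)
    body = n - 2 if vddis_tail else n
    for s in range(body):
        if study_class == "in_vivo_ddi":
            sent = _in_vivo_sentence(s, config, rng)
        elif study_class == "in_vitro_ddi":
            sent = _in_vitro_sentence(s, config, rng)
        else:
            sent = _filler_sentence(s, config, rng)
        doc.sentences.append(sent)
    if vddis_tail:
        doc.sentences.extend(_vddis_pair(body, config, rng))
    for sent in doc.sentences:
        _count_sentence(sent, tally)
    return doc


def _vddis_pair(index: int, config: GenConfig,
                rng: random.Random) -> list[Sentence]:
    """A context-mention sentence followed by a vague-DDI sentence whose
    partner is resolvable only from that context."""
    a, b_ = _two_drugs(config, rng)
    m = _SentenceBuilder(index)
    m.add("Subjects received ")
    ta = m.add_term(a, "DRUG", a)
    m.add(" pretreatment before each study phase.")
    mention = m.build("NONE")

    v = _SentenceBuilder(index + 1)
    v.add("The ")
    tq = v.add_term("AUC", "PK_PARAMETER", "AUC")
    v.add(" of ")
    tb = v.add_term(b_, "DRUG", b_)
    v.add(" was ")
    tc = v.add_term("significantly", "CHANGE", "significantly")
    v.add(" ")
    v.add_term("increased", "CHANGE", "increased")
    v.add(" by the coadministration.")
    pair = DDIPairAnnotation(_tid(tb), f"ctx:{index}:{_tid(ta)}",
                             RelationLabel.DDI, (_tid(tc), _tid(tq)))
    vddis = v.build("VDDIS", [pair])
    return [mention, vddis]


def _two_drugs(config: GenConfig, rng: random.Random) -> tuple[str, str]:
    return tuple(rng.sample(config.drugs, 2))


def _filler_sentence(index: int, config: GenConfig,
                     rng: random.Random) -> Sentence:
    b = _SentenceBuilder(index)
    kind = rng.randrange(3)
    if kind == 0:
        drug = rng.choice(config.drugs)
        n = rng.randrange(8, 48)
        b.add("The pharmacokinetics of ")
        b.add_term(drug, "DRUG", drug)
        b.add(" was evaluated in ")
        b.add_term(str(n), "NUMBER", str(n), value=float(n))
        b.add(" healthy subjects.")
    elif kind == 1:
        x = round(rng.uniform(1.0, 40.0), 1)
        b.add("The mean ")
        b.add_term("AUC", "PK_PARAMETER", "AUC")
        b.add(" was ")
        b.add_term(f"{x} mg h L^-1", "NUMBER", str(x), value=x,
                   unit="mg h L^-1")
        b.add(" across genotype groups.")
    else:
        drug = rng.choice(config.drugs)
        b.add_term(drug.capitalize(), "DRUG", drug)
        b.add(" was extensively ")
        b.add_term("metabolized", "MECHANISM", "metaboli")
        b.add(" in the liver.")
    return b.build("NONE")


def _in_vivo_sentence(index: int, config: GenConfig,
                      rng: random.Random) -> Sentence:
    if rng.random() < config.positive_rate:
        return _ddi_positive(index, config, rng)
    kind = rng.randrange(4)
    if kind == 0:
        return _ddi_negative(index, config, rng)
    if kind == 1:
        return _ddi_ambiguous(index, config, rng)
    if kind == 2:
        return _comention(index, config, rng)
    return _filler_sentence(index, config, rng)


def _ddi_positive(index: int, config: GenConfig,
                  rng: random.Random) -> Sentence:
    a, b_ = _two_drugs(config, rng)
    b = _SentenceBuilder(index)
    if rng.random() < 0.5:
        fc = round(rng.uniform(1.7, 4.0), 2)
        p = rng.choice(["P<0.01", "P<0.05"])
        ta = b.add_term(a.capitalize(), "DRUG", a)
        b.add(" ")
        tc = b.add_term("significantly", "CHANGE", "significantly")
        b.add(" ")
        b.add_term("increased", "CHANGE", "increased")
        b.add(" the ")
        tq = b.add_term("AUC", "PK_PARAMETER", "AUC")
        b.add(" of ")
        tb = b.add_term(b_, "DRUG", b_)
        b.add(" by ")
        tn = b.add_term(f"{fc} fold", "NUMBER", str(fc), value=fc,
                        unit="fold")
        b.add(" (")
        tp = b.add_term(p, "NUMBER", p, value=float(p[2:]),
                        is_pvalue=True, p_relation="lt")
        b.add(").")
        pair = DDIPairAnnotation(_tid(ta), _tid(tb), RelationLabel.DDI,
                                 (_tid(tc), _tid(tq), _tid(tn), _tid(tp)))
    else:
        pct = rng.randrange(40, 80)
        b.add("The ")
        tq = b.add_term("clearance", "PK_PARAMETER", "CL")
        b.add(" of ")
        ta = b.add_term(a, "DRUG", a)
        b.add(" was ")
        b.add_term("reduced", "CHANGE", "reduced")
        b.add(" by ")
        tn = b.add_term(f"{pct}%", "NUMBER", str(pct), value=float(pct),
                        unit="%")
        b.add(" when combined with ")
        tb = b.add_term(b_, "DRUG", b_)
        b.add(".")
        pair = DDIPairAnnotation(_tid(ta), _tid(tb), RelationLabel.DDI,
                                 (_tid(tq), _tid(tn)))
    return b.build("CDDIS", [pair])


def _ddi_negative(index: int, config: GenConfig,
                  rng: random.Random) -> Sentence:
    a, b_ = _two_drugs(config, rng)
    fc = round(rng.uniform(0.8, 1.3), 2)
    p = round(rng.uniform(0.1, 0.9), 2)
    b = _SentenceBuilder(index)
    ta = b.add_term(a.capitalize(), "DRUG", a)
    b.add(" did not ")
    tc = b.add_term("significantly", "CHANGE", "significantly")
    b.add(" alter the ")
    tq = b.add_term("AUC", "PK_PARAMETER", "AUC")
    b.add(" of ")
    tb = b.add_term(b_, "DRUG", b_)
    b.add(" (")
    tn = b.add_term(f"{fc} fold", "NUMBER", str(fc), value=fc, unit="fold")
    b.add(", ")
    tp = b.add_term(f"P={p}", "NUMBER", f"P={p}", value=p, is_pvalue=True,
                    p_relation="eq")
    b.add(").")
    pair = DDIPairAnnotation(_tid(ta), _tid(tb), RelationLabel.NDDI,
                             (_tid(tc), _tid(tq), _tid(tn), _tid(tp)))
    return b.build("CDDIS", [pair])


def _ddi_ambiguous(index: int, config: GenConfig,
                   rng: random.Random) -> Sentence:
    a, b_ = _two_drugs(config, rng)
    b = _SentenceBuilder(index)
    ta = b.add_term(a.capitalize(), "DRUG", a)
    b.add(" ")
    tm = b.add_term("may", "CHANGE", "may")
    b.add(" ")
    tc = b.add_term("moderately", "CHANGE", "moderately")
    b.add(" ")
    b.add_term("affect", "CHANGE", "affect")
    b.add(" the ")
    b.add_term("Cmax", "PK_PARAMETER", "Cmax")
    b.add(" of ")
    tb = b.add_term(b_, "DRUG", b_)
    b.add(".")
    pair = DDIPairAnnotation(_tid(ta), _tid(tb), RelationLabel.ADDI,
                             (_tid(tm), _tid(tc)))
    return b.build("CDDIS", [pair])


def _comention(index: int, config: GenConfig,
               rng: random.Random) -> Sentence:
    a, b_ = _two_drugs(config, rng)
    n = rng.randrange(6, 30)
    b = _SentenceBuilder(index)
    b.add_term(a.capitalize(), "DRUG", a)
    b.add(" and ")
    b.add_term(b_, "DRUG", b_)
    b.add(" were coadministered to ")
    b.add_term(str(n), "NUMBER", str(n), value=float(n))
    b.add(" volunteers.")
    return b.build("NONE")


def _in_vitro_sentence(index: int, config: GenConfig,
                       rng: random.Random) -> Sentence:
    if rng.random() < config.positive_rate:
        return _dei_positive(index, config, rng)
    kind = rng.randrange(3)
    if kind == 0:
        return _dei_ambiguous(index, config, rng)
    if kind == 1:
        return _dei_negative(index, config, rng)
    return _filler_sentence(index, config, rng)


def _dei_positive(index: int, config: GenConfig,
                  rng: random.Random) -> Sentence:
    drug = rng.choice(config.drugs)
    enzyme = rng.choice(config.enzymes)
    ki = round(rng.uniform(0.5, 8.0), 1)
    b = _SentenceBuilder(index)
    ta = b.add_term(drug.capitalize(), "DRUG", drug)
    b.add(" was a potent ")
    tm = b.add_term("inhibitor", "MECHANISM", "inhibit")
    b.add(" of ")
    te = b.add_term(enzyme, "ENZYME", enzyme)
    b.add(" with a ")
    tq = b.add_term("Ki", "PK_PARAMETER", "Ki")
    b.add(" of ")
    tn = b.add_term(f"{ki} microM", "NUMBER", str(ki), value=ki,
                    unit="microM")
    b.add(" (")
    tp = b.add_term("P<0.05", "NUMBER", "P<0.05", value=0.05,
                    is_pvalue=True, p_relation="lt")
    b.add(").")
    pair = DDIPairAnnotation(_tid(ta), _tid(te), RelationLabel.DEI,
                             (_tid(tm), _tid(tq), _tid(tn), _tid(tp)))
    return b.build("CDDIS", [pair])


def _dei_ambiguous(index: int, config: GenConfig,
                   rng: random.Random) -> Sentence:
    drug = rng.choice(config.drugs)
    enzyme = rng.choice(config.enzymes)
    ki = round(rng.uniform(15.0, 90.0), 1)
    b = _SentenceBuilder(index)
    ta = b.add_term(drug.capitalize(), "DRUG", drug)
    b.add(" ")
    tc = b.add_term("moderately", "CHANGE", "moderately")
    b.add(" ")
    tm = b.add_term("inhibited", "MECHANISM", "inhibit")
    b.add(" ")
    te = b.add_term(enzyme, "ENZYME", enzyme)
    b.add(" with a ")
    tq = b.add_term("Ki", "PK_PARAMETER", "Ki")
    b.add(" of ")
    tn = b.add_term(f"{ki} microM", "NUMBER", str(ki), value=ki,
                    unit="microM")
    b.add(".")
    pair = DDIPairAnnotation(_tid(ta), _tid(te), RelationLabel.ADEI,
                             (_tid(tc), _tid(tm), _tid(tq), _tid(tn)))
    return b.build("CDDIS", [pair])


def _dei_negative(index: int, config: GenConfig,
                  rng: random.Random) -> Sentence:
    drug = rng.choice(config.drugs)
    enzyme = rng.choice(config.enzymes)
    ki = round(rng.uniform(120.0, 450.0), 0)
    p = round(rng.uniform(0.2, 0.8), 2)
    b = _SentenceBuilder(index)
    ta = b.add_term(drug.capitalize(), "DRUG", drug)
    b.add(" only ")
    tc = b.add_term("slightly", "CHANGE", "slightly")
    b.add(" ")
    tm = b.add_term("inhibited", "MECHANISM", "inhibit")
    b.add(" ")
    te = b.add_term(enzyme, "ENZYME", enzyme)
    b.add(" (")
    tq = b.add_term("Ki", "PK_PARAMETER", "Ki")
    b.add(" ")
    tn = b.add_term(f"{ki:g} microM", "NUMBER", f"{ki:g}", value=ki,
                    unit="microM")
    b.add(", ")
    tp = b.add_term(f"P={p}", "NUMBER", f"P={p}", value=p, is_pvalue=True,
                    p_relation="eq")
    b.add(").")
    pair = DDIPairAnnotation(_tid(ta), _tid(te), RelationLabel.NDEI,
                             (_tid(tc), _tid(tm), _tid(tq), _tid(tn),
                              _tid(tp)))
    return b.build("CDDIS", [pair])


# ---------------------------------------------------------------------------
# Rebuilding candidates from an annotated corpus
# ---------------------------------------------------------------------------

def candidates_from_corpus(documents: list[Document]):
    """Structured candidates for every annotated pair, with evidence
    linked from the sentence's tagged terms.

    Yields (pmid, sentence index, candidate, annotated relation).  The
    study class decides the setting; drug-enzyme pairs are detected from
    the entity categories.
    """
    from .relation_rules import link_evidence
    out = []
    for doc in documents:
        setting = "in_vitro" if doc.study_class == "in_vitro_ddi" \
            else "in_vivo"
        for sent in doc.sentences:
            for p in sent.pairs:
                entities = []
                in_sentence = True
                for ref in (p.entity_a, p.entity_b):
                    if ref.startswith("ctx:"):
                        _, sidx, tid = ref.split(":")
                        term = doc.sentences[int(sidx)].term(tid)
                        in_sentence = False
                    else:
                        term = sent.term(ref)
                    entities.append(term)
                pair_type = "drug_enzyme" if any(
                    t.category == "ENZYME" for t in entities) and any(
                    t.category != "ENZYME" for t in entities) \
                    else "drug_drug"
                if p.evidence:
                    terms = [sent.term(r) for r in p.evidence]
                else:
                    terms = sent.key_terms
                quant, cues = link_evidence(sent.text, terms, setting)
                # evidence lists may omit the parameter term; re-link with
                # the full sentence when nothing was recovered
                if not quant and not cues:
                    quant, cues = link_evidence(sent.text, sent.key_terms,
                                                setting)
                cand = InteractionCandidate(
                    entities[0].normal_form, entities[1].normal_form,
                    setting, pair_type, c1=True, c2=True,
                    quant=tuple(quant), cues=tuple(cues))
                out.append((doc.pmid, sent.index, cand, p.relation))
    return out
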