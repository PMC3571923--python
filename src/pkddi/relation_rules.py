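"""Rule-based classification of drug-drug / drug-enzyme interaction pairs.

A candidate pair is judged on four conditions:

* C1 — at least one of the two entity names appears in the sentence;
* C2 — the partner entity appears in the sentence or is resolvable from the
  surrounding context;
* C3 — numeric evidence: for in vivo studies the fold change (FC) of the
  highest-priority PK parameter (AUC > CL > t1/2 > Cmax) together with its
  p-value; for in vitro studies the inhibition/induction constant (Ki >
  IC50, or EC50) in microM together with its p-value;
* C4 — language cues: definite ("significantly", "markedly", ...),
  ambiguous ("modestly", "may", ...), or negative ("slightly", "negligible",
  "doesn't interact", or a negated assertion).

The label is NONE unless C1 and C2 hold.  Numeric evidence decides when
present (C3), language cues otherwise (C4); a numeric value lying exactly on
a band boundary is indeterminate under the strict inequalities of C3 and is
then resolved by the cues, else it falls into the ambiguous band.

In vivo labels: DDI / ADDI / NDDI.  In vitro adds the drug-enzyme family
DEI / ADEI / NDEI for drug-enzyme pairs, with thresholds Ki (or EC50) below
10 microM (definite), 10-100 (ambiguous), above 100 (no interaction).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, replace
from pathlib import Path

__all__ = [
    "RelationLabel", "IN_VIVO_LABELS", "IN_VITRO_LABELS",
    "RuleConfig", "DEFAULT_CONFIG",
    "QuantEvidence", "CueEvidence", "InteractionCandidate",
    "percent_to_fold", "rank_parameter", "classify_quant", "classify_cues",
    "cue_polarity", "classify", "label_sentence",
]


class RelationLabel:
    """The seven-way relation label vocabulary."""
    DDI = "DDI"
    ADDI = "ADDI"
    NDDI = "NDDI"
    DEI = "DEI"
    ADEI = "ADEI"
    NDEI = "NDEI"
    NONE = "NONE"
    ALL = (DDI, ADDI, NDDI, DEI, ADEI, NDEI, NONE)


# the in vivo scheme has three labels; the in vitro scheme has six
IN_VIVO_LABELS = (RelationLabel.DDI, RelationLabel.ADDI, RelationLabel.NDDI)
IN_VITRO_LABELS = IN_VIVO_LABELS + (
    RelationLabel.DEI, RelationLabel.ADEI, RelationLabel.NDEI)

# family -> (definite, ambiguous, negative)
_FAMILY = {
    "ddi": (RelationLabel.DDI, RelationLabel.ADDI, RelationLabel.NDDI),
    "dei": (RelationLabel.DEI, RelationLabel.ADEI, RelationLabel.NDEI),
}

_IN_VIVO_PRIORITY = {"AUC": 1, "CL": 2, "t1/2": 3, "Cmax": 4}
_IN_VITRO_PRIORITY = {"Ki": 1, "IC50": 2}
_UNRANKED = 99

_QUANT_KINDS = ("fold_change", "percent_change", "ki", "ic50", "ec50")
_IN_VIVO_KINDS = ("fold_change", "percent_change")
_IN_VITRO_KINDS = ("ki", "ic50", "ec50")


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds and cue lists; defaults are the published ones."""

    fc_upper: float = 1.50         # in vivo definite band: FC > 1.50
    fc_lower: float = 0.67         # ... or FC < 0.67 (printed value, not 1/1.5)
    p_significant: float = 0.05
    ki_definite: float = 10.0      # microM; 0 < Ki < 10 definite
    ki_ambiguous: float = 100.0    # 10 < Ki < 100 ambiguous, > 100 none
    # how to read absent p-values: "significant" lets the magnitude band
    # decide alone (reported changes without p are asserted effects);
    # "ambiguous" demotes the definite band to the ambiguous label
    missing_p: str = "significant"
    definite_cues: tuple[str, ...] = (
        "significant", "significantly", "obviously", "markedly", "greatly",
        "pronouncedly", "potent", "potently", "strong", "strongly",
        "marked", "pronounced")
    ambiguous_cues: tuple[str, ...] = (
        "modestly", "modest", "moderately", "moderate", "probably", "may",
        "might", "possibly", "possible")
    negative_cues: tuple[str, ...] = (
        "minor significance", "minor", "slightly", "slight", "little",
        "negligible", "doesn't interact", "does not interact", "no effect")

    def __post_init__(self) -> None:
        for name in ("fc_upper", "fc_lower", "p_significant", "ki_definite",
                     "ki_ambiguous"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.missing_p not in ("significant", "ambiguous"):
            raise ValueError("missing_p must be 'significant' or 'ambiguous'")

    def save(self, path: str | Path) -> None:
        lines = []
        for name in ("fc_upper", "fc_lower", "p_significant", "ki_definite",
                     "ki_ambiguous", "missing_p"):
            lines.append(f"{name} = {getattr(self, name)}")
        for name in ("definite_cues", "ambiguous_cues", "negative_cues"):
            lines.append(f"{name} = {', '.join(getattr(self, name))}")
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "RuleConfig":
        kwargs: dict = {}
        for raw in Path(path).read_text(encoding="utf-8").splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key in ("fc_upper", "fc_lower", "p_significant",
                       "ki_definite", "ki_ambiguous"):
                kwargs[key] = float(value)
            elif key == "missing_p":
                kwargs[key] = value
            elif key in ("definite_cues", "ambiguous_cues", "negative_cues"):
                kwargs[key] = tuple(v.strip() for v in value.split(",")
                                    if v.strip())
            else:
                raise ValueError(f"unknown configuration key {key!r}")
        return cls(**kwargs)


DEFAULT_CONFIG = RuleConfig()


@dataclass(frozen=True)
class QuantEvidence:
    """One numeric measurement supporting a relation judgment.

    ``value`` is a fold change (ratio with/without the interacting drug),
    a percent change, or a Ki/IC50/EC50 in microM depending on ``kind``.
    ``direction`` qualifies percent changes (increase/decrease).
    """

    parameter: str
    kind: str
    value: float
    p_value: float | None = None
    p_relation: str | None = None  # lt/le/eq/ge/gt
    direction: str = "increase"    # percent_change only

    def __post_init__(self) -> None:
        if self.kind not in _QUANT_KINDS:
            raise ValueError(f"bad evidence kind {self.kind!r}")
        if self.kind in _IN_VITRO_KINDS and self.value <= 0:
            raise ValueError(f"{self.kind} must be positive")
        if self.kind == "percent_change" and self.value <= -100:
            raise ValueError("percent change must exceed -100")

    def fold(self) -> float:
        if self.kind == "fold_change":
            return self.value
        if self.kind == "percent_change":
            return percent_to_fold(self.value, self.direction)
        raise ValueError(f"{self.kind} evidence has no fold change")


@dataclass(frozen=True)
class CueEvidence:
    polarity: str  # definite / ambiguous / negative
    phrase: str

    def __post_init__(self) -> None:
        if self.polarity not in ("definite", "ambiguous", "negative"):
            raise ValueError(f"bad cue polarity {self.polarity!r}")


@dataclass(frozen=True)
class InteractionCandidate:
    """An ordered drug-drug or drug-enzyme pair with its attached evidence.

    ``pair_type`` distinguishes drug-enzyme pairs, which take the DEI label
    family in vitro.  ``c1``/``c2`` are the in-sentence and context
    conditions; both must hold for any non-NONE label.
    """

    entity_a: str
    entity_b: str
    setting: str = "in_vivo"
    pair_type: str = "drug_drug"
    c1: bool = True
    c2: bool = True
    quant: tuple[QuantEvidence, ...] = ()
    cues: tuple[CueEvidence, ...] = ()

    def __post_init__(self) -> None:
        if self.setting not in ("in_vivo", "in_vitro"):
            raise ValueError(f"bad setting {self.setting!r}")
        if self.pair_type not in ("drug_drug", "drug_enzyme"):
            raise ValueError(f"bad pair_type {self.pair_type!r}")


def percent_to_fold(change: float, direction: str = "increase") -> float:
    """Convert a percent change to a fold change.

    A decrease by x% gives 1 - x/100 (64% decrease -> 0.36); an increase by
    x% gives 1 + x/100.
    """
    if direction not in ("increase", "decrease"):
        raise ValueError(f"bad direction {direction!r}")
    if direction == "decrease":
        fold = 1.0 - change / 100.0
    else:
        fold = 1.0 + change / 100.0
    if fold <= 0:
        raise ValueError("percent change must leave a positive fold")
    return fold


def _priority(parameter: str, setting: str) -> int:
    table = _IN_VIVO_PRIORITY if setting == "in_vivo" else _IN_VITRO_PRIORITY
    return table.get(parameter, _UNRANKED)


def rank_parameter(evidence: list[QuantEvidence] | tuple[QuantEvidence, ...],
                   setting: str) -> QuantEvidence:
    """Return the highest-priority evidence item for ``setting``.

    Unranked parameters fall below all ranked ones; ties within one rank are
    broken by the larger absolute log fold change (fold-change kinds only),
    then by input order.
    """
    if not evidence:
        raise ValueError("rank_parameter needs at least one evidence item")

    def sort_key(item: tuple[int, QuantEvidence]):
        idx, ev = item
        rank = _priority(ev.parameter, setting)
        try:
            magnitude = abs(math.log(ev.fold()))
        except ValueError:
            magnitude = 0.0
        return (rank, -magnitude, idx)

    return min(enumerate(evidence), key=sort_key)[1]


def _is_significant(ev: QuantEvidence, config: RuleConfig) -> bool | None:
    """True/False when the p-value decides significance, None when absent."""
    if ev.p_value is None:
        return None
    rel = ev.p_relation or "eq"
    if rel in ("lt", "le", "eq"):
        return ev.p_value <= config.p_significant
    # "p > v": significant only if the whole range is below the threshold,
    # which a reported bound never is
    return False


def classify_quant(ev: QuantEvidence, setting: str,
                   pair_type: str = "drug_drug",
                   config: RuleConfig = DEFAULT_CONFIG) -> str:
    """Label a single numeric evidence item under the band rules (C3)."""
    label, _ = _classify_quant_flag(ev, setting, pair_type, config)
    return label


def _classify_quant_flag(ev: QuantEvidence, setting: str, pair_type: str,
                         config: RuleConfig) -> tuple[str, bool]:
    """As :func:`classify_quant`, also flagging exact-boundary values."""
    family = "dei" if (setting == "in_vitro" and pair_type == "drug_enzyme") \
        else "ddi"
    definite, ambiguous, negative = _FAMILY[family]

    sig = _is_significant(ev, config)
    if sig is None:
        if config.missing_p == "ambiguous":
            return ambiguous, False
        sig = True  # magnitude band decides alone

    if setting == "in_vivo":
        if ev.kind not in _IN_VIVO_KINDS:
            raise ValueError(
                f"{ev.kind} evidence is not an in vivo measurement")
        fc = ev.fold()
        if fc == config.fc_upper or fc == config.fc_lower:
            return ambiguous, True  # strict inequalities: boundary undecided
        outside = fc > config.fc_upper or fc < config.fc_lower
        if sig:
            return (definite if outside else ambiguous), False
        return (ambiguous if outside else negative), False

    if ev.kind not in _IN_VITRO_KINDS:
        raise ValueError(f"{ev.kind} evidence is not an in vitro measurement")
    v = ev.value
    if v == config.ki_definite or v == config.ki_ambiguous:
        return ambiguous, True
    if v < config.ki_definite:
        return (definite if sig else ambiguous), False
    if v < config.ki_ambiguous:
        return ambiguous, False
    return (ambiguous if sig else negative), False


def cue_polarity(phrase: str,
                 config: RuleConfig = DEFAULT_CONFIG) -> str | None:
    """Assign a cue polarity to a phrase, or None if it carries no cue.

    A negation ("not", "doesn't", "no") anywhere in the phrase makes it
    negative — "not significantly changed" asserts the absence of an
    effect — otherwise the strongest listed cue word decides.
    """
    low = phrase.lower()
    if re.search(r"\b(?:not|no|never)\b|n['’]t\b", low):
        return "negative"
    words = set(re.findall(r"[a-z']+", low))
    for cue in config.negative_cues:
        if " " in cue and cue in low or cue in words:
            return "negative"
    for cue in config.definite_cues:
        if cue in words:
            return "definite"
    for cue in config.ambiguous_cues:
        if cue in words:
            return "ambiguous"
    return None


def cues_from_text(text: str,
                   config: RuleConfig = DEFAULT_CONFIG) -> list[CueEvidence]:
    """Scan free text for cue words, attaching an adjacent negation.

    Convenience for building candidates straight from sentences; the corpus
    pipeline attaches cues from CHANGE annotations instead.
    """
    out = []
    all_cues = sorted(
        set(config.definite_cues + config.ambiguous_cues
            + config.negative_cues), key=len, reverse=True)
    alts = "|".join(re.escape(c) for c in all_cues)
    pat = re.compile(
        rf"((?:\b(?:not|no|never)\b|n['’]t\b|\bdid not\b|\bdoes not\b)\s+)?"
        rf"(?:\w+\s+)??(?<![A-Za-z])({alts})(?![A-Za-z])",
        re.IGNORECASE)
    for m in pat.finditer(text):
        phrase = m.group(0) if m.group(1) else m.group(2)
        pol = cue_polarity(phrase, config)
        if pol:
            out.append(CueEvidence(pol, phrase))
    return out


def link_evidence(text: str, key_terms, setting: str,
                  config: RuleConfig = DEFAULT_CONFIG,
                  ) -> tuple[list[QuantEvidence], list[CueEvidence]]:
    """Heuristic linker from tagged terms to structured evidence.

    Numeric terms are attached to the nearest preceding PK-parameter
    mention; p-values to the nearest preceding numeric measurement; cue
    polarities are read from a short context window around each CHANGE or
    MECHANISM term (catching adjacent negations and qualifiers).  This is
    glue for running the rules on raw tagged sentences — curated corpora
    attach evidence explicitly — and it relies on parameter/number
    adjacency.
    """
    quant: list[QuantEvidence] = []
    cues: list[CueEvidence] = []
    last_param: tuple[int, str] | None = None  # (end offset, symbol)
    for t in sorted(key_terms, key=lambda t: t.span.start):
        if t.category == "PK_PARAMETER":
            last_param = (t.span.end, t.normal_form)
        elif t.category == "NUMBER" and t.is_pvalue:
            if quant:
                prev = quant[-1]
                quant[-1] = replace(prev, p_value=t.value,
                                    p_relation=t.p_relation or "eq")
        elif t.category == "NUMBER" and t.value is not None:
            if last_param is None:
                continue
            symbol = last_param[1]
            between = text[last_param[0]:t.span.start].lower()
            direction = "decrease" if re.search(
                r"decreas|reduc|lower|declin", between) else "increase"
            kind = None
            if t.unit == "fold":
                kind = "fold_change"
            elif t.unit == "%":
                kind = "percent_change"
            elif t.unit in ("microM", "uM", "μM", "nM", "mM") and \
                    symbol in ("Ki", "IC50", "EC50", "KI"):
                kind = {"Ki": "ki", "KI": "ki", "IC50": "ic50",
                        "EC50": "ec50"}[symbol]
            if kind is None:
                continue
            try:
                quant.append(QuantEvidence(symbol, kind, t.value,
                                           direction=direction))
            except ValueError:
                continue
        elif t.category in ("CHANGE", "MECHANISM"):
            window = text[max(0, t.span.start - 16):t.span.end]
            pol = cue_polarity(window, config)
            if pol:
                cues.append(CueEvidence(pol, window.strip()))
    return quant, cues


def classify_cues(cues: list[CueEvidence] | tuple[CueEvidence, ...],
                  family: str = "ddi") -> str:
    """Aggregate language cues (C4) into a family label.

    Negative cues win unless a definite cue is also present; ambiguous cues
    without a definite cue give the ambiguous label; an empty list gives
    NONE.
    """
    definite, ambiguous, negative = _FAMILY[family]
    if not cues:
        return RelationLabel.NONE
    pols = {c.polarity for c in cues}
    if "negative" in pols and "definite" not in pols:
        return negative
    if "ambiguous" in pols and "definite" not in pols:
        return ambiguous
    if "definite" in pols:
        return definite
    return RelationLabel.NONE


def classify(candidate: InteractionCandidate,
             config: RuleConfig = DEFAULT_CONFIG) -> str:
    """Label a candidate pair: C1 AND C2 AND (C3 OR C4).

    Numeric evidence (C3) decides when present: the measurements of the
    highest-priority parameter are classified and, if they land in
    different bands (e.g. Ki values straddling 10 microM from different
    assay systems), the ambiguous band wins.  A value exactly on a band
    boundary defers to the cues when any are present.  Without numeric
    evidence the cues decide (C4).
    """
    if not (candidate.c1 and candidate.c2):
        return RelationLabel.NONE
    family = "dei" if (candidate.setting == "in_vitro"
                       and candidate.pair_type == "drug_enzyme") else "ddi"
    relevant_kinds = (_IN_VIVO_KINDS if candidate.setting == "in_vivo"
                      else _IN_VITRO_KINDS)
    quant = [q for q in candidate.quant if q.kind in relevant_kinds]
    if quant:
        top = rank_parameter(quant, candidate.setting)
        same = [q for q in quant if q.parameter == top.parameter]
        results = [_classify_quant_flag(q, candidate.setting,
                                        candidate.pair_type, config)
                   for q in same]
        labels = {label for label, _ in results}
        if len(labels) > 1:
            return _FAMILY[family][1]  # conflicting bands -> ambiguous
        label = labels.pop()
        if all(boundary for _, boundary in results) and candidate.cues:
            cue_label = classify_cues(candidate.cues, family)
            if cue_label != RelationLabel.NONE:
                return cue_label
        return label
    return classify_cues(candidate.cues, family)


def label_sentence(key_terms, *, has_context_partner: bool = False) -> str:
    """Label a tagged sentence NONE / CDDIS / VDDIS.

    CDDIS: at least two distinct interaction entities (drugs or enzymes) in
    the sentence together with an interaction statement (a mechanism or
    change term).  VDDIS: exactly one entity plus a statement, with the
    partner resolvable from context.
    """
    entities = {t.normal_form for t in key_terms
                if t.category in ("DRUG", "ENZYME")}
    statement = any(t.category in ("MECHANISM", "CHANGE") for t in key_terms)
    if statement and len(entities) >= 2:
        return "CDDIS"
    if statement and len(entities) == 1 and has_context_partner:
        return "VDDIS"
    return "NONE"
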