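"""Rule-based tagging of the six key-term classes in PK/DDI sentences.

The classes are drug names (with metabolites recognised through the ten
phase-I/phase-II affixes), CYP enzyme names, PK parameters, numbers with
units and p-values, drug-interaction mechanism words, and change cues.
Enzyme and mechanism recognition is purely pattern-based; drug and PK
parameter recognition is dictionary longest-match against a
:class:`~pkddi.lexicon.Lexicon`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from ._tokenize import tokenize
from functools import lru_cache

from .lexicon import Lexicon, builtin_lexicon


@lru_cache(maxsize=1)
def _default_lexicon() -> Lexicon:
    # shared read-only instance for the default-argument path
    return builtin_lexicon()

__all__ = [
    "Span", "KeyTerm", "CATEGORIES",
    "tag_enzymes", "tag_mechanisms", "tag_changes", "tag_numbers",
    "tag_pk_parameters", "tag_drugs", "tag_all", "select_entities",
]

CATEGORIES = ("DRUG", "METABOLITE", "ENZYME", "PK_PARAMETER", "NUMBER",
              "MECHANISM", "CHANGE")

# precedence when equal-length spans overlap (METABOLITE ranks with DRUG)
_PRECEDENCE = {"DRUG": 0, "METABOLITE": 0, "ENZYME": 1, "PK_PARAMETER": 2,
               "NUMBER": 3, "MECHANISM": 4, "CHANGE": 5}


@dataclass(frozen=True)
class Span:
    sentence_index: int
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span offsets [{self.start},{self.end})")

    def overlaps(self, other: "Span") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class KeyTerm:
    span: Span
    category: str
    normal_form: str
    unit: str | None = None        # NUMBER only
    value: float | None = None     # NUMBER only
    is_pvalue: bool = False        # NUMBER only
    p_relation: str | None = None  # lt/le/eq/ge/gt, NUMBER p-values only
    parent: str | None = None      # METABOLITE only

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"bad category {self.category!r}")


def _term(sent_idx: int, start: int, end: int, text: str, category: str,
          normal: str, **kw) -> KeyTerm:
    return KeyTerm(Span(sent_idx, start, end, text[start:end]), category,
                   normal, **kw)


# ---------------------------------------------------------------------------
# Enzymes
# ---------------------------------------------------------------------------

# Pattern as printed in the annotation guideline: an optional CYP/P450 prefix
# and a digit-letter-digit core with an optional allele star.  Anchors are
# interpreted at token level.  It fails on names with a two-digit subfamily
# number (CYP2C19) or a bare family-letter (CYP3A); the extended pattern
# below accepts those and is the default.
ENZYME_PATTERN_STRICT = re.compile(
    r"(?:cyp|CYP|P450|CYP450)?[0-9][a-zA-Z][0-9](?:\*[0-9])?")
ENZYME_PATTERN_EXTENDED = re.compile(
    r"(?:cyp|CYP|P450|CYP450)?[0-9][A-Za-z][0-9]*(?:\*[0-9]+)?",
    re.IGNORECASE)

_ENZYME_PREFIX = re.compile(r"^(?:cyp450|cyp|p450)", re.IGNORECASE)


def _enzyme_normal_form(token: str) -> str:
    core = _ENZYME_PREFIX.sub("", token)
    return "CYP" + core.upper()


def tag_enzymes(sentence: str, sentence_index: int = 0, *,
                strict: bool = False) -> list[KeyTerm]:
    """Tag CYP enzyme name tokens.

    ``strict=True`` applies the digit-letter-digit pattern verbatim (token
    anchored); the default extended pattern additionally accepts multi-digit
    and digit-less tails such as CYP2C19 and CYP3A.
    """
    pattern = ENZYME_PATTERN_STRICT if strict else ENZYME_PATTERN_EXTENDED
    out = []
    for tok in tokenize(sentence):
        if pattern.fullmatch(tok.text):
            out.append(_term(sentence_index, tok.start, tok.end, sentence,
                             "ENZYME", _enzyme_normal_form(tok.text)))
    return out


# ---------------------------------------------------------------------------
# Mechanisms: the nine stem patterns, applied as token-level full matches.
# ---------------------------------------------------------------------------

_MECHANISM_PATTERNS = [
    ("inhibit", r"inhibit(e(s|d)?|ing|ion(s)?|or)"),
    ("catalyz", r"catalyz(e(s|d)?|ing)"),
    ("correlat", r"correlat(e(s|d)?|ing|ion(s)?)"),
    ("metaboli", r"metaboli(z(e(s|d)?|ing)|sm)"),
    ("induc", r"induc(e(s|d)?|ing|tion(s)?|or)"),
    # "a?tion" so that "formation" matches, as the guideline's own
    # example requires
    ("form", r"form((s|ed)?|ing|a?tion(s)?|or)"),
    ("stimulat", r"stimulat(e(s|d)?|ing|ion(s)?)"),
    ("activ", r"activ(e(s)?|(at)(e(s|d)?|ing|ion(s)?))"),
    ("suppress", r"suppress(e(s|d)?|ing|ion(s)?)"),
]
_MECHANISMS = [(stem, re.compile(pat, re.IGNORECASE))
               for stem, pat in _MECHANISM_PATTERNS]


def tag_mechanisms(sentence: str, sentence_index: int = 0) -> list[KeyTerm]:
    """Tag drug metabolism / interaction mechanism words; the normal form is
    the stem (e.g. ``inhibited`` -> ``inhibit``)."""
    out = []
    for tok in tokenize(sentence):
        for stem, pat in _MECHANISMS:
            if pat.fullmatch(tok.text):
                out.append(_term(sentence_index, tok.start, tok.end,
                                 sentence, "MECHANISM", stem))
                break
    return out


# ---------------------------------------------------------------------------
# Change cues
# ---------------------------------------------------------------------------

_CHANGE_WORD_PATTERNS = [
    r"strong(ly)?", r"moderate(ly)?", r"high(est|er)?", r"slight(ly)?",
    r"significant(ly)?", r"obvious(ly)?", r"marked(ly)?", r"great(ly)?",
    r"pronounced(ly)?", r"modest(ly)?", r"probably", r"may", r"might",
    r"minor", r"little", r"negligible",
    r"affect((s|ed)?|ing|ion(s)?)?", r"reduc(e(s|d)?|ing|tion(s)?)",
    r"increas(e(s|d)?|ing)",
]
_CHANGE_WORDS = [re.compile(p, re.IGNORECASE) for p in _CHANGE_WORD_PATTERNS]
# multi-word cue, matched on the raw sentence
_CHANGE_PHRASE = re.compile(r"(?:doesn['’]t|does\s+not)\s+interact\w*",
                            re.IGNORECASE)


def tag_changes(sentence: str, sentence_index: int = 0) -> list[KeyTerm]:
    """Tag words and phrases that state how a PK parameter changed."""
    out = []
    taken: list[tuple[int, int]] = []
    for m in _CHANGE_PHRASE.finditer(sentence):
        out.append(_term(sentence_index, m.start(), m.end(), sentence,
                         "CHANGE", "doesn't interact"))
        taken.append((m.start(), m.end()))
    for tok in tokenize(sentence):
        if any(tok.start < e and s < tok.end for s, e in taken):
            continue
        for pat in _CHANGE_WORDS:
            if pat.fullmatch(tok.text):
                out.append(_term(sentence_index, tok.start, tok.end,
                                 sentence, "CHANGE", tok.text.lower()))
                break
    out.sort(key=lambda t: t.span.start)
    return out


# ---------------------------------------------------------------------------
# Numbers, units, p-values
# ---------------------------------------------------------------------------

_UNITS = [
    "ng*h/mL", "ng h/mL", "ng/mL", "ng/ml", "mg/mL", "mg/L", "mg/kg",
    "mg/day", "microM", "microg", "uM", "μM", "nM", "mM", "M",
    "mg h L^-1", "mg L^-1", "ml h^-1", "h^-1", "cm/sec", "ml/min", "mL/min",
    "dpm/mg protein", "ul/mg protein", "fold", "hours", "hour", "h", "hr",
    "min", "sec", "days", "day", "weeks", "week", "months", "mg", "ml",
    "mL", "L", "%",
]
_UNIT_RE = "|".join(re.escape(u) for u in
                    sorted(_UNITS, key=len, reverse=True))
_NUMBER_RE = re.compile(
    rf"(?P<num>\d+(?:\.\d+)?(?:[eE][-+]?\d+)?|\.\d+)"
    rf"(?:\s*(?P<unit>{_UNIT_RE})(?![A-Za-z]))?")
_PVALUE_RE = re.compile(
    r"[Pp](?:\s*-?\s*value)?\s*(?P<rel><=|>=|[<>=≤≥])\s*"
    r"(?P<num>\d+(?:\.\d+)?|\.\d+)")
_REL_MAP = {"<": "lt", "<=": "le", "≤": "le", "=": "eq", ">": "gt",
            ">=": "ge", "≥": "ge"}


def tag_numbers(sentence: str, sentence_index: int = 0) -> list[KeyTerm]:
    """Tag numeric values with trailing units and p-value expressions.

    P-value forms like ``P≤0.01`` and ``P=.26`` are flagged and keep the
    comparison operator, which the relation rules need to judge
    significance.
    """
    out = []
    taken: list[tuple[int, int]] = []
    for m in _PVALUE_RE.finditer(sentence):
        value = float(m.group("num"))
        out.append(_term(sentence_index, m.start(), m.end(), sentence,
                         "NUMBER", m.group(0), value=value, is_pvalue=True,
                         p_relation=_REL_MAP[m.group("rel")]))
        taken.append((m.start(), m.end()))
    for m in _NUMBER_RE.finditer(sentence):
        if any(m.start() < e and s < m.end() for s, e in taken):
            continue
        # do not split a decimal like "0.05" out of "P=0.05"-adjacent text
        unit = m.group("unit")
        out.append(_term(sentence_index, m.start(), m.end(), sentence,
                         "NUMBER", m.group(0),
                         value=float(m.group("num")), unit=unit))
    out.sort(key=lambda t: t.span.start)
    return out


# ---------------------------------------------------------------------------
# PK parameters
# ---------------------------------------------------------------------------

# collapse subscript parentheses: K(i) -> Ki, C(max) -> Cmax, t(1/2) -> t1/2
_SUBSCRIPT_RE = re.compile(r"\b([A-Za-z]{1,4})\((max|ss|i|50|int|1/2)\)",
                           re.IGNORECASE)
# a parenthesized range/time qualifier after a symbol: AUC(0-48), AUC(0-infinity)
_QUALIFIER_RE = re.compile(r"\s*\([^()]*\)")


def _parameter_regex(lexicon: Lexicon) -> re.Pattern:
    cached = lexicon._cache.get("param_re")
    if cached is None:
        surfaces = [s for s in lexicon.parameter_surfaces() if len(s) >= 2]
        surfaces.sort(key=len, reverse=True)
        alts = "|".join(re.escape(s).replace(r"\ ", r"\s+")
                        for s in surfaces)
        cached = re.compile(rf"(?<![A-Za-z0-9])(?:{alts})(?![A-Za-z0-9])",
                            re.IGNORECASE)
        lexicon._cache["param_re"] = cached
    return cached


def tag_pk_parameters(sentence: str, sentence_index: int = 0,
                      lexicon: Lexicon | None = None) -> list[KeyTerm]:
    """Tag PK parameter symbols and spelled-out synonyms, longest match
    first; ``AUC(0-48)``-style qualified symbols map to the base symbol."""
    lexicon = lexicon or _default_lexicon()
    matches: list[tuple[int, int, str]] = []  # (start, end, normal)

    # subscripted forms first
    for m in _SUBSCRIPT_RE.finditer(sentence):
        collapsed = m.group(1) + m.group(2)
        pdef = lexicon.parameter(collapsed)
        if pdef:
            matches.append((m.start(), m.end(), pdef.symbol))

    pat = _parameter_regex(lexicon)
    for m in pat.finditer(sentence):
        pdef = lexicon.parameter(m.group(0))
        if pdef is None:
            continue
        start, end = m.start(), m.end()
        # absorb a parenthesized qualifier: AUC(0-48)
        qm = _QUALIFIER_RE.match(sentence, end)
        if qm:
            end = qm.end()
        matches.append((start, end, pdef.symbol))

    # longest-match overlap resolution
    matches.sort(key=lambda t: (-(t[1] - t[0]), t[0]))
    chosen: list[tuple[int, int, str]] = []
    for s, e, normal in matches:
        if not any(s < ce and cs < e for cs, ce, _ in chosen):
            chosen.append((s, e, normal))
    chosen.sort()
    return [_term(sentence_index, s, e, sentence, "PK_PARAMETER", n)
            for s, e, n in chosen]


# ---------------------------------------------------------------------------
# Drugs and metabolites
# ---------------------------------------------------------------------------

# phase-I / phase-II metabolism affixes (prefix or suffix)
METABOLITE_AFFIXES = ("oxi", "hydroxyl", "methyl", "acetyl", "n-dealkyl",
                      "n-demethyl", "nor", "dihydroxy", "o-dealkyl", "sulfo")


def _drug_regex(lexicon: Lexicon) -> re.Pattern:
    cached = lexicon._cache.get("drug_re")
    if cached is None:
        surfaces = sorted(lexicon.drug_surfaces(), key=len, reverse=True)
        alts = "|".join(re.escape(s).replace(r"\ ", r"\s+")
                        for s in surfaces)
        cached = re.compile(rf"(?<![A-Za-z0-9])(?:{alts})(?![A-Za-z0-9])",
                            re.IGNORECASE)
        lexicon._cache["drug_re"] = cached
    return cached


def _metabolite_parent(token: str, lexicon: Lexicon) -> str | None:
    """If ``token`` is a metabolism affix attached to a known drug name,
    return the parent drug's canonical name."""
    low = token.lower()
    for affix in METABOLITE_AFFIXES:
        remainders = []
        if low.startswith(affix):
            remainders.append(low[len(affix):].lstrip("-"))
        if low.endswith(affix):
            remainders.append(low[:-len(affix)].rstrip("-"))
        for rem in remainders:
            if len(rem) < 3:
                continue
            entry = lexicon.drug(rem)
            if entry is not None:
                return entry.canonical
    return None


def tag_drugs(sentence: str, sentence_index: int = 0,
              lexicon: Lexicon | None = None) -> list[KeyTerm]:
    """Dictionary longest-match drug tagging plus affix-based metabolite
    recognition (e.g. ``norverapamil`` -> METABOLITE, parent verapamil)."""
    lexicon = lexicon or _default_lexicon()
    out = []
    taken: list[tuple[int, int]] = []
    for m in _drug_regex(lexicon).finditer(sentence):
        entry = lexicon.drug(m.group(0))
        if entry is None:
            continue
        out.append(_term(sentence_index, m.start(), m.end(), sentence,
                         "DRUG", entry.canonical))
        taken.append((m.start(), m.end()))
    for tok in tokenize(sentence):
        if any(tok.start < e and s < tok.end for s, e in taken):
            continue
        parent = _metabolite_parent(tok.text, lexicon)
        if parent is not None:
            out.append(_term(sentence_index, tok.start, tok.end, sentence,
                             "METABOLITE", tok.text.lower(), parent=parent))
    out.sort(key=lambda t: t.span.start)
    return out


# ---------------------------------------------------------------------------
# Union tagging
# ---------------------------------------------------------------------------

def tag_all(sentence: str, sentence_index: int = 0,
            lexicon: Lexicon | None = None, *,
            strict_enzymes: bool = False) -> list[KeyTerm]:
    """Run all six taggers and resolve overlaps.

    A longer span wins; on equal length the category precedence is
    DRUG > ENZYME > PK_PARAMETER > NUMBER > MECHANISM > CHANGE.  The result
    is sorted by start offset and pairwise non-overlapping.
    """
    if not sentence:
        return []
    lexicon = lexicon or _default_lexicon()
    candidates = (
        tag_drugs(sentence, sentence_index, lexicon)
        + tag_enzymes(sentence, sentence_index, strict=strict_enzymes)
        + tag_pk_parameters(sentence, sentence_index, lexicon)
        + tag_numbers(sentence, sentence_index)
        + tag_mechanisms(sentence, sentence_index)
        + tag_changes(sentence, sentence_index)
    )
    candidates.sort(key=lambda t: (-(t.span.end - t.span.start),
                                   _PRECEDENCE[t.category], t.span.start))
    chosen: list[KeyTerm] = []
    for term in candidates:
        if not any(term.span.overlaps(c.span) for c in chosen):
            chosen.append(term)
    chosen.sort(key=lambda t: t.span.start)
    return chosen


def select_entities(key_terms: list[KeyTerm]) -> list[KeyTerm]:
    """Reduce tagged terms to the pairable interaction entities.

    Metabolites are dropped (parent drugs and their metabolites rarely
    interact), enzymes are kept as pairable entities, and repeated mentions
    of one canonical entity collapse to the first mention.
    """
    seen: set[str] = set()
    out = []
    for t in key_terms:
        if t.category not in ("DRUG", "ENZYME"):
            continue
        if t.normal_form in seen:
            continue
        seen.add(t.normal_form)
        out.append(t)
    return out
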