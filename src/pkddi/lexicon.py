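"""Controlled vocabularies: PK parameters, drugs, probe roles, transporters.

The bundle shipped by :func:`builtin_lexicon` covers the in vitro / in vivo
PK parameter ontologies, the seven tissue-specific drug transporters, and the
probe inhibitors / inducers / substrates of the major CYP enzymes and
transporters, plus the handful of drugs used by the worked classification
examples.  Larger drug lists (e.g. a DrugBank export) are loaded from a
pipe-delimited text file with :func:`load_lexicon`.

All matching is case-insensitive; canonical drug names are stored lowercase.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from . import _lexicon_data as _data

__all__ = [
    "PKParameterDef", "DrugEntry", "ProbeAssignment", "TransporterRecord",
    "Lexicon", "builtin_lexicon", "load_lexicon", "write_lexicon",
]

VALID_SETTINGS = ("in_vitro", "in_vivo", "both")
VALID_ROLES = ("inhibitor", "inducer", "substrate")


@dataclass(frozen=True)
class PKParameterDef:
    """One PK parameter: symbol, free-text description, unit, and the study
    setting it belongs to.  ``priority_rank`` (1 = highest) is defined only
    for the parameters that rank interaction evidence: AUC > CL > t1/2 >
    Cmax in vivo and Ki > IC50 in vitro."""

    symbol: str
    description: str
    unit: str = ""
    setting: str = "in_vivo"
    synonyms: tuple[str, ...] = ()
    priority_rank: int | None = None

    def __post_init__(self) -> None:
        if self.setting not in VALID_SETTINGS:
            raise ValueError(f"bad setting {self.setting!r}")


@dataclass(frozen=True)
class DrugEntry:
    canonical: str
    surface_forms: tuple[str, ...] = ()
    is_metabolite: bool = False
    parent: str | None = None

    def __post_init__(self) -> None:
        canonical = self.canonical.lower()
        forms = [canonical]
        for f in self.surface_forms:
            f = f.lower()
            if f not in forms:
                forms.append(f)
        object.__setattr__(self, "canonical", canonical)
        object.__setattr__(self, "surface_forms", tuple(forms))


@dataclass(frozen=True)
class ProbeAssignment:
    enzyme: str
    role: str
    drug: str

    def __post_init__(self) -> None:
        if self.role not in VALID_ROLES:
            raise ValueError(f"bad probe role {self.role!r}")


@dataclass(frozen=True)
class TransporterRecord:
    gene: str
    aliases: tuple[str, ...] = ()
    tissues: tuple[str, ...] = ()
    function: str = "uptake"

    def __post_init__(self) -> None:
        if self.function not in ("uptake", "efflux"):
            raise ValueError(f"bad transporter function {self.function!r}")


# t1/2 appears in abstracts in several typographic guises
_THALF_VARIANTS = {"t½", "t 1/2", "t(1/2)", "t-1/2", "thalf", "t1/2"}


def _norm(surface: str) -> str:
    s = surface.strip().lower()
    if s in _THALF_VARIANTS:
        return "t1/2"
    return s


@dataclass
class Lexicon:
    """Lookup bundle over the four vocabularies."""

    parameters: list[PKParameterDef] = field(default_factory=list)
    drugs: list[DrugEntry] = field(default_factory=list)
    probes: list[ProbeAssignment] = field(default_factory=list)
    transporters: list[TransporterRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._reindex()

    def _reindex(self) -> None:
        self._cache: dict[str, object] = {}  # compiled patterns, see tagger
        self._param_by_surface: dict[str, PKParameterDef] = {}
        # symbols first so a symbol always beats a synonym of another entry
        for p in self.parameters:
            self._param_by_surface.setdefault(_norm(p.symbol), p)
        for p in self.parameters:
            for syn in p.synonyms:
                self._param_by_surface.setdefault(_norm(syn), p)
        self._drug_by_surface: dict[str, DrugEntry] = {}
        for d in self.drugs:
            for f in d.surface_forms:
                self._drug_by_surface.setdefault(_norm(f), d)
        self._probes_by_drug: dict[str, list[ProbeAssignment]] = {}
        for a in self.probes:
            self._probes_by_drug.setdefault(_norm(a.drug), []).append(a)

    # -- lookups -----------------------------------------------------------
    def parameter(self, surface: str) -> PKParameterDef | None:
        return self._param_by_surface.get(_norm(surface))

    def drug(self, surface: str) -> DrugEntry | None:
        return self._drug_by_surface.get(_norm(surface))

    def probe_roles(self, drug: str) -> list[ProbeAssignment]:
        """All (enzyme, role) probe assignments of ``drug``; empty when the
        drug has no probe role."""
        return list(self._probes_by_drug.get(_norm(drug), []))

    def parameter_surfaces(self) -> list[str]:
        return list(self._param_by_surface)

    def drug_surfaces(self) -> list[str]:
        return list(self._drug_by_surface)

    def add_drugs(self, entries: list[DrugEntry]) -> None:
        self.drugs.extend(entries)
        self._reindex()

    # -- serialization -----------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write the whole bundle as sectioned pipe-delimited UTF-8 text."""
        lines = ["#[parameters]"]
        for p in self.parameters:
            lines.append("|".join([
                p.symbol, p.description, p.unit, p.setting,
                ";".join(p.synonyms),
                "" if p.priority_rank is None else str(p.priority_rank)]))
        lines.append("#[transporters]")
        for t in self.transporters:
            lines.append("|".join([t.gene, ";".join(t.aliases),
                                   ";".join(t.tissues), t.function]))
        lines.append("#[probes]")
        for a in self.probes:
            lines.append("|".join([a.enzyme, a.role, a.drug]))
        lines.append("#[drugs]")
        for d in self.drugs:
            lines.append(_drug_line(d))
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "Lexicon":
        lex = cls()
        section = None
        for lineno, raw in enumerate(
                Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#["):
                section = line[2:].rstrip("]")
                continue
            if line.startswith("#"):
                continue
            parts = line.split("|")
            try:
                if section == "parameters":
                    sym, desc, unit, setting, syns, rank = parts
                    lex.parameters.append(PKParameterDef(
                        sym, desc, unit, setting,
                        tuple(s for s in syns.split(";") if s),
                        int(rank) if rank else None))
                elif section == "transporters":
                    gene, aliases, tissues, func = parts
                    lex.transporters.append(TransporterRecord(
                        gene, tuple(a for a in aliases.split(";") if a),
                        tuple(t for t in tissues.split(";") if t), func))
                elif section == "probes":
                    enzyme, role, drug = parts
                    lex.probes.append(ProbeAssignment(enzyme, role, drug))
                elif section == "drugs":
                    lex.drugs.append(_parse_drug_line(parts))
                else:
                    raise ValueError(f"line outside a known section: {raw!r}")
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
        lex._reindex()
        return lex


def _drug_line(d: DrugEntry) -> str:
    cols = [d.canonical, *[f for f in d.surface_forms if f != d.canonical]]
    if d.is_metabolite:
        cols.append(f"@metabolite_of={d.parent or ''}")
    return "|".join(cols)


def _parse_drug_line(parts: list[str]) -> DrugEntry:
    parent = None
    is_metabolite = False
    forms = []
    for col in parts:
        col = col.strip()
        if not col:
            continue
        if col.startswith("@metabolite_of="):
            is_metabolite = True
            parent = col.split("=", 1)[1] or None
        else:
            forms.append(col)
    if not forms:
        raise ValueError("row has no surface forms")
    return DrugEntry(forms[0], tuple(forms[1:]), is_metabolite, parent)


def load_lexicon(path: str | Path) -> tuple[list[DrugEntry], list[str]]:
    """Read a pipe-delimited drug lexicon: ``canonical|form1|form2|...``,
    one entry per line, ``#`` comments.

    Returns the entries and a warning list naming surface forms shared by
    more than one entry (all entries are kept).
    """
    entries: list[DrugEntry] = []
    for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            entries.append(_parse_drug_line(line.split("|")))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
    form_entries: dict[str, int] = {}
    for e in entries:
        for f in set(e.surface_forms):
            form_entries[f] = form_entries.get(f, 0) + 1
    warnings = sorted(f for f, c in form_entries.items() if c > 1)
    return entries, warnings


def write_lexicon(entries: list[DrugEntry], path: str | Path) -> None:
    """Inverse of :func:`load_lexicon`."""
    lines = [_drug_line(e) for e in entries]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _split_names(blob: str) -> list[str]:
    return [n.strip() for n in blob.split(",") if n.strip()]


def _builtin_drugs() -> list[DrugEntry]:
    names: dict[str, DrugEntry] = {}

    def add(name: str) -> None:
        key = name.lower()
        if key not in names:
            extra = _data.EXTRA_SURFACE_FORMS.get(key, ())
            names[key] = DrugEntry(key, tuple(extra))

    for table in (_data.CYP_PROBES, _data.TRANSPORTER_PROBES):
        for roles in table.values():
            for blob in roles.values():
                for name in _split_names(blob):
                    add(name)
    for canonical, forms in _data.EXTRA_DRUGS.items():
        key = canonical.lower()
        names.setdefault(key, DrugEntry(key, tuple(forms)))
    return sorted(names.values(), key=lambda d: d.canonical)


def _builtin_probes() -> list[ProbeAssignment]:
    probes = []
    for table in (_data.CYP_PROBES, _data.TRANSPORTER_PROBES):
        for enzyme, roles in table.items():
            for role, blob in roles.items():
                for name in _split_names(blob):
                    probes.append(ProbeAssignment(enzyme, role, name.lower()))
    return probes


def builtin_lexicon() -> Lexicon:
    """The bundled vocabulary tables as a ready-to-use :class:`Lexicon`."""
    params = [PKParameterDef(*row) for row in
              (*_data.IN_VITRO_PARAMETERS, *_data.IN_VIVO_PARAMETERS)]
    return Lexicon(
        parameters=params,
        drugs=_builtin_drugs(),
        probes=_builtin_probes(),
        transporters=[TransporterRecord(*row) for row in _data.TRANSPORTERS],
    )
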