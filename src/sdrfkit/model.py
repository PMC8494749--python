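"""Core domain types and micro-syntax parsers for SDRF-Proteomics.

SDRF column headers follow the MAGE-TAB convention of a category prefix
(``source name``, ``characteristics[...]``, ``comment[...]``,
``factor value[...]``, ``assay name``) with the attribute inside square
brackets.  Cell values for search-relevant properties (modifications,
cleavage agents, instruments) use a semicolon-separated key/value
micro-syntax, e.g. ``AC=UNIMOD:35;NT=Oxidation;MT=Variable;TA=M``.

This module implements those two small grammars plus the typed records
they populate.  Everything is pure and in-memory; file I/O lives in
:mod:`sdrfkit.sdrf` and :mod:`sdrfkit.idf`.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

__all__ = [
    "Category",
    "ColumnKey",
    "OntologyAnnotation",
    "ModType",
    "ModPosition",
    "ModificationSpec",
    "EnzymeSpec",
    "ToleranceUnit",
    "Tolerance",
    "SdrfParseError",
    "parse_column_header",
    "format_column_header",
    "parse_key_value_cell",
    "serialize_key_value_cell",
    "parse_modification",
    "serialize_modification",
    "parse_enzyme",
    "parse_tolerance",
    "parse_ontology_annotation",
]


class SdrfParseError(ValueError):
    """Raised when a header, cell or file fragment cannot be parsed."""


class Category(enum.Enum):
    """The five recognized SDRF column categories."""

    SOURCE_NAME = "source name"
    CHARACTERISTICS = "characteristics"
    COMMENT = "comment"
    FACTOR_VALUE = "factor value"
    ASSAY_NAME = "assay name"


#: Categories whose headers carry no bracketed attribute.
_BARE_CATEGORIES = frozenset({Category.SOURCE_NAME, Category.ASSAY_NAME})
#: Categories whose headers require ``prefix[attribute]``.
_BRACKETED_CATEGORIES = frozenset(
    {Category.CHARACTERISTICS, Category.COMMENT, Category.FACTOR_VALUE}
)


@dataclass(frozen=True, order=True)
class ColumnKey:
    """Parsed identity of one SDRF column.

    The attribute is stored lower-cased and stripped, so two keys that
    differ only in case or incidental whitespace compare equal.
    ``occurrence`` is the 1-based index among identically named columns
    of one table (e.g. several ``comment[modification parameters]``).
    """

    category: Category
    attribute: str = ""
    occurrence: int = 1

    def __post_init__(self) -> None:
        if self.category in _BARE_CATEGORIES:
            if self.attribute:
                raise ValueError(
                    f"{self.category.value!r} columns carry no attribute"
                )
        else:
            if not self.attribute:
                raise ValueError(
                    f"{self.category.value!r} columns require an attribute"
                )
        norm = " ".join(self.attribute.split()).lower()
        object.__setattr__(self, "attribute", norm)
        if self.occurrence < 1:
            raise ValueError("occurrence is 1-based and must be positive")

    @property
    def header(self) -> str:
        """Canonical header text (see :func:`format_column_header`)."""
        return format_column_header(self)


_ACCESSION_RE = re.compile(r"^[A-Za-z]+[A-Za-z0-9_]*:[A-Za-z0-9_.]+$")


@dataclass(frozen=True)
class OntologyAnnotation:
    """A term label with optional ``PREFIX:ID`` accession."""

    label: str
    accession: str | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.accession is not None and not _ACCESSION_RE.match(self.accession):
            raise ValueError(f"malformed accession {self.accession!r}")
        if self.accession is not None and self.source is None:
            object.__setattr__(self, "source", self.accession.split(":", 1)[0])


class ModType(enum.Enum):
    FIXED = "Fixed"
    VARIABLE = "Variable"
    ANNOTATED = "Annotated"


class ModPosition(enum.Enum):
    ANYWHERE = "Anywhere"
    PROTEIN_N_TERM = "Protein N-term"
    PROTEIN_C_TERM = "Protein C-term"
    ANY_N_TERM = "Any N-term"
    ANY_C_TERM = "Any C-term"


@dataclass(frozen=True)
class ModificationSpec:
    """A protein modification from the key/value micro-syntax.

    Keys: NT (name), AC (accession), MT (type, default Variable),
    TA (target residues, comma-separated), PP (position), MM
    (monoisotopic mass, Da), CF (chemical formula).
    """

    name: str | None = None
    accession: str | None = None
    mod_type: ModType = ModType.VARIABLE
    target_amino_acids: tuple[str, ...] = ()
    position: ModPosition | None = None
    monoisotopic_mass: float | None = None
    chemical_formula: str | None = None

    def __post_init__(self) -> None:
        if not self.name and not self.accession:
            raise ValueError("modification needs at least a name (NT) or accession (AC)")
        for aa in self.target_amino_acids:
            if not (len(aa) == 1 and aa.isalpha() and aa.isupper()):
                raise ValueError(f"target residue {aa!r} is not a single uppercase letter")


@dataclass(frozen=True)
class EnzymeSpec:
    """A cleavage agent: name (NT), optional accession (AC) and
    cleavage-site regular expression (CS)."""

    name: str
    accession: str | None = None
    cleavage_site: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("enzyme name must be non-empty")


class ToleranceUnit(enum.Enum):
    PPM = "ppm"
    DA = "Da"


@dataclass(frozen=True)
class Tolerance:
    """A mass tolerance, e.g. ``20 ppm`` or ``0.5 Da``."""

    value: float
    unit: ToleranceUnit

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError("tolerance value must be positive")

    def __str__(self) -> str:
        v = self.value
        text = f"{v:g}"
        return f"{text} {self.unit.value}"


# --------------------------------------------------------------------------
# Column headers
# --------------------------------------------------------------------------

# Accepts optional whitespace between prefix and bracket; both
# "characteristics [organism part]" and "characteristics[organism part]"
# occur in the wild.
_HEADER_RE = re.compile(
    r"^(?P<prefix>characteristics|comment|factor\s+value)\s*"
    r"\[(?P<attr>[^\[\]]*)\]$",
    re.IGNORECASE,
)

_PREFIX_TO_CATEGORY = {
    "characteristics": Category.CHARACTERISTICS,
    "comment": Category.COMMENT,
    "factor value": Category.FACTOR_VALUE,
}


def parse_column_header(header: str, occurrence: int = 1) -> ColumnKey:
    """Parse one SDRF header cell into a :class:`ColumnKey`.

    Matching is case-insensitive and tolerant of whitespace around the
    bracket; the attribute is trimmed and case-folded.

    Raises :class:`SdrfParseError` for unknown prefixes, missing closing
    brackets, or empty attributes in bracketed categories.
    """
    text = header.strip()
    if not text:
        raise SdrfParseError("empty column header")
    folded = " ".join(text.split()).lower()
    if folded == "source name":
        return ColumnKey(Category.SOURCE_NAME, "", occurrence)
    if folded == "assay name":
        return ColumnKey(Category.ASSAY_NAME, "", occurrence)
    m = _HEADER_RE.match(text)
    if m:
        prefix = " ".join(m.group("prefix").split()).lower()
        attr = m.group("attr").strip()
        if not attr:
            raise SdrfParseError(f"empty attribute in column header {header!r}")
        return ColumnKey(_PREFIX_TO_CATEGORY[prefix], attr, occurrence)
    # Diagnose the common failure modes for a useful message.
    for prefix in ("characteristics", "comment", "factor value"):
        if folded.startswith(prefix):
            if "[" in text and "]" not in text:
                raise SdrfParseError(f"missing closing bracket in column header {header!r}")
            raise SdrfParseError(f"malformed column header {header!r}")
    raise SdrfParseError(f"unknown column header prefix in {header!r}")


def format_column_header(key: ColumnKey) -> str:
    """Canonical lowercase rendering: no space before the bracket."""
    if key.category in _BARE_CATEGORIES:
        return key.category.value
    return f"{key.category.value}[{key.attribute}]"


# --------------------------------------------------------------------------
# Key/value cells
# --------------------------------------------------------------------------


def parse_key_value_cell(cell: str) -> dict[str, str]:
    """Split a key/value cell into an ordered key→value map.

    Items are separated by ``;`` and split on the first ``=``; keys are
    upper-cased, both sides whitespace-trimmed, insertion order kept.  A
    cell containing no ``=`` at all is the bare-name shorthand and maps
    to ``{"NT": cell}``.

    Raises :class:`SdrfParseError` on duplicate keys or an item missing
    ``=`` inside an otherwise key/value cell.
    """
    if not cell or not cell.strip():
        raise SdrfParseError("empty key/value cell")
    text = cell.strip()
    if "=" not in text:
        return {"NT": text}
    out: dict[str, str] = {}
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise SdrfParseError(f"item {item!r} in cell {cell!r} has no '='")
        key, value = item.split("=", 1)
        key = key.strip().upper()
        value = value.strip()
        if not key:
            raise SdrfParseError(f"empty key in cell {cell!r}")
        if key in out:
            raise SdrfParseError(f"duplicate key {key!r} in cell {cell!r}")
        out[key] = value
    return out


def serialize_key_value_cell(pairs: dict[str, str]) -> str:
    """Inverse of :func:`parse_key_value_cell` (order-preserving)."""
    return ";".join(f"{k}={v}" for k, v in pairs.items())


# --------------------------------------------------------------------------
# Typed cell parsers
# --------------------------------------------------------------------------

_MOD_POSITIONS = {p.value.lower(): p for p in ModPosition}
_MOD_TYPES = {t.value.lower(): t for t in ModType}


def parse_modification(cell: str) -> ModificationSpec:
    """Parse a modification cell such as
    ``AC=UNIMOD:35;NT=Oxidation;MT=Variable;TA=M``."""
    pairs = parse_key_value_cell(cell)
    name = pairs.get("NT")
    accession = pairs.get("AC")
    if not name and not accession:
        raise SdrfParseError(f"modification cell {cell!r} has neither NT nor AC")
    mt_raw = pairs.get("MT")
    if mt_raw is None:
        mod_type = ModType.VARIABLE
    else:
        try:
            mod_type = _MOD_TYPES[mt_raw.strip().lower()]
        except KeyError:
            raise SdrfParseError(
                f"unknown modification type {mt_raw!r} (expected Fixed/Variable/Annotated)"
            ) from None
    targets: tuple[str, ...] = ()
    if "TA" in pairs:
        targets = tuple(t.strip().upper() for t in pairs["TA"].split(",") if t.strip())
    position = None
    if "PP" in pairs:
        try:
            position = _MOD_POSITIONS[pairs["PP"].strip().lower()]
        except KeyError:
            raise SdrfParseError(f"unknown modification position {pairs['PP']!r}") from None
    mass = None
    if "MM" in pairs:
        try:
            mass = float(pairs["MM"])
        except ValueError:
            raise SdrfParseError(f"non-numeric monoisotopic mass {pairs['MM']!r}") from None
    try:
        return ModificationSpec(
            name=name,
            accession=accession,
            mod_type=mod_type,
            target_amino_acids=targets,
            position=position,
            monoisotopic_mass=mass,
            chemical_formula=pairs.get("CF"),
        )
    except ValueError as exc:
        raise SdrfParseError(str(exc)) from None


def serialize_modification(mod: ModificationSpec) -> str:
    """Render a :class:`ModificationSpec` back to the key/value syntax.

    Emits keys in a fixed AC,NT,MT,PP,TA,MM,CF order; parsing the result
    reproduces the record.
    """
    pairs: dict[str, str] = {}
    if mod.accession:
        pairs["AC"] = mod.accession
    if mod.name:
        pairs["NT"] = mod.name
    pairs["MT"] = mod.mod_type.value
    if mod.position is not None:
        pairs["PP"] = mod.position.value
    if mod.target_amino_acids:
        pairs["TA"] = ",".join(mod.target_amino_acids)
    if mod.monoisotopic_mass is not None:
        pairs["MM"] = repr(mod.monoisotopic_mass)  # shortest exact rendering
    if mod.chemical_formula:
        pairs["CF"] = mod.chemical_formula
    return serialize_key_value_cell(pairs)


def parse_enzyme(cell: str) -> EnzymeSpec:
    """Parse a cleavage-agent cell (keys NT, AC, CS)."""
    pairs = parse_key_value_cell(cell)
    name = pairs.get("NT")
    if not name:
        raise SdrfParseError(f"cleavage-agent cell {cell!r} has no NT (name)")
    return EnzymeSpec(name=name, accession=pairs.get("AC"), cleavage_site=pairs.get("CS"))


_TOLERANCE_RE = re.compile(r"^(?P<num>[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)\s*(?P<unit>[A-Za-z]+)$")


def parse_tolerance(cell: str) -> Tolerance:
    """Parse ``<number> <unit>`` with unit ppm or Da (case-insensitive)."""
    text = cell.strip()
    m = _TOLERANCE_RE.match(text)
    if not m:
        if re.fullmatch(r"[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?", text):
            raise SdrfParseError(f"tolerance {cell!r} is missing a unit (ppm or Da)")
        raise SdrfParseError(f"malformed tolerance {cell!r}")
    unit_raw = m.group("unit").lower()
    if unit_raw == "ppm":
        unit = ToleranceUnit.PPM
    elif unit_raw == "da":
        unit = ToleranceUnit.DA
    else:
        raise SdrfParseError(f"unknown tolerance unit {m.group('unit')!r} (expected ppm or Da)")
    value = float(m.group("num"))
    if not value > 0:
        raise SdrfParseError(f"tolerance value must be positive, got {value}")
    return Tolerance(value, unit)


def parse_ontology_annotation(cell: str) -> OntologyAnnotation:
    """Read a cell as an ontology term.

    Key/value cells use NT for the label and AC for the accession; a
    plain free-text cell becomes a label-only annotation.
    """
    text = cell.strip()
    if "=" in text:
        pairs = parse_key_value_cell(text)
        label = pairs.get("NT", "")
        accession = pairs.get("AC")
        if not label and not accession:
            raise SdrfParseError(f"ontology cell {cell!r} has neither NT nor AC")
        return OntologyAnnotation(label=label, accession=accession)
    return OntologyAnnotation(label=text)
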