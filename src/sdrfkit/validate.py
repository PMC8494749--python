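"""Structural, consistency, template and vocabulary validation of SDRF
tables.

Validation never raises on bad data: every problem becomes a
:class:`ValidationFinding` with a severity and a stable rule id, so a
report can show all problems at once.  Three rule families run in
order:

* structural rules S1–S14 — column presence, cell consistency across
  rows of one sample or one data file, label sanity;
* template rules — experiment-type requirements loaded from bundled
  YAML schemas (default, human, cell-line), so repository policy
  changes are data edits, not code edits;
* vocabulary rules V1–V3 — accession-carrying cells checked against an
  offline controlled-vocabulary store.

A table is *valid* exactly when it has no ERROR finding.
"""

from __future__ import annotations

import enum
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from . import labels as _labels
from .cv import CvStore
from .model import (
    Category,
    ColumnKey,
    SdrfParseError,
    format_column_header,
    parse_key_value_cell,
)
from .sdrf import SdrfTable

__all__ = [
    "Severity",
    "ValidationFinding",
    "ValidationReport",
    "TemplateSchema",
    "load_template",
    "available_templates",
    "validate_structure",
    "validate_template",
    "validate_terms",
    "validate",
    "REQUIRED_CHARACTERISTICS",
    "REQUIRED_COMMENTS",
    "RECOMMENDED_COMMENTS",
]


class Severity(enum.Enum):
    ERROR = "ERROR"
    WARNING = "WARNING"
    INFO = "INFO"


@dataclass(frozen=True)
class ValidationFinding:
    severity: Severity
    rule_id: str
    message: str
    row: int | None = None  # 1-based data-row index
    column: str | None = None  # canonical header

    def __str__(self) -> str:
        loc = []
        if self.row is not None:
            loc.append(f"row {self.row}")
        if self.column is not None:
            loc.append(f"column {self.column!r}")
        where = f" ({', '.join(loc)})" if loc else ""
        return f"{self.severity.value} [{self.rule_id}]{where}: {self.message}"

    def to_dict(self) -> dict:
        return {
            "severity": self.severity.value,
            "rule_id": self.rule_id,
            "message": self.message,
            "row": self.row,
            "column": self.column,
        }


@dataclass
class ValidationReport:
    findings: list[ValidationFinding]

    @property
    def counts(self) -> dict[str, int]:
        c = Counter(f.severity.value for f in self.findings)
        return {s.value: c.get(s.value, 0) for s in Severity}

    @property
    def n_errors(self) -> int:
        return self.counts["ERROR"]

    @property
    def valid(self) -> bool:
        return self.n_errors == 0

    def to_text(self) -> str:
        lines = [str(f) for f in self.findings]
        c = self.counts
        lines.append(
            f"{c['ERROR']} error(s), {c['WARNING']} warning(s), {c['INFO']} info "
            f"-> {'VALID' if self.valid else 'INVALID'}"
        )
        return "\n".join(lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "valid": self.valid,
                "counts": self.counts,
                "findings": [f.to_dict() for f in self.findings],
            },
            indent=2,
        )


# Universal mandatory properties: every proteomics experiment must state
# the organism, the organism part and the biological replicate for each
# sample, and the fraction identifier, technical replicate and data file
# for each acquisition.
REQUIRED_CHARACTERISTICS = ("organism", "organism part", "biological replicate")
REQUIRED_COMMENTS = ("fraction identifier", "technical replicate", "data file")
RECOMMENDED_COMMENTS = (
    "instrument",
    "cleavage agent",
    "fragment mass tolerance",
    "precursor mass tolerance",
    "modification parameters",
)

_KNOWN_KV_KEYS = frozenset({"AC", "NT", "MT", "TA", "PP", "MM", "CF", "CS", "TS"})

_SOURCE = ColumnKey(Category.SOURCE_NAME)
_ASSAY = ColumnKey(Category.ASSAY_NAME)
_DATA_FILE = ColumnKey(Category.COMMENT, "data file")
_LABEL = ColumnKey(Category.COMMENT, "label")


def _required_columns(table: SdrfTable) -> list[ColumnKey]:
    keys = [_SOURCE, _ASSAY]
    keys += [ColumnKey(Category.CHARACTERISTICS, a) for a in REQUIRED_CHARACTERISTICS]
    keys += [ColumnKey(Category.COMMENT, a) for a in REQUIRED_COMMENTS]
    keys.append(_LABEL)
    return [k for k in keys if table.has_column(k)]


def validate_structure(table: SdrfTable) -> list[ValidationFinding]:
    """Apply the structural rule registry S1–S14."""
    out: list[ValidationFinding] = []

    def finding(severity, rule, message, row=None, column=None):
        out.append(ValidationFinding(severity, rule, message, row, column))

    # S1: exactly one source name and one assay name column
    for key, what in ((_SOURCE, "source name"), (_ASSAY, "assay name")):
        n = sum(1 for k in table.columns if k.category == key.category)
        if n != 1:
            finding(
                Severity.ERROR, "S1",
                f"table must have exactly one {what!r} column, found {n}",
                column=what,
            )
    # S2: data file column present
    if not table.has_column(_DATA_FILE):
        finding(Severity.ERROR, "S2", "missing required column", column=_DATA_FILE.header)
    # S3 / S4: universal mandatory characteristics and comments
    for attr in REQUIRED_CHARACTERISTICS:
        key = ColumnKey(Category.CHARACTERISTICS, attr)
        if not table.has_column(key):
            finding(Severity.ERROR, "S3", "missing required column", column=key.header)
    for attr in ("fraction identifier", "technical replicate"):  # data file covered by S2
        key = ColumnKey(Category.COMMENT, attr)
        if not table.has_column(key):
            finding(Severity.ERROR, "S4", "missing required column", column=key.header)
    # S14: label column required (label-free uses the sentinel value)
    if not table.has_column(_LABEL):
        finding(
            Severity.ERROR, "S14",
            f"missing required column (label-free runs use the value {_labels.DEFAULT_LABEL!r})",
            column=_LABEL.header,
        )
    # S5: no empty cell in any required column that is present
    for key in _required_columns(table):
        for i, cell in enumerate(table.column_values(key), start=1):
            if not cell.strip():
                finding(Severity.ERROR, "S5", "empty cell in required column",
                        row=i, column=key.header)
    # S6: fraction identifiers are positive integers
    if table.has_column(ColumnKey(Category.COMMENT, "fraction identifier")):
        for i, cell in enumerate(
            table.column_values(ColumnKey(Category.COMMENT, "fraction identifier")), start=1
        ):
            if not re.fullmatch(r"[1-9][0-9]*", cell.strip()):
                finding(Severity.ERROR, "S6",
                        f"fraction identifier {cell!r} is not a positive integer",
                        row=i, column="comment[fraction identifier]")
    # S7: rows of one sample agree on every characteristics cell
    src_idx = table.column_index(_SOURCE)
    char_cols = [(k, table.column_index(k)) for k in table.columns_of_category(Category.CHARACTERISTICS)]
    if src_idx is not None:
        groups: dict[str, list[int]] = {}
        for i, row in enumerate(table.rows):
            groups.setdefault(row[src_idx], []).append(i)
        for name, indices in groups.items():
            for key, idx in char_cols:
                values = {table.rows[i][idx] for i in indices}
                if len(values) > 1:
                    finding(Severity.ERROR, "S7",
                            f"sample {name!r} has conflicting values {sorted(values)!r}",
                            row=indices[0] + 1, column=key.header)
        # S12: exact duplicate rows
        seen: dict[tuple, int] = {}
        for i, row in enumerate(table.rows):
            t = tuple(row)
            if t in seen:
                finding(Severity.WARNING, "S12",
                        f"row duplicates row {seen[t] + 1} exactly", row=i + 1)
            else:
                seen[t] = i
    # S8 / S9: per-file consistency
    file_idx = table.column_index(_DATA_FILE)
    label_idx = table.column_index(_LABEL)
    if file_idx is not None:
        file_groups: dict[str, list[int]] = {}
        for i, row in enumerate(table.rows):
            file_groups.setdefault(row[file_idx], []).append(i)
        per_file_attrs = ("fraction identifier", "technical replicate", "instrument")
        for fname, indices in file_groups.items():
            for attr in per_file_attrs:
                key = ColumnKey(Category.COMMENT, attr)
                idx = table.column_index(key)
                if idx is None:
                    continue
                values = {table.rows[i][idx] for i in indices}
                if len(values) > 1:
                    finding(Severity.ERROR, "S8",
                            f"data file {fname!r} has conflicting values {sorted(values)!r}",
                            row=indices[0] + 1, column=key.header)
        if label_idx is not None and src_idx is not None:
            pair_to_sources: dict[tuple[str, str], dict[str, int]] = {}
            for i, row in enumerate(table.rows):
                pair = (row[file_idx], row[label_idx])
                pair_to_sources.setdefault(pair, {}).setdefault(row[src_idx], i)
            for (fname, label), sources in pair_to_sources.items():
                if len(sources) > 1:
                    finding(Severity.ERROR, "S9",
                            f"data file {fname!r} channel {label!r} is claimed by "
                            f"several samples: {sorted(sources)!r}",
                            row=min(sources.values()) + 1, column=_DATA_FILE.header)
    # S10: recommended comments
    for attr in RECOMMENDED_COMMENTS:
        key = ColumnKey(Category.COMMENT, attr)
        if not table.has_column(key):
            finding(Severity.WARNING, "S10", "recommended column missing", column=key.header)
    # S11: label values drawn from the bundled channel list
    if label_idx is not None:
        flagged: set[str] = set()
        for i, row in enumerate(table.rows):
            value = row[label_idx]
            if value and value not in _labels.KNOWN_LABELS and value not in flagged:
                flagged.add(value)
                finding(Severity.WARNING, "S11",
                        f"label {value!r} is not in the bundled channel list",
                        row=i + 1, column=_LABEL.header)
    # S13: constant factor values
    for key in table.columns_of_category(Category.FACTOR_VALUE):
        if table.rows:
            values = set(table.column_values(key))
            if len(values) == 1:
                finding(Severity.INFO, "S13",
                        f"factor value column has a single distinct value {next(iter(values))!r}",
                        column=key.header)
    return out


# --------------------------------------------------------------------------
# Templates
# --------------------------------------------------------------------------


@dataclass
class TemplateSchema:
    """Experiment-type requirements layered over the universal rules."""

    name: str
    rules: list[dict] = field(default_factory=list)

    @property
    def required_characteristics(self) -> list[str]:
        req = list(REQUIRED_CHARACTERISTICS)
        for rule in self.rules:
            if (
                rule["kind"] == "require_column"
                and rule["category"] == "characteristics"
                and rule["severity"] == "ERROR"
            ):
                req.append(rule["attribute"])
        return req

    @property
    def required_comments(self) -> list[str]:
        req = list(REQUIRED_COMMENTS)
        for rule in self.rules:
            if (
                rule["kind"] == "require_column"
                and rule["category"] == "comment"
                and rule["severity"] == "ERROR"
            ):
                req.append(rule["attribute"])
        return req


def _template_dir():
    return resources.files("sdrfkit").joinpath("data", "templates")


def available_templates() -> list[str]:
    return sorted(p.name[: -len(".yaml")] for p in _template_dir().iterdir()
                  if p.name.endswith(".yaml"))


def load_template(name_or_path: str | Path) -> TemplateSchema:
    """Load a bundled template by name or a user schema by path."""
    path = Path(name_or_path)
    if path.suffix in {".yaml", ".yml"} and path.exists():
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
    else:
        candidate = _template_dir().joinpath(f"{name_or_path}.yaml")
        if not candidate.is_file():
            raise SdrfParseError(
                f"unknown template {name_or_path!r}; available: "
                + ", ".join(available_templates())
            )
        raw = yaml.safe_load(candidate.read_text(encoding="utf-8"))
    return TemplateSchema(name=raw["name"], rules=list(raw.get("rules") or []))


_CATEGORY_BY_NAME = {
    "characteristics": Category.CHARACTERISTICS,
    "comment": Category.COMMENT,
    "factor value": Category.FACTOR_VALUE,
}


def validate_template(table: SdrfTable, template: TemplateSchema) -> list[ValidationFinding]:
    """Apply one template's rules (on top of, not including, the
    structural registry)."""
    out: list[ValidationFinding] = []
    for rule in template.rules:
        severity = Severity[rule["severity"]]
        key = ColumnKey(_CATEGORY_BY_NAME[rule["category"]], rule["attribute"])
        kind = rule["kind"]
        message = rule.get("message", "")
        if kind == "require_column":
            if not table.has_column(key):
                out.append(ValidationFinding(severity, rule["id"],
                                             message or "required column missing",
                                             column=key.header))
        elif kind == "fixed_value":
            if table.has_column(key):
                for i, cell in enumerate(table.column_values(key), start=1):
                    if cell != rule["value"]:
                        out.append(ValidationFinding(
                            severity, rule["id"],
                            message or f"cell must equal {rule['value']!r}, found {cell!r}",
                            row=i, column=key.header))
        elif kind == "expect_value":
            if table.has_column(key) and table.rows:
                wanted = str(rule["value"]).lower()
                if not any(c.strip().lower() == wanted for c in table.column_values(key)):
                    out.append(ValidationFinding(severity, rule["id"],
                                                 message or f"no cell equals {rule['value']!r}",
                                                 column=key.header))
        else:
            raise SdrfParseError(f"unknown template rule kind {kind!r} in {template.name!r}")
    return out


# --------------------------------------------------------------------------
# Vocabulary checks
# --------------------------------------------------------------------------


def validate_terms(table: SdrfTable, store: CvStore) -> list[ValidationFinding]:
    """Check accession-carrying key/value cells against the CV store.

    Free-text cells are always accepted.  V1 — accession missing from
    the store; V2 — stored label differs from the cell's NT
    (case-insensitive); V3 (info) — key outside the documented key set,
    preserved but reported.
    """
    out: list[ValidationFinding] = []
    cols = [
        (k, table.column_index(k))
        for k in table.columns
        if k.category in (Category.CHARACTERISTICS, Category.COMMENT)
    ]
    for key, idx in cols:
        for i, row in enumerate(table.rows, start=1):
            cell = row[idx]
            if "=" not in cell:
                continue
            try:
                pairs = parse_key_value_cell(cell)
            except SdrfParseError:
                continue  # free text that merely contains '='
            for k in pairs:
                if k not in _KNOWN_KV_KEYS:
                    out.append(ValidationFinding(
                        Severity.INFO, "V3",
                        f"unrecognized key {k!r} preserved verbatim",
                        row=i, column=key.header))
            accession = pairs.get("AC")
            if not accession:
                continue
            hit = store.lookup_accession(accession)
            if hit is None:
                out.append(ValidationFinding(
                    Severity.WARNING, "V1",
                    f"accession {accession!r} not found in the vocabulary store",
                    row=i, column=key.header))
            else:
                name = pairs.get("NT")
                if name and hit[0].lower() != name.strip().lower():
                    out.append(ValidationFinding(
                        Severity.WARNING, "V2",
                        f"label {name!r} does not match the stored label {hit[0]!r} "
                        f"for {accession}",
                        row=i, column=key.header))
    return out


_RULE_SORT_RE = re.compile(r"^([A-Za-z]+)(\d+)$")


def _sort_key(f: ValidationFinding):
    m = _RULE_SORT_RE.match(f.rule_id)
    family, num = (m.group(1), int(m.group(2))) if m else (f.rule_id, 0)
    return (family, num, f.row if f.row is not None else -1, f.column or "")


def validate(
    table: SdrfTable,
    template: TemplateSchema | str | None = None,
    store: CvStore | None = None,
) -> ValidationReport:
    """Run all rule families and aggregate a deterministic report.

    *template* may be a schema, a bundled template name, or None (the
    default template); *store* may be None to skip vocabulary checks.
    """
    if template is None:
        template = load_template("default")
    elif isinstance(template, str):
        template = load_template(template)
    findings = validate_structure(table)
    findings += validate_template(table, template)
    if store is not None:
        findings += validate_terms(table, store)
    findings.sort(key=_sort_key)
    return ValidationReport(findings=findings)
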