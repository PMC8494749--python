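"""Converters from a validated SDRF table to downstream analysis inputs.

Two canonical outputs are produced:

* per-file search parameters — instrument, cleavage agent, mass
  tolerances and modifications collected from the comment columns and
  parsed through the key/value micro-syntax, emitted as a neutral
  structured-text (YAML) document per data file;
* a flat annotation table — one row per SDRF data row with run,
  fraction, channel, replicate and condition columns, the shape
  quantification tools expect for experimental-design input.

Both converters are pure: the input table is never modified and
repeated calls produce identical output.  They assume a table that
already validates without errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO

import pandas as pd
import yaml

from .model import (
    Category,
    ColumnKey,
    EnzymeSpec,
    ModificationSpec,
    ModType,
    OntologyAnnotation,
    SdrfParseError,
    Tolerance,
    parse_enzyme,
    parse_modification,
    parse_ontology_annotation,
    parse_tolerance,
    serialize_modification,
)
from .sdrf import DEFAULT_LABEL, MISSING_TOKENS, SdrfTable

__all__ = [
    "SearchParams",
    "AnnotationRow",
    "AnnotationTable",
    "extract_search_params",
    "to_annotation_table",
    "write_search_params",
]

logger = logging.getLogger(__name__)

_DATA_FILE = ColumnKey(Category.COMMENT, "data file")
_LABEL = ColumnKey(Category.COMMENT, "label")
_INSTRUMENT = ColumnKey(Category.COMMENT, "instrument")
_CLEAVAGE = ColumnKey(Category.COMMENT, "cleavage agent")
_FRAG_TOL = ColumnKey(Category.COMMENT, "fragment mass tolerance")
_PREC_TOL = ColumnKey(Category.COMMENT, "precursor mass tolerance")


@dataclass(frozen=True)
class SearchParams:
    """Search-relevant acquisition parameters of one data file."""

    data_file: str
    instrument: OntologyAnnotation | None = None
    enzyme: EnzymeSpec | None = None
    precursor_tolerance: Tolerance | None = None
    fragment_tolerance: Tolerance | None = None
    fixed_modifications: tuple[ModificationSpec, ...] = ()
    variable_modifications: tuple[ModificationSpec, ...] = ()
    annotated_modifications: tuple[ModificationSpec, ...] = ()
    label_scheme: str = DEFAULT_LABEL

    def to_dict(self) -> dict:
        """Stable-order plain mapping for serialization."""
        return {
            "data_file": self.data_file,
            "instrument": None if self.instrument is None else {
                "label": self.instrument.label,
                "accession": self.instrument.accession,
            },
            "enzyme": None if self.enzyme is None else {
                "name": self.enzyme.name,
                "accession": self.enzyme.accession,
                "cleavage_site": self.enzyme.cleavage_site,
            },
            "precursor_tolerance": None if self.precursor_tolerance is None
            else str(self.precursor_tolerance),
            "fragment_tolerance": None if self.fragment_tolerance is None
            else str(self.fragment_tolerance),
            "fixed_modifications": [serialize_modification(m) for m in self.fixed_modifications],
            "variable_modifications": [serialize_modification(m) for m in self.variable_modifications],
            "annotated_modifications": [serialize_modification(m) for m in self.annotated_modifications],
            "label_scheme": self.label_scheme,
        }


def _is_missing(cell: str) -> bool:
    return not cell.strip() or cell.strip().lower() in MISSING_TOKENS


def _unique_cell(table: SdrfTable, indices: list[int], key: ColumnKey,
                 data_file: str) -> str | None:
    idx = table.column_index(key)
    if idx is None:
        return None
    values = {table.rows[i][idx] for i in indices if not _is_missing(table.rows[i][idx])}
    if not values:
        return None
    if len(values) > 1:
        raise SdrfParseError(
            f"data file {data_file!r} has conflicting values in column "
            f"{key.header!r}: {sorted(values)!r}"
        )
    return next(iter(values))


def extract_search_params(table: SdrfTable) -> list[SearchParams]:
    """One :class:`SearchParams` record per distinct data file.

    Absent columns yield absent fields (with a logged warning);
    conflicting values across one file's rows raise
    :class:`SdrfParseError` naming the file and column.
    """
    file_idx = table.column_index(_DATA_FILE)
    if file_idx is None:
        raise SdrfParseError("table has no 'comment[data file]' column")
    for key in (_INSTRUMENT, _CLEAVAGE, _FRAG_TOL, _PREC_TOL):
        if not table.has_column(key):
            logger.warning("column %r absent; field left empty in search parameters",
                           key.header)
    mod_cols = [
        k for k in table.columns
        if k.category == Category.COMMENT and k.attribute == "modification parameters"
    ]
    label_idx = table.column_index(_LABEL)
    groups: dict[str, list[int]] = {}
    for i, row in enumerate(table.rows):
        groups.setdefault(row[file_idx], []).append(i)
    out: list[SearchParams] = []
    for data_file, indices in groups.items():
        def cell_of(key: ColumnKey) -> str | None:
            return _unique_cell(table, indices, key, data_file)

        def parse_cell(key: ColumnKey, parser):
            raw = cell_of(key)
            if raw is None:
                return None
            try:
                return parser(raw)
            except SdrfParseError as exc:
                raise SdrfParseError(
                    f"data file {data_file!r}, column {key.header!r}: {exc}"
                ) from None

        fixed: list[ModificationSpec] = []
        variable: list[ModificationSpec] = []
        annotated: list[ModificationSpec] = []
        for key in mod_cols:
            mod = parse_cell(key, parse_modification)
            if mod is None:
                continue
            {ModType.FIXED: fixed,
             ModType.VARIABLE: variable,
             ModType.ANNOTATED: annotated}[mod.mod_type].append(mod)
        if label_idx is None:
            label_scheme = DEFAULT_LABEL
        else:
            seen: list[str] = []
            for i in indices:
                value = table.rows[i][label_idx]
                if value not in seen:
                    seen.append(value)
            label_scheme = ",".join(seen)
        out.append(SearchParams(
            data_file=data_file,
            instrument=parse_cell(_INSTRUMENT, parse_ontology_annotation),
            enzyme=parse_cell(_CLEAVAGE, parse_enzyme),
            precursor_tolerance=parse_cell(_PREC_TOL, parse_tolerance),
            fragment_tolerance=parse_cell(_FRAG_TOL, parse_tolerance),
            fixed_modifications=tuple(fixed),
            variable_modifications=tuple(variable),
            annotated_modifications=tuple(annotated),
            label_scheme=label_scheme,
        ))
    return out


def write_search_params(params: list[SearchParams], out_dir: str | Path) -> list[Path]:
    """Write one YAML parameter document per data file into *out_dir*;
    returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in params:
        stem = Path(p.data_file).name.rsplit(".", 1)[0] or "params"
        path = out_dir / f"{stem}.params.yaml"
        path.write_text(
            yaml.safe_dump(p.to_dict(), sort_keys=False, allow_unicode=True),
            encoding="utf-8",
        )
        paths.append(path)
    return paths


@dataclass(frozen=True)
class AnnotationRow:
    run: str
    fraction: int
    label: str
    bio_replicate: str
    tech_replicate: str
    condition: str


@dataclass
class AnnotationTable:
    """Flat experimental-design table: one row per SDRF data row."""

    rows: list[AnnotationRow] = field(default_factory=list)

    COLUMNS = ("run", "fraction", "label", "bio_replicate", "tech_replicate", "condition")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows], columns=list(self.COLUMNS))

    def write_csv(self, stream_or_path: IO[str] | str | Path) -> None:
        df = self.to_dataframe()
        df.to_csv(stream_or_path, index=False, lineterminator="\n")


def to_annotation_table(table: SdrfTable) -> AnnotationTable:
    """Flatten the SDRF into run/fraction/label/replicate/condition rows.

    The condition is the factor value cells joined with ``_`` in column
    order; a table with no factor value column is rejected because the
    variables under study must be declared.
    """
    factor_cols = table.columns_of_category(Category.FACTOR_VALUE)
    if not factor_cols:
        raise SdrfParseError(
            "table has no 'factor value[...]' column; the variables under "
            "study must be specified"
        )
    file_idx = table.column_index(_DATA_FILE)
    if file_idx is None:
        raise SdrfParseError("table has no 'comment[data file]' column")
    label_idx = table.column_index(_LABEL)
    frac_idx = table.column_index(ColumnKey(Category.COMMENT, "fraction identifier"))
    bio_idx = table.column_index(ColumnKey(Category.CHARACTERISTICS, "biological replicate"))
    tech_idx = table.column_index(ColumnKey(Category.COMMENT, "technical replicate"))
    factor_idx = [table.column_index(k) for k in factor_cols]
    rows = []
    for i, row in enumerate(table.rows, start=1):
        frac_raw = row[frac_idx] if frac_idx is not None else "1"
        try:
            fraction = int(frac_raw.strip())
        except ValueError:
            raise SdrfParseError(
                f"row {i}: fraction identifier {frac_raw!r} is not an integer"
            ) from None
        rows.append(AnnotationRow(
            run=row[file_idx].rsplit(".", 1)[0],
            fraction=fraction,
            label=row[label_idx] if label_idx is not None else DEFAULT_LABEL,
            bio_replicate=row[bio_idx] if bio_idx is not None else "",
            tech_replicate=row[tech_idx] if tech_idx is not None else "",
            condition="_".join(row[j] for j in factor_idx),
        ))
    return AnnotationTable(rows=rows)
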