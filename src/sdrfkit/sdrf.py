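"""Reading, writing and reshaping SDRF tables.

An SDRF file is a UTF-8 tab-delimited table whose header row names the
columns and in which each data row records one sample↔data-file
relationship (for multiplexed acquisitions, one channel of one file).
``SdrfTable`` keeps cells verbatim as text; typed interpretation happens
in the validator and converters.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Mapping

import pandas as pd

from .model import (
    Category,
    ColumnKey,
    SdrfParseError,
    format_column_header,
    parse_column_header,
)

__all__ = [
    "MISSING_VALUE",
    "MISSING_TOKENS",
    "DEFAULT_LABEL",
    "SdrfTable",
    "SampleView",
    "AssayView",
    "read_sdrf",
    "write_sdrf",
    "samples_of",
    "assays_of",
    "merge_tables",
    "split_table",
]

#: Token emitted for cells absent from a source table (e.g. after merge).
MISSING_VALUE = "not available"
#: Tokens recognized as missing on read.
MISSING_TOKENS = frozenset({"not available", "not applicable"})
#: Label value used for unlabeled (label-free) acquisitions.
DEFAULT_LABEL = "label free sample"

DATA_FILE = ColumnKey(Category.COMMENT, "data file")
LABEL = ColumnKey(Category.COMMENT, "label")
SOURCE_NAME = ColumnKey(Category.SOURCE_NAME)
ASSAY_NAME = ColumnKey(Category.ASSAY_NAME)


@dataclass
class SdrfTable:
    """An in-memory SDRF table: ordered columns × verbatim text rows."""

    columns: list[ColumnKey]
    rows: list[list[str]]
    provenance: str | None = None

    def __post_init__(self) -> None:
        ncol = len(self.columns)
        for i, row in enumerate(self.rows):
            if len(row) != ncol:
                raise ValueError(
                    f"row {i + 1} has {len(row)} cells, expected {ncol}"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def headers(self) -> list[str]:
        return [format_column_header(k) for k in self.columns]

    def column_index(self, key: ColumnKey) -> int | None:
        """Index of *key* in this table, or None if absent."""
        try:
            return self.columns.index(key)
        except ValueError:
            return None

    def column_values(self, key: ColumnKey) -> list[str]:
        idx = self.column_index(key)
        if idx is None:
            raise KeyError(f"column {format_column_header(key)!r} not in table")
        return [row[idx] for row in self.rows]

    def columns_of_category(self, category: Category) -> list[ColumnKey]:
        return [k for k in self.columns if k.category == category]

    def has_column(self, key: ColumnKey) -> bool:
        return self.column_index(key) is not None

    def to_dataframe(self) -> pd.DataFrame:
        """Cells as a pandas DataFrame with canonical header names.

        Repeated keys get a ``.N`` suffix from pandas-compatible
        disambiguation of the occurrence index.
        """
        names = []
        for key in self.columns:
            base = format_column_header(key)
            names.append(base if key.occurrence == 1 else f"{base}.{key.occurrence}")
        return pd.DataFrame(self.rows, columns=names, dtype=str)

    def copy(self) -> "SdrfTable":
        return SdrfTable(
            columns=list(self.columns),
            rows=[list(r) for r in self.rows],
            provenance=self.provenance,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SdrfTable):
            return NotImplemented
        return self.columns == other.columns and self.rows == other.rows


@dataclass(frozen=True)
class SampleView:
    """All rows of one sample (one distinct source name)."""

    source_name: str
    characteristics: Mapping[str, str]
    row_indices: tuple[int, ...]


@dataclass(frozen=True)
class AssayView:
    """All rows of one acquisition channel: a (data file, label) pair."""

    data_file: str
    label: str
    comments: Mapping[str, str]
    row_indices: tuple[int, ...]


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------


def _assign_occurrences(headers: list[str]) -> list[ColumnKey]:
    keys: list[ColumnKey] = []
    counts: Counter[tuple[Category, str]] = Counter()
    errors: list[str] = []
    for pos, header in enumerate(headers, start=1):
        try:
            base = parse_column_header(header)
        except SdrfParseError as exc:
            errors.append(f"column {pos}: {exc}")
            continue
        ident = (base.category, base.attribute)
        counts[ident] += 1
        keys.append(replace(base, occurrence=counts[ident]))
    if errors:
        raise SdrfParseError("header errors: " + "; ".join(errors))
    return keys


def read_sdrf(stream: IO[str] | str, provenance: str | None = None) -> SdrfTable:
    """Read an SDRF table from a text stream or string.

    The first line is the header; repeated headers receive increasing
    occurrence indices.  Cell text is kept verbatim (no trimming beyond
    line terminators); trailing blank lines are ignored.  Ragged rows
    raise :class:`SdrfParseError` with the 1-based file line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    text = stream.read()
    lines = text.split("\n")
    # \r\n accepted on read
    lines = [ln[:-1] if ln.endswith("\r") else ln for ln in lines]
    while lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise SdrfParseError("empty SDRF: missing header line")
    columns = _assign_occurrences(lines[0].split("\t"))
    ncol = len(columns)
    rows: list[list[str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        if len(cells) != ncol:
            raise SdrfParseError(
                f"line {lineno}: row has {len(cells)} cells, expected {ncol}"
            )
        rows.append(cells)
    return SdrfTable(columns=columns, rows=rows, provenance=provenance)


def write_sdrf(table: SdrfTable, stream: IO[str]) -> None:
    """Write *table* with canonical headers, tab separators and ``\\n``
    line endings.  Cells must not embed tabs or newlines."""
    for i, row in enumerate(table.rows):
        for key, cell in zip(table.columns, row):
            if "\t" in cell or "\n" in cell or "\r" in cell:
                raise SdrfParseError(
                    f"row {i + 1}, column {format_column_header(key)!r}: "
                    "cell embeds a tab or newline"
                )
    stream.write("\t".join(table.headers) + "\n")
    for row in table.rows:
        stream.write("\t".join(row) + "\n")


def sdrf_to_string(table: SdrfTable) -> str:
    buf = io.StringIO()
    write_sdrf(table, buf)
    return buf.getvalue()


# --------------------------------------------------------------------------
# Views
# --------------------------------------------------------------------------


def samples_of(table: SdrfTable) -> list[SampleView]:
    """One view per distinct source name, in first-appearance order.

    Characteristics come from the first row of each group; conflicting
    repeats are a validator concern, not a reader error.
    """
    src_idx = table.column_index(SOURCE_NAME)
    if src_idx is None:
        raise SdrfParseError("table has no 'source name' column")
    char_cols = [
        (k, table.column_index(k)) for k in table.columns_of_category(Category.CHARACTERISTICS)
    ]
    groups: dict[str, list[int]] = {}
    for i, row in enumerate(table.rows):
        groups.setdefault(row[src_idx], []).append(i)
    views = []
    for name, indices in groups.items():
        first = table.rows[indices[0]]
        chars = {k.attribute: first[idx] for k, idx in char_cols}
        views.append(SampleView(name, chars, tuple(indices)))
    return views


def assays_of(table: SdrfTable) -> list[AssayView]:
    """One view per distinct (data file, label) pair.

    If ``comment[label]`` is absent every row is treated as label-free
    (label ``"label free sample"``).
    """
    file_idx = table.column_index(DATA_FILE)
    if file_idx is None:
        raise SdrfParseError("table has no 'comment[data file]' column")
    label_idx = table.column_index(LABEL)
    comment_cols = [
        (k, table.column_index(k)) for k in table.columns_of_category(Category.COMMENT)
    ]
    groups: dict[tuple[str, str], list[int]] = {}
    for i, row in enumerate(table.rows):
        label = row[label_idx] if label_idx is not None else DEFAULT_LABEL
        groups.setdefault((row[file_idx], label), []).append(i)
    views = []
    for (data_file, label), indices in groups.items():
        first = table.rows[indices[0]]
        comments = {k.attribute: first[idx] for k, idx in comment_cols}
        views.append(AssayView(data_file, label, comments, tuple(indices)))
    return views


# --------------------------------------------------------------------------
# Merge / split
# --------------------------------------------------------------------------


def _sample_characteristics(table: SdrfTable) -> dict[str, dict[str, str]]:
    return {v.source_name: dict(v.characteristics) for v in samples_of(table)}


def merge_tables(tables: Iterable[SdrfTable]) -> SdrfTable:
    """Concatenate SDRF tables from different datasets.

    Output columns are the union of input columns in first-appearance
    order (matched by canonical :class:`ColumnKey`); rows keep input
    order; cells missing from a source table are filled with
    ``"not available"``.  A source name that appears in several inputs
    with conflicting characteristics raises :class:`SdrfParseError` —
    samples must stay unambiguous after a merge.
    """
    tables = list(tables)
    columns: list[ColumnKey] = []
    for t in tables:
        for key in t.columns:
            if key not in columns:
                columns.append(key)
    # Detect colliding source names with conflicting sample metadata.
    seen: dict[str, dict[str, str]] = {}
    conflicts: set[str] = set()
    for t in tables:
        if t.column_index(SOURCE_NAME) is None:
            continue
        for name, chars in _sample_characteristics(t).items():
            if name in seen:
                prev = seen[name]
                for attr in set(prev) & set(chars):
                    if prev[attr] != chars[attr]:
                        conflicts.add(name)
                seen[name].update(chars)
            else:
                seen[name] = dict(chars)
    if conflicts:
        raise SdrfParseError(
            "merge would make samples ambiguous; conflicting characteristics for "
            "source name(s): " + ", ".join(sorted(conflicts))
        )
    rows: list[list[str]] = []
    for t in tables:
        mapping = [t.column_index(key) for key in columns]
        for row in t.rows:
            rows.append([row[idx] if idx is not None else MISSING_VALUE for idx in mapping])
    return SdrfTable(columns=columns, rows=rows)


def split_table(table: SdrfTable, key: ColumnKey) -> dict[str, SdrfTable]:
    """Partition *table* by the values of one column.

    Returns one sub-table per distinct cell value, keyed by that value,
    in first-appearance order; every sub-table keeps all columns and the
    original relative row order.
    """
    idx = table.column_index(key)
    if idx is None:
        raise SdrfParseError(f"split key {format_column_header(key)!r} not in table")
    parts: dict[str, list[list[str]]] = {}
    for row in table.rows:
        parts.setdefault(row[idx], []).append(list(row))
    return {
        value: SdrfTable(columns=list(table.columns), rows=rows, provenance=table.provenance)
        for value, rows in parts.items()
    }


# Canonical section order on write: sample metadata, then data-file
# properties, then the variables under study.
_SECTION_ORDER = {
    Category.SOURCE_NAME: 0,
    Category.CHARACTERISTICS: 1,
    Category.ASSAY_NAME: 2,
    Category.COMMENT: 3,
    Category.FACTOR_VALUE: 4,
}


def canonicalize(table: SdrfTable) -> SdrfTable:
    """Reorder columns into the canonical three-section layout
    (sample metadata, file properties, factor values); row order and
    cell text are untouched."""
    order = sorted(
        range(len(table.columns)),
        key=lambda i: (_SECTION_ORDER[table.columns[i].category], i),
    )
    return SdrfTable(
        columns=[table.columns[i] for i in order],
        rows=[[row[i] for i in order] for row in table.rows],
        provenance=table.provenance,
    )
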