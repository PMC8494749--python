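"""IDF (Investigation Description Format) study-description files.

An IDF file is a tab-delimited series of key/value lines: the first
cell of a line is the property key, the remaining cells its values
(most keys may carry several values, e.g. several analysis software
tools, and the Person* keys are column-aligned across people).  The
module also builds an IDF from a neutral dataset-description record of
the kind repositories capture at submission time (title, description,
submitters, instruments, publications, keywords).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO

from .model import OntologyAnnotation, SdrfParseError

__all__ = [
    "IdfDocument",
    "DatasetDescription",
    "read_idf",
    "write_idf",
    "idf_from_description",
    "description_from_idf",
]

SDRF_FILE_KEY = "SDRF File"


@dataclass
class IdfDocument:
    """Ordered key → values entries; keys compare case-insensitively
    and may appear at most once."""

    entries: list[tuple[str, list[str]]] = field(default_factory=list)
    sdrf_reference: str | None = None

    def get(self, key: str) -> list[str] | None:
        folded = key.strip().lower()
        for k, values in self.entries:
            if k.strip().lower() == folded:
                return values
        return None

    def add(self, key: str, values: list[str]) -> None:
        if self.get(key) is not None:
            raise SdrfParseError(f"duplicate IDF key {key!r}")
        self.entries.append((key, list(values)))
        if key.strip().lower() == SDRF_FILE_KEY.lower() and values:
            self.sdrf_reference = values[0]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IdfDocument):
            return NotImplemented
        return self.entries == other.entries


@dataclass
class DatasetDescription:
    """Neutral study-level record: what a repository asks a submitter
    for at deposition time."""

    title: str
    description: str = ""
    submitters: list[tuple[str, str, str]] = field(default_factory=list)  # (name, affiliation, email)
    instruments: list[OntologyAnnotation] = field(default_factory=list)
    software: list[str] = field(default_factory=list)
    publications: list[str] = field(default_factory=list)
    keywords: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.title:
            raise ValueError("dataset title must be non-empty")


def read_idf(stream: IO[str] | str) -> IdfDocument:
    """Parse an IDF document.

    Empty lines and lines starting with ``#`` are ignored; duplicate
    keys (case-insensitive) raise :class:`SdrfParseError`.  Trailing
    empty cells of a line are dropped, so a key followed only by tabs
    counts as present-with-no-values.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    doc = IdfDocument()
    for lineno, raw in enumerate(stream.read().split("\n"), start=1):
        line = raw[:-1] if raw.endswith("\r") else raw
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t")
        key = cells[0].strip()
        values = list(cells[1:])
        while values and values[-1] == "":
            values.pop()
        if doc.get(key) is not None:
            raise SdrfParseError(f"line {lineno}: duplicate IDF key {key!r}")
        doc.add(key, values)
    return doc


def write_idf(doc: IdfDocument, stream: IO[str]) -> None:
    """One tab-delimited line per entry, in stored order."""
    for key, values in doc.entries:
        for v in values:
            if "\t" in v or "\n" in v or "\r" in v:
                raise SdrfParseError(f"IDF value for key {key!r} embeds a tab or newline")
        stream.write("\t".join([key, *values]) + "\n")


def _split_person_name(name: str) -> tuple[str, str]:
    """Split on the last whitespace: everything before is the first
    name(s), the final token the last name."""
    parts = name.rsplit(None, 1)
    if len(parts) == 1:
        return "", parts[0]
    return parts[0], parts[1]


def idf_from_description(desc: DatasetDescription) -> IdfDocument:
    """Deterministic mapping from a dataset description to IDF entries.

    Person fields stay column-aligned: the i-th value of every Person
    key describes the i-th submitter.
    """
    if not desc.title:
        raise SdrfParseError("dataset description has an empty title")
    doc = IdfDocument()
    doc.add("Investigation Title", [desc.title])
    if desc.description:
        doc.add("Experiment Description", [desc.description])
    if desc.submitters:
        firsts, lasts, affiliations, emails = [], [], [], []
        for name, affiliation, email in desc.submitters:
            first, last = _split_person_name(name)
            firsts.append(first)
            lasts.append(last)
            affiliations.append(affiliation)
            emails.append(email)
        doc.add("Person Last Name", lasts)
        doc.add("Person First Name", firsts)
        doc.add("Person Affiliation", affiliations)
        doc.add("Person Email", emails)
    if desc.instruments:
        doc.add("Comment[Instrument]", [t.label for t in desc.instruments])
    if desc.software:
        doc.add("Software", list(desc.software))
    if desc.publications:
        doc.add("Publication Title", list(desc.publications))
    if desc.keywords:
        doc.add("Comment[Keywords]", list(desc.keywords))
    return doc


def description_from_idf(doc: IdfDocument) -> DatasetDescription:
    """Recover a dataset description from an IDF document (inverse of
    :func:`idf_from_description` on its image)."""
    titles = doc.get("Investigation Title") or []
    if not titles or not titles[0]:
        raise SdrfParseError("IDF has no 'Investigation Title'")
    descriptions = doc.get("Experiment Description") or [""]
    lasts = doc.get("Person Last Name") or []
    firsts = doc.get("Person First Name") or []
    affiliations = doc.get("Person Affiliation") or []
    emails = doc.get("Person Email") or []
    submitters = []
    for i, last in enumerate(lasts):
        first = firsts[i] if i < len(firsts) else ""
        name = f"{first} {last}".strip()
        submitters.append(
            (
                name,
                affiliations[i] if i < len(affiliations) else "",
                emails[i] if i < len(emails) else "",
            )
        )
    instruments = [OntologyAnnotation(label=v) for v in doc.get("Comment[Instrument]") or []]
    return DatasetDescription(
        title=titles[0],
        description=descriptions[0] if descriptions else "",
        submitters=submitters,
        instruments=instruments,
        software=list(doc.get("Software") or []),
        publications=list(doc.get("Publication Title") or []),
        keywords=list(doc.get("Comment[Keywords]") or []),
    )
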