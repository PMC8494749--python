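"""Offline controlled-vocabulary store.

SDRF property values that carry accessions (e.g. ``AC=UNIMOD:35``)
are checked against snapshots of the relevant vocabularies — EFO for
sample properties, PSI-MS and PRIDE for instrument/file properties,
UNIMOD for modifications, NCBITaxon for organisms.  Snapshots are flat
3-column TSV files (accession, label, ontology prefix) bundled with the
package; users can point the store at their own snapshot files, so the
term set is a data concern, not a code one.  No hierarchy or reasoning
is kept — this is a lookup table for validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from .model import SdrfParseError

__all__ = ["CvStore", "load_cv", "bundled_snapshot_paths", "load_default_cv"]

logger = logging.getLogger(__name__)


@dataclass
class CvStore:
    """Bidirectional accession↔label lookup over loaded snapshot terms."""

    terms: dict[str, tuple[str, str]] = field(default_factory=dict)  # accession -> (label, prefix)
    labels: dict[tuple[str, str], str] = field(default_factory=dict)  # (prefix, lower label) -> accession

    def __len__(self) -> int:
        return len(self.terms)

    def add(self, accession: str, label: str, prefix: str) -> None:
        if accession in self.terms:
            old_label, old_prefix = self.terms[accession]
            logger.info(
                "CV override: %s %r (%s) replaced by %r (%s)",
                accession, old_label, old_prefix, label, prefix,
            )
            self.labels.pop((old_prefix, old_label.lower()), None)
        self.terms[accession] = (label, prefix)
        self.labels[(prefix, label.lower())] = accession

    def lookup_accession(self, accession: str) -> tuple[str, str] | None:
        """Case-sensitive accession lookup; absent → None, never an error."""
        return self.terms.get(accession)

    def find_by_label(self, prefix: str, label: str) -> str | None:
        """Case-insensitive label match within one ontology prefix."""
        return self.labels.get((prefix, label.strip().lower()))


def load_cv(paths: Iterable[str | Path]) -> CvStore:
    """Load one store from a list of 3-column TSV snapshots.

    Later files override earlier ones on accession collision (logged at
    info level).  Malformed lines raise :class:`SdrfParseError` naming
    the file and 1-based line number.
    """
    store = CvStore()
    for path in paths:
        path = Path(path)
        with path.open("r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\r\n")
                if not line.strip() or line.startswith("#"):
                    continue
                cells = line.split("\t")
                if len(cells) != 3 or not all(c.strip() for c in cells):
                    raise SdrfParseError(
                        f"{path}:{lineno}: expected 3 tab-separated fields "
                        "(accession, label, prefix)"
                    )
                accession, label, prefix = (c.strip() for c in cells)
                store.add(accession, label, prefix)
    return store


def bundled_snapshot_paths() -> list[Path]:
    """Paths of the CV snapshot files shipped with the package."""
    root = resources.files("sdrfkit").joinpath("data", "cv")
    return sorted(Path(str(p)) for p in root.iterdir() if p.name.endswith(".tsv"))


def load_default_cv() -> CvStore:
    """Store over all bundled snapshots."""
    return load_cv(bundled_snapshot_paths())
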