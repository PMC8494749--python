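"""Synthetic experimental-design generation.

A :class:`DesignSpec` describes an experiment compactly — quantification
method, numbers of biological replicates, technical replicates and
fractions, and the factor under study — and :func:`generate_design`
expands it into a complete SDRF table that validates with zero errors.

Row semantics follow the sample↔file relationship model:

* label-free — one data file per (sample, technical replicate,
  fraction); one row per file.
* multiplexed (TMT, SILAC) — samples are packed into mixtures of at
  most one plex; one data file per (mixture, technical replicate,
  fraction); the file's rows are repeated once per occupied channel,
  with sample metadata varying per channel and file metadata repeated.

Either way each biological sample contributes exactly one row per
(technical replicate, fraction), so the table always has
``n_biological × n_technical × n_fractions`` rows.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import IO

from . import labels as _labels
from .model import Category, ColumnKey, SdrfParseError
from .sdrf import SdrfTable

__all__ = [
    "QuantMethod",
    "DesignSpec",
    "expected_row_count",
    "expected_file_count",
    "generate_design",
    "read_design_spec",
]


class QuantMethod(enum.Enum):
    """Supported quantification strategies with their channel lists."""

    LABEL_FREE = "label-free"
    TMT6 = "tmt6"
    TMT10 = "tmt10"
    TMT11 = "tmt11"
    SILAC2 = "silac2"
    SILAC3 = "silac3"

    @property
    def channels(self) -> tuple[str, ...]:
        return _CHANNELS[self]

    @property
    def plex(self) -> int:
        return len(self.channels)

    @property
    def is_multiplexed(self) -> bool:
        return self is not QuantMethod.LABEL_FREE

    @property
    def requires_full_plex(self) -> bool:
        # A SILAC run only makes sense with every metabolic channel
        # present; TMT mixtures may leave channels unused.
        return self in (QuantMethod.SILAC2, QuantMethod.SILAC3)


_CHANNELS = {
    QuantMethod.LABEL_FREE: (_labels.DEFAULT_LABEL,),
    QuantMethod.TMT6: _labels.TMT6_CHANNELS,
    QuantMethod.TMT10: _labels.TMT10_CHANNELS,
    QuantMethod.TMT11: _labels.TMT11_CHANNELS,
    QuantMethod.SILAC2: _labels.SILAC2_CHANNELS,
    QuantMethod.SILAC3: _labels.SILAC3_CHANNELS,
}

#: Instrument cell emitted for generated designs (key/value syntax with
#: a PSI-MS accession from the bundled snapshot).
DEFAULT_INSTRUMENT = "AC=MS:1001911;NT=Q Exactive"


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one synthetic experimental design.

    Factor levels are assigned to biological replicates round-robin, so
    two levels over four replicates give a balanced 2×2 design.  The
    ``seed`` field is accepted for interface stability; generation is
    deterministic.
    """

    quant_method: QuantMethod = QuantMethod.LABEL_FREE
    n_biological: int = 2
    n_technical: int = 1
    n_fractions: int = 1
    organism: str = "Homo sapiens"
    organism_part: str = "liver"
    factor_name: str = "phenotype"
    factor_levels: tuple[str, ...] = ("normal", "disease")
    file_prefix: str = "run"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_biological, self.n_technical, self.n_fractions) < 1:
            raise ValueError("replicate and fraction counts must be >= 1")
        if not self.factor_levels:
            raise ValueError("factor_levels must be non-empty")


def expected_row_count(spec: DesignSpec) -> int:
    """One row per sample–file relationship:
    ``n_biological × n_technical × n_fractions``."""
    return spec.n_biological * spec.n_technical * spec.n_fractions


def expected_file_count(spec: DesignSpec) -> int:
    """Distinct data files: samples (label-free) or mixtures
    (multiplexed) × technical replicates × fractions."""
    if spec.quant_method.is_multiplexed:
        groups = math.ceil(spec.n_biological / spec.quant_method.plex)
    else:
        groups = spec.n_biological
    return groups * spec.n_technical * spec.n_fractions


def _mixtures(spec: DesignSpec) -> list[list[int]]:
    """Pack 1-based sample indices into mixtures of at most one plex."""
    method = spec.quant_method
    if method.requires_full_plex and spec.n_biological % method.plex != 0:
        raise SdrfParseError(
            f"{method.value} needs a full channel complement per run: "
            f"{spec.n_biological} samples is not a multiple of {method.plex}"
        )
    if not method.is_multiplexed:
        return [[i] for i in range(1, spec.n_biological + 1)]
    plex = method.plex
    samples = list(range(1, spec.n_biological + 1))
    return [samples[i : i + plex] for i in range(0, len(samples), plex)]


def generate_design(spec: DesignSpec) -> SdrfTable:
    """Expand *spec* into a complete SDRF table.

    Column layout follows the canonical three sections: sample metadata
    (source name + characteristics), data-file properties (assay name +
    comments), and the factor value.  Fraction identifiers run 1..F per
    file group; channel assignment is deterministic list order, reused
    across technical re-injections of the same mixture.
    """
    factor_attr = spec.factor_name.strip().lower()
    fixed_attrs = {"organism", "organism part", "biological replicate"}
    factor_char = ColumnKey(
        Category.CHARACTERISTICS,
        spec.factor_name,
        occurrence=2 if factor_attr in fixed_attrs else 1,
    )
    columns = [
        ColumnKey(Category.SOURCE_NAME),
        ColumnKey(Category.CHARACTERISTICS, "organism"),
        ColumnKey(Category.CHARACTERISTICS, "organism part"),
        ColumnKey(Category.CHARACTERISTICS, "biological replicate"),
        factor_char,
        ColumnKey(Category.ASSAY_NAME),
        ColumnKey(Category.COMMENT, "label"),
        ColumnKey(Category.COMMENT, "fraction identifier"),
        ColumnKey(Category.COMMENT, "technical replicate"),
        ColumnKey(Category.COMMENT, "data file"),
        ColumnKey(Category.COMMENT, "instrument"),
        ColumnKey(Category.FACTOR_VALUE, spec.factor_name),
    ]
    levels = spec.factor_levels

    def level_of(sample: int) -> str:
        return levels[(sample - 1) % len(levels)]

    rows: list[list[str]] = []
    run = 0
    for m, members in enumerate(_mixtures(spec), start=1):
        channels = spec.quant_method.channels[: len(members)]
        for t in range(1, spec.n_technical + 1):
            for f in range(1, spec.n_fractions + 1):
                run += 1
                data_file = f"{spec.file_prefix}_{m}_{t}_{f}.raw"
                assay = f"run {run}"
                for sample, channel in zip(members, channels):
                    rows.append([
                        f"sample {sample}",
                        spec.organism,
                        spec.organism_part,
                        str(sample),
                        level_of(sample),
                        assay,
                        channel,
                        str(f),
                        str(t),
                        data_file,
                        DEFAULT_INSTRUMENT,
                        level_of(sample),
                    ])
    return SdrfTable(columns=columns, rows=rows)


# --------------------------------------------------------------------------
# Flat key:value design files
# --------------------------------------------------------------------------

_METHOD_ALIASES = {
    "label-free": QuantMethod.LABEL_FREE,
    "label_free": QuantMethod.LABEL_FREE,
    "labelfree": QuantMethod.LABEL_FREE,
    "lfq": QuantMethod.LABEL_FREE,
    "tmt6": QuantMethod.TMT6,
    "tmt10": QuantMethod.TMT10,
    "tmt11": QuantMethod.TMT11,
    "silac2": QuantMethod.SILAC2,
    "silac3": QuantMethod.SILAC3,
}


def read_design_spec(source: IO[str] | str | Path) -> DesignSpec:
    """Read a design from a flat ``key: value`` text document.

    Keys are the :class:`DesignSpec` field names (spaces and dashes
    accepted in place of underscores); ``factor_levels`` is a
    comma-separated list.  Unknown keys raise an error so typos do not
    silently fall back to defaults.
    """
    if isinstance(source, Path):
        text = source.read_text(encoding="utf-8")
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    fields: dict[str, object] = {}
    for lineno, raw in enumerate(text.split("\n"), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise SdrfParseError(f"design line {lineno}: expected 'key: value', got {line!r}")
        key, value = line.split(":", 1)
        key = key.strip().lower().replace(" ", "_").replace("-", "_")
        value = value.strip()
        if key == "quant_method":
            try:
                fields[key] = _METHOD_ALIASES[value.lower().replace(" ", "")]
            except KeyError:
                raise SdrfParseError(
                    f"design line {lineno}: unknown quantification method {value!r}"
                ) from None
        elif key in ("n_biological", "n_technical", "n_fractions", "seed"):
            try:
                fields[key] = int(value)
            except ValueError:
                raise SdrfParseError(f"design line {lineno}: {key} must be an integer") from None
        elif key == "factor_levels":
            fields[key] = tuple(v.strip() for v in value.split(",") if v.strip())
        elif key in ("organism", "organism_part", "factor_name", "file_prefix"):
            fields[key] = value
        else:
            raise SdrfParseError(f"design line {lineno}: unknown key {key!r}")
    try:
        return DesignSpec(**fields)  # type: ignore[arg-type]
    except ValueError as exc:
        raise SdrfParseError(str(exc)) from None
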