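"""Library sizing arithmetic and clone addressing for 384-well BAC libraries.

A BAC library is sized from the haploid genome size, the target fold
coverage and the mean insert length::

    n_clones = coverage * genome_size / mean_insert

and stored in 384-well plates (16 rows A-P by 24 columns 1-24).  Two
rounding conventions are provided because a physical plate count must be
rounded up while published summary tables are frequently rounded to the
nearest integer; see :class:`RoundingMode`.
"""

from __future__ import annotations

import enum
import math
import re
import string
from dataclasses import dataclass, field

__all__ = [
    "GenomeSpec",
    "PlateFormat",
    "LibraryLayout",
    "WellAddress",
    "RoundingMode",
    "required_clone_count",
    "required_plate_count",
    "parse_well_address",
    "format_well_address",
    "parse_length",
]

_LENGTH_UNITS = {
    "bp": 1,
    "kb": 1_000,
    "mb": 1_000_000,
    "gb": 1_000_000_000,
}

_LENGTH_RE = re.compile(
    r"^\s*(?P<num>[0-9]+(?:\.[0-9]+)?)\s*(?P<unit>bp|kbp?|mbp?|gbp?)?\s*$",
    re.IGNORECASE,
)


def parse_length(text: str | int | float) -> int:
    """Parse a genomic length with an optional ``bp``/``kb``/``Mb``/``Gb`` suffix.

    Bare numbers are taken as base pairs.  Returns an integer base-pair count.
    """
    if isinstance(text, (int, float)):
        return int(round(text))
    m = _LENGTH_RE.match(text)
    if m is None:
        raise ValueError(f"cannot parse length {text!r}")
    unit = (m.group("unit") or "bp").lower()
    if unit != "bp" and unit.endswith("p"):
        unit = unit[:-1]  # kbp -> kb etc.
    if unit not in _LENGTH_UNITS:
        raise ValueError(f"unknown length unit in {text!r}")
    return int(round(float(m.group("num")) * _LENGTH_UNITS[unit]))


class RoundingMode(enum.Enum):
    """How fractional plate/pool counts are turned into integers.

    ``PAPER_ROUND`` rounds half-up to the nearest integer (the convention
    that reproduces most published summary tables); ``STRICT_CEIL`` always
    rounds up, which is the physically meaningful choice — a fractional
    plate must exist as a whole plate.
    """

    PAPER_ROUND = "paper_round"
    STRICT_CEIL = "strict_ceil"

    def apply(self, x: float) -> int:
        if x < 0:
            raise ValueError("counts must be non-negative")
        if self is RoundingMode.PAPER_ROUND:
            return math.floor(x + 0.5)
        return math.ceil(x)


def paper_round(x: float) -> int:
    """Round half-up to the nearest integer (``floor(x + 0.5)``)."""
    return RoundingMode.PAPER_ROUND.apply(x)


@dataclass(frozen=True)
class GenomeSpec:
    """Target genome and library parameters.

    Parameters
    ----------
    genome_size:
        Haploid (1C) genome size in base pairs.
    coverage:
        Target fold coverage of the library; 3x is the usual minimum for
        reliable PCR-based screening.
    mean_insert:
        Mean cloned-insert length in base pairs (typical BAC: ~100 kb).
    """

    genome_size: int
    coverage: float = 3.0
    mean_insert: int = 100_000

    def __post_init__(self) -> None:
        if self.genome_size < 1:
            raise ValueError("genome_size must be >= 1 bp")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.mean_insert < 1:
            raise ValueError("mean_insert must be >= 1 bp")
        if self.coverage * self.genome_size < self.mean_insert:
            raise ValueError(
                "coverage x genome_size < mean_insert: library would be empty"
            )


@dataclass(frozen=True)
class PlateFormat:
    """Microtiter plate geometry; the default is the 384-well format."""

    n_rows: int = 16
    n_cols: int = 24

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("plate dimensions must be >= 1")
        if self.n_rows > 26:
            raise ValueError("row labels limited to A-Z")

    @property
    def wells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def row_labels(self) -> tuple[str, ...]:
        return tuple(string.ascii_uppercase[: self.n_rows])

    @property
    def col_labels(self) -> tuple[int, ...]:
        return tuple(range(1, self.n_cols + 1))


@dataclass(frozen=True)
class LibraryLayout:
    """An N-plate library; plates are numbered 1..N."""

    n_plates: int
    plate_format: PlateFormat = field(default_factory=PlateFormat)

    def __post_init__(self) -> None:
        if self.n_plates < 1:
            raise ValueError("n_plates must be >= 1")

    @property
    def n_wells(self) -> int:
        return self.n_plates * self.plate_format.wells

    @property
    def plate_ids(self) -> range:
        return range(1, self.n_plates + 1)


@dataclass(frozen=True, order=True)
class WellAddress:
    """A clone address: optional plate number, row letter, 1-based column."""

    row: str
    column: int
    plate: int | None = None

    def __post_init__(self) -> None:
        if len(self.row) != 1 or self.row not in string.ascii_uppercase:
            raise ValueError(f"row must be a single letter A-Z, got {self.row!r}")
        if self.column < 1:
            raise ValueError("column must be >= 1")
        if self.plate is not None and self.plate < 1:
            raise ValueError("plate must be >= 1")

    def validate(self, fmt: PlateFormat) -> None:
        if self.row not in fmt.row_labels:
            raise ValueError(f"row {self.row!r} outside plate format rows")
        if self.column > fmt.n_cols:
            raise ValueError(f"column {self.column} outside plate format columns")


_ADDR_RE = re.compile(r"^(?:P(?P<plate>\d+)-)?(?P<row>[A-Za-z])(?P<col>\d+)$")


def parse_well_address(text: str, fmt: PlateFormat | None = None) -> WellAddress:
    """Parse ``"D13"`` or ``"P23-D13"`` into a :class:`WellAddress`.

    Raises ``ValueError`` naming the offending token for malformed or
    out-of-range input.
    """
    m = _ADDR_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed well address {text!r} (expected e.g. 'D13' or 'P23-D13')")
    addr = WellAddress(
        row=m.group("row").upper(),
        column=int(m.group("col")),
        plate=int(m.group("plate")) if m.group("plate") else None,
    )
    if fmt is not None:
        addr.validate(fmt)
    return addr


def format_well_address(addr: WellAddress) -> str:
    """Inverse of :func:`parse_well_address`: ``parse(format(a)) == a``."""
    prefix = f"P{addr.plate}-" if addr.plate is not None else ""
    return f"{prefix}{addr.row}{addr.column}"


def required_clone_count(spec: GenomeSpec) -> int:
    """Number of clones for the requested coverage.

    ``round(coverage * genome_size / mean_insert)``, e.g. a 16 Gbp genome at
    3x coverage with 100 kb inserts needs 480,000 clones.
    """
    return paper_round(spec.coverage * spec.genome_size / spec.mean_insert)


def required_plate_count(
    clone_count: int,
    plate_format: PlateFormat | None = None,
    mode: RoundingMode = RoundingMode.PAPER_ROUND,
) -> int:
    """Plates needed to hold ``clone_count`` clones, per the rounding mode."""
    if clone_count < 1:
        raise ValueError("clone_count must be >= 1")
    fmt = plate_format or PlateFormat()
    return max(1, mode.apply(clone_count / fmt.wells))
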