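"""Core domain types shared by every stage of the toolkit.

Coordinates are 1-based inclusive throughout the package (VCF-like).
BED input/output converts at the boundary (:mod:`pombesv.io`), so a BED
line ``chr1 999 2000`` becomes ``start=1000, end=2000`` internally.

Structural-variant length is ``end - start + 1`` for the span-like types
(DEL/DUP/INV); an insertion's length is the length of the inserted
sequence; a translocation has no single length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Optional

from intervaltree import Interval, IntervalTree


class PombesvError(Exception):
    """Base class for all toolkit errors."""


class FormatError(PombesvError):
    """An input file does not parse as the expected format."""


class CoordinateError(PombesvError):
    """A record's coordinates are inconsistent or out of range."""


class UnknownSVTypeError(FormatError):
    """An SV type string is not one of DEL/DUP/INS/INV/TRA."""


class ParameterError(PombesvError):
    """A user-supplied parameter is out of its valid range."""


class CapacityError(PombesvError):
    """A simulation request cannot be packed into the genome."""


class SVType(str, Enum):
    """The five structural-variant classes handled by the toolkit."""

    DEL = "DEL"
    DUP = "DUP"
    INS = "INS"
    INV = "INV"
    TRA = "TRA"

    @classmethod
    def parse(cls, s: str) -> "SVType":
        try:
            return cls(s.strip().upper())
        except ValueError:
            raise UnknownSVTypeError(f"unknown SV type {s!r}") from None

    def is_cnv(self) -> bool:
        """Dosage-changing classes (deletions and duplications)."""
        return self in (SVType.DEL, SVType.DUP)

    def is_rearrangement(self) -> bool:
        """Copy-neutral order-changing classes (inversions, translocations)."""
        return self in (SVType.INV, SVType.TRA)


MISSING = None  # missing genotype sentinel in SVCall.genotypes


@dataclass
class SVCall:
    """One structural-variant call.

    For non-translocations the call spans ``chrom:start-end``.  A
    translocation is a single two-locus record with breakpoints
    ``chrom:start`` and ``chrom2:pos2`` (the internal canonical form; VCF
    dialects that split it into BND pairs are collapsed on input).

    ``pe_support`` is the paired-end read support reported by the caller;
    ``None`` means unknown, which downstream filters treat differently
    from an explicit zero.
    """

    id: str
    type: SVType
    chrom: str
    start: int
    end: int
    chrom2: Optional[str] = None
    pos2: Optional[int] = None
    length: Optional[int] = None
    pe_support: Optional[int] = None
    caller: str = ""
    genotypes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type is SVType.TRA:
            if self.chrom2 is None or self.pos2 is None:
                raise CoordinateError(
                    f"{self.id}: translocation requires chrom2/pos2"
                )
        else:
            if self.chrom2 is not None:
                raise CoordinateError(
                    f"{self.id}: chrom2 only valid for translocations"
                )
            if self.start > self.end:
                raise CoordinateError(
                    f"{self.id}: start {self.start} > end {self.end}"
                )
        if self.start < 1:
            raise CoordinateError(f"{self.id}: start {self.start} < 1")
        if self.pe_support is not None and self.pe_support < 0:
            raise CoordinateError(f"{self.id}: negative pe_support")
        if self.length is None and self.type in (SVType.DEL, SVType.DUP, SVType.INV):
            self.length = self.end - self.start + 1

    def loci(self) -> tuple:
        """Breakpoint loci as (chrom, pos) pairs; two for TRA, two for spans."""
        if self.type is SVType.TRA:
            return ((self.chrom, self.start), (self.chrom2, self.pos2))
        return ((self.chrom, self.start), (self.chrom, self.end))


@dataclass
class TruthRecord:
    """Ground truth for one simulated SV, on reference coordinates.

    DUP carries ``copies`` (total tandem copies, >= 2); INS carries the
    inserted sequence; TRA carries the partner segment
    ``chrom2:[start2, end2]`` that is reciprocally exchanged with
    ``chrom:[start, end]``.
    """

    id: str
    type: SVType
    chrom: str
    start: int
    end: int
    insert_seq: Optional[str] = None
    copies: Optional[int] = None
    chrom2: Optional[str] = None
    start2: Optional[int] = None
    end2: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise CoordinateError(f"{self.id}: bad span {self.start}-{self.end}")
        if self.type is SVType.DUP:
            if self.copies is None:
                self.copies = 2
            if self.copies < 2:
                raise CoordinateError(f"{self.id}: DUP copies must be >= 2")
        if self.type is SVType.INS and not self.insert_seq:
            raise CoordinateError(f"{self.id}: INS requires insert_seq")
        if self.type is SVType.TRA:
            if None in (self.chrom2, self.start2, self.end2):
                raise CoordinateError(f"{self.id}: TRA requires partner segment")
            if self.start2 > self.end2:
                raise CoordinateError(f"{self.id}: bad partner span")

    @property
    def length(self) -> int:
        if self.type is SVType.INS:
            return len(self.insert_seq)
        return self.end - self.start + 1

    def loci(self) -> tuple:
        if self.type is SVType.TRA:
            return ((self.chrom, self.start), (self.chrom2, self.start2))
        return ((self.chrom, self.start), (self.chrom, self.end))


class IntervalSet:
    """Per-chromosome interval collection with point/interval queries.

    Intervals are stored 0-based half-open (the BED convention they are
    read from).  Point queries take 1-based positions, matching the rest
    of the package, so a point query at position p tests containment of
    the 0-based coordinate p-1.
    """

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}

    @classmethod
    def from_tuples(
        cls, rows: Iterable[tuple]
    ) -> "IntervalSet":
        """Build from (chrom, start0, end0[, label]) tuples."""
        s = cls()
        for row in rows:
            chrom, start, end = row[0], int(row[1]), int(row[2])
            label = row[3] if len(row) > 3 else None
            s.add(chrom, start, end, label)
        return s

    def add(self, chrom: str, start0: int, end0: int, label=None) -> None:
        if end0 <= start0:
            raise CoordinateError(f"empty interval {chrom}:{start0}-{end0}")
        self._trees.setdefault(chrom, IntervalTree()).add(
            Interval(start0, end0, label)
        )

    def contains_point(self, chrom: str, pos1: int) -> bool:
        """True if the 1-based position falls in any interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos1 - 1))

    def overlaps(self, chrom: str, start1: int, end1: int) -> bool:
        """True if the 1-based inclusive span intersects any interval."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start1 - 1, end1))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def __iter__(self) -> Iterator[tuple]:
        for chrom in sorted(self._trees):
            for iv in sorted(self._trees[chrom]):
                yield (chrom, iv.begin, iv.end, iv.data)
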