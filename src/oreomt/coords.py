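"""Circular genome coordinates and reference sequence access.

The human mitochondrial reference (rCRS, NC_012920.1) is a 16,569-bp circle;
forensic convention numbers it 1-based and inclusively, and intervals such as
the control region (16,024–576) wrap through the origin.  This module is the
coordinate backbone for the whole package: a wrap-aware inclusive interval
type, length/membership/extraction operations, and the canonical region
constants used by the amplicon panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .errors import BoundsError

RCRS_LENGTH = 16569
"""Length in bases of the circular rCRS mitochondrial reference."""


@dataclass(frozen=True)
class CircularRegion:
    """A 1-based inclusive interval on a circular sequence.

    ``start > end`` denotes an interval wrapping through the origin, e.g.
    (16024, 576) on the rCRS is the 1122-bp control region.
    """

    start: int
    end: int

    def length(self, genome_length: int) -> int:
        self._check(genome_length)
        if self.start <= self.end:
            return self.end - self.start + 1
        return (genome_length - self.start + 1) + self.end

    def contains(self, position: int, genome_length: int) -> bool:
        self._check(genome_length)
        if not 1 <= position <= genome_length:
            raise BoundsError(
                f"position {position} outside [1, {genome_length}]")
        if self.start <= self.end:
            return self.start <= position <= self.end
        return position >= self.start or position <= self.end

    def offset_of(self, position: int, genome_length: int) -> int:
        """0-based offset of ``position`` from the region start (wrap-aware).

        Raises :class:`BoundsError` when the position is not in the region.
        """
        if not self.contains(position, genome_length):
            raise BoundsError(
                f"position {position} not in region ({self.start},{self.end})")
        return (position - self.start) % genome_length

    def position_at(self, offset: int, genome_length: int) -> int:
        """Inverse of :meth:`offset_of`."""
        if not 0 <= offset < self.length(genome_length):
            raise BoundsError(f"offset {offset} outside region")
        return (self.start - 1 + offset) % genome_length + 1

    def positions(self, genome_length: int) -> Iterator[int]:
        for off in range(self.length(genome_length)):
            yield (self.start - 1 + off) % genome_length + 1

    def wraps(self) -> bool:
        return self.start > self.end

    def _check(self, genome_length: int) -> None:
        for p in (self.start, self.end):
            if not 1 <= p <= genome_length:
                raise BoundsError(
                    f"region endpoint {p} outside [1, {genome_length}]")


CONTROL_REGION = CircularRegion(16024, 576)
"""The 1122-bp mtDNA control region in rCRS coordinates."""

AMPLIFIED_SPAN = CircularRegion(15989, 619)
"""The 1200-position span covered by the 10-amplicon panel."""

_VALID = set("ACGTN")
_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class ReferenceGenome:
    """An uppercase single-contig reference, circular by default."""

    name: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        bad = set(self.sequence) - _VALID
        if bad:
            raise BoundsError(f"non-ACGTN characters in sequence: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base_at(self, position: int) -> str:
        if not 1 <= position <= self.length:
            raise BoundsError(f"position {position} outside [1, {self.length}]")
        return self.sequence[position - 1]

    @property
    def full_region(self) -> CircularRegion:
        return CircularRegion(1, self.length)


def region_length(region: CircularRegion, genome_length: int) -> int:
    """Wrap-aware inclusive length of ``region`` on a circle of given size."""
    return region.length(genome_length)


def contains(region: CircularRegion, position: int, genome_length: int) -> bool:
    """True iff ``position`` lies inside the wrap-aware interval."""
    return region.contains(position, genome_length)


def extract_sequence(genome: ReferenceGenome, region: CircularRegion) -> str:
    """Sequence of ``region``; wrapping concatenates the tail and head."""
    if region.wraps():
        if not genome.circular:
            raise BoundsError("wrapping region on a non-circular genome")
        region._check(genome.length)
        return genome.sequence[region.start - 1:] + genome.sequence[:region.end]
    region._check(genome.length)
    return genome.sequence[region.start - 1:region.end]


def load_reference(path, expected_length: int | None = RCRS_LENGTH,
                   force: bool = False, circular: bool = True) -> ReferenceGenome:
    """Read the first FASTA record as the reference genome.

    The header is free-form; the genome is matched by length against
    ``expected_length`` (16,569 for the rCRS) unless ``force`` is set.
    """
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"), None)
    if record is None:
        raise BoundsError(f"no FASTA record in {path}")
    seq = str(record.seq).upper()
    if expected_length is not None and not force and len(seq) != expected_length:
        raise BoundsError(
            f"reference length {len(seq)} != expected {expected_length}; "
            "pass force=True to accept")
    return ReferenceGenome(name=record.id, sequence=seq, circular=circular)
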