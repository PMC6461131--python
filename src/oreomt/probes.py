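"""Overarching Read Enrichment Option (OREO): probe design and read counting.

Primers in a single-multiplex amplicon assay contribute their own
(reference-matching) sequence to read ends, so a genuine alternative allele
under a primer-binding site is diluted by reference alleles copied from the
primer, not from the template.  OREO sidesteps unknown primer sequences by
counting only *overarching* reads from the neighbouring overlapping amplicon:
a pair of equal-length allele-specific probes spans the queried site and
extends past the amplicon end, and a read is counted only when it contains a
probe as an exact full-length substring (either strand).  Because both probes
share length and differ only at the queried site, random sequencing errors
remove reads carrying either allele at the same expected rate, so the
surviving allele fraction is an unbiased estimate of heteroplasmy.

Probe length is kept to the minimum (within 10–30 nt) that keeps each probe
unique within the amplified reference span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .coords import (AMPLIFIED_SPAN, CircularRegion, ReferenceGenome,
                     extract_sequence, reverse_complement)
from .errors import DesignError, UndefinedFractionError


@dataclass(frozen=True)
class VariantSite:
    """A queried site: position, reference allele and one alternative.

    ``alt_allele`` is a single base for a substitution, or a simple indel
    descriptor: ``"+C"`` inserts C after the position (``44.1C`` in forensic
    nomenclature becomes position 44, ``"+C"``), ``"-"`` deletes the base.
    """

    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise DesignError(f"ref == alt at {self.position}")

    @property
    def is_snv(self) -> bool:
        return len(self.alt_allele) == 1 and self.alt_allele in "ACGT"

    @property
    def label(self) -> str:
        if self.alt_allele.startswith("+"):
            return f"{self.position}.1{self.alt_allele[1:]}"
        return f"{self.position}{self.alt_allele}"


@dataclass(frozen=True)
class ProbePair:
    """Two equal-length allele-specific probes spanning an amplicon end."""

    site: VariantSite
    ref_probe: str
    alt_probe: str
    span: CircularRegion
    crossed_boundary: int

    def __post_init__(self) -> None:
        if len(self.ref_probe) != len(self.alt_probe):
            raise DesignError("probes in a pair must share length")

    @property
    def length(self) -> int:
        return len(self.ref_probe)


@dataclass
class AlleleCounts:
    """Per-site read counts by allele.

    For OREO output ``other_count`` is zero (non-matching reads are excluded,
    not counted); the naive pileup counter fills it with reads covering the
    site that carry neither queried allele.
    """

    ref_count: int
    alt_count: int
    other_count: int = 0

    @property
    def informative(self) -> int:
        return self.ref_count + self.alt_count

    @property
    def total_considered(self) -> int:
        return self.ref_count + self.alt_count + self.other_count

    @property
    def minor(self) -> int:
        return min(self.ref_count, self.alt_count)


def count_overlapping(text: str, pattern: str) -> int:
    """Occurrences of ``pattern`` in ``text``, overlapping allowed."""
    n, i = 0, text.find(pattern)
    while i != -1:
        n += 1
        i = text.find(pattern, i + 1)
    return n


def _occurrences_both_strands(text: str, probe: str) -> int:
    return (count_overlapping(text, probe)
            + count_overlapping(reverse_complement(text), probe))


def _apply_alt(span_seq: str, off: int, site: VariantSite) -> str:
    alt = site.alt_allele
    if site.is_snv:
        return span_seq[:off] + alt + span_seq[off + 1:]
    if alt.startswith("+"):
        return span_seq[:off + 1] + alt[1:] + span_seq[off + 1:]
    if alt == "-":
        return span_seq[:off] + span_seq[off + 1:]
    raise DesignError(f"unsupported alt allele descriptor {alt!r}")


def design_probe_pair(genome: ReferenceGenome, site: VariantSite,
                      boundary: int, *, min_len: int = 10, max_len: int = 30,
                      margin: int = 1, span: CircularRegion | None = None,
                      side: str | None = None,
                      backbone: str | None = None) -> ProbePair:
    """Shortest specific probe pair covering ``site`` and crossing ``boundary``.

    ``boundary`` is the amplicon-end position whose primer shadows the site;
    ``side`` says which side of the boundary is outside the amplicon
    ("right" for a 3' end, "left" for a 5' start; inferred from the relative
    placement of site and boundary when omitted).  Specificity means each
    probe, carrying its own allele, occurs exactly once on either strand
    within ``span`` (the amplified reference span by default).  Ties at the
    minimal length are broken by maximal symmetric extension around the site,
    then by leftmost start.  ``backbone`` substitutes a sample-consensus
    sequence for the reference span when known sample variants should be
    carried by both probes.
    """
    if span is None:
        span = AMPLIFIED_SPAN if genome.length >= AMPLIFIED_SPAN.start \
            else genome.full_region
    G = genome.length
    S = backbone if backbone is not None else extract_sequence(genome, span)
    span_len = len(S)
    site_off = span.offset_of(site.position, G)
    b_off = span.offset_of(boundary, G)
    if side is None:
        side = "right" if b_off >= site_off else "left"
    if site.is_snv and backbone is None and S[site_off] != site.ref_allele:
        raise DesignError(
            f"reference mismatch at {site.position}: expected "
            f"{site.ref_allele}, found {S[site_off]}")
    S_alt = _apply_alt(S, site_off, site)

    if side == "right":
        right_min = max(site_off, b_off + margin)
        left_max = min(site_off, b_off)
    else:
        if b_off > site_off:
            raise DesignError("left-side boundary lies right of the site")
        right_min = site_off
        left_max = b_off - margin
    if left_max < 0 or right_min > span_len - 1:
        raise DesignError(
            f"probe for site {site.label} cannot cross boundary {boundary} "
            "within the amplified span")

    for L in range(min_len, max_len + 1):
        lo_a = max(0, right_min - L + 1)
        hi_a = min(left_max, span_len - L)
        cands = []
        for a in range(lo_a, hi_a + 1):
            left_flank = site_off - a
            right_flank = a + L - 1 - site_off
            cands.append((abs(left_flank - right_flank), a))
        for _, a in sorted(cands):
            ref_probe = S[a:a + L]
            alt_probe = S_alt[a:a + L]
            if "N" in ref_probe or "N" in alt_probe:
                continue
            if ref_probe == alt_probe:
                continue
            if _occurrences_both_strands(S, ref_probe) != 1:
                continue
            if _occurrences_both_strands(S_alt, alt_probe) != 1:
                continue
            return ProbePair(
                site=site, ref_probe=ref_probe, alt_probe=alt_probe,
                span=CircularRegion(span.position_at(a, G),
                                    span.position_at(a + L - 1, G)),
                crossed_boundary=boundary)
    raise DesignError(
        f"no specific probe pair of length <= {max_len} for site {site.label}")


def read_matches(sequence: str, probe: str) -> bool:
    """Exact full-length containment of ``probe`` in the read, either strand."""
    return probe in sequence or reverse_complement(probe) in sequence


def oreo_filter(reads, probes: ProbePair) -> AlleleCounts:
    """Count reads matching the ref/alt probe exactly along its full length.

    ``reads`` is an iterable of sequences or objects with a ``sequence``
    attribute.  Mates of a pair are independent reads; reads matching neither
    probe are excluded (not counted).  A read matching both probes indicates
    an invalid pair and raises :class:`DesignError`.
    """
    ref_rc = reverse_complement(probes.ref_probe)
    alt_rc = reverse_complement(probes.alt_probe)
    ref_n = alt_n = 0
    longest = 0
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        longest = max(longest, len(seq))
        r = probes.ref_probe in seq or ref_rc in seq
        a = probes.alt_probe in seq or alt_rc in seq
        if r and a:
            raise DesignError(
                f"read matches both probes of pair at {probes.site.label}")
        if r:
            ref_n += 1
        elif a:
            alt_n += 1
    if ref_n == alt_n == 0 and 0 < longest < probes.length:
        warnings.warn(
            f"probe ({probes.length} nt) longer than every read "
            f"(max {longest} nt)", stacklevel=2)
    return AlleleCounts(ref_count=ref_n, alt_count=alt_n)


def allele_fraction(counts: AlleleCounts) -> float:
    """Alternative-allele percentage among informative reads (full precision).

    Summaries round to integer percent for display; classification uses the
    exact value.  Raises :class:`UndefinedFractionError` with zero
    informative reads (the site is then reported as no-call).
    """
    if counts.informative < 1:
        raise UndefinedFractionError("no informative reads")
    return 100.0 * counts.alt_count / counts.informative


def probes_to_tsv(pairs: list[ProbePair], path) -> None:
    pd.DataFrame([
        {"position": p.site.position, "ref": p.site.ref_allele,
         "alt": p.site.alt_allele, "boundary": p.crossed_boundary,
         "ref_probe": p.ref_probe, "alt_probe": p.alt_probe,
         "span_start": p.span.start, "span_end": p.span.end}
        for p in pairs]).to_csv(path, sep="\t", index=False)


def probes_from_tsv(path) -> list[ProbePair]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        site = VariantSite(int(r.position), str(r.ref), str(r.alt))
        out.append(ProbePair(site=site, ref_probe=str(r.ref_probe),
                             alt_probe=str(r.alt_probe),
                             span=CircularRegion(int(r.span_start),
                                                 int(r.span_end)),
                             crossed_boundary=int(r.boundary)))
    return out
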