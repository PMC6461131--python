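"""Readers and writers: FASTQ(.gz), SAM/BAM pileup counts, minimal VCF, TSV.

Column orders for every tabular format are documented in docs/FORMATS.md.
"""

from __future__ import annotations

import gzip
from collections import Counter
from typing import Iterable, Iterator

import numpy as np

from .calling import SiteCall
from .coords import CircularRegion
from .errors import ParseError, PileupError
from .preprocess import ReadRecord
from .probes import AlleleCounts, VariantSite


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream 4-line FASTQ records; gzip-aware, CRLF-tolerant.

    Raises :class:`ParseError` with the record index on truncation.
    """
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    n = 0
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                n += 1
                yield ReadRecord(id=title.split()[0], sequence=seq.upper(),
                                 qualities=qual)
        except ValueError as exc:
            raise ParseError(
                f"{path}: malformed FASTQ near record {n + 1}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path) -> int:
    """Write records losslessly; returns the number written."""
    n = 0
    with _open_text(path, "wt") as fh:
        for r in reads:
            qual = r.qualities if r.qualities is not None \
                else "I" * len(r.sequence)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


def read_pileup_counts(path, position: int,
                       contig: str | None = None) -> dict[str, int]:
    """Per-base counts at a 1-based position from a SAM/BAM alignment.

    The file is streamed (no index needed); a requested contig absent from
    the header raises :class:`PileupError` naming the expected contig.
    Counts walk each read's aligned pairs, so indels are handled by the
    CIGAR, and each read (not read pair) contributes once.
    """
    import pysam

    with pysam.AlignmentFile(str(path), require_index=False) as af:
        refs = list(af.references or [])
        if contig is not None and contig not in refs:
            raise PileupError(
                f"contig {contig!r} not in alignment header {refs}")
        want = contig or (refs[0] if refs else None)
        counts: Counter = Counter()
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.query_sequence is None:
                continue
            if want is not None and read.reference_name != want:
                continue
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if rpos == position - 1:
                    counts[read.query_sequence[qpos].upper()] += 1
                    break
    return dict(counts)


def pileup_allele_counts(path, site: VariantSite,
                         contig: str | None = None) -> AlleleCounts:
    counts = read_pileup_counts(path, site.position, contig)
    ref = counts.get(site.ref_allele, 0)
    alt = counts.get(site.alt_allele, 0) if site.is_snv else 0
    return AlleleCounts(ref_count=ref, alt_count=alt,
                        other_count=sum(counts.values()) - ref - alt)


def alignment_depth_track(path, span: CircularRegion, genome_length: int,
                          contig: str | None = None) -> np.ndarray:
    """Per-position depth over ``span`` from aligned read blocks."""
    import pysam

    span_len = span.length(genome_length)
    depth = np.zeros(span_len, dtype=np.int64)
    with pysam.AlignmentFile(str(path), require_index=False) as af:
        refs = list(af.references or [])
        if contig is not None and contig not in refs:
            raise PileupError(
                f"contig {contig!r} not in alignment header {refs}")
        want = contig or (refs[0] if refs else None)
        for read in af.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            if want is not None and read.reference_name != want:
                continue
            for b_start, b_end in read.get_blocks():
                for rpos in range(b_start, b_end):
                    off = (rpos + 1 - span.start) % genome_length
                    if off < span_len:
                        depth[off] += 1
    return depth


def write_vcf(calls: list[SiteCall], path, contig: str = "chrM") -> None:
    """Minimal VCF: one row per queried site with counts and status in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##INFO=<ID=AF_PCT,Number=1,Type=Float,'
                 'Description="Alternative allele percent">\n')
        fh.write('##INFO=<ID=RC,Number=1,Type=Integer,'
                 'Description="Reference-supporting reads">\n')
        fh.write('##INFO=<ID=AC_READS,Number=1,Type=Integer,'
                 'Description="Alternative-supporting reads">\n')
        fh.write('##INFO=<ID=STATUS,Number=1,Type=String,'
                 'Description="Site classification">\n')
        fh.write('##INFO=<ID=MODE,Number=1,Type=String,'
                 'Description="Kit chemistry mode">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in sorted(calls, key=lambda c: c.site.position):
            af = "." if c.alt_fraction is None else f"{c.alt_fraction:.4f}"
            rc = c.counts.ref_count if c.counts else 0
            ac = c.counts.alt_count if c.counts else 0
            info = (f"AF_PCT={af};RC={rc};AC_READS={ac};"
                    f"STATUS={c.status.value};MODE={c.mode}")
            fh.write(f"{contig}\t{c.site.position}\t.\t{c.site.ref_allele}\t"
                     f"{c.site.alt_allele}\t.\t.\t{info}\n")


def calls_to_frame(calls: list[SiteCall]):
    import pandas as pd

    return pd.DataFrame([
        {"position": c.site.position, "ref": c.site.ref_allele,
         "alt": c.site.alt_allele,
         "status": c.status.value,
         "alt_fraction_pct": None if c.alt_fraction is None
         else round(c.alt_fraction, 4),
         "alt_fraction_display": None if c.alt_fraction is None
         else round(c.alt_fraction),
         "ref_count": c.counts.ref_count if c.counts else 0,
         "alt_count": c.counts.alt_count if c.counts else 0,
         "other_count": c.counts.other_count if c.counts else 0,
         "in_primer_region": c.in_primer,
         "used_oreo": c.used_oreo,
         "mode": c.mode,
         "reason": c.reason or ""}
        for c in calls])


def sites_from_tsv(path) -> list[VariantSite]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    return [VariantSite(int(r.position), str(r.ref), str(r.alt))
            for r in df.itertuples()]
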