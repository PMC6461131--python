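"""Screening reads for a nuclear mitochondrial insertion (numt).

A co-amplified numt — a divergent nuclear copy of an mtDNA segment — shows
up as a cluster of closely linked low-level mixed allele calls (in the
motivating case, fourteen sites within a 114-bp window at ~28% in a sample
whose cognate amplicon amplified poorly).  Given a user-supplied table of
diagnostic sites (position, mtDNA allele, numt allele), reads are assigned
by exact matching of short allele-specific anchor sequences built around
each site, reusing the probe machinery; anchors carry the appropriate
allele at *every* diagnostic site they span, since numt variants travel
together on a read.

The per-site fractions are pooled as total numt-supporting reads over total
informative reads.  Because detection of this class of insertion is known
to be inconsistent (coverage- and sample-dependent, with a high
false-negative rate against genotyped truth), the estimate carries a
presence flag but absence is never asserted.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .coords import CircularRegion, ReferenceGenome, extract_sequence
from .errors import DesignError, UndefinedFractionError
from .probes import _occurrences_both_strands, read_matches

DEFAULT_DETECTION_FLOOR_PCT = 0.1
DEFAULT_MIN_SUPPORTED_SITES = 3


@dataclass(frozen=True)
class DiagnosticSite:
    """One numt-diagnostic position with the two discriminating alleles."""

    position: int
    mt_allele: str
    numt_allele: str

    def __post_init__(self) -> None:
        if self.mt_allele == self.numt_allele:
            raise DesignError(f"mt == numt allele at {self.position}")


@dataclass(frozen=True)
class SiteAnchors:
    site: DiagnosticSite
    mt_anchor: str
    numt_anchor: str
    span: CircularRegion


@dataclass
class NumtEstimate:
    per_site: list[tuple[int, int, int, float]]
    """(position, numt-supporting reads, informative reads, fraction %)."""
    pooled_fraction: float
    sites_used: int
    present: bool


def build_anchors(genome: ReferenceGenome, diagnostics: list[DiagnosticSite],
                  *, flank: int = 8, max_flank: int = 15,
                  span: CircularRegion | None = None) -> list[SiteAnchors]:
    """Equal-length mt/numt anchor pairs centred on each diagnostic site.

    The anchor window grows from ``flank`` until the mt anchor is unique
    within ``span`` on either strand.  Within a window, all diagnostic
    positions carry the mt alleles in the mt anchor and the numt alleles in
    the numt anchor (linked substitution).
    """
    if not diagnostics:
        raise DesignError("empty diagnostic table")
    span = span or genome.full_region
    G = genome.length
    S = extract_sequence(genome, span)
    offs = {d.position: span.offset_of(d.position, G) for d in diagnostics}
    by_off = {offs[d.position]: d for d in diagnostics}
    out = []
    for d in diagnostics:
        o = offs[d.position]
        for fl in range(flank, max_flank + 1):
            a, b = o - fl, o + fl
            if a < 0 or b >= len(S):
                continue
            mt = list(S[a:b + 1])
            nu = list(S[a:b + 1])
            for p in range(a, b + 1):
                if p in by_off:
                    mt[p - a] = by_off[p].mt_allele
                    nu[p - a] = by_off[p].numt_allele
            mt_s, nu_s = "".join(mt), "".join(nu)
            if mt_s == nu_s or "N" in mt_s or "N" in nu_s:
                continue
            if _occurrences_both_strands(S, mt_s) != 1:
                continue
            out.append(SiteAnchors(
                d, mt_s, nu_s,
                CircularRegion(span.position_at(a, G), span.position_at(b, G))))
            break
        else:
            raise DesignError(
                f"no specific anchor for diagnostic site {d.position}")
    return out


def numt_fraction(reads, genome: ReferenceGenome,
                  diagnostics: list[DiagnosticSite], *,
                  span: CircularRegion | None = None, flank: int = 8,
                  detection_floor_pct: float = DEFAULT_DETECTION_FLOOR_PCT,
                  min_supported_sites: int = DEFAULT_MIN_SUPPORTED_SITES
                  ) -> NumtEstimate:
    """Per-site and pooled numt read fractions with a presence flag.

    Per site, reads matching the numt anchor count as numt-supporting and
    reads matching the mt anchor as cognate; other reads are excluded.  The
    pooled fraction is 100 x (sum of numt reads) / (sum of informative
    reads); presence is flagged when the pooled fraction reaches
    ``detection_floor_pct`` and at least ``min_supported_sites`` sites each
    show >= 1 numt-supporting read.  Raises
    :class:`UndefinedFractionError` when no site has informative reads.
    """
    anchors = build_anchors(genome, diagnostics, flank=flank, span=span)
    reads = [r if isinstance(r, str) else r.sequence for r in reads]
    per_site = []
    total_numt = total_inf = 0
    for an in anchors:
        n_mt = n_numt = 0
        for seq in reads:
            if read_matches(seq, an.numt_anchor):
                n_numt += 1
            elif read_matches(seq, an.mt_anchor):
                n_mt += 1
        inf = n_mt + n_numt
        frac = 100.0 * n_numt / inf if inf else float("nan")
        per_site.append((an.site.position, n_numt, inf, frac))
        total_numt += n_numt
        total_inf += inf
    if total_inf == 0:
        raise UndefinedFractionError("no informative reads at any site")
    pooled = 100.0 * total_numt / total_inf
    supported = sum(1 for _, n, _, _ in per_site if n >= 1)
    return NumtEstimate(
        per_site=per_site, pooled_fraction=pooled,
        sites_used=len(per_site),
        present=(pooled >= detection_floor_pct
                 and supported >= min_supported_sites))


def select_numt_reads(reads, genome: ReferenceGenome,
                      diagnostics: list[DiagnosticSite], *,
                      span: CircularRegion | None = None, flank: int = 8):
    """Split reads into (numt-supporting, complement).

    A read is selected when it matches the numt anchor at >= 1 diagnostic
    site; the two subsets are disjoint and their union is the input.
    """
    anchors = build_anchors(genome, diagnostics, flank=flank, span=span)
    selected, rest = [], []
    for read in reads:
        seq = read if isinstance(read, str) else read.sequence
        if any(read_matches(seq, an.numt_anchor) for an in anchors):
            selected.append(read)
        else:
            rest.append(read)
    return selected, rest


def diagnostics_from_tsv(path) -> list[DiagnosticSite]:
    df = pd.read_csv(path, sep="\t")
    return [DiagnosticSite(int(r.position), str(r.mt_allele),
                           str(r.numt_allele)) for r in df.itertuples()]


def estimate_to_frame(estimate: NumtEstimate) -> pd.DataFrame:
    return pd.DataFrame(
        estimate.per_site,
        columns=["position", "numt_reads", "informative_reads",
                 "numt_fraction_pct"])
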