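"""Tiered-threshold classification of sites and region-wide calling.

A site is classified from its allele counts under a set of depth and
fraction thresholds: a 20x analytical depth below which no call is
attempted (also enforced on the minor component of a heteroplasmy), a
detection threshold, and a heteroplasmy window on the alternative-allele
fraction (10–90% with the prototype chemistry, 5–95% with the nested
chemistry whose higher coverage and blocked overlap extension permit the
lower bound).  With the prototype chemistry, residual bias from primer
sequences internalised by overlap extension makes heteroplasmy calls inside
likely primer-binding regions untrustworthy, so apparent heteroplasmies
there are masked as uncallable; the nested chemistry needs no mask and OREO
calls everywhere, including under primer sites.

Region-wide calling routes each queried site by segment: overlap-segment
sites are counted from OREO-enriched overarching reads, non-overlap sites
from the naive pileup (they are unaffected by primer bias).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from fractions import Fraction
from typing import Callable, Iterable

from .amplicons import AmpliconPanel
from .coords import CircularRegion, ReferenceGenome
from .errors import ConfigError, DesignError
from .probes import (AlleleCounts, ProbePair, VariantSite,
                     design_probe_pair, oreo_filter)

PROTOTYPE = "prototype"
NESTED = "nested"


class Status(str, Enum):
    HOMOPLASMIC_REF = "homoplasmic_ref"
    HOMOPLASMIC_ALT = "homoplasmic_alt"
    HETEROPLASMIC = "heteroplasmic"
    UNCALLABLE_LOW_COVERAGE = "uncallable_low_coverage"
    UNCALLABLE_PRIMER_REGION = "uncallable_primer_region"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class ThresholdSet:
    """Depth and fraction thresholds for site classification.

    Percent thresholds are in percent units.  The heteroplasmy window bounds
    are inclusive (recorded in output metadata).
    """

    analytical_depth: int = 20
    minor_depth: int = 20
    detection_fraction: float = 5.0
    calling_fraction: float = 10.0
    het_window_low: float = 10.0
    het_window_high: float = 90.0
    primer_mask_width: int = 27

    def __post_init__(self) -> None:
        if not (0 < self.detection_fraction <= self.calling_fraction < 50):
            raise ConfigError("need 0 < detection <= calling < 50")
        if self.analytical_depth < 1:
            raise ConfigError("analytical_depth must be >= 1")
        if self.het_window_low not in (self.detection_fraction,
                                       self.calling_fraction):
            raise ConfigError(
                "het_window_low must equal the detection or calling fraction")

    @classmethod
    def for_mode(cls, mode: str) -> "ThresholdSet":
        if mode == PROTOTYPE:
            return cls(het_window_low=10.0, het_window_high=90.0)
        if mode == NESTED:
            return cls(calling_fraction=5.0, het_window_low=5.0,
                       het_window_high=95.0)
        raise ConfigError(f"unknown mode {mode!r}")

    @classmethod
    def from_file(cls, path, mode: str = NESTED) -> "ThresholdSet":
        """Read ``key=value`` overrides on top of the mode defaults."""
        base = cls.for_mode(mode)
        kwargs = {}
        with open(path) as fh:
            for i, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}:{i}: expected key=value")
                key, value = (t.strip() for t in line.split("=", 1))
                if key not in cls.__dataclass_fields__:
                    raise ConfigError(f"{path}:{i}: unknown threshold {key!r}")
                typ = int if key.endswith("depth") or key.endswith("width") \
                    else float
                kwargs[key] = typ(value)
        return replace(base, **kwargs)


@dataclass
class SiteCall:
    site: VariantSite
    counts: AlleleCounts | None
    alt_fraction: float | None
    status: Status
    mode: str
    in_primer: bool = False
    used_oreo: bool = False
    probe: ProbePair | None = None
    reason: str | None = None


def classify_site(counts: AlleleCounts, thresholds: ThresholdSet,
                  in_primer_region: bool, mode: str,
                  site: VariantSite | None = None) -> SiteCall:
    """Classify one site; a total function over (counts, flags).

    Decisions use exact rational fractions; the reported percentage is
    rounded only for display.  Failing the minor-component depth rule
    demotes an apparent heteroplasmy to uncallable rather than homoplasmic,
    to avoid silently asserting absence of the minor allele.
    """
    if mode not in (PROTOTYPE, NESTED):
        raise ConfigError(f"unknown mode {mode!r}")
    total = counts.informative
    base = dict(site=site, counts=counts, mode=mode,
                in_primer=in_primer_region)
    if total < thresholds.analytical_depth:
        return SiteCall(alt_fraction=None,
                        status=Status.UNCALLABLE_LOW_COVERAGE,
                        reason=f"depth {total} < {thresholds.analytical_depth}",
                        **base)
    frac = Fraction(100 * counts.alt_count, total)
    pct = float(frac)
    low = Fraction(thresholds.het_window_low).limit_denominator(10**6)
    high = Fraction(thresholds.het_window_high).limit_denominator(10**6)
    apparent_het = low <= frac <= high
    if mode == PROTOTYPE and in_primer_region and apparent_het:
        return SiteCall(alt_fraction=pct,
                        status=Status.UNCALLABLE_PRIMER_REGION,
                        reason="apparent heteroplasmy in likely primer region",
                        **base)
    if frac > high:
        return SiteCall(alt_fraction=pct, status=Status.HOMOPLASMIC_ALT, **base)
    if frac < low:
        return SiteCall(alt_fraction=pct, status=Status.HOMOPLASMIC_REF, **base)
    if counts.minor >= thresholds.minor_depth:
        return SiteCall(alt_fraction=pct, status=Status.HETEROPLASMIC, **base)
    return SiteCall(alt_fraction=pct, status=Status.UNCALLABLE_LOW_COVERAGE,
                    reason=f"minor component {counts.minor} < "
                           f"{thresholds.minor_depth}", **base)


def in_primer_region(position: int, panel: AmpliconPanel,
                     mask_width: int = 27) -> bool:
    """True iff the position lies within ``mask_width`` bases of any amplicon end.

    Wrap-aware: a position is masked when it sits inside an amplicon within
    the first or last ``mask_width`` positions of that amplicon.
    """
    G = panel.genome_length
    for a in panel.amplicons:
        if not a.region.contains(position, G):
            continue
        off = a.region.offset_of(position, G)
        if off < mask_width or a.expected_length(G) - 1 - off < mask_width:
            return True
    return False


def nearest_overlap_boundary(site_position: int, panel: AmpliconPanel
                             ) -> tuple[int, str]:
    """The amplicon end nearest the site inside its overlap segment.

    Returns (boundary position, side) where side says which side of the
    boundary is outside the amplicon ("right" for a 3' end, "left" for a
    5' start).
    """
    G = panel.genome_length
    best = None
    for a in panel.amplicons:
        if not a.region.contains(site_position, G):
            continue
        off = a.region.offset_of(site_position, G)
        length = a.expected_length(G)
        for dist, pos, side in ((off, a.region.start, "left"),
                                (length - 1 - off, a.region.end, "right")):
            if best is None or dist < best[0]:
                best = (dist, pos, side)
    if best is None:
        raise DesignError(f"site {site_position} outside every amplicon")
    return best[1], best[2]


def classify_naive(sites: Iterable[VariantSite],
                   pileup: Callable[[VariantSite], AlleleCounts],
                   thresholds: ThresholdSet, mode: str) -> list[SiteCall]:
    """Classify sites directly from pileup counts, with no OREO and no mask."""
    return [classify_site(pileup(s), thresholds, in_primer_region=False,
                          mode=mode, site=s) for s in sites]


def find_homopolymer_regions(genome: ReferenceGenome,
                             min_run: int = 8) -> list[CircularRegion]:
    """Homopolymer tracts of length >= ``min_run`` (linear scan, no wrap join).

    Such simple-sequence regions (and the AC repeat) are annotated as
    unevaluated and excluded from substitution calling; their length
    heteroplasmy is out of scope.
    """
    out = []
    seq = genome.sequence
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            out.append(CircularRegion(i + 1, j))
        i = j
    return out


def call_region(genome: ReferenceGenome, panel: AmpliconPanel,
                sites: list[VariantSite], *, mode: str,
                reads=None,
                pileup: Callable[[VariantSite], AlleleCounts] | None = None,
                thresholds: ThresholdSet | None = None,
                excluded_regions: list[CircularRegion] | None = None,
                probe_margin: int = 1,
                backbone: str | None = None
                ) -> tuple[list[SiteCall], dict]:
    """Call every queried site, routing by segment type.

    Overlap-segment sites are counted by OREO from ``reads`` (probe pair
    designed against the nearest amplicon end); non-overlap sites, which are
    unaffected by primer bias, use the naive ``pileup`` counts.  Probe design
    failure propagates as a no-call with its reason.  Returns the calls and a
    summary tallying SNPs (homoplasmic alternative alleles), heteroplasmies
    and every masked or demoted site.
    """
    thresholds = thresholds or ThresholdSet.for_mode(mode)
    excluded = excluded_regions or []
    reads = list(reads) if reads is not None else None
    calls: list[SiteCall] = []
    G = panel.genome_length
    for site in sites:
        in_primer = in_primer_region(site.position, panel,
                                     thresholds.primer_mask_width)
        if any(r.contains(site.position, G) for r in excluded):
            calls.append(SiteCall(site=site, counts=None, alt_fraction=None,
                                  status=Status.NO_CALL, mode=mode,
                                  in_primer=in_primer,
                                  reason="unevaluated-region"))
            continue
        try:
            segment = panel.segment_of(site.position)
        except DesignError as exc:
            calls.append(SiteCall(site=site, counts=None, alt_fraction=None,
                                  status=Status.NO_CALL, mode=mode,
                                  reason=str(exc)))
            continue
        if segment.overlap and reads is not None:
            try:
                boundary, side = nearest_overlap_boundary(site.position, panel)
                pair = design_probe_pair(
                    genome, site, boundary, margin=probe_margin,
                    span=panel.span, side=side, backbone=backbone)
                counts = oreo_filter(reads, pair)
            except DesignError as exc:
                calls.append(SiteCall(site=site, counts=None,
                                      alt_fraction=None, status=Status.NO_CALL,
                                      mode=mode, in_primer=in_primer,
                                      reason=str(exc)))
                continue
            call = classify_site(counts, thresholds, in_primer, mode, site)
            call.used_oreo = True
            call.probe = pair
        else:
            if pileup is None:
                calls.append(SiteCall(site=site, counts=None,
                                      alt_fraction=None, status=Status.NO_CALL,
                                      mode=mode, in_primer=in_primer,
                                      reason="no pileup source provided"))
                continue
            counts = pileup(site)
            call = classify_site(counts, thresholds, in_primer, mode, site)
        calls.append(call)
    summary = summarize_calls(calls)
    return calls, summary


def summarize_calls(calls: list[SiteCall]) -> dict:
    by_status: dict[str, int] = {}
    for c in calls:
        by_status[c.status.value] = by_status.get(c.status.value, 0) + 1
    return {
        "sites": len(calls),
        "snps": by_status.get(Status.HOMOPLASMIC_ALT.value, 0),
        "heteroplasmies": by_status.get(Status.HETEROPLASMIC.value, 0),
        "by_status": by_status,
        "masked_or_demoted": [
            {"position": c.site.position if c.site else None,
             "status": c.status.value, "reason": c.reason}
            for c in calls if c.reason is not None],
    }
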