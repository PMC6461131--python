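"""The overlapping-amplicon panel and its coverage geometry.

A single-multiplex control-region assay amplifies the target as a chain of
overlapping amplicons (ten of 144–237 bp in the design modelled here).  The
chain induces an alternating partition of the amplified span into
non-overlapping segments (covered by one amplicon) and overlap segments
(covered by two); coverage statistics, boundary detection from coverage
drops, and low-coverage flagging all operate on that partition.

Exact commercial amplicon coordinates are proprietary; the bundled default
panel is an approximate reconstruction with the published length and overlap
ranges and is labelled as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .coords import RCRS_LENGTH, CircularRegion, region_length
from .errors import DesignError


@dataclass(frozen=True)
class Amplicon:
    """One designed amplicon, outer bounds inclusive of primer-derived ends."""

    id: int
    region: CircularRegion

    def expected_length(self, genome_length: int) -> int:
        return region_length(self.region, genome_length)


@dataclass(frozen=True)
class Segment:
    region: CircularRegion
    overlap: bool
    amplicon_ids: frozenset[int]

    @property
    def name(self) -> str:
        ids = "/".join(f"A{i}" for i in sorted(self.amplicon_ids))
        return ids


@dataclass(frozen=True)
class SegmentCoverage:
    segment: Segment
    mean_depth: float
    normalized_depth: float


class AmpliconPanel:
    """An ordered chain of overlapping amplicons on a circular genome.

    Validates the chain property on construction: consecutive amplicons
    overlap by >= 1 base, non-consecutive amplicons do not overlap, and each
    amplicon has a non-empty exclusive segment.
    """

    def __init__(self, amplicons: list[Amplicon], genome_length: int = RCRS_LENGTH):
        if not amplicons:
            raise DesignError("empty amplicon list")
        self.amplicons = list(amplicons)
        self.genome_length = genome_length
        first = self.amplicons[0]
        G = genome_length
        # Work in linear offsets from the first amplicon's start.
        self._starts = [(a.region.start - first.region.start) % G
                        for a in self.amplicons]
        self._ends = [s + a.expected_length(G) - 1
                      for s, a in zip(self._starts, self.amplicons)]
        self._validate()
        self.span = CircularRegion(first.region.start,
                                   self.amplicons[-1].region.end)
        self._segments: list[Segment] | None = None

    def _validate(self) -> None:
        s, e = self._starts, self._ends
        for i in range(len(s) - 1):
            a, b = self.amplicons[i], self.amplicons[i + 1]
            if s[i + 1] <= s[i] or e[i + 1] <= e[i]:
                raise DesignError(
                    f"amplicons {a.id},{b.id}: chain not strictly ordered")
            if s[i + 1] > e[i]:
                raise DesignError(f"gap between amplicons {a.id} and {b.id}")
            if i > 0 and s[i + 1] <= e[i - 1]:
                raise DesignError(
                    f"non-consecutive overlap: amplicons "
                    f"{self.amplicons[i - 1].id} and {b.id}")
            if i > 0 and s[i + 1] == e[i - 1] + 1:
                raise DesignError(
                    f"amplicon {a.id} has an empty exclusive segment")

    def __len__(self) -> int:
        return len(self.amplicons)

    @property
    def span_length(self) -> int:
        return self.span.length(self.genome_length)

    def offset(self, position: int) -> int:
        return self.span.offset_of(position, self.genome_length)

    def position(self, offset: int) -> int:
        return self.span.position_at(offset, self.genome_length)

    def segments(self) -> list[Segment]:
        if self._segments is None:
            self._segments = build_segments(self, self.genome_length)
        return self._segments

    def segment_of(self, position: int) -> Segment:
        for seg in self.segments():
            if seg.region.contains(position, self.genome_length):
                return seg
        raise DesignError(f"position {position} outside the amplified span")

    def amplicon_ends(self) -> list[tuple[int, int, str]]:
        """All amplicon termini as (amplicon_id, position, 'start'|'end')."""
        out = []
        for a in self.amplicons:
            out.append((a.id, a.region.start, "start"))
            out.append((a.id, a.region.end, "end"))
        return out

    def overlap_junctions(self) -> list[CircularRegion]:
        """Overlap regions between consecutive amplicons, in chain order."""
        out = []
        for i in range(len(self.amplicons) - 1):
            nxt = self.amplicons[i + 1]
            cur = self.amplicons[i]
            out.append(CircularRegion(nxt.region.start, cur.region.end))
        return out

    @classmethod
    def from_tsv(cls, path, genome_length: int = RCRS_LENGTH) -> "AmpliconPanel":
        df = pd.read_csv(path, sep="\t")
        amps = [Amplicon(int(r.id), CircularRegion(int(r.start), int(r.end)))
                for r in df.itertuples()]
        return cls(amps, genome_length)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [{"id": a.id, "start": a.region.start, "end": a.region.end}
             for a in self.amplicons]).to_csv(path, sep="\t", index=False)

    @classmethod
    def default(cls) -> "AmpliconPanel":
        """The bundled approximate 10-amplicon control-region design.

        Spans rCRS 15,989–619 (1200 positions) with amplicon lengths
        144–237 bp and overlaps of 52–85 bp; coordinates are approximate
        reconstructions, not the proprietary kit values.
        """
        with resources.as_file(resources.files("oreomt.data")
                               .joinpath("amplicons_default.tsv")) as p:
            return cls.from_tsv(p)


def build_segments(amplicons: list[Amplicon],
                   genome_length: int = RCRS_LENGTH) -> list[Segment]:
    """Partition the amplified span into alternating exclusive/overlap segments.

    A valid chain of n amplicons yields 2n-1 segments: exclusive, overlap,
    exclusive, ..., exclusive.
    """
    panel = amplicons if isinstance(amplicons, AmpliconPanel) else \
        AmpliconPanel(amplicons, genome_length)
    amps, s, e = panel.amplicons, panel._starts, panel._ends
    G = panel.genome_length

    def pos(off: int) -> int:
        return panel.position(off)

    segs: list[Segment] = []
    n = len(amps)
    if n == 1:
        return [Segment(amps[0].region, False, frozenset({amps[0].id}))]
    for i in range(n):
        lo = 0 if i == 0 else e[i - 1] + 1
        hi = panel.span_length - 1 if i == n - 1 else s[i + 1] - 1
        segs.append(Segment(CircularRegion(pos(lo), pos(hi)), False,
                            frozenset({amps[i].id})))
        if i < n - 1:
            segs.append(Segment(CircularRegion(pos(s[i + 1]), pos(e[i])), True,
                                frozenset({amps[i].id, amps[i + 1].id})))
    return segs


def segment_coverage(depth_track: np.ndarray, segments: list[Segment],
                     panel: AmpliconPanel) -> list[SegmentCoverage]:
    """Per-segment mean depth, normalized to the mean over the whole span.

    ``depth_track`` is indexed by offset within the panel span.  Segment means
    are arithmetic over positions; normalization is to the per-sample overall
    mean (the normalization choice is recorded in the report metadata).
    """
    depth_track = np.asarray(depth_track, dtype=float)
    if len(depth_track) != panel.span_length:
        raise DesignError(
            f"depth track length {len(depth_track)} != span {panel.span_length}")
    if (depth_track < 0).any():
        raise DesignError("negative depth values")
    overall = depth_track.mean()
    out = []
    for seg in segments:
        lo = panel.offset(seg.region.start)
        hi = panel.offset(seg.region.end)
        mean = float(depth_track[lo:hi + 1].mean())
        out.append(SegmentCoverage(seg, mean,
                                   mean / overall if overall > 0 else 0.0))
    return out


def detect_boundaries(depth_track: np.ndarray, expected_count: int,
                      window: int = 10) -> list[int]:
    """Amplicon-end candidates from the sharpest single-step coverage changes.

    The change score between track positions q and q+1 (1-based within the
    track) is |d(q+1) - d(q)| / max(d(q), 1), a scale-free measure robust
    across multiplexing depths.  The ``expected_count`` top-scoring steps are
    taken greedily, suppressing further candidates within ``window`` positions
    of an accepted one; a drop is reported as the last high-coverage position
    (q), a rise as the first (q+1).  Returns sorted 1-based track positions.
    """
    if expected_count < 1:
        raise DesignError("expected_count must be >= 1")
    d = np.asarray(depth_track, dtype=float)
    if len(d) < 2:
        return []
    diff = d[1:] - d[:-1]
    score = np.abs(diff) / np.maximum(d[:-1], 1.0)
    order = np.argsort(score, kind="stable")[::-1]
    picked: list[int] = []
    bounds: list[int] = []
    for q0 in order:
        if score[q0] <= 0:
            break
        if any(abs(int(q0) - p) < window for p in picked):
            continue
        picked.append(int(q0))
        q = int(q0) + 1  # 1-based position of the left side of the step
        bounds.append(q if diff[q0] < 0 else q + 1)
        if len(bounds) == expected_count:
            break
    if len(bounds) < expected_count:
        warnings.warn(
            f"only {len(bounds)} of {expected_count} coverage steps found",
            stacklevel=2)
    return sorted(bounds)


def flag_low_coverage_amplicons(coverages: list[SegmentCoverage],
                                fold_threshold: float = 5.0) -> list[Segment]:
    """Exclusive segments whose depth is suppressed versus the rest of the sample.

    A non-overlap segment is flagged when its mean depth falls below the mean
    of all *other* segments divided by ``fold_threshold``; such suppression
    signals a primer-site variant in that amplicon, or numt visibility.
    """
    if fold_threshold <= 1:
        raise DesignError("fold_threshold must be > 1")
    flagged = []
    means = np.array([c.mean_depth for c in coverages], dtype=float)
    for i, cov in enumerate(coverages):
        if cov.segment.overlap:
            continue
        others = np.delete(means, i)
        if len(others) and cov.mean_depth < others.mean() / fold_threshold:
            flagged.append(cov.segment)
    return flagged


def coverage_report(coverages: list[SegmentCoverage],
                    flagged: list[Segment] | None = None) -> pd.DataFrame:
    flagged = flagged or []
    names = {s.name for s in flagged}
    return pd.DataFrame([
        {"segment": c.segment.name,
         "start": c.segment.region.start,
         "end": c.segment.region.end,
         "overlap": c.segment.overlap,
         "mean_depth": round(c.mean_depth, 3),
         "normalized_depth": round(c.normalized_depth, 4),
         "flagged_low_coverage": c.segment.name in names}
        for c in coverages])
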