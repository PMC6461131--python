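"""Synthetic single-multiplex control-region MPS reads with known truth.

The generative model reproduces the read classes and bias mechanisms of a
single-reaction overlapping-amplicon assay:

* full-length designed-amplicon reads (the 600-cycle paired-end chemistry
  fully spans 144-237 bp amplicons after merging, so merged single-end reads
  are emitted);
* short overlap-length by-products (52-91 bp) composed entirely of
  primer-derived, hence reference, sequence;
* primer footprints (default 20-26 bases per amplicon end) that emit the
  REFERENCE allele regardless of the template drawn - the reference-bias
  mechanism;
* prototype chemistry only: overlap extension, in which a fraction of
  designed-amplicon molecules additionally carry reference alleles at
  internalised primer blocks (the neighbouring amplicon's primer footprint
  lying inside the read body); the nested chemistry blocks this with
  flanking adapters, so the rate is forced to zero there;
* optional numt reads carrying numt alleles at diagnostic sites, emitted for
  amplicons overlapping the diagnostic window at a configured fraction of
  that amplicon's yield;
* a flat per-base substitution error applied last.

Identical seeds give byte-identical output (one integer-seeded generator,
reads drawn in a fixed order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .amplicons import AmpliconPanel
from .calling import NESTED, PROTOTYPE, SiteCall, Status, ThresholdSet
from .coords import CircularRegion, ReferenceGenome, extract_sequence
from .errors import ConfigError
from .numt import DiagnosticSite
from .preprocess import ReadRecord
from .probes import AlleleCounts, VariantSite

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

DEFAULT_PRIMER_LENGTHS = [(20, 24), (22, 21), (25, 20), (21, 26), (23, 22),
                          (20, 25), (24, 21), (22, 23), (26, 20), (21, 22)]


def synthetic_reference(length: int = 16569, seed: int = 20190501,
                        name: str = "chrM_synthetic") -> ReferenceGenome:
    """A deterministic synthetic circular genome.

    A stand-in with the rCRS length for tests and examples; it is NOT the
    real NC_012920.1 sequence.  Uniform random bases make 10-30 nt probes
    overwhelmingly unique, as on the real control region.
    """
    rng = np.random.default_rng(seed)
    seq = rng.choice(_BASES, size=length).tobytes().decode()
    return ReferenceGenome(name=name, sequence=seq, circular=True)


@dataclass(frozen=True)
class SimVariant:
    """A sample-haplotype site with its template allele fraction.

    fraction 1.0 is a homoplasmic alternative allele; anything in (0, 1)
    is a point heteroplasmy.  Substitutions only.
    """

    site: VariantSite
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigError("variant fraction outside [0, 1]")
        if not self.site.is_snv:
            raise ConfigError("the simulator emits substitutions only")


@dataclass(frozen=True)
class NumtSim:
    diagnostics: tuple[DiagnosticSite, ...]
    fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ConfigError("numt fraction outside [0, 1]")


@dataclass
class SimulationConfig:
    genome: ReferenceGenome
    panel: AmpliconPanel
    mode: str = PROTOTYPE
    n_reads: int = 10000
    yields: list[float] | None = None
    primer_lengths: list[tuple[int, int]] | None = None
    short_product_rate: float = 0.3
    overlap_extension_rate: float = 0.2
    variants: list[SimVariant] = field(default_factory=list)
    numt: NumtSim | None = None
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (PROTOTYPE, NESTED):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.mode == NESTED and self.overlap_extension_rate > 0:
            raise ConfigError(
                "overlap extension is blocked by the nested chemistry; "
                "overlap_extension_rate must be 0 in nested mode")
        for rate in (self.short_product_rate, self.overlap_extension_rate,
                     self.error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError("rates must lie in [0, 1]")
        n = len(self.panel)
        if self.yields is None:
            self.yields = [1.0] * n
        if len(self.yields) != n:
            raise ConfigError("one relative yield per amplicon required")
        if self.primer_lengths is None:
            self.primer_lengths = [DEFAULT_PRIMER_LENGTHS[i % 10]
                                   for i in range(n)]
        if len(self.primer_lengths) != n:
            raise ConfigError("one primer-length pair per amplicon required")
        for f, r in self.primer_lengths:
            if f < 1 or r < 1:
                raise ConfigError("primer lengths must be positive")


class _AmpliconTemplate:
    """Precomputed per-amplicon emission state."""

    def __init__(self, cfg: SimulationConfig, index: int):
        panel, G = cfg.panel, cfg.genome.length
        amp = panel.amplicons[index]
        self.id = amp.id
        self.start = amp.region.start
        self.length = amp.expected_length(G)
        self.template = np.frombuffer(
            extract_sequence(cfg.genome, amp.region).encode(),
            dtype=np.uint8).copy()
        fwd, rev = cfg.primer_lengths[index]
        own = np.zeros(self.length, dtype=bool)
        own[:fwd] = True
        own[self.length - rev:] = True
        self.own_footprint = own
        internal = np.zeros(self.length, dtype=bool)
        if cfg.mode == PROTOTYPE:
            for j, other in enumerate(panel.amplicons):
                if j == index:
                    continue
                of, orv = cfg.primer_lengths[j]
                blocks = [CircularRegion(
                    other.region.start,
                    other.region.position_at(of - 1, G))]
                blocks.append(CircularRegion(
                    other.region.position_at(
                        other.expected_length(G) - orv, G),
                    other.region.end))
                for block in blocks:
                    for pos in block.positions(G):
                        if amp.region.contains(pos, G):
                            internal[amp.region.offset_of(pos, G)] = True
        self.internal_blocks = internal & ~own

        def entries(sites_alleles):
            out = []
            for pos, allele in sites_alleles:
                if amp.region.contains(pos, G):
                    off = amp.region.offset_of(pos, G)
                    out.append((off, ord(allele), bool(own[off]),
                                bool(self.internal_blocks[off])))
            return out

        self.variant_entries = []
        for v in cfg.variants:
            ents = entries([(v.site.position, v.site.alt_allele)])
            if ents:
                self.variant_entries.append((ents, v))
        self.numt_entries = []
        if cfg.numt is not None:
            self.numt_entries = entries(
                [(d.position, d.numt_allele) for d in cfg.numt.diagnostics])
        self.emits_numt = bool(self.numt_entries)


def _apply_errors(arr: np.ndarray, rate: float, rng) -> None:
    if rate <= 0:
        return
    m = rng.binomial(len(arr), rate)
    if m == 0:
        return
    idx = rng.choice(len(arr), size=m, replace=False)
    for i in idx:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]


def simulate_reads(config: SimulationConfig
                   ) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Generate reads and a per-read truth table.

    Truth columns: read_id, source (amplicon|short|numt), origin (amplicon id
    or junction index), start (1-based genome position), length,
    overlap_extension (bool), and site_info - per covered variant site,
    "position:template_allele:F|T" where the trailing flag says whether the
    emitted base at the site was primer-forced to the reference.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    G = cfg.genome.length
    templates = [_AmpliconTemplate(cfg, i) for i in range(len(cfg.panel))]
    junctions = cfg.panel.overlap_junctions()
    junction_templates = [
        (j.start, np.frombuffer(
            extract_sequence(cfg.genome, j).encode(), dtype=np.uint8).copy())
        for j in junctions]
    weights = np.asarray(cfg.yields, dtype=float)
    cum = np.cumsum(weights / weights.sum())
    prototype = cfg.mode == PROTOTYPE

    reads: list[ReadRecord] = []
    truth_rows = []
    for i in range(cfg.n_reads):
        rid = f"sim{i:07d}"
        u = rng.random()
        if junction_templates and u < cfg.short_product_rate:
            j = int(rng.integers(0, len(junction_templates)))
            start, tpl = junction_templates[j]
            arr = tpl.copy()
            _apply_errors(arr, cfg.error_rate, rng)
            reads.append(ReadRecord(rid, arr.tobytes().decode(),
                                    "I" * len(arr)))
            truth_rows.append((rid, "short", j + 1, start, len(arr),
                               False, ""))
            continue
        t = templates[int(np.searchsorted(cum, rng.random(), side="right"))]
        arr = t.template.copy()
        oer = prototype and rng.random() < cfg.overlap_extension_rate
        is_numt = t.emits_numt and rng.random() < cfg.numt.fraction
        infos = []
        if is_numt:
            for off, allele, in_own, in_internal in t.numt_entries:
                forced = in_own or (oer and in_internal)
                if not forced:
                    arr[off] = allele
        else:
            for ents, var in t.variant_entries:
                is_alt = rng.random() < var.fraction
                for off, allele, in_own, in_internal in ents:
                    forced = in_own or (oer and in_internal)
                    if is_alt and not forced:
                        arr[off] = allele
                    infos.append(
                        f"{var.site.position}:"
                        f"{'alt' if is_alt else 'ref'}:{'T' if forced else 'F'}")
        _apply_errors(arr, cfg.error_rate, rng)
        reads.append(ReadRecord(rid, arr.tobytes().decode(), "I" * len(arr)))
        truth_rows.append((rid, "numt" if is_numt else "amplicon", t.id,
                           t.start, t.length, oer, ";".join(infos)))
    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "source", "origin", "start", "length",
                             "overlap_extension", "site_info"])
    return reads, truth


class TruthPileup:
    """Perfect-alignment pileup over simulated reads.

    Each simulated read's genome start is known from the truth table, which
    makes naive per-position counting equivalent to an error-free aligner;
    this is the naive counting path for simulated data (real alignments go
    through the SAM/BAM pileup reader instead).
    """

    def __init__(self, reads: list[ReadRecord], truth: pd.DataFrame,
                 genome_length: int):
        order = {r.id: i for i, r in enumerate(reads)}
        truth = truth.sort_values(
            "read_id", key=lambda s: s.map(order)).reset_index(drop=True)
        self.sequences = [r.sequence for r in reads]
        self.starts = truth["start"].to_numpy(dtype=np.int64)
        self.lengths = truth["length"].to_numpy(dtype=np.int64)
        self.G = genome_length

    def base_counts(self, position: int) -> dict[str, int]:
        offs = (position - self.starts) % self.G
        counts: dict[str, int] = {}
        for i in np.nonzero(offs < self.lengths)[0]:
            b = self.sequences[i][offs[i]]
            counts[b] = counts.get(b, 0) + 1
        return counts

    def counts_at(self, site: VariantSite) -> AlleleCounts:
        counts = self.base_counts(site.position)
        ref = counts.get(site.ref_allele, 0)
        alt = counts.get(site.alt_allele, 0)
        other = sum(counts.values()) - ref - alt
        return AlleleCounts(ref_count=ref, alt_count=alt, other_count=other)

    def depth_track(self, panel: AmpliconPanel) -> np.ndarray:
        span_len = panel.span_length
        diff = np.zeros(span_len + 1, dtype=np.int64)
        so = (self.starts - panel.span.start) % self.G
        keep = so + self.lengths <= span_len
        np.add.at(diff, so[keep], 1)
        np.add.at(diff, (so + self.lengths)[keep], -1)
        return np.cumsum(diff[:-1])


def true_status(fraction: float, thresholds: ThresholdSet) -> Status:
    pct = 100.0 * fraction
    if pct > thresholds.het_window_high:
        return Status.HOMOPLASMIC_ALT
    if pct < thresholds.het_window_low:
        return Status.HOMOPLASMIC_REF
    return Status.HETEROPLASMIC


def truth_compare(variants: list[SimVariant], calls: list[SiteCall],
                  thresholds: ThresholdSet) -> tuple[pd.DataFrame, dict]:
    """Per-site truth-vs-call table plus a confusion/bias summary.

    Sites present in only one of the two inputs are listed in the summary,
    never silently dropped.  Bias is mean(estimated - true) percentage over
    sites with a defined estimate.
    """
    by_pos = {c.site.position: c for c in calls if c.site is not None}
    rows, unmatched = [], []
    for v in variants:
        call = by_pos.pop(v.site.position, None)
        if call is None:
            unmatched.append(v.site.position)
            continue
        rows.append({
            "position": v.site.position,
            "true_fraction_pct": 100.0 * v.fraction,
            "estimated_fraction_pct": call.alt_fraction,
            "true_status": true_status(v.fraction, thresholds).value,
            "called_status": call.status.value,
        })
    table = pd.DataFrame(rows)
    defined = table.dropna(subset=["estimated_fraction_pct"]) if len(table) \
        else table
    confusion: dict[tuple[str, str], int] = {}
    for r in rows:
        key = (r["true_status"], r["called_status"])
        confusion[key] = confusion.get(key, 0) + 1
    summary = {
        "bias_pct": float((defined["estimated_fraction_pct"]
                           - defined["true_fraction_pct"]).mean())
        if len(defined) else float("nan"),
        "confusion": confusion,
        "truth_only_positions": unmatched,
        "calls_only_positions": sorted(by_pos),
    }
    return table, summary
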