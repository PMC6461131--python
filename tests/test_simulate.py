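"""Generative model invariants: determinism, allele conservation, bias."""

import numpy as np
import pytest

from oreomt import (NESTED, PROTOTYPE, SimulationConfig, SimVariant,
                    TruthPileup, VariantSite, allele_fraction, oreo_filter,
                    design_probe_pair, simulate_reads, size_select_list,
                    length_profile)
from oreomt.calling import nearest_overlap_boundary
from oreomt.errors import ConfigError


def _variant(genome, position, alt_choices="ACGT"):
    ref = genome.base_at(position)
    alt = next(b for b in alt_choices if b != ref)
    return VariantSite(position, ref, alt)


def test_nested_mode_forbids_overlap_extension(genome, panel):
    with pytest.raises(ConfigError, match="nested"):
        SimulationConfig(genome=genome, panel=panel, mode=NESTED,
                         overlap_extension_rate=0.1)


def test_error_free_no_variant_reads_are_reference_substrings(genome, panel):
    cfg = SimulationConfig(genome=genome, panel=panel, n_reads=300,
                           error_rate=0.0, seed=3)
    reads, truth = simulate_reads(cfg)
    doubled = genome.sequence * 2  # wrap-aware substring check
    assert all(r.sequence in doubled for r in reads)
    assert len(truth) == len(reads)


def test_same_seed_is_byte_identical(genome, panel):
    cfg = dict(genome=genome, panel=panel, n_reads=500, seed=11,
               variants=[SimVariant(_variant(genome, 16045), 0.3)])
    r1, t1 = simulate_reads(SimulationConfig(**cfg))
    r2, t2 = simulate_reads(SimulationConfig(**cfg))
    assert [x.sequence for x in r1] == [x.sequence for x in r2]
    assert t1.equals(t2)
    r3, _ = simulate_reads(SimulationConfig(**cfg, error_rate=0.0))
    assert [x.sequence for x in r1] != [x.sequence for x in r3]


def test_read_length_support(genome, panel):
    """Prototype lengths are overlap-product or designed-amplicon lengths;
    after size selection at 95 only designed lengths remain."""
    cfg = SimulationConfig(genome=genome, panel=panel, n_reads=2000,
                           short_product_rate=0.4, seed=5)
    reads, truth = simulate_reads(cfg)
    G = genome.length
    designed = {a.expected_length(G) for a in panel.amplicons}
    shorts = {j.length(G) for j in panel.overlap_junctions()}
    assert set(length_profile(reads)) <= designed | shorts
    assert max(shorts) <= 91 and min(designed) >= 144
    kept, _ = size_select_list(reads, 95)
    assert set(length_profile(kept)) <= designed


def test_short_product_removed_fraction(genome, panel):
    """Removed fraction tracks the configured short-product rate."""
    rate = 0.4
    cfg = SimulationConfig(genome=genome, panel=panel, mode=NESTED,
                           overlap_extension_rate=0.0, n_reads=20000,
                           short_product_rate=rate, seed=9)
    reads, _ = simulate_reads(cfg)
    kept, summary = size_select_list(reads, 95)
    removed_frac = summary.removed / summary.total
    sd = np.sqrt(rate * (1 - rate) / summary.total)
    assert abs(removed_frac - rate) < 3 * sd
    assert all(len(r) >= 95 for r in kept)


def test_allele_conservation_unshadowed_site(genome, panel):
    """At a site outside every primer footprint the empirical allele fraction
    converges to the configured fraction (law of large numbers)."""
    frac = 0.30
    site = _variant(genome, 16045)  # interior of amplicon 1's exclusive segment
    cfg = SimulationConfig(genome=genome, panel=panel, n_reads=50000,
                           short_product_rate=0.3,
                           variants=[SimVariant(site, frac)],
                           error_rate=0.0, seed=21)
    reads, truth = simulate_reads(cfg)
    pile = TruthPileup(reads, truth, genome.length)
    counts = pile.counts_at(site)
    n = counts.informative
    sd = np.sqrt(frac * (1 - frac) / n)
    assert abs(counts.alt_count / n - frac) < 3 * sd


def test_primer_footprint_forces_reference(genome, panel):
    """A heteroplasmy inside a primer footprint is diluted in the naive
    pileup but fully recovered by OREO (the bias mechanism)."""
    frac = 0.30
    site = _variant(genome, 16160)  # inside amplicon 1's 3' primer footprint
    cfg = SimulationConfig(genome=genome, panel=panel, mode=PROTOTYPE,
                           n_reads=30000, short_product_rate=0.5,
                           overlap_extension_rate=0.0,
                           variants=[SimVariant(site, frac)],
                           error_rate=0.0, seed=13)
    reads, truth = simulate_reads(cfg)
    pile = TruthPileup(reads, truth, genome.length)
    naive_pct = allele_fraction(pile.counts_at(site))
    assert naive_pct < 100 * frac * 0.7  # materially diluted
    boundary, side = nearest_overlap_boundary(site.position, panel)
    pair = design_probe_pair(genome, site, boundary, span=panel.span,
                             side=side)
    oreo_pct = allele_fraction(oreo_filter(reads, pair))
    n = oreo_filter(reads, pair).informative
    sd_pct = 100 * np.sqrt(frac * (1 - frac) / n)
    assert abs(oreo_pct - 100 * frac) < 3 * sd_pct


def test_overlap_extension_internalizes_reference(genome, panel):
    """With overlap extension on, even overarching reads carry residual
    reference bias at the shadowed site, at the configured molecule rate."""
    oer = 0.3
    site = _variant(genome, 16160)
    cfg = SimulationConfig(genome=genome, panel=panel, mode=PROTOTYPE,
                           n_reads=30000, short_product_rate=0.3,
                           overlap_extension_rate=oer,
                           variants=[SimVariant(site, 1.0)],
                           error_rate=0.0, seed=17)
    reads, _ = simulate_reads(cfg)
    boundary, side = nearest_overlap_boundary(site.position, panel)
    pair = design_probe_pair(genome, site, boundary, span=panel.span,
                             side=side)
    counts = oreo_filter(reads, pair)
    est = counts.alt_count / counts.informative
    sd = np.sqrt(oer * (1 - oer) / counts.informative)
    assert abs(est - (1 - oer)) < 4 * sd


def test_numt_reads_only_from_window_amplicons(genome, panel):
    from oreomt import DiagnosticSite, NumtSim
    diag = [DiagnosticSite(16329, genome.base_at(16329),
                           "A" if genome.base_at(16329) != "A" else "G")]
    cfg = SimulationConfig(genome=genome, panel=panel, mode=NESTED,
                           overlap_extension_rate=0.0, n_reads=5000,
                           numt=NumtSim(tuple(diag), 0.3), seed=23)
    _, truth = simulate_reads(cfg)
    numt_rows = truth[truth.source == "numt"]
    assert len(numt_rows) > 0
    assert set(numt_rows.origin) == {3}  # only amplicon 3 spans the site


def test_truth_compare_identity(genome, panel):
    from oreomt import AlleleCounts, ThresholdSet, truth_compare
    from oreomt.calling import classify_site
    thresholds = ThresholdSet.for_mode(NESTED)
    site = _variant(genome, 16045)
    variants = [SimVariant(site, 0.5)]
    call = classify_site(AlleleCounts(500, 500), thresholds, False, NESTED,
                         site=site)
    table, summary = truth_compare(variants, [call], thresholds)
    assert summary["confusion"] == {("heteroplasmic", "heteroplasmic"): 1}
    assert abs(summary["bias_pct"]) < 1e-9
    assert summary["truth_only_positions"] == []
    # unmatched sites are listed, not dropped
    _, summary2 = truth_compare(variants, [], thresholds)
    assert summary2["truth_only_positions"] == [site.position]
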