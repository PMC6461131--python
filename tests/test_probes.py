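"""OREO probe design and exact-match counting against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oreomt import (AlleleCounts, ReferenceGenome,
                    VariantSite, allele_fraction, design_probe_pair,
                    oreo_filter, reverse_complement)
from oreomt.errors import DesignError, UndefinedFractionError
from oreomt.probes import count_overlapping


def _brute_force_min_probe(genome, site, boundary, side, min_len, max_len,
                           margin=1):
    """Exhaustive search over all (start, length) probe placements."""
    S = genome.sequence
    so, bo = site.position - 1, boundary - 1
    S_alt = S[:so] + site.alt_allele + S[so + 1:]

    def occ(text, probe):
        return (count_overlapping(text, probe)
                + count_overlapping(reverse_complement(text), probe))

    best = None
    for L in range(min_len, max_len + 1):
        for a in range(0, len(S) - L + 1):
            b = a + L - 1
            if not a <= so <= b:
                continue
            if side == "right" and not (a <= bo and b >= bo + margin):
                continue
            if side == "left" and not (b >= so and a <= bo - margin):
                continue
            rp, ap = S[a:a + L], S_alt[a:a + L]
            if occ(S, rp) == 1 and occ(S_alt, ap) == 1:
                if best is None or L < best:
                    best = L
        if best is not None:
            return best
    return None


@pytest.fixture(scope="module")
def random_genome():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=60))
    return ReferenceGenome("toy60", seq, circular=False)


def test_minimal_probe_on_nonrepetitive_genome(random_genome):
    """A unique 10-mer suffices in random non-repetitive sequence."""
    g = random_genome
    site = VariantSite(30, g.base_at(30),
                       "A" if g.base_at(30) != "A" else "C")
    pair = design_probe_pair(g, site, boundary=28, span=g.full_region,
                             side="right")
    assert pair.length == 10
    assert pair.span.contains(30, g.length)
    assert pair.span.end >= 29  # at least one base beyond the boundary
    # probes share length and differ exactly at the queried site
    diffs = [i for i, (a, b) in
             enumerate(zip(pair.ref_probe, pair.alt_probe)) if a != b]
    assert len(diffs) == 1


def test_probe_grows_past_duplicated_kmer():
    """A duplicated 12-mer around the site forces a longer probe; the result
    matches exhaustive enumeration of all placements."""
    rng = np.random.default_rng(3)
    core = "".join(rng.choice(list("ACGT"), size=40))
    dup = core[14:26]  # duplicate the 12-mer surrounding the site
    seq = core + "TT" + dup + "".join(rng.choice(list("ACGT"), size=20))
    g = ReferenceGenome("dup", seq, circular=False)
    site = VariantSite(20, g.base_at(20), "G" if g.base_at(20) != "G" else "T")
    boundary = 18
    pair = design_probe_pair(g, site, boundary, span=g.full_region,
                             side="right")
    expected = _brute_force_min_probe(g, site, boundary, "right", 10, 30)
    assert expected is not None
    assert pair.length == expected


@given(st.integers(0, 200))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_design_minimality_random_genomes(seed):
    """Returned probe length equals the exhaustive minimum on random toys."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=70))
    g = ReferenceGenome("r", seq, circular=False)
    site_pos = int(rng.integers(25, 45))
    boundary = site_pos + int(rng.integers(0, 4))
    ref = g.base_at(site_pos)
    alt = rng.choice([b for b in "ACGT" if b != ref])
    site = VariantSite(site_pos, ref, str(alt))
    expected = _brute_force_min_probe(g, site, boundary, "right", 10, 30)
    if expected is None:
        with pytest.raises(DesignError):
            design_probe_pair(g, site, boundary, span=g.full_region,
                              side="right")
    else:
        pair = design_probe_pair(g, site, boundary, span=g.full_region,
                                 side="right")
        assert pair.length == expected


def test_site_at_boundary_crosses_it(random_genome):
    g = random_genome
    site = VariantSite(28, g.base_at(28), "T" if g.base_at(28) != "T" else "A")
    pair = design_probe_pair(g, site, boundary=28, span=g.full_region,
                             side="right")
    assert pair.span.end >= 29


def test_left_side_boundary(random_genome):
    g = random_genome
    site = VariantSite(32, g.base_at(32), "C" if g.base_at(32) != "C" else "G")
    pair = design_probe_pair(g, site, boundary=30, span=g.full_region,
                             side="left")
    assert pair.span.start <= 29
    assert pair.span.contains(32, g.length)


def test_reference_mismatch_rejected(random_genome):
    g = random_genome
    wrong = "A" if g.base_at(30) != "A" else "C"
    other = "G" if wrong != "G" else "T"
    with pytest.raises(DesignError, match="mismatch"):
        design_probe_pair(g, VariantSite(30, wrong, other), 28,
                          span=g.full_region, side="right")


def test_design_failure_names_site():
    g = ReferenceGenome("rep", "AC" * 50, circular=False)
    site = VariantSite(40, g.base_at(40), "G")
    with pytest.raises(DesignError, match="40"):
        design_probe_pair(g, site, 38, span=g.full_region, side="right")


def test_insertion_probe_pair(random_genome):
    """An insertion alt probe carries the inserted base at equal total length."""
    g = random_genome
    site = VariantSite(30, g.base_at(30), "+C")
    pair = design_probe_pair(g, site, boundary=28, span=g.full_region,
                             side="right")
    assert len(pair.ref_probe) == len(pair.alt_probe)
    assert pair.ref_probe != pair.alt_probe
    # the alt probe is a substring of the insertion-bearing sequence
    S_alt = g.sequence[:30] + "C" + g.sequence[30:]
    assert pair.alt_probe in S_alt


def _brute_force_counts(reads, pair):
    ref = alt = 0
    for r in reads:
        seq = r if isinstance(r, str) else r.sequence
        r_hit = any(seq[i:i + pair.length] == pair.ref_probe
                    or seq[i:i + pair.length]
                    == reverse_complement(pair.ref_probe)
                    for i in range(len(seq) - pair.length + 1))
        a_hit = any(seq[i:i + pair.length] == pair.alt_probe
                    or seq[i:i + pair.length]
                    == reverse_complement(pair.alt_probe)
                    for i in range(len(seq) - pair.length + 1))
        if r_hit:
            ref += 1
        elif a_hit:
            alt += 1
    return ref, alt


def test_exact_match_definition(random_genome):
    g = random_genome
    site = VariantSite(30, g.base_at(30), "A" if g.base_at(30) != "A" else "C")
    pair = design_probe_pair(g, site, 28, span=g.full_region, side="right")
    containing = g.sequence[15:45]
    mismatched = list(containing)
    idx = containing.find(pair.ref_probe) + 3
    mismatched[idx] = "A" if mismatched[idx] != "A" else "C"
    counts = oreo_filter([containing, "".join(mismatched)], pair)
    assert (counts.ref_count, counts.alt_count) == (1, 0)
    assert counts.informative == 1


def test_reverse_complement_strand_counted(random_genome):
    g = random_genome
    site = VariantSite(30, g.base_at(30), "A" if g.base_at(30) != "A" else "C")
    pair = design_probe_pair(g, site, 28, span=g.full_region, side="right")
    read = reverse_complement("GG" + pair.alt_probe + "TT")
    counts = oreo_filter([read], pair)
    assert counts.alt_count == 1


def test_probe_longer_than_reads_warns(random_genome):
    g = random_genome
    site = VariantSite(30, g.base_at(30), "A" if g.base_at(30) != "A" else "C")
    pair = design_probe_pair(g, site, 28, span=g.full_region, side="right")
    with pytest.warns(UserWarning, match="longer than every read"):
        counts = oreo_filter(["ACGT"], pair)
    assert counts.informative == 0


def test_n_bases_never_match(random_genome):
    g = random_genome
    site = VariantSite(30, g.base_at(30), "A" if g.base_at(30) != "A" else "C")
    pair = design_probe_pair(g, site, 28, span=g.full_region, side="right")
    read = pair.ref_probe[:4] + "N" + pair.ref_probe[5:]
    assert oreo_filter([read], pair).informative == 0


@given(st.integers(0, 100))
@settings(max_examples=20, deadline=None, derandomize=True)
def test_filter_matches_brute_force_scan(seed):
    """oreo_filter equals a brute-force substring scan over random read sets."""
    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=80))
    g = ReferenceGenome("r", seq, circular=False)
    pos = int(rng.integers(30, 50))
    ref = g.base_at(pos)
    alt = str(rng.choice([b for b in "ACGT" if b != ref]))
    try:
        pair = design_probe_pair(g, VariantSite(pos, ref, alt), pos - 2,
                                 span=g.full_region, side="right")
    except DesignError:
        return
    reads = []
    for _ in range(200):
        a = int(rng.integers(0, 50))
        ln = int(rng.integers(15, 31))
        sub = list(seq[a:a + ln])
        if rng.random() < 0.4 and sub:
            sub[int(rng.integers(0, len(sub)))] = str(rng.choice(list("ACGT")))
        s = "".join(sub)
        reads.append(reverse_complement(s) if rng.random() < 0.3 else s)
    counts = oreo_filter(reads, pair)
    assert (counts.ref_count, counts.alt_count) == \
        _brute_force_counts(reads, pair)


@pytest.mark.parametrize("alt,total,expected_pct", [
    (2966, 7824, 38),   # primer-shadowed site, raw reads
    (2909, 2998, 97),   # same site after OREO enrichment
    (0, 100, 0),
])
def test_allele_fraction_display_rounding(alt, total, expected_pct):
    counts = AlleleCounts(ref_count=total - alt, alt_count=alt)
    assert round(allele_fraction(counts)) == expected_pct


def test_allele_fraction_undefined():
    with pytest.raises(UndefinedFractionError):
        allele_fraction(AlleleCounts(0, 0))
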