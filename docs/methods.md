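# Methods

## The problem

Single-multiplex amplicon assays for the human mtDNA control region amplify
the 1122-bp target (rCRS 16,024-576, inside the amplified span 15,989-619 on
the 16,569-bp circle) as ten overlapping amplicons of 144-237 bp in one
reaction. Because PCR primers are designed from the reference sequence and
physically become part of the amplicon, any read that starts or ends in a
primer reports the *reference* base across the primer footprint regardless
of the template. At a site under a primer-binding region a genuine
alternative allele is therefore diluted toward the reference — reference
sequence bias — which miscalls homoplasmic variants as heteroplasmies and
distorts heteroplasmy fractions. Two aggravating artifacts accompany the
single-reaction design: preferentially amplified short by-products with the
length of the amplicon overlaps (52-91 bp), which are almost entirely
primer-derived; and, in the prototype chemistry, overlap extension, in which
overlapping single-stranded products prime on each other and internalise
primer-derived sequence *inside* read bodies, where end-trimming cannot
reach it. Commercial primer sequences are proprietary, so trimming cannot be
targeted.

## OREO

The Overarching Read Enrichment Option replaces trimming with selection.
For a queried site near an amplicon end, a pair of equal-length
allele-specific probes (10-30 nt) is designed to cover the site and extend
at least one base past the amplicon end. A read is counted for an allele
only when it contains that probe as an exact, full-length substring on
either strand. Any read whose end is primer-derived terminates at the
amplicon end and cannot contain the boundary-crossing probe, so only
overarching reads from the neighbouring amplicon — which read genuine
template across the primer site — survive. Because the two probes share
length and differ only at the queried base, a random sequencing error
anywhere else in the probe window removes reference- and
alternative-carrying reads at the same expected rate, making the surviving
allele fraction an unbiased estimator of the template fraction. The cost is
coverage: at the queried position the usable depth drops to roughly the
yield of the single contributing amplicon.

Design choices:

* **Specificity** is defined as exactly one occurrence of the probe
  (carrying its own allele) on either strand within the amplified span, not
  genome-wide: only control-region amplicons are sequenced, so uniqueness
  beyond the span adds length (and error-loss) for no benefit.
* **Minimality**: the shortest feasible length is chosen; ties are broken by
  the most symmetric placement around the site, then the leftmost start.
  This keeps the per-read exclusion probability (≈ probe length × error
  rate) as small as possible.
* **Boundary crossing** is one base past the amplicon end by default
  (`margin` parameter); one base past the 3' primer terminus already
  excludes every primer-derived read end.
* Probes are reference-backbone except at the queried site; a
  sample-consensus backbone can be supplied when known flanking variants
  would otherwise break exact matching.
* Indel alternatives keep the pair equal-length by letting the edit shift
  the flank that the fixed window retains.
* Quality scores are ignored (matching is sequence-exact); `N` never
  matches; paired-end mates count as independent reads and duplicates are
  not removed, as amplicon data make duplicate removal meaningless.

## Site classification

Counts are classified under tiered thresholds, all configurable:

| parameter | default | meaning |
|---|---|---|
| `analytical_depth` | 20 reads | below this, no call is attempted |
| `minor_depth` | 20 reads | the minor component of a heteroplasmy must also reach this |
| `detection_fraction` | 5% | reporting floor for an alternative allele |
| `calling_fraction` | 10% (prototype), 5% (nested) | lower bound of the heteroplasmy window |
| `het_window` | 10-90% (prototype), 5-95% (nested) | alternative-allele window called heteroplasmic |
| `primer_mask_width` | 27 bases | primer-region mask width from each amplicon end |

Fractions above the window are homoplasmic-alternative ("SNP"), below it
homoplasmic-reference; window bounds are inclusive (recorded in output
metadata). An apparent heteroplasmy whose minor component misses
`minor_depth` is demoted to uncallable rather than homoplasmic, so the
absence of the minor allele is never silently asserted. Decisions use exact
rational arithmetic; percentages are rounded only for display.

**Primer-region masking** applies in prototype mode only: overlap extension
leaves residual internal primer bias that OREO cannot remove, so an
apparent heteroplasmy within 27 bases of any amplicon end (the observed
extent of biased SNPs) is reported `uncallable_primer_region`. The nested
chemistry blocks overlap extension with flanking adapters, so nested-mode
calls are made everywhere, including under primer sites.

**Routing**: overlap-segment sites are counted by OREO; non-overlap sites
are unaffected by the bias and use the naive pileup. A site for which no
probe of ≤30 nt can reach an amplicon end (deep inside a wide overlap)
propagates as a no-call with the design failure as its reason. Homopolymer
tracts and the AC repeat are annotatable as unevaluated regions and excluded
from substitution calling; their length heteroplasmy is out of scope.

## Coverage model

The amplicon chain partitions the span into 2n-1 alternating
exclusive/overlap segments. Per-segment mean depth is the arithmetic mean
over positions, normalised to the per-sample mean over the whole span
(normalisation after segment averaging; the choice is echoed in report
metadata). Amplicon ends are detectable as the sharpest single-step relative
changes |d(p+1)-d(p)|/max(d(p),1) — a scale-free score chosen because
multiplexing depth varies by orders of magnitude across samples — with
greedy non-overlapping-window suppression. A non-overlap segment whose mean
depth falls below the mean of the other segments divided by a fold
threshold (default 5, conservative against the ~13-fold suppression
observed in practice) is flagged as a possible primer-site variant or numt
window.

## Size selection

Reads shorter than 95 bases are removed before calling nested-kit data; the
cutoff is inclusive-≥95 to match the published number, and any value in
92-95 would equally separate the 52-91 bp by-products from the ≥144 bp
designed amplicons. Mates are filtered independently.

## numt screening

Given a user-supplied diagnostic table (position, mt allele, numt allele),
equal-length anchor pairs are built around each site, carrying the
respective allele at *every* diagnostic position inside the window, since
numt variants are linked on a read. Anchors grow from 17 nt until unique in
the span. The pooled fraction is total numt-supporting reads over total
informative reads; presence is flagged at ≥0.1% pooled with ≥3 individually
supported sites. Absence is never asserted: detection of such insertions is
known to be strongly coverage- and sample-dependent. The bundled diagnostic
table is synthetic (the real alleles of the chr11 insertion are not bundled)
and exists only as a format example.

## The simulator

The generator emits the study conditions, not a tunable benchmark:

* full-length single-end amplicon reads (the 600-cycle paired-end chemistry
  fully spans 144-237 bp amplicons after merging, so merged reads are
  simulated and no merging stage is modelled);
* primer footprints of 20-26 bases per end (per-amplicon override), which
  force the reference base regardless of the drawn template allele;
* short overlap-length products (default rate 0.3, a free parameter chosen
  to make the overlap-segment coverage excess visible, as no true
  proportion is published) consisting wholly of reference sequence;
* overlap extension in prototype mode only (default rate 0.2 of
  designed-amplicon molecules; no rate is published, but the residual bias
  it explains was substantial, and 0.2 reproduces that qualitative picture),
  forcing reference bases at internalised neighbour-primer blocks;
* optional numt reads for window-spanning amplicons at a configured
  fraction of each amplicon's yield, carrying numt alleles at unforced
  diagnostic positions;
* a flat per-base substitution error (default 0.002) applied last; no
  indel errors, no PCR kinetics, no instrument error profile;
* constant quality strings — quality plays no role in the method.

Identical seeds give byte-identical FASTQ; all randomness flows from one
integer-seeded generator. Per-read truth records provenance, template
alleles and primer-forcing, enabling exact naive pileups
(`TruthPileup`, equivalent to a perfect aligner) and truth-vs-call
comparison.

What the simulator does *not* emulate — real base composition (the bundled
reference is a synthetic stand-in of correct length), haplogroup-correlated
variant patterns, amplification-efficiency kinetics, chimeras beyond
overlap extension, quality-value structure — means passing tests establish
the correctness of the *mechanisms* (bias injection and removal, routing,
thresholds, size selection, numt pooling), not performance on any
particular real library.

## Problem sizes and numerical choices

Simulation-based tests use 20,000-50,000 reads, which gives ≥1000x
informative OREO depth at queried junctions (three binomial standard
deviations ≤2 percentage points at 50% heteroplasmy) while keeping the full
suite in well under a minute. Stochastic assertions use seeded generators
and 3-4 binomial-SD tolerances computed from the realised counts, with the
sampling unit taken as distinct reads (per-site counts pooled across a
shared read set are correlated). Degenerate inputs are total: empty read
sets, zero informative reads, flat coverage tracks and infeasible probe
designs all map to defined statuses, warnings or typed errors rather than
exceptions mid-pipeline.

## Known limitations

* Exact amplicon coordinates of commercial kits are proprietary; the
  bundled panel is an approximate reconstruction and user tables should be
  supplied for real data.
* OREO cannot query a site farther than ~29 bases from both ends of its
  overlap (no ≤30-nt probe reaches a boundary); such sites fall to the
  naive path's no-call and are unaffected by primer bias in any case.
* Length heteroplasmy in homopolymers and the AC repeat is flagged as
  unevaluated, not quantified.
* The numt screen estimates a fraction for *given* diagnostics; it does not
  discover numts.
* Only single-contig circular references are supported.
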