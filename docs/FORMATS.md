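# File formats

All tabular files are tab-separated with a header row; coordinates are
1-based inclusive rCRS-style positions that may wrap through the circular
origin (`start > end`).

## Reference FASTA
Standard FASTA; only the first record is read. The header is free-form: the
genome is matched by length (16,569 for the rCRS) unless
`--force-reference-length` / `force=True` is given. The bundled
`oreomt/data/rcrs_synthetic.fasta` is a synthetic stand-in of the correct
length, not NC_012920.1.

## Amplicon table (`--amplicons`)
Columns, in order: `id`, `start`, `end`.
Amplicons must form a chain: consecutive amplicons overlap, non-consecutive
ones do not. The bundled `oreomt/data/amplicons_default.tsv` is an
approximate reconstruction of the 10-amplicon design (lengths 144-237 bp,
overlaps 52-85 bp, span 15,989-619).

## Variant-site table (`--sites`)
Columns: `position`, `ref`, `alt`.
`alt` is a base for a substitution, `+X` for an insertion of X after the
position (forensic `44.1C` = position 44, `+C`), `-` for a single-base
deletion.

## Probe table (`oreo design` output / `oreo count` input)
Columns: `position`, `ref`, `alt`, `boundary`, `ref_probe`, `alt_probe`,
`span_start`, `span_end`.

## numt diagnostic table (`--diagnostics`)
Columns: `position`, `mt_allele`, `numt_allele`.
The bundled `oreomt/data/numt_diagnostics_synthetic.tsv` uses synthetic
alleles as a documented placeholder; real diagnostic alleles are
user-supplied.

## Calls TSV (`oreo call --out-tsv`)
Columns: `position`, `ref`, `alt`, `status`, `alt_fraction_pct` (4 decimal
places), `alt_fraction_display` (integer percent), `ref_count`, `alt_count`,
`other_count`, `in_primer_region`, `used_oreo`, `mode`, `reason`.
`status` is one of `homoplasmic_ref`, `homoplasmic_alt`, `heteroplasmic`,
`uncallable_low_coverage`, `uncallable_primer_region`, `no_call`.

## Minimal VCF (`oreo call --out-vcf`)
VCFv4.2, contig `chrM` (override with `--contig`), 1-based POS; INFO carries
`AF_PCT`, `RC`, `AC_READS`, `STATUS`, `MODE`.

## Segment coverage report (`oreo coverage --out`)
Columns: `segment`, `start`, `end`, `overlap`, `mean_depth`,
`normalized_depth`, `flagged_low_coverage`. Normalization is to the
per-sample mean over the whole amplified span, applied after segment
averaging.

## Size-selection summary (`oreo sizeselect --summary`)
Columns: `retained`, `removed`, `retained_fraction`, `min_length`.

## numt report (`oreo numt --out`)
Columns: `position`, `numt_reads`, `informative_reads`, `numt_fraction_pct`.

## Thresholds file (`oreo call --thresholds`)
`key = value` lines over the mode defaults; `#` comments allowed. Keys:
`analytical_depth`, `minor_depth`, `detection_fraction`, `calling_fraction`,
`het_window_low`, `het_window_high`, `primer_mask_width`.

## Simulation config (`oreo simulate --config`)
A single JSON object with keys: `reference` (FASTA path), `expected_length`,
`force_reference_length`, `amplicons` (TSV path, optional), `mode`
(`prototype`|`nested`), `n_reads`, `yields` (per-amplicon relative),
`primer_lengths` (per-amplicon `[fwd, rev]`), `short_product_rate`,
`overlap_extension_rate`, `variants` (list of `{position, ref, alt,
fraction}`), `numt` (`{fraction, diagnostics: [{position, mt_allele,
numt_allele}]}`), `error_rate`, `seed`.

## Truth table (`oreo simulate --out-truth`)
Columns: `read_id`, `source` (`amplicon`|`short`|`numt`), `origin`
(amplicon id or junction index), `start`, `length`, `overlap_extension`,
`site_info` (semicolon list of `position:template_allele:F|T`, the flag
marking primer-forced emission).

## Run report (`oreo call --report`)
JSON: tool/version, sha256 input digests, effective thresholds, per-stage
counts, and every masked or demoted site with its reason.
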