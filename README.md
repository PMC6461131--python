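# oreomt

Reference-bias-aware variant and heteroplasmy calling for single-multiplex
overlapping-amplicon sequencing of the human mtDNA control region.

## The problem

Forensic and population workflows sequence the 1122-bp control region
(rCRS 16,024-576 on the 16,569-bp circular mitochondrial genome) as ten
overlapping PCR amplicons of 144-237 bp in a single multiplex. PCR primers
are copied into the amplicons, and because primers match the reference
sequence, every read that begins or ends in a primer reports reference
bases across the primer footprint regardless of the template. At a site
under a primer-binding region a genuine variant is diluted toward the
reference — *reference sequence bias* — producing spurious heteroplasmies
and distorted allele fractions. Commercial primer sequences are
proprietary, so targeted trimming is impossible.

## The method

**OREO (Overarching Read Enrichment Option)** bypasses unknown primers by
selection instead of trimming. For a queried site (position *p*, reference
allele R, alternative A) near an amplicon end, a pair of equal-length
probes (10-30 nt) is designed to cover *p* and extend past the amplicon
end; a read is counted for an allele only if it contains the corresponding
probe as an exact full-length substring on either strand. Primer-derived
read ends stop at the amplicon end and can never contain a
boundary-crossing probe, so only *overarching* reads from the neighbouring
amplicon are counted, and the alternative-allele fraction

    f_alt = 100 x n_A / (n_R + n_A)

is an unbiased heteroplasmy estimate: equal probe lengths make random
sequencing-error losses symmetric between alleles.

Sites are classified under tiered thresholds (20x analytical depth, also
required of the minor component; heteroplasmy window 10-90% with the
prototype chemistry or 5-95% with the nested chemistry; inclusive bounds),
with primer-region masking of apparent heteroplasmies in prototype mode,
where overlap extension internalises primer sequence beyond OREO's reach.
Around the caller sit the supporting stages: segment-wise coverage
statistics with amplicon-boundary detection and low-coverage flagging,
in-silico size selection at 95 bp removing the 52-91 bp overlap-length
by-products, a numt (nuclear mitochondrial insertion) screen pooling
diagnostic-site fractions, and a generative read simulator that reproduces
every bias mechanism with per-read ground truth. See `docs/methods.md`.

## Worked example

`examples/bias_removal.py` simulates a prototype-chemistry run with a 30%
heteroplasmy inside amplicon 1's 3' primer footprint and counts the
alternative allele both ways:

```
site 16160T, true heteroplasmy 30%
probe pair of 10 nt crossing amplicon end 16168
naive pileup:  alt 470/4695 reads = 10.0%
OREO enriched: alt 463/1475 reads = 31.4%
```

The naive pileup sees 10%: two thirds of the covering reads carry
primer-derived or short-product reference bases at the site. OREO keeps
only the 1475 overarching reads that span the amplicon end — these cannot
contain primer sequence at the queried position — and recovers the
configured 30% within binomial sampling error. Note the coverage cost: the
OREO depth is roughly the yield of the single neighbouring amplicon.

The other examples show nested-mode processing (`oreo sizeselect` at 95 bp,
then numt-fraction pooling; `examples/size_selection_and_numt.py`) and the
segment coverage model with boundary detection
(`examples/coverage_segments.py`). The same operations are available from
the shell:

```sh
oreo simulate --config sim.json --seed 1 --out-fastq reads.fastq --out-truth truth.tsv
oreo sizeselect reads.fastq kept.fastq --min-len 95 --summary sizes.tsv
oreo design --reference ref.fasta --sites sites.tsv --out probes.tsv
oreo count  --probes probes.tsv --reads kept.fastq --out counts.tsv
oreo call   --reference ref.fasta --sites sites.tsv --reads kept.fastq \
            --alignment aln.sam --mode nested --out-vcf calls.vcf --out-tsv calls.tsv
oreo numt   --reference ref.fasta --diagnostics numt.tsv --reads kept.fastq --out numt.tsv
oreo coverage --reference ref.fasta --alignment aln.sam --out segments.tsv
```

File formats are documented in `docs/FORMATS.md`. The bundled reference
(`oreomt/data/rcrs_synthetic.fasta`) is a synthetic stand-in with the rCRS
length, and the bundled amplicon table is an approximate reconstruction of
the 10-amplicon design; supply real tables for real data.

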