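# External benchmark: the original cohort's pileups

The published observation this package operationalises was made on
whole-exome sequencing data deposited in the NCBI Sequence Read Archive
under accession **SRP107053**. Five tumor runs showed the candidate
variants with alt/total depths 3/37, 9/71, 10/69, 7/69 and 7/44:

| run         | sample type |
|-------------|-------------|
| SRR5602384  | tumor (FFPE) |
| SRR5602389  | tumor (FFPE) |
| SRR5602393  | tumor (FFPE) |
| SRR5602414  | tumor (FFPE) |
| SRR5602419  | tumor (FFPE) |
| SRR5602363  | normal (whole blood) |
| SRR5602367  | normal (whole blood) |

Reproducing those depths requires downloading the runs and realigning them
with a genome-scale aligner against hg19 — neither of which belongs in this
package's tested core (the synthetic generator stands in for the loci and
read sets). For reference, the workflow is:

```bash
# ~tens of GB download; needs sra-tools, bwa and samtools
prefetch SRP107053            # or fasterq-dump per SRR accession
fasterq-dump SRR5602384
bwa mem -t 8 hg19.fa SRR5602384.fastq | samtools sort -o SRR5602384.bam
samtools index SRR5602384.bam
# pileup over the gene locus caught in the homology trap
samtools mpileup -r chr9:80537082-80537222 -f hg19.fa SRR5602384.bam
```

The per-read screening itself (two-criterion check, cross-locus SNP
pattern) can then be applied to the real alignments by loading the hg19
segments `chr9:80537082-80537222` and `chr2:132182125-132182265` as the two
loci and the dbSNP records rs3730150, rs3730148, rs3730153 (and
rs753716491) as the catalogue, using exactly the library entry points the
synthetic pipeline uses (`derive_envelope`, `align_read`, `screen_cohort`).

None of this is exercised by the test suite; it is an optional, documented
benchmark for users with the data in hand.
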