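# Upstream read processing (external tools, not run by this package)

`dhmut` starts at per-sample genotype calls in VCF. Producing those calls
from raw sequencing reads uses standard external tools; the template below
documents the expected preamble so that real-data runs are reproducible. The
package never invokes these tools and its tests do not depend on them.

```bash
# per sample; $REF is the reference FASTA, $R1/$R2 the paired FASTQ files
fastp -i $R1 -I $R2 -o clean_1.fq.gz -O clean_2.fq.gz

bwa index $REF   # once
bwa mem -t 8 -R "@RG\tID:$SAMPLE\tSM:$SAMPLE" $REF clean_1.fq.gz clean_2.fq.gz \
  | samtools sort -o $SAMPLE.sorted.bam -
gatk MarkDuplicates -I $SAMPLE.sorted.bam -O $SAMPLE.dedup.bam -M dup_metrics.txt \
  --REMOVE_DUPLICATES true
samtools index $SAMPLE.dedup.bam

# call variants from reads with mapping quality >= 20 only
bcftools mpileup -q 20 -f $REF $SAMPLE.dedup.bam \
  | bcftools call -m -v -Ov -o $SAMPLE.vcf
```

The per-sample callable genome size — the denominator of the per-Mb
mutation frequency — is the cumulative length of regions covered by
MQ ≥ 20 reads at usable depth, e.g.:

```bash
samtools depth -Q 20 -a $SAMPLE.dedup.bam \
  | awk '$3 >= 2 && $3 <= 30 {n++} END {print n}'
```

Record one `sample<TAB>size` line per sample in a TSV and pass it to
`dhmut call --callable-sizes`.

Gene-coding intervals are supplied as BED3 (0-based, half-open). From a GFF3
annotation the one-line conversion is:

```bash
awk '$3 == "gene" {print $1 "\t" $4-1 "\t" $5}' annotation.gff3 > genes.bed
```
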