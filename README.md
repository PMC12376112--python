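# diphap

Haplotig purging and inter-haplotype divergence for highly heterozygous
diploid genome assemblies — with a truth-labeled diploid genome
simulator, so every stage can be validated offline against a known
answer.

## The problem

When a highly heterozygous diploid genome (heterozygosity of several
percent, as in outbreeding forage grasses) is assembled into a haploid
representation, the two alleles of many loci assemble as *separate*
contigs. The shorter, redundant copy of such an allelic pair is a
**haplotig**; left in place it inflates assembly size and duplicates
single-copy genes. Purely sequence-alignment-based purgers struggle
exactly when heterozygosity is high, because allelic contigs diverge too
much to align well. `diphap` implements a three-evidence purge: a contig
is a haplotig of a longer contig if it fulfils **any one** of

1. **coverage** — more than 70% of the shorter contig aligns to the
   longer one (union over all alignment segments, measured on the
   shorter contig);
2. **micro-synteny** — the pair shares a collinear block of at least
   5 genes (longest chain of matched gene anchors, monotone in both
   gene orders, same or inverted orientation);
3. **markers** — the pair shares at least 1 single-copy complete
   ortholog marker (BUSCO-style; "single-copy" is judged per contig, so
   a genome-wide duplicated marker present once on each contig links
   them).

Classification is greedy by descending length, and the purged/primary
split is a pure partition of the input (no base lost or duplicated).

The second component measures how different the two haplotypes actually
are. Variants are extracted from base-level whole-genome alignments
(`=/X/I/D` CIGARs): each mismatch base is a SNP, indels shorter than
50 bp are small INDELs, and 50 bp or longer are presence/absence
variations (PAVs). A variant only counts if an independent read-based
callset corroborates it: SNPs/INDELs must share the exact start
position, PAVs must overlap or have breakpoints within 10 bp, and PAVs
containing assembly-gap bases are discarded. Sequence identity is then
reported per 100-kb window of the reference haplotype:

    identity = (W − common-variant bp − gap bp − unaligned bp) / W

where the masked bases are counted as a union (never a sum) and W is the
effective window width.

The simulator generates the whole test surface from one seed: a random
haplotype 1, a haplotype 2 derived by planted non-overlapping variants
at realistic rates (3.43 SNPs per 100 bp by default), an assembly-like
contig set with known haplotigs, gene anchors, marker tables, exact PAF
alignments and two noisy VCF callsets — everything with truth labels.

## Worked example

```sh
diphap simulate --seed 1 --out scene --genome-bp 400000 --n-chroms 1 \
    --n-primary-contigs 3 --n-haplotigs 2
diphap purge --contigs scene/contigs.fa --paf scene/contigs.paf \
    --anchors scene/anchors.tsv --matches scene/matches.tsv \
    --markers scene/markers.tsv --out purge_out
diphap divergence --ref scene/h1.fa --query scene/h2.fa \
    --paf scene/haplotypes.paf --read-vcf scene/callset_read.vcf \
    --out div_out
```

prints

```
wrote 14 files to scene
2/5 contigs purged as haplotigs; report in purge_out/purge_report.tsv
4 windows; mean identity 0.9038, min 0.8922; outputs in div_out
```

The purge report lists each contig with its label, partner and the
evidence that triggered the call:

```
contig_id  length  label     partner_id  coverage  collinear_genes  shared_markers  criteria
h000       76001   haplotig  p000        1.0       17               3               coverage,synteny,marker
h001       87039   haplotig  p002        1.0       19               3               coverage,synteny,marker
```

Both simulated haplotigs are purged into their true partners, and all
three criteria fire. The divergence output (`identity.tsv`) shows, per
100-kb window, the masked base counts and the resulting identity — here
a mean of 0.90 at the default 3.43% SNP rate: once INDELs and PAVs are
masked too, windows diverge far more than the SNP rate alone suggests.

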