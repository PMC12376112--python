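# Methods

## Coordinate conventions

All internal coordinates are 0-based half-open `[start, end)` on the
forward strand. VCF (1-based, anchor-base alleles) and PAF are converted
at the I/O boundary; reverse-strand PAF records keep query coordinates
on the query's forward strand, matching the format's own convention.
Every base-counting quantity (coverage, window masking) is computed on
interval *unions*, so overlapping evidence is never double-counted.

## Haplotig purge

### Model

Allelic redundancy is modeled as a pairwise relation: a shorter contig
is the alternate allele of a longer one. Three independent evidence
channels detect the relation, combined by OR — a deliberate choice,
since at high heterozygosity the alignment channel alone fails exactly
where purging matters most, while gene order and single-copy markers
remain informative:

| channel  | statistic                                         | threshold |
|----------|---------------------------------------------------|-----------|
| coverage | union bp of the shorter contig aligned to the longer / shorter length | > 0.70 (strict) |
| synteny  | largest collinear block of matched gene anchors   | ≥ 5 genes |
| markers  | markers complete with exactly 1 copy on each contig | ≥ 1     |

Threshold semantics follow the criteria's wording: coverage is strict
("greater than 70%"), the counts are inclusive ("at least").

Coverage is measured on the **shorter** contig of each pair — the
fraction of the putative haplotig that aligns — pooling both alignment
orientations. The criteria's source description does not pin the
denominator; the shorter-contig convention matches the semantics of the
all-by-all purge tools this procedure generalises.

Collinear blocks are chains of matched gene anchors strictly monotone
in both contigs' gene-rank orders; decreasing rank on one contig
(inverted blocks) counts too, since allelic contigs may assemble in
opposite orientation. Chaining is an O(n²) dynamic program (n = matched
anchors per contig pair, typically tens) with a configurable cap on the
rank gap between consecutive chain members (`max_anchor_gap`, default
10) so that two isolated matches at opposite ends of a gene-dense
contig do not chain across unrelated genes.

"Single-copy complete" is judged **per contig**: a marker that BUSCO
would call Duplicated genome-wide but that sits exactly once on each of
two contigs links them — allelic duplication is precisely the signal.

### Classification

Contigs are processed in decreasing length (ties break toward the
lexicographically smaller id acting as the longer contig, logged). Each
contig is labeled haplotig of its best qualifying longer partner —
most criteria triggered, then highest coverage, then most collinear
genes, then lexicographically smallest partner id. A contig already
purged stays eligible as a *recorded* partner for still shorter contigs
(in a chain C < B < A, both B and C are purged; C's reported partner is
B), which keeps the output a pure partition: primary bp + haplotig bp
always equals input bp. Raising `min_coverage` with the other
thresholds fixed can only shrink the purged set, since coverage enters
a single monotone comparison.

By default no mapping-quality filter is applied to alignments
(`min_mapq = 0`, configurable); the evidence PAF is assumed to come
from a deliberate all-by-all contig comparison.

## Divergence between haplotypes

### Variant extraction

Variants are read directly from base-level alignment CIGARs: `X` runs
decompose into per-base SNPs (a k-long mismatch run is k SNPs, so SNP
counts equal masked mismatch bases); `I`/`D` runs shorter than 50 bp
are INDELs and of at least 50 bp are PAVs, the conventional size split
between small indels and structural presence/absence variation.
Ambiguous `M` ops are rejected with instructions to regenerate
extended-CIGAR alignments. An insertion occupies a 1-bp anchor on the
reference (the base at the insertion point): every variant then covers
a nonempty reference interval, and window masking can never exceed the
window width. The unaligned mask is the complement of target-aligned
intervals per reference sequence.

### Concordance

Only variants corroborated by a second, independent callset are
counted. SNPs and INDELs match on identical reference sequence and
exact start position (allele agreement is not required by default; a
strict mode compares alleles where both sides carry them). PAVs match
if their reference spans overlap or if the start of either lies within
10 bp downstream of the end of the other — applied in both directions,
since either caller's breakpoint may come first. Matched variants are
reported with the WGA callset's coordinates (the WGA is the coordinate
authority; the read callset corroborates). PAVs whose span contains at
least one assembly-gap (N) base are discarded: a breakpoint spanning a
scaffolding gap is not trustworthy.

### Window identity

Windows of 100 kb tile each reference sequence (the last window may be
short; identity uses the effective width). Masked bases are the union
of common-variant reference spans, N-gap runs and unaligned intervals,
clipped to the window; identity is `(W_eff − masked) / W_eff`, clamped
to [0, 1]. Gaps subtracted here are reference-haplotype gaps; query-side
gaps enter only through the gap-PAV filter. Masked-bp bookkeeping is
exact integer arithmetic; the only floating-point step is the final
division.

## The simulator

### What it emulates

A single highly heterozygous diploid: haplotype 2 differs from a random
haplotype 1 by planted, mutually non-overlapping events —
substitutions at 0.0343 per bp (the 3.43% heterozygosity regime, three
to four SNPs per 100 bp), INDEL events at 0.00283 per bp and PAV events
at 0.00082 per bp. The two event rates are set so the planted class
counts reproduce the roughly 12:1 SNP:INDEL and 42:1 SNP:PAV ratios
observed in such genomes; both are freely configurable. INDEL lengths
are geometric (p = 0.35, clipped below 50 bp — most real indels are
1–3 bp); PAV lengths are uniform on [50, 300] bp. Events keep a 1-bp
spacer between each other so that no two same-type events abut (abutting
deletions would coalesce into a single alignment gap and change the
variant count), which keeps extraction-vs-truth comparison exact.

The assembly scene tiles haplotype 1 into `n_primary_contigs` primary
contigs (jittered equal tiles) and cuts `n_haplotigs` intervals of
haplotype 2, each lying inside one primary's interval and strictly
shorter than it; a configurable fraction is reverse-complemented.
Alignments between each haplotig and its primary (and between whole
haplotype chromosomes) are constructed *exactly* from the planted
variants as `=/X/I/D` CIGARs — no aligner runs, so alignment-derived
truth is exact by construction. Genes are planted collinearly (30 per
primary by default, copied onto the haplotig in the same order, reversed
on inverted haplotigs); 3 markers per allelic pair are planted
single-copy complete on both members. Two callsets are derived from the
truth by independent per-variant Bernoulli dropout (`callset_fnr`,
default 0.1) with PAV breakpoints in the read callset jittered by at
most `pav_jitter_bp` (default 5 bp) — realistic caller behaviour where
two methods miss different variants and disagree slightly on SV
breakpoints.

Default scene scale is 5 Mb over 2 chromosomes with 40 primaries and
25 haplotigs: large enough for ~190,000 planted variants and stable
statistics, small enough that the full suite and the acceptance script
run in minutes on one CPU.

### What it does not emulate

No sequencing reads, base errors, repeats or segmental duplications; no
phase-switch mosaics (primaries are pure haplotype 1, haplotigs pure
haplotype 2); no spurious alignments between non-allelic contigs; gene
anchors are coordinates, not sequences. Consequently, perfect truth
recovery on clean simulated scenes demonstrates the correctness of the
decision procedure and the masking arithmetic — not robustness to
repeat-induced false pairing or chimeric contigs, which the degradation
helpers (anchor dropout, alignment trimming) only approximate.

### Determinism

One seed feeds a `SeedSequence` hierarchy with a named substream per
stage (genome, mutate, fragment, genes, callsets), so identical
parameters give byte-identical output files and changing one stage's
parameters does not perturb another stage's draws.

## Numerical and design notes

- Interval unions use sort-and-merge; abutting intervals coalesce
  (union length is unaffected).
- `window_identity` compares and reports integers until the final
  division; tests compare identities at 1e-12 absolute tolerance to
  absorb the one-ulp difference between `(W−m)/W` and `1−m/W`.
- Equal-length purge candidates are resolved lexicographically and
  logged; the classifier's output is independent of input record order.
- VCF records are written explicitly (anchor-base REF/ALT) when alleles
  are known, and symbolically (`<DEL>`/`<INS>` with SVTYPE/SVLEN/END)
  otherwise — the read-callset writer uses symbolic PAVs, the
  convention of long-read SV callers. An unknown anchor base is written
  as `N`.
- PAF records without a `cg:Z` CIGAR are accepted for coverage evidence
  and skipped (with a log line) by variant extraction.
- The gene-anchor reader accepts TSV or BED; the marker reader accepts
  the native 4-column TSV or a BUSCO full-table layout, mapping
  Complete/Duplicated rows to per-contig complete copy counts.

## Known limitations

- Coverage evidence aggregates all alignment orientations into one
  union; per-orientation coverage is not computed separately.
- The divergence stage assumes one reference axis (h1); query-side gap
  projection beyond the gap-PAV filter is not implemented.
- Inversion interiors are whatever the alignment says: an inversion
  aligned base-by-base contributes X runs, an unaligned one contributes
  to the unaligned mask; no inversion-aware special case exists.
- The simulator plants no overlapping or nested events, so the
  reconstruction invariant is exact; real haplotypes contain nested and
  overlapping variation that WGA callers represent ambiguously.
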