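"""Inter-haplotype divergence from whole-genome alignment.

The pipeline mirrors how divergence between two assembled haplotypes is
measured in practice: variants (SNPs, small INDELs below 50 bp, PAVs of
50 bp and above) are extracted from base-level whole-genome alignments,
corroborated against an independent read-based callset, filtered against
assembly gaps, and summarised as windowed sequence identity on the
reference haplotype:

    identity = (W - common-variant bp - gap bp - unaligned bp) / W

per window of W = 100 kb (union of masked bases, clipped to the window;
the last window of a sequence may be shorter). Concordance rules:
SNPs/INDELs must share the exact start position across the two callsets;
PAVs match if their reference spans overlap or lie within 10 bp of each
other; PAVs containing assembly gap bases are discarded.
"""
from __future__ import annotations

import logging
from bisect import bisect_left
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from . import io as dio
from .intervals import clip, complement, merge, union_length
from .types import (
    AlignmentRecord,
    ConcordanceResult,
    Contig,
    DivergenceConfig,
    MaskTrack,
    Variant,
    WindowIdentity,
)

log = logging.getLogger("diphap")


# ---------------------------------------------------------------------------
# Variant extraction from alignments


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def call_variants_from_alignment(
    alignments: Iterable[AlignmentRecord],
    ref_lengths: Dict[str, int],
    ref_seqs: Optional[Dict[str, Contig]] = None,
    query_seqs: Optional[Dict[str, Contig]] = None,
) -> Tuple[List[Variant], List[MaskTrack]]:
    """Extract variants and the unaligned mask from base-level alignments.

    CIGARs must use {=, X, I, D}; ambiguous M is rejected. Each base of
    an X run becomes one SNP; I/D runs become INDELs (< 50 bp) or PAVs
    (>= 50 bp). Insertions are anchored on the reference base at the
    insertion point. The unaligned track is the complement of
    target-aligned intervals per reference sequence. Alleles are filled
    in when sequences are supplied (forward-strand alignments; reverse-
    strand alleles are left unset).

    Returns ``(variants, unaligned_tracks)`` with variants tagged
    source="wga" and sorted by position.
    """
    if ref_seqs is not None:
        ref_seqs = {c.id: c for c in ref_seqs.values()}
    if query_seqs is not None:
        query_seqs = {c.id: c for c in query_seqs.values()}
    variants: List[Variant] = []
    aligned: Dict[str, List[Tuple[int, int]]] = {r: [] for r in ref_lengths}
    for rec in alignments:
        if rec.coverage_only:
            log.info(
                "skipping CIGAR-less alignment %s->%s in variant extraction",
                rec.query_id, rec.target_id,
            )
            continue
        if any(op == "M" for op, _ in rec.cigar):
            raise dio.IntegrityError(
                f"alignment {rec.query_id}->{rec.target_id} uses ambiguous "
                f"'M' CIGAR ops; regenerate with extended (=/X) CIGARs"
            )
        if rec.target_id not in ref_lengths:
            raise dio.IntegrityError(
                f"alignment targets unknown reference {rec.target_id!r}"
            )
        tlen = ref_lengths[rec.target_id]
        aligned.setdefault(rec.target_id, []).append(
            (rec.target_start, rec.target_end)
        )
        rseq = ref_seqs[rec.target_id].seq if ref_seqs else None
        qseq = None
        if query_seqs is not None and rec.strand == "+":
            qseq = query_seqs[rec.query_id].seq
        t = rec.target_start
        q = rec.query_start
        for op, n in rec.cigar:
            if op == "=":
                t += n
                q += n
            elif op == "X":
                for k in range(n):
                    variants.append(Variant.snp(
                        rec.target_id, t + k, source="wga",
                        ref_allele=rseq[t + k] if rseq else None,
                        alt_allele=qseq[q + k] if qseq else None,
                    ))
                t += n
                q += n
            elif op == "D":
                variants.append(Variant.deletion(
                    rec.target_id, t, n, source="wga",
                    ref_allele=rseq[t:t + n] if rseq else None,
                ))
                t += n
            elif op == "I":
                anchor = min(t, tlen - 1)  # I at sequence end: anchor last base
                variants.append(Variant.insertion(
                    rec.target_id, anchor, n, source="wga",
                    alt_allele=qseq[q:q + n] if qseq else None,
                ))
                q += n
    variants.sort(key=lambda v: v.sort_key)
    unaligned = [
        MaskTrack(rid, "unaligned", complement(ivs, ref_lengths[rid]))
        for rid, ivs in sorted(aligned.items())
    ]
    return variants, unaligned


def find_gaps(contig: Contig, config: Optional[DivergenceConfig] = None,
              ) -> MaskTrack:
    """Maximal runs of N of length >= min_gap_run, as a gap mask track."""
    config = config or DivergenceConfig()
    intervals: List[Tuple[int, int]] = []
    seq = contig.seq
    i = seq.find("N")
    while i != -1:
        j = i
        while j < len(seq) and seq[j] == "N":
            j += 1
        if j - i >= config.min_gap_run:
            intervals.append((i, j))
        i = seq.find("N", j)
    return MaskTrack(contig.id, "gap", intervals)


# ---------------------------------------------------------------------------
# Concordance between the WGA and read callsets


def match_point_variants(
    set_wga: Sequence[Variant],
    set_read: Sequence[Variant],
    vclass: str,
    strict_alleles: bool = False,
) -> List[Variant]:
    """SNPs/INDELs common to both callsets: same class, same reference
    sequence, exact same start position. Returns the WGA copies (the WGA
    callset is the coordinate authority), sorted.

    ``strict_alleles`` additionally requires allele strings to agree
    where both sides carry them.
    """
    if vclass not in ("SNP", "INDEL"):
        raise ValueError(f"match_point_variants is for SNP/INDEL, not {vclass}")

    def key(v: Variant):
        return (v.ref_id, v.ref_start)

    read_keys: Dict[Tuple[str, int], List[Variant]] = {}
    for v in set_read:
        if v.vclass == vclass:
            read_keys.setdefault(key(v), []).append(v)
    out = []
    for v in set_wga:
        if v.vclass != vclass:
            continue
        partners = read_keys.get(key(v))
        if not partners:
            continue
        if strict_alleles and not any(
            _alleles_agree(v, p) for p in partners
        ):
            continue
        out.append(v)
    return sorted(out, key=lambda v: v.sort_key)


def _alleles_agree(a: Variant, b: Variant) -> bool:
    for x, y in ((a.ref_allele, b.ref_allele), (a.alt_allele, b.alt_allele)):
        if x is not None and y is not None and x != y:
            return False
    return True


def match_pavs(
    set_wga: Sequence[Variant],
    set_read: Sequence[Variant],
    config: Optional[DivergenceConfig] = None,
) -> List[Variant]:
    """PAVs common to both callsets, by span overlap or breakpoint slack.

    PAV ``a`` matches ``b`` if their reference spans overlap, or the
    start of one lies within ``pav_match_slack_bp`` (10 bp) downstream of
    the end of the other — in either direction, since breakpoints of the
    same event jitter between callers. Symmetric in the two sets; each
    WGA PAV is reported at most once.
    """
    config = config or DivergenceConfig()
    slack = config.pav_match_slack_bp
    by_ref: Dict[str, List[Tuple[int, int]]] = {}
    for v in set_read:
        if v.vclass == "PAV":
            by_ref.setdefault(v.ref_id, []).append((v.ref_start, v.ref_end))
    for ivs in by_ref.values():
        ivs.sort()
    starts = {rid: [s for s, _ in ivs] for rid, ivs in by_ref.items()}
    out = []
    for v in set_wga:
        if v.vclass != "PAV":
            continue
        ivs = by_ref.get(v.ref_id)
        if not ivs:
            continue
        # candidates: read PAVs with start <= v.ref_end + slack; scan the
        # window around the insertion point rather than the whole list.
        hi = bisect_left(starts[v.ref_id], v.ref_end + slack + 1)
        matched = False
        for s, e in ivs[:hi]:
            if s < v.ref_end and v.ref_start < e:  # overlap
                matched = True
                break
            if 0 <= v.ref_start - e <= slack or 0 <= s - v.ref_end <= slack:
                matched = True
                break
        if matched:
            out.append(v)
    return sorted(out, key=lambda v: v.sort_key)


def filter_gap_pavs(
    pavs: Sequence[Variant],
    gaps: Sequence[MaskTrack],
) -> List[Variant]:
    """Drop PAVs whose reference span contains at least one gap base."""
    gap_ivs = {t.ref_id: t.intervals for t in gaps if t.category == "gap"}
    out = []
    for v in pavs:
        ivs = gap_ivs.get(v.ref_id, ())
        if any(s < v.ref_end and v.ref_start < e for s, e in ivs):
            continue
        out.append(v)
    return out


def concordant_variants(
    set_wga: Sequence[Variant],
    set_read: Sequence[Variant],
    gaps: Sequence[MaskTrack] = (),
    config: Optional[DivergenceConfig] = None,
) -> ConcordanceResult:
    """Apply all concordance rules and the gap-PAV filter; only the
    resulting common variants enter the identity calculation."""
    config = config or DivergenceConfig()
    strict = config.strict_allele_match
    snps = match_point_variants(set_wga, set_read, "SNP", strict)
    indels = match_point_variants(set_wga, set_read, "INDEL", strict)
    pavs = filter_gap_pavs(match_pavs(set_wga, set_read, config), gaps)
    return ConcordanceResult(snps, indels, pavs)


# ---------------------------------------------------------------------------
# Windowed identity


def window_identity(
    ref_lengths: Dict[str, int],
    common_variants: Sequence[Variant],
    gaps: Sequence[MaskTrack] = (),
    unaligned: Sequence[MaskTrack] = (),
    config: Optional[DivergenceConfig] = None,
) -> List[WindowIdentity]:
    """Per-window sequence identity along each reference sequence.

    Windows of ``window_bp`` tile each sequence (last window possibly
    short). Masked bases are the union of common-variant reference
    spans, gap intervals and unaligned intervals clipped to the window;
    an insertion contributes only its 1-bp reference anchor, so masking
    never exceeds the window width.
    """
    config = config or DivergenceConfig()
    W = config.window_bp
    var_ivs: Dict[str, List[Tuple[int, int]]] = {}
    for v in common_variants:
        var_ivs.setdefault(v.ref_id, []).append((v.ref_start, v.ref_end))
    gap_ivs = {t.ref_id: t.intervals for t in gaps}
    una_ivs = {t.ref_id: t.intervals for t in unaligned}
    out: List[WindowIdentity] = []
    for rid in sorted(ref_lengths):
        L = ref_lengths[rid]
        mv = merge(var_ivs.get(rid, ()))
        mg = merge(gap_ivs.get(rid, ()))
        mu = merge(una_ivs.get(rid, ()))
        for start in range(0, L, W):
            end = min(start + W, L)
            w_eff = end - start
            cv = clip(mv, start, end)
            cg = clip(mg, start, end)
            cu = clip(mu, start, end)
            masked = union_length(cv + cg + cu)
            identity = max(0.0, (w_eff - masked)) / w_eff
            out.append(WindowIdentity(
                rid, start, end,
                variant_bp=sum(e - s for s, e in cv),
                gap_bp=sum(e - s for s, e in cg),
                unaligned_bp=sum(e - s for s, e in cu),
                masked_union_bp=masked,
                identity=min(1.0, identity),
            ))
    return out


# ---------------------------------------------------------------------------
# End-to-end


def run_divergence(
    ref_fasta,
    paf_path,
    out_dir,
    query_fasta=None,
    wga_vcf=None,
    read_vcf=None,
    config: Optional[DivergenceConfig] = None,
) -> List[WindowIdentity]:
    """Full divergence pipeline on files.

    The WGA callset is extracted from the PAF CIGARs unless ``wga_vcf``
    is given. If ``read_vcf`` is given, concordance intersects the two
    callsets; otherwise the WGA callset is used as-is (single-callset
    mode). Writes common-variant VCF, gap BED, unaligned BED, identity
    BED4 and the per-category TSV into ``out_dir``.
    """
    config = config or DivergenceConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ref = dio.read_fasta(ref_fasta)
    ref_lengths = {cid: c.length for cid, c in ref.items()}
    query = dio.read_fasta(query_fasta) if query_fasta else None
    alignments = dio.read_paf(paf_path)
    gaps = [find_gaps(c, config) for _, c in sorted(ref.items())]
    if wga_vcf:
        set_wga = dio.read_vcf(wga_vcf, source="wga")
        unaligned = [
            MaskTrack(rid, "unaligned", complement(
                [(r.target_start, r.target_end)
                 for r in alignments if r.target_id == rid],
                ref_lengths[rid]))
            for rid in sorted(ref_lengths)
        ]
    else:
        set_wga, unaligned = call_variants_from_alignment(
            alignments, ref_lengths, ref_seqs=ref, query_seqs=query)
    if read_vcf:
        set_read = dio.read_vcf(read_vcf, source="read")
        result = concordant_variants(set_wga, set_read, gaps, config)
    else:
        pavs = filter_gap_pavs(
            [v for v in set_wga if v.vclass == "PAV"], gaps)
        result = ConcordanceResult(
            [v for v in set_wga if v.vclass == "SNP"],
            [v for v in set_wga if v.vclass == "INDEL"],
            pavs,
        )
    windows = window_identity(
        ref_lengths, result.all_variants, gaps, unaligned, config)
    dio.write_vcf(result.all_variants, ref_lengths,
                  out_dir / "common_variants.vcf")
    dio.write_bed(gaps, out_dir / "gaps.bed")
    dio.write_bed(unaligned, out_dir / "unaligned.bed")
    dio.write_identity_bed(windows, out_dir / "identity.bed")
    dio.write_identity_tsv(windows, out_dir / "identity.tsv")
    log.info(
        "divergence: %d common SNPs, %d INDELs, %d PAVs; %d windows",
        *(result.counts[k] for k in ("SNP", "INDEL", "PAV")), len(windows),
    )
    return windows
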