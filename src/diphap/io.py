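"""Readers and writers for the standard formats the toolkit touches.

Internally everything is 0-based half-open; VCF (1-based, anchor-base
conventions) and PAF are converted here at the boundary. FASTA goes
through Biopython, VCF parsing through pysam; PAF and the small tabular
formats (gene anchors, marker hits, gene matches, purge report) are
simple TSVs handled directly.
"""
from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    AlignmentRecord,
    Contig,
    GeneAnchor,
    MarkerHit,
    MaskTrack,
    Variant,
    WindowIdentity,
    classify_variant,
)

log = logging.getLogger("diphap")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class ParseError(ValueError):
    """A malformed record in an input file (reported with line number)."""


class IntegrityError(ValueError):
    """Inconsistent data: CIGAR/coordinate mismatch, unknown contig, ..."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Dict[str, Contig]:
    """Read contigs; returns an id-ordered dict, ids must be unique."""
    contigs: Dict[str, Contig] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise IntegrityError(f"duplicate contig id {rec.id!r} in {path}")
        contigs[rec.id] = Contig(rec.id, str(rec.seq))
    return contigs


def write_fasta(contigs: Iterable[Contig], path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(c.seq), id=c.id, description="") for c in contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# PAF


def parse_cigar(text: str) -> Tuple[Tuple[str, int], ...]:
    """Parse a cg:Z CIGAR string into ((op, run_length), ...)."""
    ops = []
    pos = 0
    for m in _CIGAR_RE.finditer(text):
        if m.start() != pos:
            raise ParseError(f"unparseable CIGAR near {text[pos:pos + 10]!r}")
        ops.append((m.group(2), int(m.group(1))))
        pos = m.end()
    if pos != len(text):
        raise ParseError(f"unparseable CIGAR near {text[pos:pos + 10]!r}")
    return tuple(ops)


def cigar_to_string(cigar: Sequence[Tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in cigar)


def read_paf(path) -> List[AlignmentRecord]:
    """Read PAF alignments; the cg:Z CIGAR tag is optional.

    Records lacking a CIGAR are flagged coverage-only (usable for purge
    coverage, excluded from variant extraction) and logged.
    """
    records: List[AlignmentRecord] = []
    n_coverage_only = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}:{lineno}: PAF line has {len(fields)} columns, "
                    f"expected >= 12"
                )
            try:
                qlen, qs, qe = (int(fields[i]) for i in (1, 2, 3))
                tlen, ts, te = (int(fields[i]) for i in (6, 7, 8))
                mapq = int(fields[11])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            cigar: Tuple[Tuple[str, int], ...] = ()
            for tag in fields[12:]:
                if tag.startswith("cg:Z:"):
                    cigar = parse_cigar(tag[5:])
            try:
                rec = AlignmentRecord(
                    query_id=fields[0], query_len=qlen,
                    query_start=qs, query_end=qe, strand=fields[4],
                    target_id=fields[5], target_len=tlen,
                    target_start=ts, target_end=te,
                    cigar=cigar, mapq=mapq,
                )
            except ValueError as exc:
                raise IntegrityError(f"{path}:{lineno}: {exc}") from exc
            if rec.coverage_only:
                n_coverage_only += 1
            records.append(rec)
    if n_coverage_only:
        log.info(
            "%s: %d/%d records lack cg:Z CIGAR; usable for coverage only",
            path, n_coverage_only, len(records),
        )
    return records


def write_paf(records: Iterable[AlignmentRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            n_match = sum(n for op, n in r.cigar if op == "=")
            block = sum(n for op, n in r.cigar) if r.cigar else max(
                r.query_end - r.query_start, r.target_end - r.target_start
            )
            fields = [
                r.query_id, r.query_len, r.query_start, r.query_end,
                r.strand, r.target_id, r.target_len, r.target_start,
                r.target_end, n_match, block, r.mapq,
            ]
            if r.cigar:
                fields.append("cg:Z:" + cigar_to_string(r.cigar))
            fh.write("\t".join(str(f) for f in fields) + "\n")


# ---------------------------------------------------------------------------
# VCF

_VCF_HEADER_LINES = [
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV class">',
    '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description='
    '"Signed SV length">',
    '##INFO=<ID=END,Number=1,Type=Integer,Description="SV end (1-based)">',
]


def write_vcf(variants: Sequence[Variant], ref_lengths: Dict[str, int],
              path, symbolic_sv: bool = False) -> None:
    """Write a minimal VCF 4.2 callset.

    SNPs and INDELs/PAVs with known alleles and a known preceding anchor
    base are written with explicit REF/ALT; otherwise the record is
    written in symbolic style (``<DEL>``/``<INS>`` with SVTYPE, SVLEN and
    END). ``symbolic_sv=True`` forces symbolic style for all PAVs, the
    convention of long-read SV callers.
    """
    lines = ["##fileformat=VCFv4.2"]
    for cid, ln in ref_lengths.items():
        lines.append(f"##contig=<ID={cid},length={ln}>")
    lines.extend(_VCF_HEADER_LINES)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for i, v in enumerate(sorted(variants, key=lambda v: v.sort_key)):
        if v.subtype == "substitution":
            pos0 = v.ref_start
            ref = v.ref_allele or "N"
            alt = v.alt_allele or "N"
            info = "."
        else:
            if v.ref_start < 1:
                raise IntegrityError(
                    f"cannot express {v.subtype} at {v.ref_id}:{v.ref_start} "
                    f"in VCF without a preceding anchor base"
                )
            pos0 = v.ref_start - 1
            allele = v.ref_allele if v.subtype == "deletion" else v.alt_allele
            explicit = allele is not None and not (
                symbolic_sv and v.vclass == "PAV"
            )
            if explicit:
                # VCF anchors at the base before; 'N' stands in when the
                # actual anchor base is not known to the caller.
                anchor = "N"
                if v.subtype == "deletion":
                    ref, alt = anchor + allele, anchor
                else:
                    ref, alt = anchor, anchor + allele
                info = "."
            else:
                ref = "N"
                if v.subtype == "deletion":
                    alt, svlen, end = "<DEL>", -v.ref_len, v.ref_end
                else:
                    alt, svlen, end = "<INS>", v.alt_len, pos0 + 1
                info = f"SVTYPE={alt[1:-1]};SVLEN={svlen};END={end}"
        lines.append(
            f"{v.ref_id}\t{pos0 + 1}\tv{i}\t{ref}\t{alt}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path, source: str = "read") -> List[Variant]:
    """Read a VCF callset into internal variants (0-based half-open).

    Handles explicit REF/ALT records (anchor-base convention) and
    symbolic ``<DEL>``/``<INS>`` records with SVTYPE/SVLEN/END.
    """
    variants: List[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ParseError(
                    f"{path}: record at {rec.chrom}:{rec.pos} must have "
                    f"exactly one ALT allele"
                )
            alt = rec.alts[0]
            ref = rec.ref or ""
            if alt == "<DEL>":
                start = rec.start + 1
                svlen = rec.info.get("SVLEN")
                length = abs(int(svlen)) if svlen is not None \
                    else rec.stop - start
                variants.append(Variant.deletion(
                    rec.chrom, start, length, source=source))
            elif alt == "<INS>":
                svlen = rec.info.get("SVLEN")
                if svlen is None:
                    raise ParseError(
                        f"{path}: <INS> at {rec.chrom}:{rec.pos} lacks SVLEN"
                    )
                variants.append(Variant.insertion(
                    rec.chrom, rec.start + 1, int(svlen), source=source))
            elif len(ref) == 1 and len(alt) == 1:
                variants.append(Variant.snp(
                    rec.chrom, rec.start, source=source,
                    ref_allele=ref, alt_allele=alt))
            elif len(alt) == 1 and len(ref) > 1:
                variants.append(Variant.deletion(
                    rec.chrom, rec.start + 1, len(ref) - 1, source=source,
                    ref_allele=ref[1:] if set(ref[1:]) != {"N"} else None))
            elif len(ref) == 1 and len(alt) > 1:
                variants.append(Variant.insertion(
                    rec.chrom, rec.start + 1, len(alt) - 1, source=source,
                    alt_allele=alt[1:] if set(alt[1:]) != {"N"} else None))
            else:
                raise ParseError(
                    f"{path}: unsupported REF/ALT pair at "
                    f"{rec.chrom}:{rec.pos} ({ref}/{alt})"
                )
    return variants


# ---------------------------------------------------------------------------
# Gene anchors, gene matches, marker hits

_BUSCO_STATUSES = {"Complete", "Duplicated", "Fragmented", "Missing"}


def assign_ranks(anchors: Sequence[GeneAnchor]) -> List[GeneAnchor]:
    """Assign per-contig ordinal ranks (1..n by start coordinate)."""
    by_contig: Dict[str, List[GeneAnchor]] = {}
    for a in anchors:
        by_contig.setdefault(a.contig_id, []).append(a)
    out: List[GeneAnchor] = []
    for contig_id in by_contig:
        group = sorted(by_contig[contig_id], key=lambda a: (a.start, a.end))
        for rank, a in enumerate(group, 1):
            a.rank = rank
            out.append(a)
    return out


def read_anchors(path) -> List[GeneAnchor]:
    """Read gene anchors from TSV (gene_id contig_id start end strand)
    or BED4+ (contig start end gene_id [score] [strand]); ranks are
    recomputed from coordinates."""
    anchors: List[GeneAnchor] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0] == "gene_id":  # header
                continue
            try:
                if f[1].lstrip("-").isdigit():  # BED: chrom start end name
                    strand = f[5] if len(f) > 5 else "+"
                    anchors.append(GeneAnchor(
                        f[3], f[0], int(f[1]), int(f[2]), strand))
                else:
                    strand = f[4] if len(f) > 4 else "+"
                    anchors.append(GeneAnchor(
                        f[0], f[1], int(f[2]), int(f[3]), strand))
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return assign_ranks(anchors)


def write_anchors(anchors: Sequence[GeneAnchor], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcontig_id\tstart\tend\tstrand\n")
        for a in sorted(anchors, key=lambda a: (a.contig_id, a.start)):
            fh.write(
                f"{a.gene_id}\t{a.contig_id}\t{a.start}\t{a.end}\t"
                f"{a.strand}\n"
            )


def read_matches(path) -> List[Tuple[str, str]]:
    """Read a two-column gene-id pairing table."""
    pairs: List[Tuple[str, str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0] in ("gene_a", "gene_id_a"):
                continue
            pairs.append((f[0], f[1]))
    return pairs


def write_matches(pairs: Iterable[Tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in pairs:
            fh.write(f"{a}\t{b}\n")


def read_markers(path) -> List[MarkerHit]:
    """Read marker hits from the native TSV (marker_id contig_id status
    copies) or from a BUSCO full-table layout (one row per hit; Complete
    and Duplicated rows count as complete copies on their contig)."""
    rows: List[List[str]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0] == "marker_id":
                continue
            rows.append(f)
    if not rows:
        return []
    if len(rows[0]) > 1 and rows[0][1] in _BUSCO_STATUSES:
        counts: Dict[Tuple[str, str], int] = {}
        frag: Dict[Tuple[str, str], bool] = {}
        for f in rows:
            status = f[1]
            if status == "Missing" or len(f) < 3 or not f[2]:
                continue
            key = (f[0], f[2])
            if status == "Fragmented":
                frag[key] = True
                counts.setdefault(key, 0)
                counts[key] += 1
            else:
                counts[key] = counts.get(key, 0) + 1
        return [
            MarkerHit(m, c, "fragmented" if frag.get((m, c)) else "complete",
                      n)
            for (m, c), n in sorted(counts.items())
        ]
    hits = []
    for f in rows:
        hits.append(MarkerHit(f[0], f[1], f[2], int(f[3])))
    return hits


def write_markers(hits: Sequence[MarkerHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tcontig_id\tstatus\tcopies\n")
        for h in sorted(hits, key=lambda h: (h.marker_id, h.contig_id)):
            fh.write(
                f"{h.marker_id}\t{h.contig_id}\t{h.status}\t"
                f"{h.copies_on_contig}\n"
            )


# ---------------------------------------------------------------------------
# BED / window identity


def write_bed(tracks: Sequence[MaskTrack], path) -> None:
    with open(path, "w") as fh:
        for t in tracks:
            for s, e in t.intervals:
                fh.write(f"{t.ref_id}\t{s}\t{e}\t{t.category}\n")


def read_bed(path) -> Dict[str, List[Tuple[int, int]]]:
    out: Dict[str, List[Tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            if len(f) < 3 or line.startswith(("#", "track")):
                continue
            out.setdefault(f[0], []).append((int(f[1]), int(f[2])))
    return out


def write_identity_bed(windows: Sequence[WindowIdentity], path) -> None:
    """BED4: chrom, start, end, identity."""
    with open(path, "w") as fh:
        for w in windows:
            fh.write(f"{w.ref_id}\t{w.start}\t{w.end}\t{w.identity:.6f}\n")


def write_identity_tsv(windows: Sequence[WindowIdentity], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "ref_id\tstart\tend\tvariant_bp\tgap_bp\tunaligned_bp\t"
            "masked_union_bp\tidentity\n"
        )
        for w in windows:
            fh.write(
                f"{w.ref_id}\t{w.start}\t{w.end}\t{w.variant_bp}\t"
                f"{w.gap_bp}\t{w.unaligned_bp}\t{w.masked_union_bp}\t"
                f"{w.identity:.6f}\n"
            )


# ---------------------------------------------------------------------------
# Config


def load_yaml_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}
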