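"""Three-evidence haplotig purging.

A contig is a haplotig of a longer contig if any one of three criteria
holds: (1) more than 70% of the shorter contig aligns to the longer one,
(2) the pair shares a collinear block of at least five genes
(micro-synteny, same or inverted orientation), or (3) the pair shares at
least one single-copy complete ortholog marker. Sequence-alignment
coverage alone misses allelic contigs in highly heterozygous genomes —
that is what the gene-order and marker channels are for.

Classification is greedy by descending contig length, so a chain
C < B < A resolves to "B haplotig of A, C haplotig of B"; once a contig
is purged it remains eligible as a *recorded* partner for still shorter
contigs, and the purged set is removed as a whole, keeping the output a
pure partition of the input.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from . import io as dio
from .intervals import union_length
from .types import (
    AlignmentRecord,
    CollinearBlock,
    Contig,
    GeneAnchor,
    MarkerHit,
    PairEvidence,
    PurgeConfig,
    PurgeDecision,
)

log = logging.getLogger("diphap")

CRITERIA = ("coverage", "synteny", "marker")


def _length_order_key(contig_id: str, lengths: Dict[str, int]):
    """Sort key for descending length; equal lengths break toward the
    lexicographically smaller id acting as the longer contig."""
    return (-lengths[contig_id], contig_id)


def _is_shorter(a: str, b: str, lengths: Dict[str, int]) -> bool:
    """True if contig ``a`` takes the 'shorter' role against ``b``."""
    return _length_order_key(a, lengths) > _length_order_key(b, lengths)


# ---------------------------------------------------------------------------
# Criterion 1: alignment coverage


def compute_pair_coverage(
    alignments: Iterable[AlignmentRecord],
    lengths: Dict[str, int],
    config: Optional[PurgeConfig] = None,
) -> Dict[Tuple[str, str], float]:
    """Fraction of the shorter contig of each pair covered by alignments
    to the longer, keyed ``(short_id, long_id)``.

    Coverage is a union over all alignment segments of the pair (both
    orientations pooled), measured on the shorter contig — the fraction
    of the putative haplotig that aligns. Self-alignments are ignored.
    """
    config = config or PurgeConfig()
    per_pair: Dict[Tuple[str, str], List[Tuple[int, int]]] = {}
    for rec in alignments:
        if rec.query_id == rec.target_id:
            continue
        if rec.mapq < config.min_mapq:
            continue
        for cid in (rec.query_id, rec.target_id):
            if cid not in lengths:
                raise dio.IntegrityError(
                    f"alignment references unknown contig {cid!r}"
                )
        if _is_shorter(rec.query_id, rec.target_id, lengths):
            key = (rec.query_id, rec.target_id)
            iv = (rec.query_start, rec.query_end)
        else:
            key = (rec.target_id, rec.query_id)
            iv = (rec.target_start, rec.target_end)
        per_pair.setdefault(key, []).append(iv)
    return {
        key: union_length(ivs) / lengths[key[0]]
        for key, ivs in per_pair.items()
    }


# ---------------------------------------------------------------------------
# Criterion 2: micro-synteny


def _best_chain(pairs: List[Tuple[int, int]], max_gap: int,
                inverted: bool) -> List[Tuple[int, int]]:
    """Longest chain of (rank_a, rank_b) pairs, strictly increasing in
    rank_a and strictly increasing (or decreasing, if inverted) in
    rank_b, with consecutive rank gaps <= max_gap on both contigs.
    O(n^2) dynamic program; anchor counts per contig pair are small.
    """
    if not pairs:
        return []
    pts = sorted(
        ((ra, -rb) if inverted else (ra, rb)) for ra, rb in pairs
    )
    n = len(pts)
    best = [1] * n
    parent = [-1] * n
    for i in range(n):
        ai, bi = pts[i]
        for j in range(i):
            aj, bj = pts[j]
            if aj >= ai or bj >= bi:
                continue
            if ai - aj > max_gap or abs(bi - bj) > max_gap:
                continue
            if best[j] + 1 > best[i]:
                best[i] = best[j] + 1
                parent[i] = j
    end = max(range(n), key=lambda i: (best[i], -pts[i][0]))
    chain = []
    while end != -1:
        a, b = pts[end]
        chain.append((a, -b) if inverted else (a, b))
        end = parent[end]
    return chain[::-1]


def detect_collinear_blocks(
    anchors_a: Sequence[GeneAnchor],
    anchors_b: Sequence[GeneAnchor],
    matches: Iterable[Tuple[str, str]],
    config: Optional[PurgeConfig] = None,
) -> List[CollinearBlock]:
    """Chain matched gene anchors into collinear blocks between two contigs.

    ``matches`` pairs gene ids on contig a with gene ids on contig b
    (one-to-one; extra matches for a gene are dropped best-hit style).
    Returns the best block per orientation, largest first; the pair's
    collinear-gene count is the size of the first block.
    """
    config = config or PurgeConfig()
    for anchors in (anchors_a, anchors_b):
        ranks = [a.rank for a in anchors]
        if None in ranks:
            raise dio.IntegrityError("anchors must carry ranks (assign_ranks)")
        if len(set(ranks)) != len(ranks):
            raise dio.IntegrityError(
                f"duplicate anchor rank on contig "
                f"{anchors[0].contig_id if anchors else '?'}"
            )
    rank_a = {a.gene_id: a.rank for a in anchors_a}
    rank_b = {b.gene_id: b.rank for b in anchors_b}
    pairs: List[Tuple[int, int]] = []
    used_a, used_b = set(), set()
    for ga, gb in matches:
        if ga in rank_a and gb in rank_b:
            if ga in used_a or gb in used_b:
                continue  # enforce one-to-one
            used_a.add(ga)
            used_b.add(gb)
            pairs.append((rank_a[ga], rank_b[gb]))
    if not pairs:
        return []
    ca = anchors_a[0].contig_id
    cb = anchors_b[0].contig_id
    blocks = []
    for orientation, inverted in (("same", False), ("inverted", True)):
        chain = _best_chain(pairs, config.max_anchor_gap, inverted)
        if chain:
            blocks.append(CollinearBlock(ca, cb, chain, orientation))
    blocks.sort(key=lambda b: -b.size)
    return blocks


def collinear_genes_map(
    anchors: Sequence[GeneAnchor],
    matches: Iterable[Tuple[str, str]],
    config: Optional[PurgeConfig] = None,
) -> Dict[Tuple[str, str], int]:
    """Largest collinear-block size for every contig pair linked by at
    least one gene match, keyed by the sorted contig-id pair."""
    config = config or PurgeConfig()
    by_contig: Dict[str, List[GeneAnchor]] = {}
    contig_of: Dict[str, str] = {}
    for a in anchors:
        by_contig.setdefault(a.contig_id, []).append(a)
        contig_of[a.gene_id] = a.contig_id
    pair_matches: Dict[Tuple[str, str], List[Tuple[str, str]]] = {}
    for ga, gb in matches:
        ca, cb = contig_of.get(ga), contig_of.get(gb)
        if ca is None or cb is None or ca == cb:
            continue
        if ca <= cb:
            pair_matches.setdefault((ca, cb), []).append((ga, gb))
        else:
            pair_matches.setdefault((cb, ca), []).append((gb, ga))
    out = {}
    for (ca, cb), ms in pair_matches.items():
        blocks = detect_collinear_blocks(
            by_contig[ca], by_contig[cb], ms, config)
        out[(ca, cb)] = blocks[0].size if blocks else 0
    return out


# ---------------------------------------------------------------------------
# Criterion 3: shared single-copy markers


def shared_single_copy_markers(
    marker_hits: Iterable[MarkerHit],
) -> Dict[Tuple[str, str], int]:
    """Markers complete with exactly one copy on each contig of a pair,
    keyed by the sorted contig-id pair.

    Single-copy is judged per contig: a marker duplicated genome-wide but
    present once on each of two contigs links them — allelic duplication
    is precisely what this criterion detects.
    """
    single: Dict[str, List[str]] = {}
    for h in marker_hits:
        if h.status == "complete" and h.copies_on_contig == 1:
            single.setdefault(h.marker_id, []).append(h.contig_id)
    counts: Dict[Tuple[str, str], int] = {}
    for contigs in single.values():
        contigs = sorted(set(contigs))
        for i, ca in enumerate(contigs):
            for cb in contigs[i + 1:]:
                counts[(ca, cb)] = counts.get((ca, cb), 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Evidence assembly and classification


def build_pair_evidence(
    coverage: Dict[Tuple[str, str], float],
    collinear: Dict[Tuple[str, str], int],
    markers: Dict[Tuple[str, str], int],
    lengths: Dict[str, int],
) -> List[PairEvidence]:
    """Merge the three evidence channels into per-(short, long) records."""
    merged: Dict[Tuple[str, str], PairEvidence] = {}

    def orient(a: str, b: str) -> Tuple[str, str]:
        return (a, b) if _is_shorter(a, b, lengths) else (b, a)

    for (s, l), cov in coverage.items():
        key = orient(s, l)
        ev = merged.setdefault(key, PairEvidence(*key))
        ev.coverage = max(ev.coverage, cov)
    for (a, b), n in collinear.items():
        key = orient(a, b)
        ev = merged.setdefault(key, PairEvidence(*key))
        ev.collinear_genes = max(ev.collinear_genes, n)
    for (a, b), n in markers.items():
        key = orient(a, b)
        ev = merged.setdefault(key, PairEvidence(*key))
        ev.shared_markers = max(ev.shared_markers, n)
    return [merged[k] for k in sorted(merged)]


def _triggered(ev: PairEvidence, config: PurgeConfig) -> Tuple[str, ...]:
    out = []
    if ev.coverage > config.min_coverage:
        out.append("coverage")
    if ev.collinear_genes >= config.min_collinear_genes:
        out.append("synteny")
    if ev.shared_markers >= config.min_shared_markers:
        out.append("marker")
    return tuple(out)


def classify_haplotigs(
    evidence: Sequence[PairEvidence],
    lengths: Dict[str, int],
    config: Optional[PurgeConfig] = None,
) -> List[PurgeDecision]:
    """Label every contig primary or haplotig, greedily by descending length.

    For each contig (longest first) the best qualifying longer partner is
    chosen by most criteria triggered, then highest coverage, then most
    collinear genes, then lexicographic partner id. Equal-length pairs
    break toward purging the lexicographically larger id (logged as a
    tie). Returns one decision per contig id in ``lengths``.
    """
    config = config or PurgeConfig()
    by_short: Dict[str, List[PairEvidence]] = {}
    for ev in evidence:
        if not _is_shorter(ev.short_id, ev.long_id, lengths):
            raise dio.IntegrityError(
                f"evidence pair ({ev.short_id}, {ev.long_id}) is not "
                f"oriented short->long"
            )
        by_short.setdefault(ev.short_id, []).append(ev)

    order = sorted(lengths, key=lambda c: _length_order_key(c, lengths))
    decisions: List[PurgeDecision] = []
    for cid in order:
        best: Optional[Tuple[tuple, PairEvidence]] = None
        for ev in by_short.get(cid, ()):
            crit = _triggered(ev, config)
            if not crit:
                continue
            score = (len(crit), ev.coverage, ev.collinear_genes)
            if best is None or score > best[0] or (
                score == best[0] and ev.long_id < best[1].long_id
            ):
                best = (score, ev)
        if best is None:
            decisions.append(PurgeDecision(cid, "primary"))
        else:
            ev = best[1]
            if lengths[cid] == lengths[ev.long_id]:
                log.info(
                    "equal-length tie: purging %s into %s", cid, ev.long_id
                )
            decisions.append(PurgeDecision(
                cid, "haplotig", partner_id=ev.long_id,
                triggered_criteria=_triggered(ev, config),
                coverage=ev.coverage,
                collinear_genes=ev.collinear_genes,
                shared_markers=ev.shared_markers,
            ))
    return decisions


# ---------------------------------------------------------------------------
# Output


def purge_assembly(
    contigs: Dict[str, Contig],
    decisions: Sequence[PurgeDecision],
):
    """Partition contigs by decision; every contig lands in exactly one
    output set, so total bp is conserved."""
    by_id = {d.contig_id: d for d in decisions}
    unknown = set(by_id) - set(contigs)
    if unknown:
        raise dio.IntegrityError(
            f"decisions reference unknown contigs: {sorted(unknown)}"
        )
    missing = set(contigs) - set(by_id)
    if missing:
        raise dio.IntegrityError(
            f"no decision for contigs: {sorted(missing)}"
        )
    primary = [c for cid, c in contigs.items()
               if by_id[cid].label == "primary"]
    haplotigs = [c for cid, c in contigs.items()
                 if by_id[cid].label == "haplotig"]
    report = []
    for cid in sorted(contigs):
        d = by_id[cid]
        report.append({
            "contig_id": cid,
            "length": contigs[cid].length,
            "label": d.label,
            "partner_id": d.partner_id or ".",
            "coverage": round(d.coverage, 6),
            "collinear_genes": d.collinear_genes,
            "shared_markers": d.shared_markers,
            "criteria": ",".join(d.triggered_criteria) or ".",
        })
    return primary, haplotigs, report


def write_report(report, path) -> None:
    cols = ["contig_id", "length", "label", "partner_id", "coverage",
            "collinear_genes", "shared_markers", "criteria"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in report:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")


def run_purge(
    contigs_path,
    paf_path,
    out_dir,
    anchors_path=None,
    matches_path=None,
    markers_path=None,
    config: Optional[PurgeConfig] = None,
) -> List[PurgeDecision]:
    """End-to-end purge: read evidence, classify, write primary/haplotig
    FASTAs and the decision report TSV into ``out_dir``."""
    config = config or PurgeConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = dio.read_fasta(contigs_path)
    lengths = {cid: c.length for cid, c in contigs.items()}
    alignments = dio.read_paf(paf_path)
    coverage = compute_pair_coverage(alignments, lengths, config)
    collinear: Dict[Tuple[str, str], int] = {}
    if anchors_path and matches_path:
        anchors = dio.read_anchors(anchors_path)
        matches = dio.read_matches(matches_path)
        collinear = collinear_genes_map(anchors, matches, config)
    markers: Dict[Tuple[str, str], int] = {}
    if markers_path:
        markers = shared_single_copy_markers(dio.read_markers(markers_path))
    evidence = build_pair_evidence(coverage, collinear, markers, lengths)
    decisions = classify_haplotigs(evidence, lengths, config)
    primary, haplotigs, report = purge_assembly(contigs, decisions)
    dio.write_fasta(primary, out_dir / "primary.fa")
    dio.write_fasta(haplotigs, out_dir / "haplotigs.fa")
    write_report(report, out_dir / "purge_report.tsv")
    n_hap = sum(1 for d in decisions if d.label == "haplotig")
    log.info("purged %d/%d contigs as haplotigs", n_hap, len(decisions))
    return decisions
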