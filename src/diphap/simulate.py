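"""Truth-labeled synthetic heterozygous diploid genomes.

The generator plants non-overlapping substitutions, small INDELs
(< 50 bp) and PAVs (>= 50 bp) on a random haplotype 1 to derive
haplotype 2, then fragments the two haplotypes into an assembly-like
contig set in which every haplotig (drawn from haplotype 2) is a
strictly shorter redundant copy of exactly one primary contig (drawn
from haplotype 1). Gene anchors, single-copy marker hits, exact
base-level alignments (PAF with =/X/I/D CIGARs) and two noisy variant
callsets are emitted alongside, all with truth labels, so the purge and
divergence stages can be validated offline against a known answer.

Default rates emulate a highly heterozygous forage-grass genome:
3.43 substitutions per 100 bp, with INDEL and PAV event rates set to
reproduce the roughly 12:1 SNP:INDEL and 42:1 SNP:PAV count ratios such
genomes show. Every draw descends from one seed through named
substreams, so outputs are byte-reproducible and changing one stage's
parameters does not perturb another stage's draws.
"""
from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import io as dio
from .intervals import clip, merge
from .types import Contig, GeneAnchor, MarkerHit, Variant

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class SimulationError(RuntimeError):
    """Raised when parameters cannot be realised (rates too high, ...)."""


@dataclass
class SimParams:
    """Scene parameters; the seed fully determines all outputs.

    Rates are per reference bp (events per bp for INDELs/PAVs). Genes
    and markers are planted per primary contig and per allelic pair
    respectively.
    """

    genome_bp: int = 5_000_000
    n_chroms: int = 2
    snp_rate: float = 0.0343
    indel_rate: float = 0.00283
    pav_rate: float = 0.00082
    pav_len_range: Tuple[int, int] = (50, 300)
    indel_len_p: float = 0.35  # geometric length parameter, clipped below 50
    n_genes: int = 30
    n_markers: int = 3
    n_primary_contigs: int = 40
    n_haplotigs: int = 25
    haplotig_len_range: Tuple[int, int] = (60_000, 100_000)
    inverted_haplotig_frac: float = 0.3
    callset_fnr: float = 0.1
    pav_jitter_bp: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate", "pav_rate", "callset_fnr",
                     "inverted_haplotig_frac"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.pav_len_range[0] < 50:
            raise ValueError("pav_len_range minimum must be >= 50 bp")
        if self.n_haplotigs > self.n_primary_contigs:
            raise ValueError("n_haplotigs cannot exceed n_primary_contigs")
        if self.n_chroms < 1 or self.genome_bp < self.n_chroms:
            raise ValueError("need at least 1 bp per chromosome")


@dataclass
class PrimaryInfo:
    contig_id: str
    chrom: str
    start: int  # haplotype-1 coordinates
    end: int


@dataclass
class HaplotigInfo:
    contig_id: str
    partner_id: str
    chrom: str
    h1_start: int
    h1_end: int
    h2_start: int
    h2_end: int
    inverted: bool


@dataclass
class SimTruth:
    """Ground truth surface: what the analysis stages should recover."""

    variants: List[Variant]
    labels: Dict[str, str]  # contig_id -> primary | haplotig
    partners: Dict[str, Optional[str]]
    gene_anchors: List[GeneAnchor]
    gene_matches: List[Tuple[str, str]]
    marker_hits: List[MarkerHit]
    per_window_masked_bp: Dict[Tuple[str, int], int]
    primaries: List[PrimaryInfo] = field(default_factory=list)
    haplotigs: List[HaplotigInfo] = field(default_factory=list)


@dataclass
class SimDataset:
    params: SimParams
    h1: Dict[str, Contig]
    h2: Dict[str, Contig]
    contigs: Dict[str, Contig]
    truth: SimTruth
    contig_alignments: list  # haplotig <-> primary, exact CIGARs
    haplotype_alignments: list  # h2 chromosome vs h1 chromosome
    callset_wga: List[Variant]
    callset_read: List[Variant]


# ---------------------------------------------------------------------------
# Haplotype 1 and planted variants


def _random_chromosome(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


class _SpanIndex:
    """Sorted disjoint spans with O(log n) overlap queries/inserts."""

    def __init__(self) -> None:
        self.starts: List[int] = []
        self.ends: List[int] = []

    def overlaps(self, s: int, e: int) -> bool:
        i = bisect_right(self.starts, s)
        if i and self.ends[i - 1] > s:
            return True
        return i < len(self.starts) and self.starts[i] < e

    def add(self, s: int, e: int) -> None:
        i = bisect_right(self.starts, s)
        self.starts.insert(i, s)
        self.ends.insert(i, e)

    def flat(self) -> np.ndarray:
        out = np.empty(2 * len(self.starts), dtype=np.int64)
        out[0::2] = self.starts
        out[1::2] = self.ends
        return out


def _place_events(rng, L, spans, n, length_of, retry: int = 200):
    """Sample n non-overlapping [s, s+len) spans by rejection."""
    placed = []
    for _ in range(n):
        ln = length_of()
        for attempt in range(retry):
            s = int(rng.integers(1, L - ln - 1))
            # 1-bp spacer so same-op runs of distinct events never abut
            # (abutting deletions would coalesce into one CIGAR run)
            if not spans.overlaps(s - 1, s + ln + 1):
                spans.add(s, s + ln)
                placed.append((s, ln))
                break
        else:
            raise SimulationError(
                "could not place non-overlapping events; lower the "
                "snp/indel/pav rates or enlarge the genome"
            )
    return placed


def mutate_haplotype(
    h1: Dict[str, Contig],
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[Dict[str, Contig], List[Variant]]:
    """Derive haplotype 2 from haplotype 1 by planted variants.

    Events never overlap one another, so applying the returned truth
    list to haplotype 1 reconstructs haplotype 2 exactly and truth
    masking stays additive. Event counts are Binomial(L, rate) per
    chromosome. Insertions are anchored on the reference base
    immediately after the insertion point.
    """
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    truth: List[Variant] = []
    for chrom in h1:
        seq = h1[chrom].seq
        L = len(seq)
        spans = _SpanIndex()
        chrom_vars: List[Variant] = []

        n_pav = int(rng.binomial(L, params.pav_rate))
        lo, hi = params.pav_len_range
        for s, ln in _place_events(
            rng, L, spans, n_pav, lambda: int(rng.integers(lo, hi + 1))
        ):
            if rng.random() < 0.5:
                chrom_vars.append(Variant.deletion(
                    chrom, s, ln, ref_allele=seq[s:s + ln]))
            else:
                spans.ends[bisect_left(spans.starts, s)] = s + 1  # anchor only
                alt = _random_chromosome(rng, ln)
                chrom_vars.append(Variant.insertion(chrom, s, ln,
                                                    alt_allele=alt))

        n_indel = int(rng.binomial(L, params.indel_rate))

        def indel_len() -> int:
            return int(min(rng.geometric(params.indel_len_p), 49))

        for s, ln in _place_events(rng, L, spans, n_indel, indel_len):
            if rng.random() < 0.5:
                chrom_vars.append(Variant.deletion(
                    chrom, s, ln, ref_allele=seq[s:s + ln]))
            else:
                spans.ends[bisect_left(spans.starts, s)] = s + 1
                alt = _random_chromosome(rng, ln)
                chrom_vars.append(Variant.insertion(chrom, s, ln,
                                                    alt_allele=alt))

        n_snp = int(rng.binomial(L, params.snp_rate))
        flat = spans.flat()
        positions: List[int] = []
        want = n_snp
        guard = 0
        while want > 0:
            draw = rng.choice(L - 2, size=min(L - 2, int(want * 1.3) + 16),
                              replace=False) + 1
            idx = np.searchsorted(flat, draw, side="right")
            free = draw[(idx % 2 == 0)]
            free = np.setdiff1d(free, np.asarray(positions, dtype=free.dtype))
            positions.extend(int(p) for p in free[:want])
            want = n_snp - len(positions)
            guard += 1
            if guard > 50:
                raise SimulationError("snp_rate too high for free positions")
        base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for p in positions:
            ref = seq[p]
            alt = "ACGT"[(base_idx[ref] + int(rng.integers(1, 4))) % 4]
            chrom_vars.append(Variant.snp(chrom, p, ref_allele=ref,
                                          alt_allele=alt))

        chrom_vars.sort(key=lambda v: v.sort_key)
        truth.extend(chrom_vars)
    h2 = apply_variants(h1, truth)
    return h2, truth


def apply_variants(
    h1: Dict[str, Contig],
    variants: Sequence[Variant],
    id_suffix: str = "_h2",
) -> Dict[str, Contig]:
    """Apply non-overlapping variants to haplotype 1 (the constructive
    inverse of variant extraction). Variants must carry alleles."""
    by_chrom: Dict[str, List[Variant]] = {c: [] for c in h1}
    for v in variants:
        by_chrom[v.ref_id].append(v)
    out: Dict[str, Contig] = {}
    for chrom, seq in ((c, h1[c].seq) for c in h1):
        parts: List[str] = []
        cur = 0
        for v in sorted(by_chrom[chrom], key=lambda v: v.sort_key):
            parts.append(seq[cur:v.ref_start])
            if v.subtype == "substitution":
                parts.append(v.alt_allele)
                cur = v.ref_start + 1
            elif v.subtype == "deletion":
                cur = v.ref_end
            else:  # insertion: alt bases go before the anchor base
                parts.append(v.alt_allele)
                cur = v.ref_start
        parts.append(seq[cur:])
        out[chrom] = Contig(chrom + id_suffix, "".join(parts))
    return out


# ---------------------------------------------------------------------------
# Exact alignments from the truth variant list


def _coalesce(ops: List[Tuple[str, int]]) -> Tuple[Tuple[str, int], ...]:
    out: List[Tuple[str, int]] = []
    for op, n in ops:
        if n == 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return tuple(out)


def cigar_between(variants: Sequence[Variant], a: int, b: int):
    """Exact =/X/I/D CIGAR for reference window [a, b) given the sorted
    planted variants whose spans fall inside it."""
    ops: List[Tuple[str, int]] = []
    cur = a
    for v in variants:
        if v.ref_start < a or v.ref_start >= b:
            continue
        ops.append(("=", v.ref_start - cur))
        if v.subtype == "substitution":
            ops.append(("X", 1))
            cur = v.ref_start + 1
        elif v.subtype == "deletion":
            ops.append(("D", v.ref_len))
            cur = v.ref_end
        else:
            ops.append(("I", v.alt_len))
            cur = v.ref_start
    ops.append(("=", b - cur))
    return _coalesce(ops)


class _CoordMap:
    """Monotone haplotype-1 -> haplotype-2 coordinate map from the
    planted variants of one chromosome."""

    def __init__(self, variants: Sequence[Variant]):
        self.dels = [(v.ref_start, v.ref_end) for v in variants
                     if v.subtype == "deletion"]
        self.del_starts = [s for s, _ in self.dels]
        # cumulative h2-offset breakpoints: at reference position p the
        # offset is ins_alt(anchor < p) - del_ref(end <= p)
        events = []
        for v in variants:
            if v.subtype == "deletion":
                events.append((v.ref_end, -v.ref_len))
            elif v.subtype == "insertion":
                events.append((v.ref_start + 1, v.alt_len))
        events.sort()
        self.pos = [p for p, _ in events]
        self.cum = np.cumsum([d for _, d in events]).tolist() if events else []

    def safe(self, p: int) -> int:
        """Shift p right until it does not fall strictly inside a deletion."""
        i = bisect_right(self.del_starts, p) - 1
        if i >= 0 and self.dels[i][0] < p < self.dels[i][1]:
            return self.dels[i][1]
        return p

    def cut(self, p: int) -> int:
        """h2 coordinate of the cut point at safe reference position p;
        bases inserted exactly at p fall to the right of the cut."""
        i = bisect_right(self.pos, p) - 1
        return p + (self.cum[i] if i >= 0 else 0)


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# Fragmentation into primaries + redundant haplotigs


def fragment_with_redundancy(
    h1: Dict[str, Contig],
    h2: Dict[str, Contig],
    truth_variants: Sequence[Variant],
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
):
    """Tile haplotype 1 into primary contigs and sample haplotigs from
    haplotype 2, each a strictly shorter redundant copy of exactly one
    primary. Returns (contigs, truth-partial, contig_alignments)."""
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    by_chrom: Dict[str, List[Variant]] = {c: [] for c in h1}
    for v in truth_variants:
        by_chrom[v.ref_id].append(v)
    maps = {c: _CoordMap(by_chrom[c]) for c in h1}

    total = sum(h1[c].length for c in h1)
    n_per: Dict[str, int] = {}
    assigned = 0
    chroms = list(h1)
    for i, c in enumerate(chroms):
        if i == len(chroms) - 1:
            n_per[c] = params.n_primary_contigs - assigned
        else:
            n_per[c] = max(1, round(
                params.n_primary_contigs * h1[c].length / total))
            assigned += n_per[c]
    if min(n_per.values()) < 1 or sum(n_per.values()) != params.n_primary_contigs:
        raise SimulationError("cannot distribute primary contigs over "
                              "chromosomes")

    primaries: List[PrimaryInfo] = []
    contigs: Dict[str, Contig] = {}
    pidx = 0
    for c in chroms:
        L = h1[c].length
        n = n_per[c]
        tile = L / n
        cuts = [0]
        for k in range(1, n):
            jitter = int(rng.integers(-int(tile * 0.05), int(tile * 0.05) + 1))
            cuts.append(maps[c].safe(int(round(k * tile)) + jitter))
        cuts.append(L)
        for a, b in zip(cuts, cuts[1:]):
            cid = f"p{pidx:03d}"
            pidx += 1
            contigs[cid] = Contig(cid, h1[c].seq[a:b])
            primaries.append(PrimaryInfo(cid, c, a, b))

    min_plen = min(p.end - p.start for p in primaries)
    if params.n_haplotigs and params.haplotig_len_range[1] >= min_plen:
        raise SimulationError(
            f"haplotig_len_range max {params.haplotig_len_range[1]} must be "
            f"shorter than the shortest primary contig ({min_plen} bp)"
        )

    haplotigs: List[HaplotigInfo] = []
    alignments = []
    hosts = rng.choice(len(primaries), size=params.n_haplotigs,
                       replace=False)
    lo, hi = params.haplotig_len_range
    for hidx, host_i in enumerate(sorted(int(i) for i in hosts)):
        host = primaries[host_i]
        cmap = maps[host.chrom]
        ln = int(rng.integers(lo, hi + 1))
        a = cmap.safe(int(rng.integers(host.start, host.end - ln)))
        b = cmap.safe(a + ln)
        if b > host.end:
            b = host.end  # chromosome/primary boundaries are safe cuts
        ca, cb = cmap.cut(a), cmap.cut(b)
        seg = h2[host.chrom].seq[ca:cb]
        inverted = bool(rng.random() < params.inverted_haplotig_frac)
        cid = f"h{hidx:03d}"
        contigs[cid] = Contig(cid, _revcomp(seg) if inverted else seg)
        haplotigs.append(HaplotigInfo(
            cid, host.contig_id, host.chrom, a, b, ca, cb, inverted))
        cigar = cigar_between(by_chrom[host.chrom], a, b)
        qspan = sum(n for op, n in cigar if op in "=XI")
        if qspan != len(seg):  # exactness guard on the generator itself
            raise SimulationError("internal: CIGAR/segment length mismatch")
        alignments.append(dio.AlignmentRecord(
            query_id=cid, query_len=len(seg), query_start=0,
            query_end=len(seg), strand="-" if inverted else "+",
            target_id=host.contig_id,
            target_len=host.end - host.start,
            target_start=a - host.start, target_end=b - host.start,
            cigar=cigar,
        ))

    labels = {p.contig_id: "primary" for p in primaries}
    partners: Dict[str, Optional[str]] = {p.contig_id: None
                                          for p in primaries}
    for h in haplotigs:
        labels[h.contig_id] = "haplotig"
        partners[h.contig_id] = h.partner_id
    return contigs, primaries, haplotigs, labels, partners, alignments


# ---------------------------------------------------------------------------
# Genes and markers


def plant_genes_and_markers(
    primaries: Sequence[PrimaryInfo],
    haplotigs: Sequence[HaplotigInfo],
    truth_variants: Sequence[Variant],
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
    contig_lengths: Optional[Dict[str, int]] = None,
):
    """Place genes collinearly on each primary and copy the ones falling
    inside a haplotig's source interval onto the haplotig (same order;
    reversed and strand-flipped on inverted haplotigs). Markers are
    complete single-copy on each member of a primary/haplotig pair."""
    rng = rng if rng is not None else np.random.default_rng(0)
    by_chrom: Dict[str, List[Variant]] = {}
    for v in truth_variants:
        by_chrom.setdefault(v.ref_id, []).append(v)
    maps = {c: _CoordMap(vs) for c, vs in by_chrom.items()}
    hap_by_partner = {h.partner_id: h for h in haplotigs}

    gene_len = 600
    anchors: List[GeneAnchor] = []
    matches: List[Tuple[str, str]] = []
    markers: List[MarkerHit] = []
    for p in primaries:
        plen = p.end - p.start
        slot = plen / params.n_genes if params.n_genes else 0
        if params.n_genes and slot < gene_len * 2:
            raise SimulationError(
                f"n_genes={params.n_genes} too dense for primary contig "
                f"length {plen}"
            )
        cmap = maps.get(p.chrom)
        hap = hap_by_partner.get(p.contig_id)
        hlen = (hap.h2_end - hap.h2_start) if hap else 0
        for gi in range(params.n_genes):
            center = p.start + (gi + 0.5) * slot + float(
                rng.uniform(-0.2 * slot, 0.2 * slot))
            gs = int(center - gene_len / 2)
            ge = gs + gene_len
            gid = f"g_{p.contig_id}_{gi:03d}"
            anchors.append(GeneAnchor(
                gid, p.contig_id, gs - p.start, ge - p.start, "+"))
            if hap and hap.h1_start <= gs and ge <= hap.h1_end:
                hs = (cmap.cut(cmap.safe(gs)) if cmap else gs) - hap.h2_start
                he = (cmap.cut(cmap.safe(ge)) if cmap else ge) - hap.h2_start
                if he <= hs:
                    continue  # gene swallowed by a planted deletion
                if hap.inverted:
                    hs, he = hlen - he, hlen - hs
                    strand = "-"
                else:
                    strand = "+"
                hid = f"{gid}.h"
                anchors.append(GeneAnchor(hid, hap.contig_id, hs, he, strand))
                matches.append((gid, hid))
        if hap:
            for mi in range(params.n_markers):
                mid = f"m_{p.contig_id}_{mi}"
                markers.append(MarkerHit(mid, p.contig_id, "complete", 1))
                markers.append(MarkerHit(mid, hap.contig_id, "complete", 1))
        elif params.n_markers:
            markers.append(MarkerHit(
                f"m_{p.contig_id}_0", p.contig_id, "complete", 1))
    return dio.assign_ranks(anchors), matches, markers


# ---------------------------------------------------------------------------
# Noisy callsets


def emit_noisy_callsets(
    truth: Sequence[Variant],
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
    ref_lengths: Optional[Dict[str, int]] = None,
) -> Tuple[List[Variant], List[Variant]]:
    """Two corroborating callsets: truth minus independent Bernoulli
    false-negative dropouts per callset; PAV breakpoints in the read
    callset are shifted by a uniform jitter of at most pav_jitter_bp
    (clamped inside the reference when lengths are given)."""
    rng = rng if rng is not None else np.random.default_rng(params.seed + 2)
    keep_wga = rng.random(len(truth)) >= params.callset_fnr
    keep_read = rng.random(len(truth)) >= params.callset_fnr
    wga: List[Variant] = []
    read: List[Variant] = []
    for i, v in enumerate(truth):
        if keep_wga[i]:
            wga.append(Variant(v.vclass, v.subtype, v.ref_id, v.ref_start,
                               v.ref_end, v.ref_len, v.alt_len, "wga",
                               v.ref_allele, v.alt_allele))
        shift = 0
        if v.vclass == "PAV" and params.pav_jitter_bp:
            shift = int(rng.integers(-params.pav_jitter_bp,
                                     params.pav_jitter_bp + 1))
        if keep_read[i]:
            s = max(1, v.ref_start + shift)
            if ref_lengths is not None:
                span = v.ref_len if v.subtype == "deletion" else 1
                s = min(s, ref_lengths[v.ref_id] - span - 1)
            if v.subtype == "insertion":
                read.append(Variant.insertion(v.ref_id, s, v.alt_len,
                                              source="read"))
            elif v.subtype == "deletion":
                read.append(Variant.deletion(v.ref_id, s, v.ref_len,
                                             source="read"))
            else:
                read.append(Variant.snp(v.ref_id, s, source="read",
                                        ref_allele=v.ref_allele,
                                        alt_allele=v.alt_allele))
    wga.sort(key=lambda v: v.sort_key)
    read.sort(key=lambda v: v.sort_key)
    return wga, read


# ---------------------------------------------------------------------------
# Orchestration


def _truth_window_mask(h1: Dict[str, Contig], variants: Sequence[Variant],
                       window_bp: int = 100_000) -> Dict[Tuple[str, int], int]:
    ivs: Dict[str, List[Tuple[int, int]]] = {c: [] for c in h1}
    for v in variants:
        ivs[v.ref_id].append((v.ref_start, v.ref_end))
    out: Dict[Tuple[str, int], int] = {}
    for c in h1:
        m = merge(ivs[c]) if ivs[c] else []
        L = h1[c].length
        for start in range(0, L, window_bp):
            end = min(start + window_bp, L)
            out[(c, start)] = sum(
                e - s for s, e in clip(m, start, end))
    return out


def simulate(params: SimParams) -> SimDataset:
    """Generate the full truth-labeled scene from one seed."""
    root = np.random.SeedSequence(params.seed)
    rng_genome, rng_mut, rng_frag, rng_genes, rng_call = (
        np.random.default_rng(s) for s in root.spawn(5))

    base = params.genome_bp // params.n_chroms
    h1: Dict[str, Contig] = {}
    for i in range(params.n_chroms):
        ln = base if i < params.n_chroms - 1 else (
            params.genome_bp - base * (params.n_chroms - 1))
        name = f"chr{i + 1}"
        h1[name] = Contig(name, _random_chromosome(rng_genome, ln))

    h2, truth_variants = mutate_haplotype(h1, params, rng_mut)
    (contigs, primaries, haplotigs, labels, partners,
     contig_alignments) = fragment_with_redundancy(
        h1, h2, truth_variants, params, rng_frag)
    anchors, matches, markers = plant_genes_and_markers(
        primaries, haplotigs, truth_variants, params, rng_genes)
    callset_wga, callset_read = emit_noisy_callsets(
        truth_variants, params, rng_call,
        ref_lengths={c: h1[c].length for c in h1})

    by_chrom: Dict[str, List[Variant]] = {c: [] for c in h1}
    for v in truth_variants:
        by_chrom[v.ref_id].append(v)
    hap_alignments = []
    for c in h1:
        cigar = cigar_between(by_chrom[c], 0, h1[c].length)
        hap_alignments.append(dio.AlignmentRecord(
            query_id=h2[c].id, query_len=h2[c].length,
            query_start=0, query_end=h2[c].length, strand="+",
            target_id=c, target_len=h1[c].length,
            target_start=0, target_end=h1[c].length, cigar=cigar))

    truth = SimTruth(
        variants=truth_variants, labels=labels, partners=partners,
        gene_anchors=anchors, gene_matches=matches, marker_hits=markers,
        per_window_masked_bp=_truth_window_mask(h1, truth_variants),
        primaries=primaries, haplotigs=haplotigs,
    )
    return SimDataset(params, h1, h2, contigs, truth,
                      contig_alignments, hap_alignments,
                      callset_wga, callset_read)


def write_dataset(ds: SimDataset, out_dir) -> Dict[str, Path]:
    """Write the scene to disk in standard formats; byte-deterministic."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "h1": out / "h1.fa", "h2": out / "h2.fa",
        "contigs": out / "contigs.fa",
        "contig_paf": out / "contigs.paf",
        "haplotype_paf": out / "haplotypes.paf",
        "anchors": out / "anchors.tsv", "matches": out / "matches.tsv",
        "markers": out / "markers.tsv",
        "wga_vcf": out / "callset_wga.vcf",
        "read_vcf": out / "callset_read.vcf",
        "truth_variants": out / "truth_variants.tsv",
        "truth_labels": out / "truth_labels.tsv",
        "truth_window_mask": out / "truth_window_mask.tsv",
        "params": out / "params.yaml",
    }
    dio.write_fasta(ds.h1.values(), paths["h1"])
    dio.write_fasta(ds.h2.values(), paths["h2"])
    dio.write_fasta(ds.contigs.values(), paths["contigs"])
    dio.write_paf(ds.contig_alignments, paths["contig_paf"])
    dio.write_paf(ds.haplotype_alignments, paths["haplotype_paf"])
    dio.write_anchors(ds.truth.gene_anchors, paths["anchors"])
    dio.write_matches(ds.truth.gene_matches, paths["matches"])
    dio.write_markers(ds.truth.marker_hits, paths["markers"])
    ref_lengths = {c: ds.h1[c].length for c in ds.h1}
    dio.write_vcf(ds.callset_wga, ref_lengths, paths["wga_vcf"])
    dio.write_vcf(ds.callset_read, ref_lengths, paths["read_vcf"],
                  symbolic_sv=True)
    with open(paths["truth_variants"], "w") as fh:
        fh.write("vclass\tsubtype\tref_id\tref_start\tref_end\t"
                 "ref_len\talt_len\n")
        for v in ds.truth.variants:
            fh.write(f"{v.vclass}\t{v.subtype}\t{v.ref_id}\t{v.ref_start}\t"
                     f"{v.ref_end}\t{v.ref_len}\t{v.alt_len}\n")
    with open(paths["truth_labels"], "w") as fh:
        fh.write("contig_id\tlabel\tpartner_id\n")
        for cid in sorted(ds.truth.labels):
            fh.write(f"{cid}\t{ds.truth.labels[cid]}\t"
                     f"{ds.truth.partners[cid] or '.'}\n")
    with open(paths["truth_window_mask"], "w") as fh:
        fh.write("ref_id\twindow_start\tmasked_bp\n")
        for (c, s), bp in sorted(ds.truth.per_window_masked_bp.items()):
            fh.write(f"{c}\t{s}\t{bp}\n")
    cfg = asdict(ds.params)
    cfg["pav_len_range"] = list(cfg["pav_len_range"])
    cfg["haplotig_len_range"] = list(cfg["haplotig_len_range"])
    with open(paths["params"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths


# ---------------------------------------------------------------------------
# Degradation helpers (noise applied on top of a clean scene)


def drop_anchors(anchors: Sequence[GeneAnchor], frac: float,
                 rng: np.random.Generator) -> List[GeneAnchor]:
    """Random anchor dropout (models imperfect gene placement); ranks
    are recomputed so they stay a per-contig permutation."""
    kept = [GeneAnchor(a.gene_id, a.contig_id, a.start, a.end, a.strand)
            for a in anchors if rng.random() >= frac]
    return dio.assign_ranks(kept)


def trim_alignments(alignments, frac: float):
    """Symmetrically trim a fraction of each alignment's length (models
    soft-clipped, unalignable flanks); the result is coverage-only."""
    out = []
    for r in alignments:
        dq = int((r.query_end - r.query_start) * frac / 2)
        dt = int((r.target_end - r.target_start) * frac / 2)
        qs, qe = r.query_start + dq, r.query_end - dq
        ts, te = r.target_start + dt, r.target_end - dt
        if qe <= qs or te <= ts:
            continue
        out.append(dio.AlignmentRecord(
            query_id=r.query_id, query_len=r.query_len,
            query_start=qs, query_end=qe, strand=r.strand,
            target_id=r.target_id, target_len=r.target_len,
            target_start=ts, target_end=te, cigar=(), mapq=r.mapq))
    return out
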