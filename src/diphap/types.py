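"""Core domain types for diploid assembly curation and haplotype divergence.

All coordinates are 0-based, half-open ``[start, end)`` on the forward
strand. Standard formats that use other conventions (VCF, BED score
columns, PAF) are converted at the I/O boundary.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

#: Variants with max(ref_len, alt_len) at or above this are presence/absence
#: variations (PAVs); below it they are small INDELs.
PAV_MIN_BP = 50

VClass = Literal["SNP", "INDEL", "PAV"]
Subtype = Literal["substitution", "insertion", "deletion"]
Source = Literal["wga", "read", "truth"]

# CIGAR ops that consume query / target (reference) bases.
_QUERY_OPS = frozenset("=XIM")
_TARGET_OPS = frozenset("=XDM")


def classify_variant(ref_len: int, alt_len: int) -> VClass:
    """Classify a variant by allele lengths: SNP, small INDEL, or PAV.

    A 1-bp substitution is a SNP; any length difference shorter than
    ``PAV_MIN_BP`` (50 bp) is an INDEL; 50 bp or longer is a PAV.
    """
    if ref_len == 1 and alt_len == 1:
        return "SNP"
    if max(ref_len, alt_len) < PAV_MIN_BP:
        return "INDEL"
    return "PAV"


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval ``[start, end)`` on one sequence."""

    seq_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Contig:
    """A named assembly sequence. ``seq`` is uppercase DNA over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentRecord:
    """One query-to-target alignment segment (one PAF line).

    Query coordinates are always on the forward strand of the query, even
    for ``-`` strand alignments (PAF convention). ``cigar`` is an ordered
    list of ``(op, run_length)`` with ops in {=, X, I, D, M}; records
    without a CIGAR (``coverage_only``) can support coverage evidence but
    not variant extraction.
    """

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    cigar: tuple = ()
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.cigar:
            qspan = sum(n for op, n in self.cigar if op in _QUERY_OPS)
            tspan = sum(n for op, n in self.cigar if op in _TARGET_OPS)
            if qspan != self.query_end - self.query_start:
                raise ValueError(
                    f"CIGAR query span {qspan} != coordinate span "
                    f"{self.query_end - self.query_start} "
                    f"({self.query_id} vs {self.target_id})"
                )
            if tspan != self.target_end - self.target_start:
                raise ValueError(
                    f"CIGAR target span {tspan} != coordinate span "
                    f"{self.target_end - self.target_start} "
                    f"({self.query_id} vs {self.target_id})"
                )

    @property
    def coverage_only(self) -> bool:
        return not self.cigar


@dataclass
class GeneAnchor:
    """A gene placement on a contig; ``rank`` is the ordinal position of
    the gene along its contig when anchors are sorted by start."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    rank: Optional[int] = None


@dataclass
class MarkerHit:
    """A single-copy-ortholog marker hit on one contig (BUSCO-like)."""

    marker_id: str
    contig_id: str
    status: str  # complete | fragmented | missing
    copies_on_contig: int

    def __post_init__(self) -> None:
        if (self.copies_on_contig == 0) != (self.status == "missing"):
            raise ValueError(
                f"marker {self.marker_id} on {self.contig_id}: "
                f"copies {self.copies_on_contig} inconsistent with status "
                f"{self.status!r}"
            )


@dataclass(frozen=True)
class Variant:
    """A typed difference between two haplotypes on reference coordinates.

    ``ref_start``/``ref_end`` delimit the reference span the variant
    occupies for window masking: the substituted/deleted bases for SNPs
    and deletions, and a single anchor base for insertions (the reference
    base immediately after the insertion point), so every variant covers
    a nonempty reference interval.
    """

    vclass: VClass
    subtype: Subtype
    ref_id: str
    ref_start: int
    ref_end: int
    ref_len: int
    alt_len: int
    source: Source = "truth"
    ref_allele: Optional[str] = None
    alt_allele: Optional[str] = None

    def __post_init__(self) -> None:
        if self.subtype == "insertion":
            if self.ref_end != self.ref_start + 1 or self.ref_len != 0:
                raise ValueError(
                    f"insertion at {self.ref_id}:{self.ref_start} must span "
                    f"exactly its 1-bp anchor"
                )
        else:
            if self.ref_end - self.ref_start != self.ref_len:
                raise ValueError(
                    f"{self.subtype} at {self.ref_id}:{self.ref_start} span "
                    f"{self.ref_end - self.ref_start} != ref_len {self.ref_len}"
                )
        if classify_variant(self.ref_len, self.alt_len) != self.vclass:
            raise ValueError(
                f"variant at {self.ref_id}:{self.ref_start} with lengths "
                f"({self.ref_len}, {self.alt_len}) is not a {self.vclass}"
            )

    @property
    def span(self) -> Interval:
        return Interval(self.ref_id, self.ref_start, self.ref_end)

    @property
    def sort_key(self):
        return (self.ref_id, self.ref_start, self.ref_end, self.subtype)

    # -- constructors ------------------------------------------------------

    @classmethod
    def snp(cls, ref_id: str, pos: int, source: Source = "truth",
            ref_allele: Optional[str] = None,
            alt_allele: Optional[str] = None) -> "Variant":
        return cls("SNP", "substitution", ref_id, pos, pos + 1, 1, 1,
                   source, ref_allele, alt_allele)

    @classmethod
    def deletion(cls, ref_id: str, start: int, length: int,
                 source: Source = "truth",
                 ref_allele: Optional[str] = None) -> "Variant":
        vclass = classify_variant(length, 0)
        return cls(vclass, "deletion", ref_id, start, start + length,
                   length, 0, source, ref_allele, None)

    @classmethod
    def insertion(cls, ref_id: str, anchor: int, length: int,
                  source: Source = "truth",
                  alt_allele: Optional[str] = None) -> "Variant":
        vclass = classify_variant(0, length)
        return cls(vclass, "insertion", ref_id, anchor, anchor + 1,
                   0, length, source, None, alt_allele)


@dataclass
class WindowIdentity:
    """Masked-base accounting and sequence identity for one reference window.

    ``identity = (W_eff - masked_union_bp) / W_eff`` where ``W_eff`` is the
    (possibly short, for the last window) window width and
    ``masked_union_bp`` is the union of variant, gap and unaligned bases —
    a union, never a sum, so identity stays in [0, 1].
    """

    ref_id: str
    start: int
    end: int
    variant_bp: int
    gap_bp: int
    unaligned_bp: int
    masked_union_bp: int
    identity: float


@dataclass
class PurgeConfig:
    """Thresholds for the three haplotig-pairing evidence channels.

    Coverage is strict (> min_coverage, i.e. "greater than 70%"); the
    collinear-gene and shared-marker counts are inclusive (>= 5, >= 1,
    i.e. "at least").
    """

    min_coverage: float = 0.70
    min_collinear_genes: int = 5
    min_shared_markers: int = 1
    max_anchor_gap: int = 10
    min_mapq: int = 0  # alignments below this MAPQ are ignored (0 = keep all)

    def __post_init__(self) -> None:
        if not 0 < self.min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")
        if self.min_collinear_genes < 1 or self.min_shared_markers < 1:
            raise ValueError("count thresholds must be >= 1")


@dataclass
class DivergenceConfig:
    """Parameters of the inter-haplotype divergence computation."""

    window_bp: int = 100_000
    pav_min_bp: int = PAV_MIN_BP
    pav_match_slack_bp: int = 10
    min_gap_run: int = 1
    strict_allele_match: bool = False

    def __post_init__(self) -> None:
        for name in ("window_bp", "pav_min_bp", "pav_match_slack_bp",
                     "min_gap_run"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PairEvidence:
    """Evidence linking a shorter contig to a longer candidate partner."""

    short_id: str
    long_id: str
    coverage: float = 0.0
    collinear_genes: int = 0
    shared_markers: int = 0


@dataclass
class PurgeDecision:
    """Final per-contig label with the evidence that triggered it."""

    contig_id: str
    label: str  # primary | haplotig
    partner_id: Optional[str] = None
    triggered_criteria: tuple = ()
    coverage: float = 0.0
    collinear_genes: int = 0
    shared_markers: int = 0

    def __post_init__(self) -> None:
        if (self.label == "haplotig") != (
            self.partner_id is not None and len(self.triggered_criteria) > 0
        ):
            raise ValueError(
                f"decision for {self.contig_id}: haplotig label requires a "
                f"partner and at least one triggered criterion"
            )


@dataclass
class CollinearBlock:
    """A maximal chain of matched gene anchors, monotone in both rank
    orders (increasing on both contigs, or increasing on one and
    decreasing on the other for inverted blocks)."""

    contig_a: str
    contig_b: str
    anchor_pairs: list  # ordered (rank_on_a, rank_on_b) pairs
    orientation: str  # same | inverted

    @property
    def size(self) -> int:
        return len(self.anchor_pairs)


@dataclass
class ConcordanceResult:
    """Variants corroborated by both callsets, split by class."""

    common_snps: list
    common_indels: list
    common_pavs: list

    @property
    def counts(self) -> dict:
        return {
            "SNP": len(self.common_snps),
            "INDEL": len(self.common_indels),
            "PAV": len(self.common_pavs),
        }

    @property
    def all_variants(self) -> list:
        return sorted(
            self.common_snps + self.common_indels + self.common_pavs,
            key=lambda v: v.sort_key,
        )


@dataclass
class MaskTrack:
    """A category of masked reference intervals (variant / gap / unaligned)."""

    ref_id: str
    category: str
    intervals: list = field(default_factory=list)  # sorted (start, end) tuples

    def __post_init__(self) -> None:
        self.intervals = sorted((int(s), int(e)) for s, e in self.intervals)
        for s, e in self.intervals:
            if s < 0 or e <= s:
                raise ValueError(
                    f"bad {self.category} interval [{s}, {e}) on {self.ref_id}"
                )
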