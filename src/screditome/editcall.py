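"""Pileup construction and strand-aware A-to-I editing-site calling.

Pseudo-bulk reads of one cell type are split by orientation; genes
transcribed from the forward strand are screened on forward reads and
reverse-strand genes on reverse reads, so an edited adenosine always
appears as an A>G mismatch *on the gene strand* (a T>C mismatch against
the forward reference for a minus-strand gene). Candidate mismatches at
known SNP positions, or with any identity other than A>G, are rejected.
Surviving candidates get a logistic confidence score ``p_edit``
combining the features that distinguish true editing: Alu-repeat
membership, the A>G identity (hard requirement), the editing level phi,
and sequencing depth. Sites below the depth floor (30x by default) or
the confidence threshold are filtered out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

from .annotate import GeneModel, RepeatInterval, in_alu
from .model import AlignedRead, CandidateSite, EditingSite, complement

_BASES = "ACGT"


class PileupCall(NamedTuple):
    base: str
    base_qual: int
    mapq: int
    cb: Optional[str]
    umi: Optional[str]
    is_reverse: bool
    read_name: str


@dataclass
class PileupColumn:
    chrom: str
    pos0: int
    ref_base: str
    calls: list[PileupCall] = field(default_factory=list)

    @property
    def depth(self) -> int:
        return len(self.calls)

    def base_counts(self) -> dict[str, int]:
        counts = dict.fromkeys(_BASES, 0)
        for c in self.calls:
            if c.base in counts:
                counts[c.base] += 1
        return counts


def build_pileup(
    reads: Iterable[AlignedRead],
    reference: Mapping[str, str],
    region: Optional[tuple[str, int, int]] = None,
    min_mq: int = 20,
    min_bq: int = 20,
    exclude_duplicates: bool = True,
) -> list[PileupColumn]:
    """Build per-position pileup columns from aligned reads.

    Calls exclude duplicate-flagged reads, reads below ``min_mq`` and
    bases below ``min_bq`` (the mpileup ``--min-MQ 20 --min-BQ 20
    --excl-flags DUP`` behaviour, without base-alignment-quality
    recalibration). CIGAR soft clips, insertions and deletions are
    walked so query offsets stay in register with the reference.
    Columns are returned sorted by (chrom, pos0).
    """
    if region is not None and region[0] not in reference:
        raise KeyError(f"region chromosome {region[0]!r} absent from reference")
    columns: dict[tuple[str, int], PileupColumn] = {}
    for read in reads:
        if exclude_duplicates and read.is_duplicate:
            continue
        if read.mapq < min_mq:
            continue
        if region is not None:
            chrom, start, end = region
            if read.chrom != chrom or read.ref_end <= start or read.pos0 >= end:
                continue
        ref_seq = reference.get(read.chrom)
        if ref_seq is None:
            raise KeyError(f"read chromosome {read.chrom!r} absent from reference")
        for q, r in read.aligned_pairs():
            if region is not None and not (region[1] <= r < region[2]):
                continue
            bq = int(read.base_quals[q])
            if bq < min_bq:
                continue
            key = (read.chrom, r)
            col = columns.get(key)
            if col is None:
                col = columns[key] = PileupColumn(read.chrom, r, ref_seq[r].upper())
            col.calls.append(
                PileupCall(read.seq[q].upper(), bq, read.mapq, read.cb, read.umi, read.is_reverse, read.read_name)
            )
    return [columns[k] for k in sorted(columns)]


def site_depth(
    reads: Iterable[AlignedRead],
    chrom: str,
    pos0: int,
    min_mq: int = 20,
    min_bq: int = 20,
    exclude_duplicates: bool = True,
) -> int:
    """Filtered pileup depth at a single position (coverage query)."""
    depth = 0
    for read in reads:
        if exclude_duplicates and read.is_duplicate:
            continue
        if read.mapq < min_mq or read.chrom != chrom:
            continue
        if not (read.pos0 <= pos0 < read.ref_end):
            continue
        hit = read.base_at(pos0)
        if hit is not None and hit[1] >= min_bq:
            depth += 1
    return depth


def site_depths(
    reads: Iterable[AlignedRead],
    positions: Iterable[tuple[str, int]],
    min_mq: int = 20,
    min_bq: int = 20,
    exclude_duplicates: bool = True,
) -> dict[tuple[str, int], int]:
    """Filtered pileup depth at many positions in one pass over the reads."""
    from bisect import bisect_left

    by_chrom: dict[str, list[int]] = {}
    for chrom, pos in positions:
        by_chrom.setdefault(chrom, []).append(pos)
    for chrom in by_chrom:
        by_chrom[chrom] = sorted(set(by_chrom[chrom]))
    depths = {(c, p): 0 for c, ps in by_chrom.items() for p in ps}
    for read in reads:
        if exclude_duplicates and read.is_duplicate:
            continue
        if read.mapq < min_mq:
            continue
        pos_list = by_chrom.get(read.chrom)
        if not pos_list:
            continue
        i = bisect_left(pos_list, read.pos0)
        while i < len(pos_list) and pos_list[i] < read.ref_end:
            hit = read.base_at(pos_list[i])
            if hit is not None and hit[1] >= min_bq:
                depths[(read.chrom, pos_list[i])] += 1
            i += 1
    return depths


def detect_candidates(
    columns: Iterable[PileupColumn],
    snp_index: frozenset | set,
    gene_strand: str,
    min_alt_reads: int = 3,
) -> list[CandidateSite]:
    """Screen pileup columns for mismatch candidates on the gene strand.

    ``snp_index`` is a set of (chrom, pos0) known-variant positions.
    For a minus-strand gene, bases are complemented onto the gene
    strand, so a forward-reference T>C mismatch is reported as A>G.
    The alt allele is the most frequent non-reference base (ties break
    in A<C<G<T order).
    """
    if gene_strand not in "+-":
        raise ValueError(f"invalid gene strand {gene_strand!r}")
    out: list[CandidateSite] = []
    for col in columns:
        ref = col.ref_base
        if ref not in _BASES:
            continue
        counts = col.base_counts()
        alts = sorted((b for b in _BASES if b != ref), key=lambda b: (-counts[b], b))
        alt = alts[0]
        n_alt = counts[alt]
        if n_alt < min_alt_reads:
            continue
        if gene_strand == "-":
            ref_s, alt_s = complement(ref), complement(alt)
        else:
            ref_s, alt_s = ref, alt
        out.append(
            CandidateSite(
                chrom=col.chrom,
                pos0=col.pos0,
                gene_strand=gene_strand,
                ref_on_strand=ref_s,
                alt_on_strand=alt_s,
                n_ref=counts[ref],
                n_alt=n_alt,
                depth=col.depth,
                is_known_snp=(col.chrom, col.pos0) in snp_index,
            )
        )
    return out


@dataclass(frozen=True)
class ScoreWeights:
    """Logistic weights for the editing confidence score.

    z = b0 + b_alu*[in Alu] + b_level*phi + b_depth*log10(depth);
    p_edit = 1 / (1 + exp(-z)). Monotonically non-decreasing in phi,
    depth and Alu membership for non-negative weights.
    """

    b0: float = -2.0
    b_alu: float = 2.5
    b_level: float = 4.0
    b_depth: float = 1.0


def score_site(c: CandidateSite, in_alu: bool, weights: ScoreWeights = ScoreWeights()) -> float:
    """Confidence that a candidate is a true A-to-I editing site.

    Hard rules first: known SNPs and any identity other than A>G on the
    gene strand score 0.
    """
    if c.is_known_snp or c.ref_on_strand != "A" or c.alt_on_strand != "G":
        return 0.0
    if c.depth <= 0:
        raise ValueError("candidate with non-positive depth")
    phi = c.n_alt / c.depth
    z = weights.b0 + weights.b_alu * float(in_alu) + weights.b_level * phi + weights.b_depth * math.log10(c.depth)
    return 1.0 / (1.0 + math.exp(-z))


def filter_sites(
    sites: Iterable[EditingSite],
    min_depth: int = 30,
    p_edit_threshold: float = 0.5,
) -> list[EditingSite]:
    """Coverage and confidence filtering; output sorted by (chrom, pos0)."""
    kept = [s for s in sites if s.depth >= min_depth and s.p_edit >= p_edit_threshold]
    return sorted(kept, key=lambda s: (s.chrom, s.pos0))


@dataclass(frozen=True)
class CallParams:
    min_mq: int = 20
    min_bq: int = 20
    min_depth: int = 30
    min_alt_reads: int = 3
    p_edit_threshold: float = 0.5
    weights: ScoreWeights = ScoreWeights()


def call_gene(
    reads: Sequence[AlignedRead],
    gene: GeneModel,
    reference: Mapping[str, str],
    repeats: Sequence[RepeatInterval],
    snp_index: frozenset | set,
    params: CallParams = CallParams(),
    cell_type: str = "",
) -> list[EditingSite]:
    """Score A>G candidates over one gene from strand-matched reads.

    ``reads`` must already be restricted to the orientation matching
    ``gene.strand`` (forward reads for '+', reverse for '-').
    """
    columns = build_pileup(
        reads,
        reference,
        region=(gene.chrom, gene.start, gene.end),
        min_mq=params.min_mq,
        min_bq=params.min_bq,
    )
    sites: list[EditingSite] = []
    for cand in detect_candidates(columns, snp_index, gene.strand, params.min_alt_reads):
        alu = in_alu(cand.chrom, cand.pos0, repeats)
        p = score_site(cand, alu, params.weights)
        phi = cand.n_alt / cand.depth
        if phi <= 0.0:
            continue
        sites.append(
            EditingSite(
                chrom=cand.chrom,
                pos0=cand.pos0,
                gene_strand=cand.gene_strand,
                ref_on_strand=cand.ref_on_strand,
                alt_on_strand=cand.alt_on_strand,
                depth=cand.depth,
                n_alt=cand.n_alt,
                editing_level=phi,
                p_edit=p,
                in_alu=alu,
                cell_type=cell_type,
                gene_id=gene.gene_id,
            )
        )
    return sites


def call_editome(
    reads_by_cell_type: Mapping[str, Sequence[AlignedRead]],
    reference: Mapping[str, str],
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatInterval],
    snp_index: frozenset | set,
    params: CallParams = CallParams(),
) -> dict[str, list[EditingSite]]:
    """Call the editome of every cell type's pseudo-bulk.

    Per cell type: strand split, per-gene pileup on the matching strand,
    candidate screen, confidence scoring, then depth/confidence
    filtering. Reads are expected to carry duplicate flags already
    (duplicates are excluded from every pileup). When two genes on the
    same strand overlap a position, the call with the higher confidence
    is kept. Deterministic given inputs and parameters.
    """
    from .bamops import split_by_strand

    result: dict[str, list[EditingSite]] = {}
    for cell_type in reads_by_cell_type:
        try:
            forward, reverse = split_by_strand(reads_by_cell_type[cell_type])
            sites: dict[tuple, EditingSite] = {}
            for gene in genes:
                strand_reads = forward if gene.strand == "+" else reverse
                for site in call_gene(strand_reads, gene, reference, repeats, snp_index, params, cell_type):
                    prev = sites.get(site.key)
                    if prev is None or site.p_edit > prev.p_edit:
                        sites[site.key] = site
            result[cell_type] = filter_sites(sites.values(), params.min_depth, params.p_edit_threshold)
        except Exception as exc:  # pragma: no cover - error context plumbing
            raise RuntimeError(f"editome calling failed for cell type {cell_type!r}") from exc
    return result
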