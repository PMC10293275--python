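"""Genomic-element annotation, strand-consistency filtering, and miRNA
seed-match scanning.

A-to-I editing concentrates in Alu repeats and untranslated regions, so
sites are labelled with the genomic element they fall in (precedence
CDS > 3'UTR > 5'UTR > non-coding exon > intron > intergenic) and with
Alu membership. Because the library is strand-specific, a site called
from reads of one orientation is only credible if a gene is transcribed
from that same strand; ``strand_filter`` enforces this.

Editing in a 3'UTR can create or destroy miRNA target sites.
``scan_mirna_sites`` finds the canonical seed-match classes (6mer,
7mer-A1, 7mer-m8, 8mer) of a miRNA in a UTR and reports which editing
positions fall inside each match, before and after applying the edits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .model import EditingSite, revcomp

ELEMENTS = ("CDS", "3UTR", "5UTR", "ncRNA_exon", "intron", "intergenic")
_PRECEDENCE = {e: i for i, e in enumerate(ELEMENTS)}

Interval = tuple[int, int]  # 0-based half-open


@dataclass
class GeneModel:
    """A gene with exon/CDS/UTR structure on one strand.

    Intervals are 0-based half-open genomic coordinates; UTR and CDS
    intervals are subsets of the exons.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def introns(self) -> list[Interval]:
        ex = sorted(self.exons)
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1) if ex[i][1] < ex[i + 1][0]]

    def element_at(self, pos0: int) -> Optional[str]:
        """Element label at a position, or None when outside the gene."""
        if not (self.start <= pos0 < self.end):
            return None
        if _in(pos0, self.cds):
            return "CDS"
        if _in(pos0, self.utr3):
            return "3UTR"
        if _in(pos0, self.utr5):
            return "5UTR"
        if _in(pos0, self.exons):
            # exonic but not CDS/UTR: non-coding exon (for coding genes this
            # only arises from incomplete UTR annotation)
            return "ncRNA_exon"
        return "intron"


def _in(pos0: int, intervals: Iterable[Interval]) -> bool:
    return any(s <= pos0 < e for s, e in intervals)


@dataclass(frozen=True)
class RepeatInterval:
    chrom: str
    start0: int
    end0: int
    family: str = "Alu"

    def __post_init__(self) -> None:
        if self.start0 >= self.end0:
            raise ValueError("empty repeat interval")

    @property
    def is_alu(self) -> bool:
        return self.family.lower().startswith("alu")


@dataclass
class SiteAnnotation:
    site: EditingSite
    element: str
    gene_id: Optional[str]
    in_alu: bool
    strand_consistent: bool


def in_alu(chrom: str, pos0: int, repeats: Sequence[RepeatInterval]) -> bool:
    return any(r.chrom == chrom and r.start0 <= pos0 < r.end0 and r.is_alu for r in repeats)


def annotate_site(
    site: EditingSite,
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatInterval],
) -> SiteAnnotation:
    """Assign a genomic element and Alu membership to one site.

    Among overlapping genes, a gene on the site's calling strand is
    preferred; remaining ties resolve to the most specific element in
    the precedence order, then the lexicographically smallest gene id.
    """
    hits: list[tuple[bool, int, str, str]] = []  # (strand mismatch, precedence, gene_id, element)
    for gene in genes:
        if gene.chrom != site.chrom:
            continue
        element = gene.element_at(site.pos0)
        if element is None:
            continue
        hits.append((gene.strand != site.gene_strand, _PRECEDENCE[element], gene.gene_id, element))
    alu = in_alu(site.chrom, site.pos0, repeats)
    if not hits:
        return SiteAnnotation(site, "intergenic", None, alu, False)
    mismatch, _, gene_id, element = min(hits)
    return SiteAnnotation(site, element, gene_id, alu, strand_consistent=not mismatch)


def annotate_sites(
    sites: Iterable[EditingSite],
    genes: Sequence[GeneModel],
    repeats: Sequence[RepeatInterval],
) -> list[SiteAnnotation]:
    return [annotate_site(s, genes, repeats) for s in sites]


def strand_filter(annotated: Iterable[SiteAnnotation]) -> list[SiteAnnotation]:
    """Keep sites whose calling strand matches the annotated gene strand.

    Intergenic sites have no gene strand to match and are dropped.
    """
    return [a for a in annotated if a.gene_id is not None and a.strand_consistent]


# ---------------------------------------------------------------------------
# miRNA seed matching


@dataclass(frozen=True)
class MirnaSiteMatch:
    mirna_id: str
    start: int  # 0-based half-open interval within the UTR
    end: int
    site_type: str  # 6mer | 7mer-A1 | 7mer-m8 | 8mer
    overlapping_edit_positions: tuple[int, ...] = ()


_SITE_LEN = {"6mer": 6, "7mer-A1": 7, "7mer-m8": 7, "8mer": 8}


def _normalize(seq: str, what: str) -> str:
    s = seq.upper().replace("U", "T")
    if any(b not in "ACGT" for b in s):
        raise ValueError(f"{what} contains non-ACGU/T characters")
    return s


def scan_mirna_sites(
    utr_seq: str,
    mirna_seq: str,
    edit_positions: Sequence[int] = (),
    mirna_id: str = "miRNA",
) -> list[MirnaSiteMatch]:
    """Find canonical seed matches of a miRNA in a UTR sequence.

    The UTR is given 5'->3' on the gene strand; the miRNA 5'->3'. A seed
    match is the reverse complement of miRNA positions 2-7 (6mer) or 2-8
    (7mer-m8) appearing in the UTR; an adenosine in the UTR opposite
    miRNA position 1 upgrades these to 7mer-A1 and 8mer respectively.
    Each anchor position is reported once with its most specific type.
    """
    utr = _normalize(utr_seq, "UTR")
    mirna = _normalize(mirna_seq, "miRNA")
    if len(mirna) < 8:
        raise ValueError("miRNA sequence must be at least 8 nt")
    seed_2_7 = revcomp(mirna[1:7])  # 6 nt
    seed_2_8 = revcomp(mirna[1:8])  # 7 nt, m8 complement first
    matches: list[MirnaSiteMatch] = []
    for s in range(len(utr) - 5):
        if utr[s : s + 7] == seed_2_8:
            if s + 7 < len(utr) and utr[s + 7] == "A":
                site_type, end = "8mer", s + 8
            else:
                site_type, end = "7mer-m8", s + 7
        elif utr[s : s + 6] == seed_2_7:
            if s + 6 < len(utr) and utr[s + 6] == "A":
                site_type, end = "7mer-A1", s + 7
            else:
                site_type, end = "6mer", s + 6
        else:
            continue
        overlap = tuple(p for p in edit_positions if s <= p < end)
        matches.append(MirnaSiteMatch(mirna_id, s, end, site_type, overlap))
    return matches


@dataclass
class EditedScanResult:
    reference_matches: list[MirnaSiteMatch]
    edited_matches: list[MirnaSiteMatch]
    gained: list[MirnaSiteMatch]
    lost: list[MirnaSiteMatch]


def scan_with_edits(
    utr_seq: str,
    mirna_seq: str,
    edit_positions: Sequence[int],
    mirna_id: str = "miRNA",
) -> EditedScanResult:
    """Scan the UTR before and after applying A->G edits.

    Matches gained/lost are compared by (start, site_type): an edit that
    disrupts a seed match (the typical consequence of 3'UTR editing)
    shows up in ``lost``, one that creates a new match in ``gained``.
    """
    ref = scan_mirna_sites(utr_seq, mirna_seq, edit_positions, mirna_id)
    utr = _normalize(utr_seq, "UTR")
    edited = list(utr)
    for p in edit_positions:
        if not 0 <= p < len(edited):
            raise ValueError(f"edit position {p} outside UTR")
        if edited[p] == "A":
            edited[p] = "G"
    alt = scan_mirna_sites("".join(edited), mirna_seq, edit_positions, mirna_id)
    ref_ids = {(m.start, m.site_type) for m in ref}
    alt_ids = {(m.start, m.site_type) for m in alt}
    gained = [m for m in alt if (m.start, m.site_type) not in ref_ids]
    lost = [m for m in ref if (m.start, m.site_type) not in alt_ids]
    return EditedScanResult(ref, alt, gained, lost)
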