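"""Core in-memory records shared across the pipeline.

The pipeline works on lightweight alignment records rather than raw
``pysam.AlignedSegment`` objects so that every stage (pseudo-bulk split,
duplicate marking, pileup, per-cell assignment) can run on plain Python
data, with BAM conversion confined to :mod:`screditome.io`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, NamedTuple, Optional, Sequence

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

# CIGAR operations that consume query / reference bases.
_CONSUMES_QUERY = frozenset("MIS=X")
_CONSUMES_REF = frozenset("MDN=X")
_ALIGNED = frozenset("M=X")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples.

    Raises ``ValueError`` on malformed input or when nothing matches.
    """
    ops = [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    return ops


@dataclass
class AlignedRead:
    """One aligned sequencing read.

    ``pos0`` is the 0-based leftmost *aligned* reference coordinate
    (soft-clipped bases excluded), mirroring the standard alignment
    format. ``is_reverse`` corresponds to bit 16 of the alignment flag.
    ``cb``/``umi`` hold the cell-barcode and UMI tags when present.
    """

    read_name: str
    chrom: str
    pos0: int
    is_reverse: bool
    cigar: str
    seq: str
    base_quals: Sequence[int]
    mapq: int = 60
    cb: Optional[str] = None
    umi: Optional[str] = None
    is_duplicate: bool = False

    def __post_init__(self) -> None:
        if self.pos0 < 0:
            raise ValueError(f"{self.read_name}: negative position")
        if len(self.seq) != len(self.base_quals):
            raise ValueError(f"{self.read_name}: seq/qual length mismatch")
        qlen = sum(n for n, op in self.cigar_ops if op in _CONSUMES_QUERY and op != "H")
        if qlen != len(self.seq):
            raise ValueError(
                f"{self.read_name}: CIGAR consumes {qlen} query bases, "
                f"sequence has {len(self.seq)}"
            )

    @property
    def cigar_ops(self) -> list[tuple[int, str]]:
        return parse_cigar(self.cigar)

    @property
    def ref_end(self) -> int:
        """0-based exclusive end of the aligned reference span."""
        return self.pos0 + sum(n for n, op in self.cigar_ops if op in _CONSUMES_REF)

    @property
    def unclipped_pos0(self) -> int:
        """0-based 5'-most unclipped coordinate.

        For a forward read this is the alignment start minus leading
        clips; for a reverse read the 5' end is the rightmost aligned
        base plus trailing clips. Duplicate marking keys on this value
        so that PCR copies that were soft-clipped differently still
        collapse (the Picard convention).
        """
        ops = self.cigar_ops
        if not self.is_reverse:
            lead = 0
            for n, op in ops:
                if op in "SH":
                    lead += n
                else:
                    break
            return self.pos0 - lead
        trail = 0
        for n, op in reversed(ops):
            if op in "SH":
                trail += n
            else:
                break
        return self.ref_end - 1 + trail

    @property
    def qual_sum(self) -> int:
        return int(sum(self.base_quals))

    def aligned_pairs(self) -> Iterator[tuple[int, int]]:
        """Yield (query_offset, reference_pos0) for every aligned base."""
        q, r = 0, self.pos0
        for n, op in self.cigar_ops:
            if op in _ALIGNED:
                for i in range(n):
                    yield q + i, r + i
                q += n
                r += n
            elif op in "IS":
                q += n
            elif op in "DN":
                r += n
            # H, P consume neither

    def base_at(self, rpos: int) -> Optional[tuple[str, int]]:
        """(base, base_quality) aligned over reference position, or None."""
        for q, r in self.aligned_pairs():
            if r == rpos:
                return self.seq[q], int(self.base_quals[q])
            if r > rpos:
                return None
        return None


class DuplicateKey(NamedTuple):
    """Reads sharing all five fields are PCR copies of one molecule."""

    chrom: str
    unclipped_pos0: int
    is_reverse: bool
    umi: str
    cb: str


@dataclass
class CellTypeMap:
    """Barcode -> cell-type assignment driving pseudo-bulk construction."""

    entries: dict[str, str]
    cell_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty cell-type map")
        seen: list[str] = []
        for label in self.entries.values():
            if not label:
                raise ValueError("empty cell-type label")
            if label not in seen:
                seen.append(label)
        if not self.cell_types:
            self.cell_types = seen
        else:
            missing = set(seen) - set(self.cell_types)
            if missing:
                raise ValueError(f"labels missing from cell_types: {sorted(missing)}")

    @classmethod
    def from_tsv(cls, path: str) -> "CellTypeMap":
        """Read a 2-column (barcode, cell_type) TSV; '#' comments allowed."""
        entries: dict[str, str] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2 or not fields[0] or not fields[1]:
                    raise ValueError(f"{path}:{lineno}: expected 'barcode<TAB>cell_type', got {line!r}")
                entries[fields[0]] = fields[1]
        return cls(entries=entries)


@dataclass(frozen=True)
class CandidateSite:
    """A mismatch position, expressed on the gene (transcribed) strand."""

    chrom: str
    pos0: int
    gene_strand: str
    ref_on_strand: str
    alt_on_strand: str
    n_ref: int
    n_alt: int
    depth: int
    is_known_snp: bool = False

    def __post_init__(self) -> None:
        if self.alt_on_strand == self.ref_on_strand:
            raise ValueError("alt equals ref")
        if self.n_ref + self.n_alt > self.depth:
            raise ValueError("allele counts exceed depth")


@dataclass
class EditingSite:
    """A called A-to-I editing site on one cell type's pseudo-bulk.

    ``editing_level`` is the fraction of filtered, non-duplicate calls
    carrying G on the gene strand; ``p_edit`` is the confidence score in
    [0, 1].
    """

    chrom: str
    pos0: int
    gene_strand: str
    ref_on_strand: str
    alt_on_strand: str
    depth: int
    n_alt: int
    editing_level: float
    p_edit: float
    in_alu: bool
    cell_type: str = ""
    gene_id: Optional[str] = None

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos0, self.gene_strand)
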