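"""Alignment-record plumbing.

Pseudo-bulk construction (splitting reads by cell type), UMI/cell-barcode
aware PCR-duplicate marking, and strand partitioning. Single-cell
libraries tag each read with a cell barcode (CB) and a unique molecular
identifier (UMI): reads with identical mapping coordinate, orientation,
UMI *and* barcode are PCR copies of one captured molecule, whereas a
bulk-style, position-only duplicate rule (Picard's) collapses distinct
molecules that merely co-locate and thereby discards usable reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

from .model import AlignedRead, CellTypeMap, DuplicateKey

logger = logging.getLogger(__name__)

DedupMode = Literal["umi", "position"]


def split_by_cell_type(
    reads: Iterable[AlignedRead], ctmap: CellTypeMap
) -> tuple[dict[str, list[AlignedRead]], list[AlignedRead]]:
    """Partition reads into per-cell-type pseudo-bulk collections.

    Returns ``(by_type, unassigned)``. Reads without a CB tag, or with a
    barcode absent from the map, go to ``unassigned``. Input order is
    preserved within each collection.
    """
    by_type: dict[str, list[AlignedRead]] = {ct: [] for ct in ctmap.cell_types}
    unassigned: list[AlignedRead] = []
    for read in reads:
        label = ctmap.entries.get(read.cb) if read.cb is not None else None
        if label is None:
            unassigned.append(read)
        else:
            by_type[label].append(read)
    return by_type, unassigned


@dataclass
class DedupResult:
    retained: list[AlignedRead]
    n_duplicates: int
    n_untagged: int = 0
    all_reads: list[AlignedRead] = field(default_factory=list)


def _position_key(read: AlignedRead) -> tuple:
    return (read.chrom, read.unclipped_pos0, read.is_reverse)


def _umi_key(read: AlignedRead) -> DuplicateKey:
    return DuplicateKey(read.chrom, read.unclipped_pos0, read.is_reverse, read.umi, read.cb)


def mark_duplicates(reads: Iterable[AlignedRead], mode: DedupMode = "umi") -> DedupResult:
    """Mark PCR duplicates, retaining the highest-base-quality read per group.

    ``mode="umi"`` groups by (chrom, unclipped 5' position, orientation,
    UMI, cell barcode): only reads from the same cell with the same UMI
    are duplicates. ``mode="position"`` emulates the bulk-style baseline
    keyed on (chrom, unclipped 5' position, orientation) alone.

    Within each group the read maximizing the summed per-base Phred
    quality wins; ties break to the lexicographically smallest read name
    for determinism. Reads lacking a CB or UMI tag (umi mode only) are
    never marked duplicate and are counted in ``n_untagged``.

    The ``is_duplicate`` flag is set/cleared in place on every read.
    """
    groups: dict[object, list[AlignedRead]] = {}
    untagged: list[AlignedRead] = []
    ordered: list[AlignedRead] = []
    for read in reads:
        ordered.append(read)
        if mode == "umi":
            if read.cb is None or read.umi is None:
                read.is_duplicate = False
                untagged.append(read)
                continue
            key: object = _umi_key(read)
        else:
            key = _position_key(read)
        groups.setdefault(key, []).append(read)

    n_dup = 0
    for members in groups.values():
        winner = min(members, key=lambda r: (-r.qual_sum, r.read_name))
        for r in members:
            r.is_duplicate = r is not winner
        n_dup += len(members) - 1
    if untagged:
        logger.warning("%d reads lack CB/UMI tags; retained unconditionally", len(untagged))
    retained = [r for r in ordered if not r.is_duplicate]
    return DedupResult(retained=retained, n_duplicates=n_dup, n_untagged=len(untagged), all_reads=ordered)


def split_by_strand(
    reads: Iterable[AlignedRead],
) -> tuple[list[AlignedRead], list[AlignedRead]]:
    """Split reads on the flag-16 orientation bit: (forward, reverse)."""
    forward: list[AlignedRead] = []
    reverse: list[AlignedRead] = []
    for read in reads:
        (reverse if read.is_reverse else forward).append(read)
    return forward, reverse


def count_available_reads(reads: Iterable[AlignedRead]) -> int:
    """Number of reads not flagged as duplicates."""
    return sum(1 for r in reads if not r.is_duplicate)
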