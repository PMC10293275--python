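"""Per-cell edited/unedited assignment and expression comparison.

After a site is called on a cell type's pseudo-bulk, individual cells
are revisited: a cell with at least one deduplicated, quality-passing
read carrying the edited base at the site is an *edited cell*. The
proportion of edited cells is computed over cells that express the
gene, and the expression of edited versus unedited cells is compared
with a two-sided Wilcoxon rank-sum test (exact enumeration for small
groups, tie-corrected normal approximation otherwise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from .model import AlignedRead, EditingSite


@dataclass(frozen=True)
class CellEditCall:
    site_key: tuple
    barcode: str
    n_support: int  # edited-base reads passing filters

    @property
    def edited(self) -> bool:
        return self.n_support >= 1


def assign_edited_cells(
    reads: Iterable[AlignedRead],
    site: EditingSite,
    min_mq: int = 20,
    min_bq: int = 20,
) -> list[CellEditCall]:
    """Count per-cell reads supporting the edit at one site.

    ``reads`` must be duplicate-marked; duplicates, reads below the
    mapping/base-quality floors and reads without a cell barcode are
    ignored. The edited base is G on the gene strand, i.e. G on the
    forward reference for a '+' gene and C for a '-' gene. A barcode is
    reported whenever it has at least one passing read over the site;
    ``edited`` is true when at least one of them carries the edit.
    """
    edited_fwd = "G" if site.gene_strand == "+" else "C"
    support: dict[str, int] = {}
    for read in reads:
        if read.is_duplicate or read.cb is None or read.mapq < min_mq:
            continue
        if read.chrom != site.chrom or not (read.pos0 <= site.pos0 < read.ref_end):
            continue
        hit = read.base_at(site.pos0)
        if hit is None or hit[1] < min_bq:
            continue
        support.setdefault(read.cb, 0)
        if hit[0].upper() == edited_fwd:
            support[read.cb] += 1
    return [CellEditCall(site.key, cb, n) for cb, n in sorted(support.items())]


def edited_cell_set(calls: Iterable[CellEditCall]) -> set[str]:
    return {c.barcode for c in calls if c.edited}


@dataclass
class ExpressionVector:
    """One gene's expression across cells.

    ``values`` maps barcode -> (normalized) expression; ``expressed``
    is the set of barcodes with raw count > 0 for the gene.
    """

    gene_id: str
    values: dict[str, float]
    expressed: set[str]

    def __post_init__(self) -> None:
        extra = self.expressed - set(self.values)
        if extra:
            raise ValueError(f"expressed barcodes missing values: {sorted(extra)[:3]}")


def edited_fraction(calls: Iterable[CellEditCall], expr: ExpressionVector) -> Optional[float]:
    """Proportion of expressing cells edited at any of the gene's sites.

    Cells that do not express the gene are excluded from numerator and
    denominator. Returns None when no cell expresses the gene.
    """
    if not expr.expressed:
        return None
    edited = edited_cell_set(calls) & expr.expressed
    return len(edited) / len(expr.expressed)


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def rank_sum_test(x: Sequence[float], y: Sequence[float], exact_max_n: int = 10) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    When both groups have at most ``exact_max_n`` observations the
    p-value is computed by exact enumeration over all C(n1+n2, n1)
    assignments of the pooled (mid-)ranks: the proportion of splits
    whose rank-sum deviates from its mean at least as much as observed.
    Larger samples use the tie-corrected normal approximation without
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    dev = abs(w_obs - mu)
    if n1 <= exact_max_n and n2 <= exact_max_n:
        count = 0
        total = 0
        for idx in combinations(range(n), n1):
            total += 1
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9:
                count += 1
        return count / total
    # tie-corrected variance of the rank sum
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    z = (w_obs - mu) / math.sqrt(sigma2)
    return float(math.erfc(abs(z) / math.sqrt(2.0)))


@dataclass
class ExpressionComparison:
    log2_fold_change: float
    p_value: float
    n_edited: int
    n_unedited: int


def compare_expression(
    expr: ExpressionVector,
    edited: set[str],
    unedited: set[str],
    eps: float = 1e-9,
) -> Optional[ExpressionComparison]:
    """Expression of edited vs unedited cells for one gene.

    Groups must be disjoint; cells missing from the expression vector
    are dropped. log2FC compares group means with an ``eps`` guard for
    zero means; the p-value is the two-sided Wilcoxon rank-sum test.
    Returns None if either group is empty after filtering.
    """
    if edited & unedited:
        raise ValueError("edited and unedited barcode sets overlap")
    xs = [expr.values[cb] for cb in sorted(edited) if cb in expr.values]
    ys = [expr.values[cb] for cb in sorted(unedited) if cb in expr.values]
    if not xs or not ys:
        return None
    log2fc = math.log2(float(np.mean(xs)) + eps) - math.log2(float(np.mean(ys)) + eps)
    p = rank_sum_test(xs, ys)
    return ExpressionComparison(log2fc, p, len(xs), len(ys))


def normalize_expression(counts: Mapping[str, Mapping[str, float]], scale: float = 1e4) -> dict[str, dict[str, float]]:
    """Library-size normalize then log1p a genes x barcodes count mapping.

    ``counts[gene][barcode]`` are raw molecule counts. Each cell is
    scaled to ``scale`` total counts before log1p, mirroring the common
    single-cell normalization.
    """
    totals: dict[str, float] = {}
    for gene_counts in counts.values():
        for cb, v in gene_counts.items():
            totals[cb] = totals.get(cb, 0.0) + v
    out: dict[str, dict[str, float]] = {}
    for gene, gene_counts in counts.items():
        out[gene] = {
            cb: math.log1p(v / totals[cb] * scale) if totals.get(cb) else 0.0
            for cb, v in gene_counts.items()
        }
    return out
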