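"""Cross-cell-type editing landscape: matrix construction, editing-pattern
classification, and weighted-correlation co-editing modules.

The editing matrix holds one row per site covered at >=30x in *every*
cell type, with the confidence score ``p_edit`` per cell type (0 means
covered but not edited there). Patterns follow the landscape taxonomy:
a site edited in all cell types is *shared*, one edited in exactly one
lineage group (lymphoid, myeloid, HSC/MPP) is *group-specific*, one
edited in exactly one cell type is *type-specific*, anything else is
*other*.

Co-editing modules use the weighted-correlation-network recipe: a soft
threshold power is chosen as the smallest exponent whose network is
approximately scale-free (R^2 of the log-log degree fit >= 0.8), the
adjacency ``|cor|^beta`` is transformed into a topological overlap
matrix (TOM), and modules come from average-linkage clustering of
1 - TOM with a minimum module size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .model import EditingSite

SiteKey = tuple[str, int, str]  # (chrom, pos0, gene_strand)


@dataclass
class EditingMatrix:
    """Sites x cell types matrix of editing confidence scores."""

    site_keys: list[SiteKey]
    cell_types: list[str]
    p_edit: np.ndarray  # float, shape (n_sites, n_cell_types)
    covered: np.ndarray  # bool, same shape

    def __post_init__(self) -> None:
        self.p_edit = np.asarray(self.p_edit, dtype=float)
        self.covered = np.asarray(self.covered, dtype=bool)
        if self.p_edit.shape != (len(self.site_keys), len(self.cell_types)):
            raise ValueError("p_edit shape does not match keys/cell types")
        if np.any((self.p_edit > 0) & ~self.covered):
            raise ValueError("p_edit > 0 at uncovered entries")

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index([f"{c}:{p}:{s}" for c, p, s in self.site_keys], name="site")
        return pd.DataFrame(self.p_edit, index=idx, columns=self.cell_types)


def build_matrix(
    sites_by_cell_type: Mapping[str, Sequence[EditingSite]],
    depth_fn: Callable[[SiteKey, str], int],
    cell_types: Optional[Sequence[str]] = None,
    min_depth: int = 30,
) -> EditingMatrix:
    """Assemble the cross-cell-type matrix from per-type site tables.

    ``depth_fn(site_key, cell_type)`` answers the filtered coverage of a
    site in a cell type's pseudo-bulk. Rows are the union of called
    sites restricted to those with depth >= ``min_depth`` in every cell
    type; entries are the called ``p_edit`` or 0 where covered but not
    called.
    """
    if cell_types is None:
        cell_types = list(sites_by_cell_type)
    missing = [ct for ct in cell_types if ct not in sites_by_cell_type]
    if missing:
        raise KeyError(f"cell types absent from site tables: {missing}")
    called: dict[SiteKey, dict[str, float]] = {}
    for ct in cell_types:
        for site in sites_by_cell_type[ct]:
            called.setdefault(site.key, {})[ct] = site.p_edit
    keys: list[SiteKey] = []
    rows: list[list[float]] = []
    for key in sorted(called):
        if all(depth_fn(key, ct) >= min_depth for ct in cell_types):
            keys.append(key)
            rows.append([called[key].get(ct, 0.0) for ct in cell_types])
    p = np.array(rows, dtype=float) if rows else np.empty((0, len(cell_types)))
    covered = np.ones_like(p, dtype=bool)
    return EditingMatrix(keys, list(cell_types), p, covered)


@dataclass
class LineageConfig:
    """Named, disjoint groups of cell types (differentiation branches)."""

    groups: dict[str, frozenset] = field(
        default_factory=lambda: {
            "lymphoid": frozenset({"LMPP", "MLP"}),
            "myeloid": frozenset({"MEMP", "CMP", "GMP", "MEP"}),
            "HSC/MPP": frozenset({"HSC", "MPP"}),
        }
    )

    def __post_init__(self) -> None:
        self.groups = {k: frozenset(v) for k, v in self.groups.items()}
        seen: set = set()
        for name, members in self.groups.items():
            if seen & members:
                raise ValueError(f"lineage group {name!r} overlaps another group")
            seen |= members


class PatternLabel(NamedTuple):
    kind: str  # shared | group_specific | type_specific | other
    target: str = ""

    def __str__(self) -> str:
        return self.kind if not self.target else f"{self.kind}:{self.target}"


def classify_patterns(
    matrix: EditingMatrix,
    lineages: LineageConfig = LineageConfig(),
    edited_threshold: float = 0.0,
) -> dict[SiteKey, PatternLabel]:
    """Label each site's cross-cell-type editing pattern.

    A site is *edited* in a cell type when its p_edit exceeds
    ``edited_threshold`` (default: any positive score, i.e. the site
    was called there). Labels are mutually exclusive and exhaustive.
    """
    all_types = set(matrix.cell_types)
    labels: dict[SiteKey, PatternLabel] = {}
    for i, key in enumerate(matrix.site_keys):
        edited = {ct for j, ct in enumerate(matrix.cell_types) if matrix.p_edit[i, j] > edited_threshold}
        if edited == all_types:
            labels[key] = PatternLabel("shared")
            continue
        if len(edited) == 1:
            labels[key] = PatternLabel("type_specific", next(iter(edited)))
            continue
        for name, members in lineages.groups.items():
            if edited == (members & all_types) and edited:
                labels[key] = PatternLabel("group_specific", name)
                break
        else:
            labels[key] = PatternLabel("other")
    return labels


# ---------------------------------------------------------------------------
# Weighted correlation network


def _correlation(profiles: np.ndarray) -> np.ndarray:
    """Pearson correlation between rows; rows must have variance."""
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(profiles)
    return np.nan_to_num(np.atleast_2d(cor), nan=0.0)


def adjacency_from_profiles(profiles: np.ndarray, power: int) -> np.ndarray:
    """Unsigned adjacency |cor|^power with zero diagonal."""
    a = np.abs(_correlation(profiles)) ** power
    np.fill_diagonal(a, 0.0)
    return a


def scale_free_r2(connectivity: np.ndarray, n_bins: int = 10) -> float:
    """Signed R^2 of the log-log degree-distribution fit.

    Connectivities are split into ``n_bins`` equal-width bins over
    [min(k), max(k)]; the fit regresses log10(bin frequency) on
    log10(mean connectivity in bin), skipping empty bins. A scale-free
    network has *decreasing* frequency in k, so the index is
    ``-sign(slope) * R^2`` (negative for an increasing fit), the
    convention of the weighted-correlation-network literature.
    Degenerate inputs (fewer than 3 usable bins) return 0.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 3 or np.isclose(k.min(), k.max()):
        return 0.0
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    freqs, means = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        freqs.append(mask.sum() / k.size)
        means.append(k[mask].mean())
    if len(freqs) < 3:
        return 0.0
    fit = linregress(np.log10(means), np.log10(freqs))
    r2 = float(fit.rvalue**2) * (-float(np.sign(fit.slope)))
    return r2 if np.isfinite(r2) else 0.0


def pick_soft_power(
    profiles: np.ndarray,
    powers: Sequence[int] = tuple(range(1, 21)),
    r2_cutoff: float = 0.8,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Smallest power whose network reaches the scale-free R^2 cutoff.

    ``profiles`` is sites x samples (rows with fewer than 2 distinct
    values are dropped before correlating). Returns (power, table of
    per-power R^2). If no power reaches the cutoff, the argmax-R^2
    power is returned with a warning.
    """
    x = np.asarray(profiles, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a sites x samples matrix with >= 2 columns")
    keep = np.array([np.unique(row).size > 1 for row in x])
    x = x[keep]
    if x.shape[0] < 3:
        raise ValueError("fewer than 3 variable site profiles")
    records = []
    for p in powers:
        a = adjacency_from_profiles(x, p)
        r2 = scale_free_r2(a.sum(axis=1), n_bins)
        records.append({"power": p, "r2": r2})
    table = pd.DataFrame.from_records(records)
    reaching = table[table["r2"] >= r2_cutoff]
    if len(reaching):
        beta = int(reaching["power"].iloc[0])
    else:
        beta = int(table.loc[table["r2"].idxmax(), "power"])
        warnings.warn(
            f"no power reached scale-free R^2 >= {r2_cutoff}; using argmax power {beta}",
            stacklevel=2,
        )
    return beta, table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a symmetric, zero-diagonal adjacency.

    tom_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) for
    i != j; tom_ii = 1. The corresponding clustering dissimilarity is
    1 - TOM.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a  # diagonal terms vanish because diag(a) == 0
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    dissimilarity: np.ndarray,
    min_module_size: int = 30,
    cut_height: float = 0.995,
) -> np.ndarray:
    """Average-linkage modules from a TOM dissimilarity.

    The dendrogram is cut at ``cut_height``; clusters smaller than
    ``min_module_size`` are labelled 0 (unassigned) and surviving
    modules are renumbered 1.. by decreasing size.
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if n == 0:
        return np.zeros(0, dtype=int)
    if n == 1:
        return np.array([1 if min_module_size <= 1 else 0])
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = [(int((raw == c).sum()), int(np.argmax(raw == c)), c) for c in np.unique(raw)]
    next_id = 1
    for size, _, c in sorted(sizes, key=lambda t: (-t[0], t[1])):
        if size >= min_module_size:
            labels[raw == c] = next_id
            next_id += 1
    return labels


@dataclass
class CoeditNetwork:
    """Bundle of the co-editing network analysis for one editing matrix."""

    power: int
    power_table: pd.DataFrame
    adjacency: np.ndarray
    tom: np.ndarray
    module_labels: np.ndarray
    site_keys: list[SiteKey]

    @classmethod
    def from_matrix(
        cls,
        matrix: EditingMatrix,
        powers: Sequence[int] = tuple(range(1, 21)),
        r2_cutoff: float = 0.8,
        min_module_size: int = 30,
        cut_height: float = 0.995,
    ) -> "CoeditNetwork":
        x = matrix.p_edit
        keep = np.array([np.unique(row).size > 1 for row in x])
        kept_keys = [k for k, m in zip(matrix.site_keys, keep) if m]
        x = x[keep]
        beta, table = pick_soft_power(x, powers, r2_cutoff)
        adj = adjacency_from_profiles(x, beta)
        tom = tom_similarity(adj)
        labels = detect_modules(1.0 - tom, min_module_size, cut_height)
        return cls(beta, table, adj, tom, labels, kept_keys)
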