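"""Independent oracles and small generators shared across tests.

Everything here deliberately re-derives quantities from first principles
(brute-force grouping, sliding-window comparison, literal formula loops,
pairwise-count rank statistics) so the package implementation is checked
against code that shares none of its machinery.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from screditome.annotate import GeneModel, RepeatInterval
from screditome.bamops import mark_duplicates, split_by_cell_type
from screditome.editcall import CallParams, call_editome
from screditome.model import AlignedRead, CellTypeMap, revcomp


# ---------------------------------------------------------------------------
# random reads with key collisions (for dedup tests)


def random_reads(
    seed: int,
    n: int,
    n_positions: int = 12,
    n_umis: int = 6,
    n_cbs: int = 4,
    chroms: tuple[str, ...] = ("chr1", "chr2"),
) -> list[AlignedRead]:
    """Reads drawn from small key pools so duplicate groups are frequent."""
    rng = np.random.default_rng(seed)
    reads = []
    for i in range(n):
        pos = int(rng.integers(0, n_positions)) * 50 + 10
        clip = int(rng.integers(0, 2)) * 5
        rev = bool(rng.integers(0, 2))
        if clip:
            cigar = "45M5S" if rev else "5S45M"
            pos0 = pos if rev else pos + clip
        else:
            cigar, pos0 = "50M", pos
        reads.append(
            AlignedRead(
                read_name=f"r{i:05d}",
                chrom=chroms[int(rng.integers(0, len(chroms)))],
                pos0=pos0,
                is_reverse=rev,
                cigar=cigar,
                seq="".join(rng.choice(list("ACGT"), 50)),
                base_quals=rng.integers(10, 41, 50).tolist(),
                cb=f"CB{int(rng.integers(0, n_cbs))}",
                umi=f"UMI{int(rng.integers(0, n_umis))}",
            )
        )
    return reads


def brute_force_retained(reads) -> set[str]:
    """Names of reads a literal 5-tuple grouping with max-quality pick keeps."""
    groups: dict[tuple, list] = {}
    for r in reads:
        if r.cb is None or r.umi is None:
            groups[("untagged", r.read_name)] = [r]
            continue
        key = (r.chrom, r.unclipped_pos0, r.is_reverse, r.umi, r.cb)
        groups.setdefault(key, []).append(r)
    kept = set()
    for members in groups.values():
        best = sorted(members, key=lambda r: (-sum(r.base_quals), r.read_name))[0]
        kept.add(best.read_name)
    return kept


# ---------------------------------------------------------------------------
# shared pipeline shortcut on a SimResult


def call_sim(sim, params: CallParams = CallParams()):
    """Split -> dedup -> call a simulation; returns (by_type, sites_by_type)."""
    ctmap = CellTypeMap(entries=dict(sim.truth.barcode_map), cell_types=list(sim.config.cell_types))
    by_type, _ = split_by_cell_type(sim.reads, ctmap)
    for rs in by_type.values():
        mark_duplicates(rs)
    sites = call_editome(
        by_type, sim.genome.seqs, sim.genome.genes, sim.genome.repeats, sim.genome.snp_index(), params
    )
    return by_type, sites


# ---------------------------------------------------------------------------
# genome mirroring (coordinate-flip + reverse complement)


def mirror_reads_and_genome(sim):
    """Reverse-complement every chromosome and flip all coordinates.

    A site at pos p on strand s must then be called at L-1-p on the
    opposite strand with the same alleles on the gene strand.
    """
    lengths = sim.genome.chrom_lengths
    seqs = {c: revcomp(s) for c, s in sim.genome.seqs.items()}

    def flip_iv(chrom, iv):
        L = lengths[chrom]
        return (L - iv[1], L - iv[0])

    genes = []
    for g in sim.genome.genes:
        genes.append(
            GeneModel(
                gene_id=g.gene_id,
                chrom=g.chrom,
                strand="-" if g.strand == "+" else "+",
                exons=sorted(flip_iv(g.chrom, iv) for iv in g.exons),
                cds=sorted(flip_iv(g.chrom, iv) for iv in g.cds),
                utr5=sorted(flip_iv(g.chrom, iv) for iv in g.utr5),
                utr3=sorted(flip_iv(g.chrom, iv) for iv in g.utr3),
            )
        )
    repeats = [
        RepeatInterval(r.chrom, *flip_iv(r.chrom, (r.start0, r.end0)), r.family)
        for r in sim.genome.repeats
    ]
    snp_index = frozenset((c, lengths[c] - 1 - p) for c, p in sim.genome.snp_index())

    def flip_cigar(cigar, read):
        return "".join(f"{n}{op}" for n, op in reversed(read.cigar_ops))

    reads = []
    for r in sim.reads:
        L = lengths[r.chrom]
        reads.append(
            AlignedRead(
                read_name=r.read_name,
                chrom=r.chrom,
                pos0=L - r.ref_end,
                is_reverse=not r.is_reverse,
                cigar=flip_cigar(r.cigar, r),
                seq=revcomp(r.seq),
                base_quals=list(reversed(list(r.base_quals))),
                mapq=r.mapq,
                cb=r.cb,
                umi=r.umi,
                is_duplicate=r.is_duplicate,
            )
        )
    return seqs, genes, repeats, snp_index, reads


# ---------------------------------------------------------------------------
# seed-match oracle: literal sliding-window comparison


def brute_force_seed_matches(utr: str, mirna: str) -> list[tuple[int, int, str]]:
    utr = utr.upper().replace("U", "T")
    mirna = mirna.upper().replace("U", "T")
    rc6 = revcomp(mirna[1:7])
    rc7 = revcomp(mirna[1:8])
    out = []
    for s in range(len(utr)):
        w7 = utr[s : s + 7]
        w6 = utr[s : s + 6]
        if w7 == rc7:
            if s + 7 < len(utr) and utr[s + 7] == "A":
                out.append((s, s + 8, "8mer"))
            else:
                out.append((s, s + 7, "7mer-m8"))
        elif w6 == rc6 and len(w6) == 6:
            if s + 6 < len(utr) and utr[s + 6] == "A":
                out.append((s, s + 7, "7mer-A1"))
            else:
                out.append((s, s + 6, "6mer"))
    return out


# ---------------------------------------------------------------------------
# TOM oracle: literal triple loop


def tom_triple_loop(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    k = [sum(a[i, u] for u in range(n) if u != i) for i in range(n)]
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l_ij = sum(a[i, u] * a[u, j] for u in range(n) if u != i and u != j)
            tom[i, j] = (l_ij + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


# ---------------------------------------------------------------------------
# rank-sum oracle: pairwise-count statistic over explicit splits


def exact_ranksum_oracle(x, y) -> float:
    """Two-sided exact p via the Mann-Whitney pairwise-count statistic."""
    pooled = list(x) + list(y)
    n1, n = len(x), len(x) + len(y)

    def u_stat(group, rest):
        u = 0.0
        for a in group:
            for b in rest:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    obs = u_stat(list(x), list(y))
    mu = n1 * (n - n1) / 2.0
    dev = abs(obs - mu)
    hits = total = 0
    for idx in combinations(range(n), n1):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(n) if i not in idx]
        total += 1
        if abs(u_stat(grp, rest) - mu) >= dev - 1e-9:
            hits += 1
    return hits / total
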