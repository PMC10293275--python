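"""Seeded generator of a toy editing study: genome, annotations, barcoded
cell populations, and UMI-tagged aligned reads with planted A-to-I
editing sites, heterozygous SNPs, PCR duplicates and sequencing errors.

The generator emulates the data model of a strand-specific, droplet
scRNA-seq experiment at the aligned-record level: each captured mRNA
molecule gets a cell barcode, a UMI and one 100-bp read confined to a
single exon (no splice-junction reads); PCR re-amplification re-emits a
molecule's read with fresh base qualities and errors; genes transcribed
from the minus strand yield flag-16 (reverse) reads. Editing is a
molecule-level event: at a planted site, a molecule from a cell of type
t carries G (on the gene strand) with probability phi(site, t), where
the per-type phi vector encodes the site's cross-cell-type pattern
(shared / lineage-group-specific / type-specific). Every emitted read
is traceable to a ground-truth record, which the test-suite uses as the
oracle for duplicate marking, site recovery, annotation, patterns and
per-cell edited assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import GeneModel, RepeatInterval
from .model import AlignedRead

_DEFAULT_CELL_TYPES = ("HSC", "MPP", "LMPP", "MLP", "MEMP", "CMP", "GMP", "MEP")
_DEFAULT_LINEAGES = {
    "lymphoid": ("LMPP", "MLP"),
    "myeloid": ("MEMP", "CMP", "GMP", "MEP"),
    "HSC/MPP": ("HSC", "MPP"),
}
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Defaults emulate a small strand-specific droplet scRNA-seq study:
    8 annotated progenitor populations, 16-bp cell barcodes, 10-bp
    UMIs, 100-bp transcript reads, ~40x pseudo-bulk coverage per cell
    type, a 30% PCR duplication rate and a 1e-3 per-base error rate.
    Planted editing sites concentrate in Alu repeats (94%) and 3'UTRs,
    with editing levels drawn from {0.1, 0.3, 0.6, 1.0}.
    """

    # genome layout
    n_chroms: int = 2
    n_genes: int = 8
    exon_lengths: tuple[int, ...] = (400, 550)
    intron_length: int = 300
    utr5_length: int = 150
    cds_length: int = 350
    intergenic_gap: int = 400
    # repeats
    alu_fraction: float = 0.3  # of combined 3'UTR + intron space
    alu_length: int = 120
    # populations
    cell_types: tuple[str, ...] = _DEFAULT_CELL_TYPES
    lineages: dict = field(default_factory=lambda: dict(_DEFAULT_LINEAGES))
    cells_per_type: int = 20
    # library
    read_length: int = 100
    cb_length: int = 16
    umi_length: int = 10
    mean_depth: float = 40.0  # target pseudo-bulk coverage per cell type
    low_expression_genes: int = 1  # trailing genes expressed at low_expression_factor
    low_expression_factor: float = 0.4
    duplication_rate: float = 0.3
    error_rate: float = 0.001
    softclip_prob: float = 0.15
    softclip_length: int = 5
    base_qual_range: tuple[int, int] = (30, 40)
    mapq: int = 60
    # planted variation
    n_editing_sites: int = 40
    phi_levels: tuple[float, ...] = (0.1, 0.3, 0.6, 1.0)
    pattern_fractions: dict = field(
        default_factory=lambda: {"shared": 0.4, "group_specific": 0.3, "type_specific": 0.3}
    )
    edit_alu_fraction: float = 0.94
    edit_element_weights: dict = field(
        default_factory=lambda: {"3UTR": 0.75, "CDS": 0.15, "5UTR": 0.10}
    )
    n_snps: int = 12
    snp_alt_fraction: float = 0.5

    def validate(self) -> None:
        for name in ("alu_fraction", "duplication_rate", "error_rate", "softclip_prob",
                     "edit_alu_fraction", "snp_alt_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(not 0.0 < p <= 1.0 for p in self.phi_levels):
            raise ValueError("phi levels must be in (0, 1]")
        if min(self.exon_lengths) < 2 * self.read_length:
            raise ValueError("exons must be at least twice the read length")
        if self.utr5_length + self.cds_length >= sum(self.exon_lengths):
            raise ValueError("UTR5 + CDS longer than the transcript")
        if self.n_genes < self.n_chroms:
            raise ValueError("need at least one gene per chromosome")


@dataclass
class SyntheticGenome:
    seqs: dict[str, str]
    genes: list[GeneModel]
    repeats: list[RepeatInterval]
    snps: pd.DataFrame  # chrom, pos0, gene_id, ref_fwd, alt_fwd, alt_fraction

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.seqs.items()}

    def snp_index(self) -> frozenset:
        return frozenset(zip(self.snps["chrom"], self.snps["pos0"]))


def _transcript_structure(exons: list[tuple[int, int]], strand: str, utr5_len: int, cds_len: int):
    """Split exons (genomic order) into 5'UTR / CDS / 3'UTR intervals."""
    ordered = exons if strand == "+" else list(reversed(exons))
    sections = [("utr5", utr5_len), ("cds", cds_len), ("utr3", sum(e - s for s, e in exons) - utr5_len - cds_len)]
    out: dict[str, list[tuple[int, int]]] = {"utr5": [], "cds": [], "utr3": []}
    sec_iter = iter(sections)
    name, remaining = next(sec_iter)
    for s, e in ordered:
        # walk the exon in transcript direction
        cursor = s if strand == "+" else e
        left = e - s
        while left > 0:
            take = min(left, remaining)
            if strand == "+":
                out[name].append((cursor, cursor + take))
                cursor += take
            else:
                out[name].append((cursor - take, cursor))
                cursor -= take
            left -= take
            remaining -= take
            if remaining == 0:
                try:
                    name, remaining = next(sec_iter)
                except StopIteration:
                    left = 0
    return {k: sorted(v) for k, v in out.items()}


def simulate_genome(cfg: SimConfig, seed: int) -> SyntheticGenome:
    """Deterministically generate the toy reference, gene models, Alu
    intervals and heterozygous SNPs."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 101)))
    gene_span = sum(cfg.exon_lengths) + cfg.intron_length * (len(cfg.exon_lengths) - 1)
    per_chrom = [cfg.n_genes // cfg.n_chroms + (1 if i < cfg.n_genes % cfg.n_chroms else 0) for i in range(cfg.n_chroms)]
    seqs: dict[str, np.ndarray] = {}
    genes: list[GeneModel] = []
    gi = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        length = cfg.intergenic_gap + per_chrom[ci] * (gene_span + cfg.intergenic_gap)
        seqs[chrom] = _BASES[rng.integers(0, 4, size=length)]
        cursor = cfg.intergenic_gap
        for _ in range(per_chrom[ci]):
            strand = "+" if gi % 2 == 0 else "-"
            exons: list[tuple[int, int]] = []
            pos = cursor
            for li, elen in enumerate(cfg.exon_lengths):
                exons.append((pos, pos + elen))
                pos += elen + (cfg.intron_length if li < len(cfg.exon_lengths) - 1 else 0)
            structure = _transcript_structure(exons, strand, cfg.utr5_length, cfg.cds_length)
            genes.append(
                GeneModel(
                    gene_id=f"G{gi + 1:03d}",
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds=structure["cds"],
                    utr5=structure["utr5"],
                    utr3=structure["utr3"],
                )
            )
            cursor += gene_span + cfg.intergenic_gap
            gi += 1

    repeats = _place_alus(cfg, genes, rng)
    snps = _plant_snps(cfg, genes, seqs, repeats, rng)
    return SyntheticGenome({c: "".join(s) for c, s in seqs.items()}, genes, repeats, snps)


def _place_alus(cfg: SimConfig, genes: list[GeneModel], rng: np.random.Generator) -> list[RepeatInterval]:
    """Tile Alu intervals over a target fraction of 3'UTR + intron space."""
    repeats: list[RepeatInterval] = []
    for gene in genes:
        regions = sorted(gene.utr3) + gene.introns()
        for s, e in regions:
            span = e - s
            n = int(round(cfg.alu_fraction * span / cfg.alu_length))
            if n == 0:
                continue
            slot = span // n
            if slot < cfg.alu_length:
                n = span // cfg.alu_length
                slot = span // max(n, 1)
            for i in range(n):
                lo = s + i * slot
                hi = min(s + (i + 1) * slot, e) - cfg.alu_length
                if hi < lo:
                    continue
                start = int(rng.integers(lo, hi + 1))
                repeats.append(RepeatInterval(gene.chrom, start, start + cfg.alu_length, "AluY"))
    return sorted(repeats, key=lambda r: (r.chrom, r.start0))


def _plateau(exon: tuple[int, int], read_len: int) -> tuple[int, int]:
    """Genomic interval with full read coverage when starts are uniform."""
    s, e = exon
    return (s + read_len - 1, e - read_len + 1)


def _strand_a_positions(
    genome_seq: np.ndarray, gene: GeneModel, intervals: Sequence[tuple[int, int]], read_len: int
) -> np.ndarray:
    """Positions in the coverage plateau whose gene-strand base is A."""
    want = "A" if gene.strand == "+" else "T"
    pos: list[int] = []
    for exon in gene.exons:
        plo, phi = _plateau(exon, read_len)
        for s, e in intervals:
            lo, hi = max(s, plo), min(e, phi)
            if lo >= hi:
                continue
            block = genome_seq[lo:hi]
            pos.extend((lo + np.nonzero(block == want)[0]).tolist())
    return np.array(sorted(pos), dtype=int)


def _plant_snps(
    cfg: SimConfig,
    genes: list[GeneModel],
    seqs: dict[str, np.ndarray],
    repeats: list[RepeatInterval],
    rng: np.random.Generator,
) -> pd.DataFrame:
    records = []
    for i in range(cfg.n_snps):
        gene = genes[int(rng.integers(0, len(genes)))]
        pool = _strand_a_positions(seqs[gene.chrom], gene, gene.exons, cfg.read_length)
        if pool.size == 0:
            continue
        pos0 = int(pool[int(rng.integers(0, pool.size))])
        if any(r["chrom"] == gene.chrom and r["pos0"] == pos0 for r in records):
            continue
        ref_fwd = "A" if gene.strand == "+" else "T"
        alt_fwd = "G" if gene.strand == "+" else "C"
        records.append(
            {
                "chrom": gene.chrom,
                "pos0": pos0,
                "gene_id": gene.gene_id,
                "strand": gene.strand,
                "ref_fwd": ref_fwd,
                "alt_fwd": alt_fwd,
                "alt_fraction": cfg.snp_alt_fraction,
            }
        )
    df = pd.DataFrame(records, columns=["chrom", "pos0", "gene_id", "strand", "ref_fwd", "alt_fwd", "alt_fraction"])
    return df.sort_values(["chrom", "pos0"]).reset_index(drop=True)


@dataclass
class GroundTruth:
    """Planted truth tables sufficient to score every pipeline stage."""

    sites: pd.DataFrame  # site_id, chrom, pos0, gene_id, strand, element, in_alu, pattern, phi_<type>...
    reads: pd.DataFrame  # read_name, molecule_id, cb, umi, cell_type, gene_id, is_extra_copy
    snps: pd.DataFrame
    expression: pd.DataFrame  # genes x barcodes raw molecule counts
    barcode_map: dict[str, str]
    molecule_edits: dict[int, dict[int, bool]]  # molecule -> {site_id: carries edit}
    molecule_span: dict[int, tuple[str, int, int]]  # molecule -> (chrom, start, end)

    def phi(self, site_id: int, cell_type: str) -> float:
        return float(self.sites.loc[self.sites["site_id"] == site_id, f"phi_{cell_type}"].iloc[0])

    def reads_per_cell_type(self) -> dict[str, int]:
        return self.reads.groupby("cell_type").size().to_dict()

    def edited_cells(self, site_id: int) -> set[str]:
        """Barcodes with >= 1 sampled molecule carrying the edit over the site."""
        mols = [m for m, edits in self.molecule_edits.items() if edits.get(site_id)]
        mol_cb = self.reads.drop_duplicates("molecule_id").set_index("molecule_id")["cb"]
        return {mol_cb[m] for m in mols}

    def cells_covering(self, site_id: int) -> set[str]:
        row = self.sites.loc[self.sites["site_id"] == site_id].iloc[0]
        pos = int(row["pos0"])
        chrom = str(row["chrom"])
        mol_cb = self.reads.drop_duplicates("molecule_id").set_index("molecule_id")["cb"]
        out = set()
        for m, (c, s, e) in self.molecule_span.items():
            if c == chrom and s <= pos < e:
                out.add(mol_cb[m])
        return out


@dataclass
class SimResult:
    config: SimConfig
    seed: int
    genome: SyntheticGenome
    reads: list[AlignedRead]
    truth: GroundTruth

    def write(self, outdir) -> dict[str, str]:
        from . import io as sio

        return sio.write_simulation(self, outdir)


def _plant_editing_sites(
    cfg: SimConfig, genome: SyntheticGenome, rng: np.random.Generator
) -> pd.DataFrame:
    seqs = {c: np.array(list(s)) for c, s in genome.seqs.items()}
    taken = set(zip(genome.snps["chrom"], genome.snps["pos0"]))
    alu_by_chrom: dict[str, list[RepeatInterval]] = {}
    for r in genome.repeats:
        alu_by_chrom.setdefault(r.chrom, []).append(r)

    groups = {g: tuple(m for m in members if m in cfg.cell_types) for g, members in cfg.lineages.items()}
    groups = {g: m for g, m in groups.items() if m}
    pat_names = list(cfg.pattern_fractions)
    pat_probs = np.array([cfg.pattern_fractions[p] for p in pat_names], dtype=float)
    pat_probs = pat_probs / pat_probs.sum()

    elem_names = list(cfg.edit_element_weights)
    elem_probs = np.array([cfg.edit_element_weights[e] for e in elem_names], dtype=float)
    elem_probs = elem_probs / elem_probs.sum()

    records = []
    attempts = 0
    while len(records) < cfg.n_editing_sites and attempts < cfg.n_editing_sites * 50:
        attempts += 1
        gene = genome.genes[int(rng.integers(0, len(genome.genes)))]
        in_alu = bool(rng.random() < cfg.edit_alu_fraction)
        if in_alu:
            alus = [
                (r.start0, r.end0)
                for r in alu_by_chrom.get(gene.chrom, [])
                if any(s <= r.start0 and r.end0 <= e for s, e in gene.utr3)
            ]
            if not alus:
                continue
            element = "3UTR"
            pool = _strand_a_positions(seqs[gene.chrom], gene, alus, cfg.read_length)
        else:
            element = str(rng.choice(elem_names, p=elem_probs))
            intervals = {"3UTR": gene.utr3, "CDS": gene.cds, "5UTR": gene.utr5}[element]
            if element == "3UTR":
                intervals = _subtract_alus(intervals, alu_by_chrom.get(gene.chrom, []))
            pool = _strand_a_positions(seqs[gene.chrom], gene, intervals, cfg.read_length)
        if pool.size == 0:
            continue
        pos0 = int(pool[int(rng.integers(0, pool.size))])
        if (gene.chrom, pos0) in taken:
            continue
        taken.add((gene.chrom, pos0))

        pattern_kind = str(rng.choice(pat_names, p=pat_probs))
        phi = float(rng.choice(np.array(cfg.phi_levels)))
        if pattern_kind == "shared":
            edited_in = set(cfg.cell_types)
            pattern = "shared"
        elif pattern_kind == "group_specific" and groups:
            gname = sorted(groups)[int(rng.integers(0, len(groups)))]
            edited_in = set(groups[gname])
            pattern = f"group_specific:{gname}"
        else:
            t = cfg.cell_types[int(rng.integers(0, len(cfg.cell_types)))]
            edited_in = {t}
            pattern = f"type_specific:{t}"
        rec = {
            "site_id": len(records),
            "chrom": gene.chrom,
            "pos0": pos0,
            "gene_id": gene.gene_id,
            "strand": gene.strand,
            "element": element,
            "in_alu": in_alu,
            "pattern": pattern,
            "phi": phi,
        }
        for ct in cfg.cell_types:
            rec[f"phi_{ct}"] = phi if ct in edited_in else 0.0
        records.append(rec)
    return pd.DataFrame(records)


def _subtract_alus(intervals, alus) -> list[tuple[int, int]]:
    out = []
    for s, e in intervals:
        cuts = [(s, e)]
        for r in alus:
            nxt = []
            for cs, ce in cuts:
                if r.end0 <= cs or r.start0 >= ce:
                    nxt.append((cs, ce))
                else:
                    if cs < r.start0:
                        nxt.append((cs, r.start0))
                    if r.end0 < ce:
                        nxt.append((r.end0, ce))
            cuts = nxt
        out.extend(cuts)
    return out


def _random_kmers(rng: np.random.Generator, n: int, k: int) -> list[str]:
    """n distinct random DNA k-mers."""
    out: set[str] = set()
    while len(out) < n:
        block = _BASES[rng.integers(0, 4, size=(n - len(out) + 8, k))]
        out.update("".join(row) for row in block)
    return sorted(out)[:n]


def simulate_reads(genome: SyntheticGenome, cfg: SimConfig, seed: int) -> SimResult:
    """Sample barcoded, UMI-tagged aligned reads with planted signals."""
    cfg.validate()
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 202)))
    sites = _plant_editing_sites(cfg, genome, rng)
    seq_arrays = {c: np.array(list(s)) for c, s in genome.seqs.items()}

    # cells
    n_cells = len(cfg.cell_types) * cfg.cells_per_type
    barcodes = _random_kmers(rng, n_cells, cfg.cb_length)
    barcode_map = {
        barcodes[i]: cfg.cell_types[i // cfg.cells_per_type] for i in range(n_cells)
    }

    # per-gene molecule budget
    valid_starts = [e - cfg.read_length + 1 for e in cfg.exon_lengths]
    total_starts = sum(valid_starts)
    base_mean = cfg.mean_depth * total_starts / (cfg.read_length * cfg.cells_per_type)
    gene_factor = {
        g.gene_id: (cfg.low_expression_factor if i >= len(genome.genes) - cfg.low_expression_genes else 1.0)
        for i, g in enumerate(genome.genes)
    }

    # per-gene numpy views of the planted tables (fast molecule loop)
    sites_by_gene: dict[str, tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]] = {}
    if len(sites):
        for gid, df in sites.groupby("gene_id"):
            phis = {ct: df[f"phi_{ct}"].to_numpy() for ct in cfg.cell_types}
            sites_by_gene[gid] = (df["pos0"].to_numpy(), df["site_id"].to_numpy(), phis)
    snps_by_gene: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    if len(genome.snps):
        for gid, df in genome.snps.groupby("gene_id"):
            snps_by_gene[gid] = (
                df["pos0"].to_numpy(),
                df["alt_fraction"].to_numpy(),
                df["alt_fwd"].to_numpy(),
            )

    reads: list[AlignedRead] = []
    read_records = []
    molecule_edits: dict[int, dict[int, bool]] = {}
    molecule_span: dict[int, tuple[str, int, int]] = {}
    expr_counts = pd.DataFrame(
        0, index=[g.gene_id for g in genome.genes], columns=barcodes, dtype=int
    )
    qlo, qhi = cfg.base_qual_range
    mol_id = 0
    for gene in genome.genes:
        gseq = seq_arrays[gene.chrom]
        gene_sites = sites_by_gene.get(gene.gene_id)
        gene_snps = snps_by_gene.get(gene.gene_id)
        mean = base_mean * gene_factor[gene.gene_id]
        edited_base = "G" if gene.strand == "+" else "C"
        for cb in barcodes:
            cell_type = barcode_map[cb]
            n_mol = int(rng.poisson(mean))
            if n_mol == 0:
                continue
            expr_counts.loc[gene.gene_id, cb] += n_mol
            umis = [
                "".join(_BASES[rng.integers(0, 4, size=cfg.umi_length)]) for _ in range(n_mol)
            ]
            for umi in umis:
                # choose exon by available start positions, then a start
                exon_idx = int(rng.choice(len(cfg.exon_lengths), p=np.array(valid_starts) / total_starts))
                es, _ = gene.exons[exon_idx]
                start = es + int(rng.integers(0, valid_starts[exon_idx]))
                end = start + cfg.read_length
                template = gseq[start:end].copy()

                edits_here: dict[int, bool] = {}
                if gene_sites is not None:
                    spos, sids, phis = gene_sites
                    for j in np.nonzero((spos >= start) & (spos < end))[0]:
                        phi = float(phis[cell_type][j])
                        carries = bool(rng.random() < phi) if phi > 0 else False
                        edits_here[int(sids[j])] = carries
                        if carries:
                            template[int(spos[j]) - start] = edited_base
                if gene_snps is not None:
                    vpos, vfrac, valt = gene_snps
                    for j in np.nonzero((vpos >= start) & (vpos < end))[0]:
                        if rng.random() < float(vfrac[j]):
                            template[int(vpos[j]) - start] = str(valt[j])
                molecule_edits[mol_id] = edits_here
                molecule_span[mol_id] = (gene.chrom, start, end)

                n_copies = 1
                while n_copies < 5 and rng.random() < cfg.duplication_rate:
                    n_copies += 1
                for copy_idx in range(n_copies):
                    seq = template.copy()
                    if cfg.error_rate > 0:
                        err = np.nonzero(rng.random(cfg.read_length) < cfg.error_rate)[0]
                        for p in err:
                            choices = [b for b in "ACGT" if b != seq[p]]
                            seq[p] = choices[int(rng.integers(0, 3))]
                    quals = rng.integers(qlo, qhi + 1, size=cfg.read_length)
                    clip = cfg.softclip_length if rng.random() < cfg.softclip_prob else 0
                    if clip and edits_here:
                        # keep planted sites inside the aligned span so the
                        # molecule-level truth stays exact for every copy
                        zone = (
                            range(start, start + clip)
                            if gene.strand == "+"
                            else range(end - clip, end)
                        )
                        spos, sids, _ = gene_sites
                        if any(int(p) in zone for p in spos):
                            clip = 0
                    if clip:
                        if gene.strand == "+":
                            cigar = f"{clip}S{cfg.read_length - clip}M"
                            pos0 = start + clip
                        else:
                            cigar = f"{cfg.read_length - clip}M{clip}S"
                            pos0 = start
                    else:
                        cigar = f"{cfg.read_length}M"
                        pos0 = start
                    name = f"m{mol_id:07d}_{copy_idx}"
                    reads.append(
                        AlignedRead(
                            read_name=name,
                            chrom=gene.chrom,
                            pos0=pos0,
                            is_reverse=(gene.strand == "-"),
                            cigar=cigar,
                            seq="".join(seq),
                            base_quals=quals.tolist(),
                            mapq=cfg.mapq,
                            cb=cb,
                            umi=umi,
                        )
                    )
                    read_records.append(
                        {
                            "read_name": name,
                            "molecule_id": mol_id,
                            "cb": cb,
                            "umi": umi,
                            "cell_type": cell_type,
                            "gene_id": gene.gene_id,
                            "is_extra_copy": copy_idx > 0,
                        }
                    )
                mol_id += 1

    order = sorted(range(len(reads)), key=lambda i: (reads[i].chrom, reads[i].pos0, reads[i].read_name))
    reads = [reads[i] for i in order]
    truth = GroundTruth(
        sites=sites,
        reads=pd.DataFrame(read_records),
        snps=genome.snps,
        expression=expr_counts,
        barcode_map=barcode_map,
        molecule_edits=molecule_edits,
        molecule_span=molecule_span,
    )
    return SimResult(config=cfg, seed=seed, genome=genome, reads=reads, truth=truth)


def simulate(cfg: Optional[SimConfig] = None, seed: int = 0) -> SimResult:
    """Generate genome and reads in one call (deterministic per seed)."""
    cfg = cfg or SimConfig()
    genome = simulate_genome(cfg, seed)
    return simulate_reads(genome, cfg, seed)


def simulate_scalefree_profiles(
    n_sites: int = 150,
    n_samples: int = 30,
    seed: int = 21,
) -> np.ndarray:
    """Profiles whose correlation network is approximately scale-free.

    Each site couples to a shared latent driver with a heavy-tailed
    coupling strength, so a few hub sites are strongly connected while
    most are weakly connected — the regime the soft-threshold power
    scan expects. Used to exercise ``pick_soft_power``.
    """
    rng = np.random.default_rng(seed)
    driver = rng.standard_normal(n_samples)
    coupling = rng.uniform(0.05, 1.0, n_sites) ** 3
    rows = [
        c * driver + np.sqrt(1.0 - c**2) * rng.standard_normal(n_samples)
        for c in coupling
    ]
    return np.array(rows)


def simulate_block_profiles(
    n_sites_per_block: int = 40,
    n_blocks: int = 2,
    n_samples: int = 40,
    within_cor: float = 0.95,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Editing-level profiles with planted co-editing blocks.

    Sites within a block share a latent driver (pairwise correlation
    ~``within_cor``); across blocks profiles are independent. Returns
    (profiles, block_labels). Used to exercise module detection.
    """
    rng = np.random.default_rng(seed)
    rho = np.sqrt(within_cor)
    rows = []
    labels = []
    for b in range(n_blocks):
        driver = rng.standard_normal(n_samples)
        for _ in range(n_sites_per_block):
            noise = rng.standard_normal(n_samples)
            rows.append(rho * driver + np.sqrt(1 - rho**2) * noise)
            labels.append(b)
    return np.array(rows), np.array(labels)
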