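"""Readers and writers for the standard formats at the package boundary.

BAM I/O goes through pysam; the reference through pysam's FASTA
handling; gene models through gffutils; the SNP VCF through pysam's
variant reader; expression matrices through scipy's matrix-market
support. Internally everything is converted to the lightweight records
in :mod:`screditome.model`.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam

from .annotate import GeneModel, RepeatInterval, SiteAnnotation
from .model import AlignedRead, EditingSite, complement

# ---------------------------------------------------------------------------
# BAM


def read_bam(
    path: str,
    cb_tag: str = "CB",
    umi_tags: Sequence[str] = ("UB", "UR"),
    exclude_secondary: bool = True,
    region: Optional[str] = None,
) -> list[AlignedRead]:
    """Load aligned records as :class:`AlignedRead` objects.

    Unmapped records are skipped; secondary/supplementary alignments are
    skipped unless ``exclude_secondary`` is false. The UMI is taken from
    the first tag in ``umi_tags`` that is present.
    """
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(path, "rb") as bam:
        it = bam.fetch(region=region) if region else bam
        for rec in it:
            if rec.is_unmapped or rec.cigarstring is None:
                continue
            if exclude_secondary and (rec.is_secondary or rec.is_supplementary):
                continue
            umi = None
            for tag in umi_tags:
                if rec.has_tag(tag):
                    umi = rec.get_tag(tag)
                    break
            reads.append(
                AlignedRead(
                    read_name=rec.query_name,
                    chrom=rec.reference_name,
                    pos0=rec.reference_start,
                    is_reverse=rec.is_reverse,
                    cigar=rec.cigarstring,
                    seq=rec.query_sequence,
                    base_quals=list(rec.query_qualities),
                    mapq=rec.mapping_quality,
                    cb=rec.get_tag(cb_tag) if rec.has_tag(cb_tag) else None,
                    umi=umi,
                    is_duplicate=rec.is_duplicate,
                )
            )
    return reads


def write_bam(
    path: str,
    reads: Iterable[AlignedRead],
    chrom_lengths: dict[str, int],
    cb_tag: str = "CB",
    umi_tag: str = "UB",
    index: bool = True,
) -> None:
    """Write coordinate-sorted records with CB/UMI tags and index them."""
    names = list(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_lengths[c])} for c in names],
    }
    tid = {c: i for i, c in enumerate(names)}
    ordered = sorted(reads, key=lambda r: (tid[r.chrom], r.pos0, r.read_name))
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for r in ordered:
            rec = pysam.AlignedSegment(bam.header)
            rec.query_name = r.read_name
            rec.reference_id = tid[r.chrom]
            rec.reference_start = r.pos0
            rec.mapping_quality = r.mapq
            rec.cigarstring = r.cigar
            rec.query_sequence = r.seq
            rec.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.base_quals)
            )
            flag = 0
            if r.is_reverse:
                flag |= 16
            if r.is_duplicate:
                flag |= 1024
            rec.flag = flag
            tags = []
            if r.cb is not None:
                tags.append((cb_tag, r.cb))
            if r.umi is not None:
                tags.append((umi_tag, r.umi))
            rec.set_tags(tags)
            bam.write(rec)
    if index:
        pysam.index(path)


# ---------------------------------------------------------------------------
# FASTA / GTF / BED / VCF


def write_fasta(path: str, seqs: dict[str, str], width: int = 70, index: bool = True) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    if index:
        pysam.faidx(path)


def read_fasta(path: str) -> dict[str, str]:
    with pysam.FastaFile(path) as fa:
        return {name: fa.fetch(name) for name in fa.references}


_GTF_FEATURES = (("exon", "exons"), ("CDS", "cds"), ("five_prime_utr", "utr5"), ("three_prime_utr", "utr3"))


def write_gtf(path: str, genes: Sequence[GeneModel]) -> None:
    with open(path, "w") as fh:
        for gene in genes:
            attrs = f'gene_id "{gene.gene_id}"; transcript_id "{gene.gene_id}.t1";'
            rows = [("gene", gene.start, gene.end)]
            for feature, attr in _GTF_FEATURES:
                for s, e in sorted(getattr(gene, attr)):
                    rows.append((feature, s, e))
            for feature, s, e in rows:
                fh.write(
                    f"{gene.chrom}\tscreditome\t{feature}\t{s + 1}\t{e}\t.\t{gene.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str) -> list[GeneModel]:
    """Parse gene models (exon/CDS/UTR features) from a GTF file."""
    import gffutils

    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
    )
    genes: dict[str, GeneModel] = {}
    kinds = {
        "exon": "exons",
        "CDS": "cds",
        "five_prime_utr": "utr5",
        "three_prime_utr": "utr3",
        "5UTR": "utr5",
        "3UTR": "utr3",
    }
    for feat in db.all_features():
        if feat.featuretype not in kinds:
            continue
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        model = genes.get(gene_id)
        if model is None:
            model = genes[gene_id] = GeneModel(gene_id, feat.seqid, feat.strand, [])
        getattr(model, kinds[feat.featuretype]).append((feat.start - 1, feat.end))
    for model in genes.values():
        for attr in ("exons", "cds", "utr5", "utr3"):
            setattr(model, attr, sorted(set(getattr(model, attr))))
        if not model.exons:
            raise ValueError(f"gene {model.gene_id} has no exon features")
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


def write_bed(path: str, repeats: Sequence[RepeatInterval]) -> None:
    with open(path, "w") as fh:
        for r in repeats:
            fh.write(f"{r.chrom}\t{r.start0}\t{r.end0}\t{r.family}\n")


def read_bed(path: str) -> list[RepeatInterval]:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    fam = df[3] if df.shape[1] > 3 else pd.Series(["Alu"] * len(df))
    return [
        RepeatInterval(str(c), int(s), int(e), str(f))
        for c, s, e, f in zip(df[0], df[1], df[2], fam)
    ]


def write_snp_vcf(path: str, snps: pd.DataFrame, chrom_lengths: dict[str, int]) -> None:
    """Minimal VCF of known SNP positions (1-based, forward alleles)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for _, row in snps.sort_values(["chrom", "pos0"]).iterrows():
            fh.write(
                f"{row['chrom']}\t{int(row['pos0']) + 1}\t.\t{row['ref_fwd']}\t{row['alt_fwd']}\t.\tPASS\t.\n"
            )


def read_snp_vcf(path: str) -> frozenset:
    """(chrom, pos0) known-variant positions from a VCF (1-based on disk)."""
    positions = set()
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            positions.add((rec.chrom, rec.pos - 1))
    return frozenset(positions)


# ---------------------------------------------------------------------------
# Site / annotation / matrix tables


def sites_to_frame(sites: Sequence[EditingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.chrom,
                "pos": s.pos0 + 1,  # 1-based in tables
                "strand": s.gene_strand,
                "ref": s.ref_on_strand,
                "alt": s.alt_on_strand,
                "depth": s.depth,
                "n_alt": s.n_alt,
                "editing_level": round(s.editing_level, 6),
                "p_edit": round(s.p_edit, 6),
                "in_alu": int(s.in_alu),
                "cell_type": s.cell_type,
                "gene_id": s.gene_id or ".",
            }
            for s in sites
        ],
        columns=[
            "chrom", "pos", "strand", "ref", "alt", "depth", "n_alt",
            "editing_level", "p_edit", "in_alu", "cell_type", "gene_id",
        ],
    )


def write_sites_tsv(path: str, sites: Sequence[EditingSite]) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path: str) -> list[EditingSite]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        out.append(
            EditingSite(
                chrom=str(r["chrom"]),
                pos0=int(r["pos"]) - 1,
                gene_strand=str(r["strand"]),
                ref_on_strand=str(r["ref"]),
                alt_on_strand=str(r["alt"]),
                depth=int(r["depth"]),
                n_alt=int(r["n_alt"]),
                editing_level=float(r["editing_level"]),
                p_edit=float(r["p_edit"]),
                in_alu=bool(r["in_alu"]),
                cell_type=str(r["cell_type"]),
                gene_id=None if str(r["gene_id"]) == "." else str(r["gene_id"]),
            )
        )
    return out


def write_sites_vcf(path: str, sites: Sequence[EditingSite], chrom_lengths: dict[str, int]) -> None:
    """VCF-style site output with forward-strand alleles and INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        for line in (
            '##INFO=<ID=STRAND,Number=1,Type=String,Description="Gene strand">',
            '##INFO=<ID=PEDIT,Number=1,Type=Float,Description="Editing confidence">',
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="Filtered depth">',
            '##INFO=<ID=NALT,Number=1,Type=Integer,Description="Edited-base reads">',
            '##INFO=<ID=PHI,Number=1,Type=Float,Description="Editing level">',
            '##INFO=<ID=ALU,Number=0,Type=Flag,Description="Inside an Alu repeat">',
        ):
            fh.write(line + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(sites, key=lambda x: (x.chrom, x.pos0)):
            if s.gene_strand == "+":
                ref, alt = s.ref_on_strand, s.alt_on_strand
            else:
                ref, alt = complement(s.ref_on_strand), complement(s.alt_on_strand)
            info = (
                f"STRAND={s.gene_strand};PEDIT={s.p_edit:.4f};DP={s.depth};"
                f"NALT={s.n_alt};PHI={s.editing_level:.4f}"
            )
            if s.in_alu:
                info += ";ALU"
            fh.write(f"{s.chrom}\t{s.pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\n")


def write_annotations_tsv(path: str, annotations: Sequence[SiteAnnotation]) -> None:
    rows = [
        {
            "chrom": a.site.chrom,
            "pos": a.site.pos0 + 1,
            "strand": a.site.gene_strand,
            "cell_type": a.site.cell_type,
            "element": a.element,
            "gene_id": a.gene_id or ".",
            "in_alu": int(a.in_alu),
            "strand_consistent": int(a.strand_consistent),
        }
        for a in annotations
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "cell_type", "element", "gene_id", "in_alu", "strand_consistent"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Expression matrices


def write_mtx(prefix: str, counts: pd.DataFrame) -> None:
    """Write genes x barcodes counts as matrix-market triplets.

    Produces ``<prefix>.mtx``, ``<prefix>.features.tsv`` and
    ``<prefix>.barcodes.tsv``.
    """
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(f"{prefix}.mtx", csr_matrix(counts.to_numpy()))
    pd.Series(counts.index).to_csv(f"{prefix}.features.tsv", sep="\t", index=False, header=False)
    pd.Series(counts.columns).to_csv(f"{prefix}.barcodes.tsv", sep="\t", index=False, header=False)


def read_mtx(prefix: str) -> pd.DataFrame:
    from scipy.io import mmread

    m = mmread(f"{prefix}.mtx").toarray()
    features = pd.read_csv(f"{prefix}.features.tsv", sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(f"{prefix}.barcodes.tsv", sep="\t", header=None)[0].tolist()
    return pd.DataFrame(m, index=features, columns=barcodes)


def write_barcode_map(path: str, barcode_map: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write("# barcode\tcell_type\n")
        for cb in sorted(barcode_map):
            fh.write(f"{cb}\t{barcode_map[cb]}\n")


# ---------------------------------------------------------------------------
# Simulation bundle


def write_simulation(sim, outdir) -> dict[str, str]:
    """Write a :class:`~screditome.synthetic.SimResult` as a file fixture.

    Emits BAM(+index), FASTA(+index), GTF, BED, SNP VCF, expression MTX,
    the barcode map, and the ground-truth TSV tables.
    """
    os.makedirs(outdir, exist_ok=True)
    p = lambda name: os.path.join(str(outdir), name)
    paths = {
        "bam": p("reads.bam"),
        "fasta": p("genome.fa"),
        "gtf": p("genes.gtf"),
        "alu_bed": p("alu.bed"),
        "snp_vcf": p("snps.vcf"),
        "celltypes": p("celltypes.tsv"),
        "expression": p("expression"),
        "truth_sites": p("truth_sites.tsv"),
        "truth_reads": p("truth_reads.tsv"),
        "truth_snps": p("truth_snps.tsv"),
    }
    write_bam(paths["bam"], sim.reads, sim.genome.chrom_lengths)
    write_fasta(paths["fasta"], sim.genome.seqs)
    write_gtf(paths["gtf"], sim.genome.genes)
    write_bed(paths["alu_bed"], sim.genome.repeats)
    write_snp_vcf(paths["snp_vcf"], sim.genome.snps, sim.genome.chrom_lengths)
    write_barcode_map(paths["celltypes"], sim.truth.barcode_map)
    write_mtx(paths["expression"], sim.truth.expression)
    sim.truth.sites.to_csv(paths["truth_sites"], sep="\t", index=False)
    sim.truth.reads.to_csv(paths["truth_reads"], sep="\t", index=False)
    sim.truth.snps.to_csv(paths["truth_snps"], sep="\t", index=False)
    return paths
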