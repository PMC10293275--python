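"""End-to-end pipeline: pseudo-bulk -> dedup -> strand split -> call ->
annotate -> profile -> cells, with a machine-readable run manifest.

Each stage communicates through declared files in the run directory;
re-running with identical inputs reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass
from typing import Optional

import pandas as pd

from . import io as sio
from .annotate import annotate_sites, strand_filter
from .bamops import count_available_reads, mark_duplicates, split_by_cell_type
from .cells import (
    ExpressionVector,
    assign_edited_cells,
    compare_expression,
    edited_cell_set,
    edited_fraction,
    normalize_expression,
)
from .editcall import CallParams, ScoreWeights, call_editome, site_depths
from .model import CellTypeMap
from .profiles import CoeditNetwork, LineageConfig, build_matrix, classify_patterns

logger = logging.getLogger(__name__)

STAGES = ("pseudobulk", "dedup", "strandsplit", "call", "annotate", "profile", "cells")


@dataclass
class PipelineConfig:
    bam: str
    celltypes: str
    reference: str
    gtf: str
    alu_bed: str
    snp_vcf: str
    outdir: str
    expression_prefix: Optional[str] = None  # MTX prefix for the cells stage
    focus_gene: Optional[str] = None  # gene for edited-fraction / expression comparison
    cb_tag: str = "CB"
    umi_tags: tuple[str, ...] = ("UB", "UR")
    min_mq: int = 20
    min_bq: int = 20
    min_depth: int = 30
    min_alt_reads: int = 3
    p_edit_threshold: float = 0.5
    min_module_size: int = 30
    cut_height: float = 0.995
    r2_cutoff: float = 0.8
    lineages: Optional[dict] = None
    include_secondary: bool = False

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "umi_tags" in raw:
            raw["umi_tags"] = tuple(raw["umi_tags"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("bam", "celltypes", "reference", "gtf", "alu_bed", "snp_vcf"):
            path = getattr(self, name)
            if not os.path.exists(path):
                raise FileNotFoundError(f"{name} input missing: {path}")
        if not 0 <= self.p_edit_threshold <= 1:
            raise ValueError("p_edit_threshold must be in [0, 1]")
        if self.min_depth < 1 or self.min_mq < 0 or self.min_bq < 0:
            raise ValueError("thresholds out of range")


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    from . import __version__

    cfg.validate()
    os.makedirs(cfg.outdir, exist_ok=True)
    out = lambda name: os.path.join(cfg.outdir, name)
    manifest: dict = {
        "version": __version__,
        "parameters": {k: v for k, v in asdict(cfg).items()},
        "inputs": {
            name: _checksum(getattr(cfg, name))
            for name in ("bam", "celltypes", "reference", "gtf", "alu_bed", "snp_vcf")
        },
        "stages": [],
    }
    stage_log = manifest["stages"]

    current = "pseudobulk"
    try:
        # --- pseudobulk ---------------------------------------------------
        reads = sio.read_bam(
            cfg.bam, cb_tag=cfg.cb_tag, umi_tags=cfg.umi_tags, exclude_secondary=not cfg.include_secondary
        )
        ctmap = CellTypeMap.from_tsv(cfg.celltypes)
        by_type, unassigned = split_by_cell_type(reads, ctmap)
        stage_log.append(
            {
                "stage": "pseudobulk",
                "reads_in": len(reads),
                "reads_out": {ct: len(rs) for ct, rs in by_type.items()},
                "unassigned": len(unassigned),
            }
        )

        # --- dedup --------------------------------------------------------
        current = "dedup"
        dedup_counts = {}
        for ct, rs in by_type.items():
            res = mark_duplicates(rs)
            dedup_counts[ct] = {
                "duplicates": res.n_duplicates,
                "untagged": res.n_untagged,
                "available": count_available_reads(rs),
            }
        stage_log.append({"stage": "dedup", "per_cell_type": dedup_counts})

        # --- strandsplit (bookkeeping; calling re-splits internally) ------
        current = "strandsplit"
        from .bamops import split_by_strand

        strand_counts = {}
        for ct, rs in by_type.items():
            fwd, rev = split_by_strand(rs)
            strand_counts[ct] = {"forward": len(fwd), "reverse": len(rev)}
        stage_log.append({"stage": "strandsplit", "per_cell_type": strand_counts})

        # --- call ---------------------------------------------------------
        current = "call"
        reference = sio.read_fasta(cfg.reference)
        genes = sio.read_gtf(cfg.gtf)
        repeats = sio.read_bed(cfg.alu_bed)
        snp_index = sio.read_snp_vcf(cfg.snp_vcf)
        params = CallParams(
            min_mq=cfg.min_mq,
            min_bq=cfg.min_bq,
            min_depth=cfg.min_depth,
            min_alt_reads=cfg.min_alt_reads,
            p_edit_threshold=cfg.p_edit_threshold,
            weights=ScoreWeights(),
        )
        sites_by_type = call_editome(by_type, reference, genes, repeats, snp_index, params)
        all_sites = [s for ct in ctmap.cell_types for s in sites_by_type.get(ct, [])]
        sio.write_sites_tsv(out("sites.tsv"), all_sites)
        chrom_lengths = {c: len(s) for c, s in reference.items()}
        sio.write_sites_vcf(out("sites.vcf"), all_sites, chrom_lengths)
        stage_log.append(
            {"stage": "call", "sites_per_cell_type": {ct: len(sites_by_type.get(ct, [])) for ct in ctmap.cell_types}}
        )

        # --- annotate -----------------------------------------------------
        current = "annotate"
        annotations = annotate_sites(all_sites, genes, repeats)
        retained = strand_filter(annotations)
        sio.write_annotations_tsv(out("annotated.tsv"), retained)
        stage_log.append(
            {"stage": "annotate", "sites_in": len(annotations), "strand_consistent": len(retained)}
        )

        # --- profile --------------------------------------------------------
        current = "profile"
        kept_keys = {a.site.key for a in retained}
        filtered_by_type = {
            ct: [s for s in sites_by_type.get(ct, []) if s.key in kept_keys] for ct in ctmap.cell_types
        }
        union_positions = sorted({(s.chrom, s.pos0) for ss in filtered_by_type.values() for s in ss})
        depth_by_type = {
            ct: site_depths(by_type[ct], union_positions, min_mq=cfg.min_mq, min_bq=cfg.min_bq)
            for ct in ctmap.cell_types
        }

        def depth_fn(key, ct):
            return depth_by_type[ct].get((key[0], key[1]), 0)

        matrix = build_matrix(filtered_by_type, depth_fn, ctmap.cell_types, cfg.min_depth)
        matrix.to_frame().to_csv(out("matrix.tsv"), sep="\t")
        lineages = LineageConfig(groups=cfg.lineages) if cfg.lineages else LineageConfig()
        patterns = classify_patterns(matrix, lineages)
        pd.DataFrame(
            [
                {"site": f"{c}:{p}:{s}", "pattern": str(patterns[(c, p, s)])}
                for c, p, s in matrix.site_keys
            ],
            columns=["site", "pattern"],
        ).to_csv(out("patterns.tsv"), sep="\t", index=False)
        module_info: dict = {"n_sites": len(matrix.site_keys)}
        try:
            network = CoeditNetwork.from_matrix(
                matrix,
                r2_cutoff=cfg.r2_cutoff,
                min_module_size=cfg.min_module_size,
                cut_height=cfg.cut_height,
            )
            pd.DataFrame(
                {
                    "site": [f"{c}:{p}:{s}" for c, p, s in network.site_keys],
                    "module": network.module_labels,
                },
                columns=["site", "module"],
            ).to_csv(out("modules.tsv"), sep="\t", index=False)
            network.power_table.to_csv(out("soft_power.tsv"), sep="\t", index=False)
            module_info.update(
                {"power": network.power, "n_modules": int(network.module_labels.max(initial=0))}
            )
        except ValueError as exc:
            # too few variable profiles for a network; still emit empty table
            pd.DataFrame(columns=["site", "module"]).to_csv(out("modules.tsv"), sep="\t", index=False)
            module_info["network_skipped"] = str(exc)
        stage_log.append({"stage": "profile", **module_info})

        # --- cells ----------------------------------------------------------
        current = "cells"
        cells_info: dict = {}
        if cfg.expression_prefix and cfg.focus_gene:
            counts = sio.read_mtx(cfg.expression_prefix)
            gene_sites = [s for s in all_sites if s.gene_id == cfg.focus_gene]
            calls = []
            for site in gene_sites:
                ct_reads = by_type.get(site.cell_type, [])
                calls.extend(assign_edited_cells(ct_reads, site, cfg.min_mq, cfg.min_bq))
            pd.DataFrame(
                [
                    {"site": f"{c.site_key[0]}:{c.site_key[1]}", "barcode": c.barcode, "n_support": c.n_support}
                    for c in calls
                ],
                columns=["site", "barcode", "n_support"],
            ).to_csv(out("edited_cells.tsv"), sep="\t", index=False)
            norm = normalize_expression({g: counts.loc[g].to_dict() for g in counts.index})
            raw = counts.loc[cfg.focus_gene]
            expr = ExpressionVector(
                cfg.focus_gene,
                values=norm[cfg.focus_gene],
                expressed={cb for cb in counts.columns if raw[cb] > 0},
            )
            frac = edited_fraction(calls, expr)
            edited = edited_cell_set(calls) & expr.expressed
            unedited = expr.expressed - edited
            comparison = compare_expression(expr, edited, unedited) if edited and unedited else None
            cells_info = {
                "gene": cfg.focus_gene,
                "edited_fraction": frac,
                "log2_fold_change": comparison.log2_fold_change if comparison else None,
                "p_value": comparison.p_value if comparison else None,
            }
            pd.DataFrame([cells_info]).to_csv(out("expression_comparison.tsv"), sep="\t", index=False)
        stage_log.append({"stage": "cells", **cells_info})

    except Exception as exc:
        with open(out("FAILED"), "w") as fh:
            fh.write(f"stage {current} failed: {exc}\n")
        raise RuntimeError(f"pipeline stage {current!r} failed") from exc

    with open(out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
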