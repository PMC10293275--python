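"""Pileup arithmetic, candidate screening, confidence scoring, filtering."""

from __future__ import annotations

import math

import pytest

from screditome.editcall import (
    ScoreWeights,
    build_pileup,
    detect_candidates,
    filter_sites,
    score_site,
    site_depths,
)
from screditome.io import sites_to_frame
from screditome.model import AlignedRead, CandidateSite, EditingSite

from helpers import call_sim, mirror_reads_and_genome

REF = {"chr1": "A" * 200}


def read_at(pos0, seq, name="r", cigar=None, dup=False, mapq=60, quals=None, rev=False):
    quals = quals if quals is not None else [30] * len(seq)
    return AlignedRead(
        read_name=name,
        chrom="chr1",
        pos0=pos0,
        is_reverse=rev,
        cigar=cigar or f"{len(seq)}M",
        seq=seq,
        base_quals=quals,
        mapq=mapq,
        is_duplicate=dup,
    )


class TestBuildPileup:
    def test_duplicates_excluded(self):
        reads = [
            read_at(95, "A" * 10, "a"),
            read_at(98, "A" * 10, "b"),
            read_at(100, "A" * 10, "c", dup=True),
        ]
        cols = {c.pos0: c for c in build_pileup(reads, REF)}
        assert cols[100].depth == 2

    def test_softclip_query_offset(self):
        # CIGAR 5S10M starting at p: reference position p maps to query offset 5
        read = read_at(100, "CCCCC" + "GAAAAAAAAA", cigar="5S10M")
        col = [c for c in build_pileup([read], REF, min_bq=0) if c.pos0 == 100][0]
        assert col.calls[0].base == "G"
        assert read.base_at(100) == ("G", 30)

    def test_quality_floors(self):
        low_mq = read_at(100, "A" * 10, "m", mapq=5)
        low_bq = read_at(100, "G" * 10, "q", quals=[5] * 10)
        cols = build_pileup([low_mq, low_bq], REF)
        assert cols == []

    def test_insertion_and_deletion_walk(self):
        # 4M2I4M: insertion consumes query only; 4M2D4M consumes reference only
        ins = read_at(100, "AAAATTAAAA", cigar="4M2I4M")
        by_ref = {r: q for q, r in ins.aligned_pairs()}
        assert by_ref[103] == 3 and by_ref[104] == 6  # inserted bases skipped
        dele = read_at(100, "AAAAAAAA", cigar="4M2D4M")
        by_ref = {r: q for q, r in dele.aligned_pairs()}
        assert by_ref[103] == 3 and 104 not in by_ref and by_ref[106] == 4

    def test_missing_chrom_raises(self):
        with pytest.raises(KeyError):
            build_pileup([read_at(0, "AAAA")], REF, region=("chrX", 0, 10))

    def test_error_free_depth_matches_truth(self, clean_sim, clean_called, clean_depths):
        """At planted sites the measured depth tracks the molecule count."""
        by_type, _ = clean_called
        truth = clean_sim.truth
        mol_reads = truth.reads.drop_duplicates("molecule_id")
        for row in truth.sites.itertuples():
            for ct in ("HSC", "MEP"):
                cells = {cb for cb, t in truth.barcode_map.items() if t == ct}
                covering = sum(
                    1
                    for m in mol_reads[mol_reads["cb"].isin(cells)]["molecule_id"]
                    if truth.molecule_span[m][0] == row.chrom
                    and truth.molecule_span[m][1] <= row.pos0 < truth.molecule_span[m][2]
                )
                measured = clean_depths[ct][(row.chrom, int(row.pos0))]
                # soft-clipped copies can shorten the aligned span slightly
                assert measured <= covering
                assert measured >= 0.8 * covering - 2


class TestDetectCandidates:
    def _column(self, ref, bases):
        reads = [read_at(100, b * 10, f"r{i}") for i, b in enumerate(bases)]
        reference = {"chr1": ref * 200}
        return build_pileup(reads, reference)

    def test_forward_gene_a_to_g(self):
        cols = self._column("A", ["A"] * 35 + ["G"] * 5)
        (cand,) = [c for c in detect_candidates(cols, frozenset(), "+") if c.pos0 == 100]
        assert (cand.ref_on_strand, cand.alt_on_strand, cand.n_alt, cand.depth) == ("A", "G", 5, 40)

    def test_minus_gene_complements_to_a_to_g(self):
        cols = self._column("T", ["T"] * 30 + ["C"] * 10)
        (cand,) = [c for c in detect_candidates(cols, frozenset(), "-") if c.pos0 == 100]
        assert (cand.ref_on_strand, cand.alt_on_strand) == ("A", "G")
        assert cand.n_alt == 10

    def test_known_snp_flagged(self):
        cols = self._column("A", ["A"] * 20 + ["G"] * 20)
        cands = detect_candidates(cols, frozenset({("chr1", 100)}), "+")
        flagged = {c.pos0: c.is_known_snp for c in cands}
        assert flagged[100] is True and flagged[101] is False

    def test_min_alt_reads_floor(self):
        cols = self._column("A", ["A"] * 38 + ["G"] * 2)
        assert detect_candidates(cols, frozenset(), "+", min_alt_reads=3) == []


class TestScoreSite:
    def cand(self, ref="A", alt="G", n_alt=10, depth=50, snp=False):
        return CandidateSite("chr1", 100, "+", ref, alt, depth - n_alt, n_alt, depth, snp)

    def test_formula_value(self):
        # independent evaluation: z = -2 + 2.5 + 4*0.2 + log10(50)
        z = -2.0 + 2.5 + 4.0 * 0.2 + math.log10(50)
        expected = 1.0 / (1.0 + math.exp(-z))
        p = score_site(self.cand(n_alt=10, depth=50), in_alu=True)
        assert p == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(0.9525, abs=5e-4)

    def test_hard_zero_rules(self):
        assert score_site(self.cand(snp=True), in_alu=True) == 0.0
        assert score_site(self.cand(ref="C", alt="T"), in_alu=True) == 0.0

    def test_monotonicity(self):
        base = score_site(self.cand(n_alt=5, depth=50), in_alu=False)
        assert score_site(self.cand(n_alt=10, depth=50), in_alu=False) > base
        assert score_site(self.cand(n_alt=5, depth=50), in_alu=True) > base
        # higher depth at fixed phi
        lo = score_site(self.cand(n_alt=5, depth=50), in_alu=False)
        hi = score_site(self.cand(n_alt=10, depth=100), in_alu=False)
        assert hi > lo

    def test_custom_weights(self):
        p = score_site(self.cand(n_alt=50, depth=50), in_alu=False, weights=ScoreWeights(0, 0, 0, 0))
        assert p == pytest.approx(0.5)


class TestFilterSites:
    def site(self, depth, p_edit=0.9, pos0=100):
        return EditingSite("chr1", pos0, "+", "A", "G", depth, 5, 5 / depth, p_edit, True)

    def test_depth_boundary(self):
        assert filter_sites([self.site(29)]) == []
        kept = filter_sites([self.site(30)])
        assert len(kept) == 1 and kept[0].depth == 30

    def test_confidence_threshold_and_sorting(self):
        sites = [self.site(40, 0.4, pos0=5), self.site(40, 0.6, pos0=200), self.site(40, 0.9, pos0=10)]
        kept = filter_sites(sites)
        assert [s.pos0 for s in kept] == [10, 200]


class TestCallEditome:
    def test_empty_cell_type(self, clean_sim):
        from screditome.editcall import call_editome

        out = call_editome(
            {"empty": []},
            clean_sim.genome.seqs,
            clean_sim.genome.genes,
            clean_sim.genome.repeats,
            clean_sim.genome.snp_index(),
        )
        assert out == {"empty": []}

    def test_no_snp_and_only_a_to_g_calls(self, clean_sim, clean_called):
        _, sites_by_type = clean_called
        snps = clean_sim.genome.snp_index()
        for sites in sites_by_type.values():
            for s in sites:
                assert (s.chrom, s.pos0) not in snps
                assert (s.ref_on_strand, s.alt_on_strand) == ("A", "G")
                assert s.depth >= 30 and s.p_edit >= 0.5

    def test_deterministic_tables(self, clean_sim):
        _, first = call_sim(clean_sim)
        _, second = call_sim(clean_sim)
        for ct in first:
            a = sites_to_frame(first[ct]).to_csv(index=False)
            b = sites_to_frame(second[ct]).to_csv(index=False)
            assert a == b

    def test_minus_strand_sites_reported_on_gene_strand(self, clean_sim, clean_called):
        """Planted T>C (forward reference) edits come back as A>G, strand '-'."""
        _, sites_by_type = clean_called
        truth = clean_sim.truth.sites
        minus = truth[truth["strand"] == "-"]
        assert len(minus) > 0
        called = {(s.chrom, s.pos0): s for ss in sites_by_type.values() for s in ss}
        n_checked = 0
        for row in minus.itertuples():
            s = called.get((row.chrom, int(row.pos0)))
            if s is None:
                continue
            n_checked += 1
            assert s.gene_strand == "-"
            assert (s.ref_on_strand, s.alt_on_strand) == ("A", "G")
            assert clean_sim.genome.seqs[s.chrom][s.pos0] == "T"
        assert n_checked > 0

    def test_mirrored_genome_gives_mirrored_calls(self):
        """Reverse-complementing the whole problem mirrors the site list."""
        from screditome.bamops import mark_duplicates, split_by_cell_type
        from screditome.editcall import call_editome
        from screditome.model import CellTypeMap
        from screditome.synthetic import simulate
        from conftest import small_config

        sim = simulate(small_config(error_rate=0.0, phi_levels=(0.5, 1.0), cells_per_type=10), seed=19)
        _, orig = call_sim(sim)

        seqs, genes, repeats, snp_index, reads = mirror_reads_and_genome(sim)
        ctmap = CellTypeMap(dict(sim.truth.barcode_map), list(sim.config.cell_types))
        by_type, _ = split_by_cell_type(reads, ctmap)
        for rs in by_type.values():
            mark_duplicates(rs)
        mirrored = call_editome(by_type, seqs, genes, repeats, snp_index)

        lengths = sim.genome.chrom_lengths
        for ct in orig:
            a = {(s.chrom, s.pos0, s.gene_strand, s.ref_on_strand, s.alt_on_strand, s.depth, s.n_alt) for s in orig[ct]}
            b = {
                (s.chrom, lengths[s.chrom] - 1 - s.pos0, "-" if s.gene_strand == "+" else "+",
                 s.ref_on_strand, s.alt_on_strand, s.depth, s.n_alt)
                for s in mirrored[ct]
            }
            assert a == b


def test_site_depths_matches_single_queries(clean_sim, clean_called):
    from screditome.editcall import site_depth

    by_type, _ = clean_called
    reads = by_type["HSC"]
    rows = clean_sim.truth.sites.head(5)
    bulk = site_depths(reads, [(r.chrom, int(r.pos0)) for r in rows.itertuples()])
    for r in rows.itertuples():
        assert bulk[(r.chrom, int(r.pos0))] == site_depth(reads, r.chrom, int(r.pos0))
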