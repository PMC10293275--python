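# Methods

This note records the models, defaults and numerical choices behind
`screditome`, and what the synthetic studies do and do not demonstrate.

## Duplicate model

Droplet scRNA-seq tags every captured mRNA molecule with a cell barcode
(CB) and a unique molecular identifier (UMI) before PCR. Two reads are
PCR copies of the same molecule if and only if they agree on all of
(chromosome, unclipped 5' coordinate, orientation, UMI, CB). The
unclipped coordinate — alignment start minus leading clips for forward
reads, rightmost aligned base plus trailing clips for reverse reads —
makes the key invariant to soft-clipping differences between copies,
mirroring standard duplicate-marking behaviour. Within a group the read
with the largest summed per-base Phred score is kept; ties break to the
lexicographically smallest read name so the choice is deterministic.
UMIs are compared by exact string match (no error-tolerant collapsing),
reads missing either tag are never marked duplicate (they are counted
and logged), and mates of paired-end input are keyed independently — a
documented limitation, acceptable for libraries that put the transcript
on a single read. Secondary and supplementary alignments are excluded
at BAM ingestion by default (`--include-secondary` restores them);
which convention the duplicate definition intends is not observable
from a description alone, and excluding them matches common practice.

The position-only key (chromosome, unclipped 5' position, orientation)
is also implemented as the bulk-style baseline. Since its groups are
unions of molecule-aware groups, the molecule-aware key retains at
least as many reads for any input — the dominance property the test
suite asserts — with equality only when UMIs/CBs collide.

## Editing-site calling

Pileups are built per gene from reads whose orientation matches the
gene's strand, with mapping quality ≥ 20, base quality ≥ 20, duplicates
excluded, and no base-alignment-quality recalibration — the filtering
conventions of `samtools mpileup -B --min-MQ 20 --min-BQ 20
--excl-flags DUP`. The CIGAR walk treats M/=/X as aligned, I/S as
query-consuming, D/N as reference-consuming.

A column becomes a candidate when at least `min_alt_reads` (default 3)
calls mismatch the reference; the alt allele is the most frequent
non-reference base (ties break in A<C<G<T order). Bases are
complemented onto the gene strand for minus-strand genes. Two hard
rules then apply: candidates at known SNP positions and candidates that
are not A>G on the gene strand score zero. The remaining candidates
get a transparent logistic confidence

    z      = β₀ + β_alu·[in Alu] + β_φ·φ + β_d·log10(depth)
    P_edit = 1 / (1 + exp(−z))

with defaults β₀ = −2, β_alu = 2.5, β_φ = 4, β_d = 1 (all configurable).
The score is monotone in each feature: Alu membership and the A-G
identity are the two features known to enrich genuine A-to-I events,
and editing level and depth control the evidence strength. A trained
machine-learning detector could occupy the same interface; a fixed,
documented formula was chosen so that every call is auditable and the
(0, 1) confidence scale is preserved. `min_alt_reads = 3` and the
requirement φ > 0 suppress isolated sequencing-error artifacts.

Sites are reported when depth ≥ 30 (i.e. "coverage less than 30×"
removed) and P_edit ≥ 0.5, sorted by coordinate. Depth is the filtered,
non-duplicate call count, not raw coverage. Homopolymer and end-of-read
artifact filters are not applied; they would be natural extensions.
When two same-strand genes overlap a position the higher-confidence
call wins. C-to-U calling and hyper-editing cluster detection are out
of scope.

## Annotation and strand consistency

Elements are assigned by precedence CDS > 3'UTR > 5'UTR > non-coding
exon > intron > intergenic among genes overlapping the position. Genes
on the calling strand are preferred; among equals the more specific
element, then the smaller gene id, wins — a deterministic total order.
Finer categories (splicing, upstream/downstream) are deliberately
collapsed to these six coarse labels. A site is kept only if some
overlapping gene is transcribed from the strand the site was called on;
intergenic sites have no strand to match and are dropped. Coding and
non-coding exons are kept distinct.

Alu membership is a point-in-interval test against repeat intervals
whose family name starts with "alu" (case-insensitive).

## miRNA seed matching

For a miRNA given 5'→3', the scanner finds in a UTR (gene-strand
sequence) the canonical site types: 6mer (reverse complement of miRNA
positions 2–7), 7mer-m8 (rc of 2–8), 7mer-A1 (rc of 2–7 followed by A)
and 8mer (rc of 2–8 followed by A). Each anchor offset is reported once
with its most specific type; nested shorter matches at shifted anchors
are separate, genuine matches and are reported as such. Re-scanning
after applying A→G edits classifies matches as gained or lost. Wobble
(G:U) pairing, compensatory 3' pairing and context scoring are not
modeled — the scanner answers only whether an editing site falls inside
a canonical seed-match interval.

## Cross-cell-type profiles

The editing matrix contains the union of called sites restricted to
those covered ≥ 30× in **every** population; entries are P_edit, with 0
meaning covered-but-not-edited there. A site is *edited* in a
population when its entry is positive. Patterns are mutually exclusive
and exhaustive: shared (edited everywhere), group-specific (edited-set
equals exactly one lineage group — defaults lymphoid = {LMPP, MLP},
myeloid = {MEMP, CMP, GMP, MEP}, HSC/MPP = {HSC, MPP}), type-specific
(exactly one population), other.

Co-editing modules follow the weighted correlation network recipe on
the site × population P_edit profiles: Pearson correlation, unsigned
adjacency |cor|^β (unsigned is the cited package default; the
description does not specify signed vs unsigned), topological overlap

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

and average-linkage clustering of 1 − TOM with a static cut (default
height 0.995) and minimum module size 30; smaller clusters stay
unassigned (label 0) and modules are numbered by decreasing size. A
static cut stands in for dynamic tree cutting, whose exact variant and
parameters are not reconstructable; the height is configurable. The
soft power β is the smallest integer in 1..20 whose network reaches a
scale-free fit index of 0.8. The fit regresses log10(frequency) on
log10(mean connectivity) over 10 equal-width connectivity bins and is
signed by the slope (−sign(slope)·R²), since a scale-free degree
distribution must *decrease*; equal-occupancy binning is unusable here
because it forces a flat frequency by construction. If no power
reaches the cutoff the argmax-R² power is used with a warning. With
only 8 population columns the correlations are noisy; rows with fewer
than two distinct values are dropped before correlating. Whether the
original analysis correlated over 8 population values or finer
replicates is unknown; this implementation uses the population columns
and the tests exercise the network machinery on matrices with more
columns where statistical stability is required. Specific power values
and module counts are data-dependent and are not treated as expected
results. Eigengenes, module–trait correlation and GO enrichment are out
of scope.

## Per-cell assignment and expression comparison

A cell is *edited* at a site when ≥ 1 of its deduplicated reads passing
the MQ/BQ ≥ 20 floors carries the edited base (G on the gene strand, so
C against the forward reference for minus-strand genes). "Expressing"
means raw UMI count > 0 for the gene. The edited fraction is
|edited ∩ expressing| / |expressing|, with a cell counting as edited if
edited at any of the gene's sites; dropout cells leave both numerator
and denominator. Expression comparison uses
log2(mean(edited)+ε) − log2(mean(unedited)+ε) with ε = 1e−9 guarding
empty means, on either raw counts or library-size-normalized log1p
values (both offered; results should be labeled by mode). The p-value
is a two-sided Wilcoxon rank-sum: exact enumeration over all
C(n₁+n₂, n₁) rank assignments when both groups have ≤ 10 observations
(the extremeness test uses a 1e−9 tolerance on rank-sum deviations so
midranks compare safely), otherwise the tie-corrected normal
approximation without continuity correction.

## Synthetic study conditions

The generator emulates a strand-specific droplet experiment at the
aligned-record level. Defaults, chosen once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| populations | 8 (HSC, MPP, LMPP, MLP, MEMP, CMP, GMP, MEP), 20 cells each | the progenitor hierarchy the lineage groups describe |
| genome | 2 chromosomes, 8 genes (alternating strands), exons 400+550 bp, 300 bp intron | smallest layout exercising both strands, splicing structure and every element class |
| read length | 100 bp, CB 16 bp, UMI 10 bp | droplet chemistry with a 100-bp transcript read |
| pseudo-bulk coverage | 40× per population (one gene at 0.4×, to exercise the coverage filter) | enough to clear the 30× floor away from exon edges |
| duplication rate | 0.30 per molecule (geometric, ≤ 4 extra copies) | moderate PCR amplification |
| sequencing error | 1e−3 per base, uniform substitution | Phred ~30 instruments |
| base qualities | uniform 30–40, mapq 60 | all pass the 20/20 floors, so filtering behaviour is governed by flags not qualities |
| soft clips | 5 bp at the 5' end of 15% of reads | exercises unclipped-coordinate deduplication |
| editing sites | 40; φ ∈ {0.1, 0.3, 0.6, 1.0}; patterns 40% shared / 30% group / 30% type-specific; 94% in Alu; elements 75% 3'UTR, 15% CDS, 10% 5'UTR | the Alu fraction and 3'UTR dominance observed for human A-to-I editing |
| SNPs | 12 heterozygous A>G (gene strand), alt fraction 0.5 | the confounder class the SNP index must remove |

Editing is molecule-level: each molecule covering a planted site
carries G with probability φ(site, population). Reads are confined to
single exons (no splice-junction reads), so planted sites sit in the
full-coverage plateau of an exon; intronic editing, which in real data
dominates via pre-mRNA reads, is therefore not simulated. A planned
soft-clip is suppressed when it would cut across a planted site so that
molecule-level truth stays exact for every PCR copy. Other realism
gaps: no barcode/UMI sequencing errors, no instrument-specific quality
profiles, no ambient RNA, no overlapping genes, uniform expression
within a population. Passing tests therefore demonstrate correctness
of the algorithms under the stated model, not performance on real
tissue.

Every stochastic step runs off one `numpy` seed sequence per component,
so outputs are byte-identical per seed.

## Problem sizes in the checks

The test-suite and `scripts/acceptance.py` measure: duplicate-marking
oracle equivalence on libraries up to 2,000 reads; caller recall/FDR on
runs with 3 populations × 6 genes at 100× (noise 1e−3, all φ levels),
aggregated over seeds; exactness checks (coverage filter, annotation,
patterns, per-cell assignment) on a noiseless 8-population run at 60×
with φ ≥ 0.5; module recovery on 2 × 40-site planted blocks over 40
profile columns at fixed power 6; rank-sum enumeration up to n₁ = n₂
= 10 against an independent pairwise-count oracle and the asymptotic
branch against an independent reference implementation. These sizes
keep a full run in a few minutes on one CPU while leaving each measured
quantity statistically meaningful.
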