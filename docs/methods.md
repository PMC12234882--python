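# Methods

This note records the models, parameter choices and numerical decisions
behind `scmeth`, and what the synthetic-data generator does and does not
emulate.

## Scope and data model

All coordinates are 0-based half-open in memory; BED output stays 0-based
and VCF is 1-based. A CpG is addressed by the position of its top-strand C;
the paired G is at `pos + 1`. Directional bisulfite reads carry a
parent-strand label: original-top (OT) reads report the top strand (C =
methylated, T = unmethylated at a CpG C) and original-bottom (OB) reads the
mirror evidence at the paired G. Read ends are trimmed before any counting
(10 bp at the 5' end, 5 bp at the 3' end by default) because random-priming
ends carry methylation bias. Reads flagged duplicate, or with mapping
quality below 40, never contribute.

## Methylation calling and conversion QC

`methcall.call_methylation` piles up per-(cell, CpG, strand, allele)
counts; β = methylated / total. CG merging, when requested, combines the
two strands of a dyad only within the same allele (or both unassigned) so
hemi-methylation remains measurable in allele-resolved data.

Conversion QC counts retention at non-CpG cytosines by context (CpA, CpC,
CpT); CpY retention is the mean of the CpC and CpT rates. Two read filters
exist with different defaults: the alignment-polishing filter removes
reads with *more than one* CpY retention event; the strict variant used
for cross-protocol comparisons removes reads with *one or more*.

## The discordance metric

For sites covered i ≥ 2 times, with d_i discordant (0 < β < 1) of n_i
total,

D = [Σ d_i · 2^i/(2^i − 2)] / [Σ n_i].

Under random assortment of i independent calls, P(discordant) =
(2^i − 2)/2^i, so each depth's contribution is normalized to 1 under
randomness; D is therefore comparable across depth compositions, and a
property test verifies D → 1 on coin-flip data at mixed depths.

D is computed here on **strand-resolved** allele-resolved calls for QC
purposes: conflicting calls for the *same cytosine on the same strand of
the same allele* indicate errors, S-phase parent/daughter-strand mixtures,
or doublets — whereas hemi-methylation (a biological signal) lives across
strands and must not inflate the QC statistic. The resulting bands are:
clean G1 cells near zero, S-phase cells elevated but below 3%, doublets
above 3% (2% is the exclusion default, 3% the doublet band).

## Cell exclusion and anomalous regions

Cells are excluded when covering fewer than 20% of genomic CpGs or when
sequenced past a species cap (55 M reads human, 80 M mouse; both
overridable). Anomalous high-coverage regions are found on 100 bp windows
tiled every 50 bp (a read counts when overlapping at least half a window):
per cell, windows above the cell's 80th count percentile are flagged and
extended while above the 67th (strict inequalities; percentiles are
linear-interpolation/type-7), flagged runs ≤ 250 bp apart merge, a window
is anomalous when flagged in > 90% of cells, and anomalous regions
< 250 bp apart join. The procedure presupposes heavy-tailed real coverage;
on uniform synthetic coverage individual cells flag many windows but the
90% cross-cell vote removes them, which the tests exercise both ways.

## Allele resolution

*Strict deduplication* unpairs reads (mate links cleared, read number
appended to the name) and re-marks duplicates in single-end mode on
(chrom, start, strand): multiple rounds of random priming can produce
pairs with identical first-read starts but different mate starts, which
pair-aware tools miss and which otherwise cause false variant calls.

*Variant discovery* piles trimmed, ≤ 7-mismatch reads (mismatches counted
against the unpatched reference, excluding conversion-consistent changes)
into per-base evidence that ignores conversion-ambiguous observations (a
read T on OT never supports a C/T decision; a read A on OB never a G/A
decision). Candidate het SNVs must have pseudo-bulk alt frequency in
[0.25, 0.75] over unambiguous evidence, a quorum of supporting cells
(≥ max(5, 5% of cells), a cell supports with ≥ 1 unambiguous alt read),
and must not lie in a 500 bp bin with mean read MAPQ < 45.

*Deconversion* rewrites a read as: reference everywhere, except at known
het SNVs where an ambiguous base becomes N and an informative base the
supported allele. (The corresponding rule for inserted bases is vacuous
here because the read model carries no indels.) Deconversion is
idempotent.

*Phasing* accumulates cis/trans votes for SNV pairs co-observed on a
fragment (mates pooled; within-fragment conflicting evidence for one SNV
is dropped). Edges resolve greedily in decreasing |cis − trans| order over
a union-find with parity; a tie breaks the edge, and an edge with net
majority weight below 2 is not trusted either — a single erroneous
fragment must not join or mis-orient a phase set. Anything never linked
becomes a singleton phase set. This greedy majority solver replaces an
external quality-aware phaser; it is validated purely by truth recovery.

*Haplotagging* trims (10/5), drops reads with ≥ 7 mismatches, pools SNP
evidence across mates, picks the phase set with the most informative SNVs
(cross-set tie → unassigned) and takes the majority vote within it (vote
tie → unassigned). On error-free simulations precision against truth tags
is exactly 1; at base error 10⁻³ the irreducible floor is single-SNV reads
whose one informative base is an error mimicking the other allele
(≈ err/3), giving ~99.97% precision at ~84k assigned reads on the 5 Mb
benchmark.

*ARM calling* runs against a patched reference containing all possible
CpGs (alt alleles of CpG-creating SNVs applied), annotates each call with
the contributing phase sets, and discards: calls at a CpG-creating or
-destroying SNV on the allele lacking the CpG; calls whose reads span
multiple phase sets; CpGs whose both bases are SNVs.

*Two-strand states* classify dyads covered on both strands of one allele
(consistent phase sets, no intra-strand conflict) as sym_meth / hemi /
sym_unmeth; counts are conserved by construction. TFBS enrichment reports,
per cell group and TFBS set, the fraction of sym_meth and of hemi events
overlapping the set, dropping sets with ≤ 250 events in either class;
hemi is read against the methylation fraction because absolute
hemi-methylation tracks overall TFBS methylation.

## Cell typing

Marker-region scores are mean β over covered CpGs in each cell type's
hypomethylated region set; the quadrant classifier at 0.65 labels cells
(own-type score low, other high), with both-low marking mixed-type
doublets. Promoters are TSS −1500/+200 strand-aware; the display set keeps
promoters with > 25% of CpGs covered in ≥ 60% of cells and cross-cell SD
> 0.2; clustering is Ward on Euclidean distance; differential testing is
an unpaired two-sided t-test per promoter with Benjamini–Hochberg
correction, and promoters overlapping a CpG island by ≥ 200 bp are
annotated.

## Masked NMF

The solver minimizes squared error over observed entries only, by
alternating closed-form two-variable non-negative least squares per
row/column (vectorized normal equations; the fallback for an infeasible
unconstrained optimum compares the two axis solutions). Tolerance 10⁻⁶
relative objective change, ≤ 500 iterations, seeded uniform
initialization. The objective is non-increasing per iteration and the fit
is provably independent of masked values; both are asserted in tests.

Input construction: stack [β; 1 − β] so per-cell column sums are
independent of overall methylation level; observed zeros become 10⁻¹²
(sparse-storage sentinel), missing entries 0 under the mask; columns are
scaled to unit sum over observed entries and then log1p-transformed. The
exact "column-normalized and log-transformed" recipe is a dialect choice:
a plain log of sub-1 normalized values would be negative, which NMF cannot
factor, so log1p is used. CpG selection for the genome-wide cell map takes
CpGs at or above the 25th percentile of cell-coverage and the 67th of
cross-cell SD (≥, because the coverage distribution saturates at the cell
count under deep simulation, tying the percentile to the maximum).

For chromosome X, every allele-resolved CpG contributes a β and a
complement feature per local allele (≤ 4 features per CpG). After
factorization: features > 500 bp from a CpG island are dropped, features
with either loading above that factor's 95th percentile are dropped,
loadings are scaled to max 1, and features whose scaled loading falls
outside [0.05, 0.85] (0.75 preset for human fibroblasts) in both factors
are dropped. Features join their argmax factor; each CpG's local allele
maps to NMF allele A/B by majority vote over its features (a methylation
feature votes its factor, a complement feature the opposite; local allele
2 votes are flipped), ties discarded. Cell groups are argmax cell
loadings. Labels are arbitrary up to one joint permutation; scoring
against truth evaluates both.

## Replication dynamics

RPMM = bin count × 10⁶ / total retained reads. Bins outside a cell's
5th–95th RPMM percentile in > 75% of cells, or with > 10% missing data,
are excluded. Ideal cells have coarse-bin (default 5 Mb) within-bin SD
< 2.5 and whole-genome SD of coarse-bin means in (1, 1.75); these
absolute thresholds are calibrated to genome-scale RPMM magnitudes, so on
the small synthetic genome the pipeline either passes scale-appropriate
bounds or falls back (with a warning) to the all-cell per-bin median,
which is equivalent when most cells are G1. Corrected values hover near 1,
making the ploidy mode rule scale-free.

Timing scores: per 50 kb bin, the score-weighted mean of the indices of
the three highest repli-seq fractions, rounded half-up; bins scoring 1,
15, 16 (or all-zero) are excluded; groups are very_early 2–4, early 5–8,
late 9–12, very_late 13–14. Phase calls: S when the very-early share of
corrected reads (grouped bins only) exceeds 0.335 and allele-resolved
D < 0.03; doublet when D > 0.03; pG2 when the read distribution is even
(share ≤ 0.335) but D exceeds the provisional-G1 median + 3×MAD — the
paper-style categories with the pG2 boundary formalized here, since no
numeric rule exists for it. Ploidy: Gaussian-KDE mode (Silverman
bandwidth) of corrected values; values / mode × 2 when the mode ≤ 1.1 and
the cell is not G2-flagged, else × 4. Methylation-state profiles
discretize β from CpGs covered ≥ 2× into {0, (0,1), 1} per 50 kb bin,
drop bins with < 15 measurements, group by rounded ploidy, and weight
bins by their RPMM share. CNV clustering averages corrected RPMM into
0.5 Mb bins and cuts a Ward tree at k clusters, optionally pre-filtering
cells with < 24% very-early reads or too few CpGs.

## X-inactivation

Direct calls need chromosome-scale phasing (a strain-cross SNP catalog in
practice; the simulator truth in the pipeline's known-SNP mode): per cell,
mean CpG-island β per allele, cells with < 50 calls on either allele
removed; the inactive X is the allele with the higher mean when the means
separate by ≥ 0.2, otherwise ambiguous (where opposite-state doublets
land). The margin is a choice of this package; the underlying separation
in clean cells is near-total, so its exact value is uncritical. Xa/Xi
feature summaries pool calls across confidently-called cells over CGI
promoters (CGI within TSS −1.5 kb/+1 kb), non-promoter CGIs, non-CGI
promoters (TSS −1.5 kb/+200 bp without a nearby CGI) and CGIs ± 500 bp
shores, dropping features with < 100 calls. The metagene profile uses
genes whose promoters have ≥ 100 calls, Xa mean < 0.25 and Xi mean
> 0.25; bodies scale to a common axis (50 bins) with ± 5 kb flanks (25
bins each), body bins weighted by gene length, smoothed by lowess with
span 0.2. Bin counts are artifact choices.

Cross-passage transfer phases another cohort's calls through the NMF
allele map keyed by (CpG, local allele) — valid when both cohorts share
the phasing that defined the local labels. CGI variability (SD of
per-allele CGI β across cells, ≥ 3 cells) separates a mixed-XCI
population (high chrX SD) from a drifted one; differential CGIs require
cross-cell SD > 0.2 with < 20% missing ("variable") and per-cluster
two-sided t-tests at BH-adjusted p < 0.01 with |Δβ| > 0.15.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions under which every claim above is validated.

**Genome.** Two 2 Mb autosomes and a 1 Mb chrX of A/T-rich, CpG-depleted
background sequence; CpG islands (CG-dense blocks, ~400–1200 bp) at every
chrX TSS, half of autosomal TSSs, and free-standing every ~20 kb; gene
models every ~15 kb with random strand; per-type marker region sets and
four TFBS sets on autosomes, disjoint from islands; PMDs defined as the
latest-replicating quintile, containing solo-WCGW CpGs (A/T-flanked, no
CpG neighbour within 35 bp). Replication timing is a smooth wave over
50 kb bins spanning scores ~2–14 with Gaussian 16-fraction profiles; the
composition leaves the retained very-early share near 0.31 — an
early-skewed genome on which the 33.5% very-early-read rule can separate
all S-phase stages from G1 (a share much below ~0.30 provably loses
late-S cells, one above ~0.335 mislabels G1).

**Diploid truth.** Het SNVs at 1/600 bp (Bernoulli per base, adjacent
positions thinned), ~15% biased toward CpG-creating alternates; each SNV
phased to a haplotype; per-allele sequences and CpG sets derived.

**Cells.** Types from the configured mixture; the inactive X drawn 50/50;
15% S-phase (progress uniform in 0.2–0.8), 5% G2, 5% doublets (a second
full cell sharing the well). Methylation states draw from a shared
per-chromosome random field so the two alleles agree except for a 2%
allele-specific flip rate plus the planted structure: background 0.80,
CGIs 0.05, Xi CGIs 0.90 (minus escapees), own-type marker regions 0.12 vs
0.88 elsewhere, type-specific promoters 0.08/0.90, solo-WCGW 0.60, chrX
promoters and gene bodies split by Xa/Xi. Residual G1 hemi-methylation
rises with timing score (0.5% → 2.5%); S-phase cells replicate bins in
timing order up to their progress, doubling copy number there, with
daughter strands unremethylated at 3.5–5% (monotone in timing score).
These three rates are set jointly so that the validated structures
coexist: hemi share rising with timing score in G1 cells, replicated 4n
bins showing more partial methylation than 2n bins mid-S, and S-phase
strand-resolved discordance staying inside the 3% band that separates S
cells from doublets.

**Reads.** Pre-aligned directional pairs (coordinates exact, MAPQ 60):
fragments sampled with bin weights proportional to copy number; allele,
duplex (parental vs daughter-containing) and parent strand drawn
uniformly; C→T (or G→A) conversion applied from the chosen strand's
state; i.i.d. substitution errors at 10⁻³; exact-duplicate pairs (2%,
FLAG-marked) and re-primed same-R1/different-R2 pairs (1%, unmarked — the
strict dedup target); a configurable fraction of low-MAPQ randomized
reads exercises filters. True allele and cell ride in scoring-only tags.
Per-cell RNG streams derive from (seed, stage, crc32(cell id)), so a
fixed seed reproduces outputs byte-identically regardless of call order.

**Not emulated** — and therefore not demonstrated by passing tests:
indels and structural variation, CpH methylation (retention QC still
measures its absence), base-quality strings, alignment errors beyond the
randomized low-MAPQ fraction, imprinting, chromatin-state-linked coverage
bias, and the long-tailed coverage artifacts real anomalous-region
scans target. The direct XCI cohort generator
(`simulate_xci_cohort`) emits allele-resolved β values rather than reads;
it scrambles local allele labels per CpG island to pose exactly the
problem the NMF inference solves, and can inherit another cohort's
labeling to emulate shared phasing across passages.

## Problem sizes used in validation

The haplotag benchmark uses the full default genome (5 Mb, ~8.3k SNVs,
~206k read pairs at 8×, error 10⁻³). The XCI benchmark uses 96 cells ×
240 CGIs at 30% coverage. Test cohorts elsewhere use 0.2–2.5 Mb genomes
with 6–18 cells at 3–5× — sizes chosen so each check retains comfortable
statistical power while the whole suite stays interactive.

## Known limitations

- The ideal-cell SD thresholds are genome-scale constants; small genomes
  rely on the documented all-cell-median fallback.
- The greedy phaser is validated by truth recovery only; its tie and
  weak-link behavior is deliberately conservative and will fragment phase
  sets faster than a quality-aware solver on noisy data.
- The pG2 boundary (G1 median + 3×MAD) is a formalization of a
  qualitative description, not an estimated operating point.
- Real-genome converted base composition (≈ 49% T / 30% A / 20% G / 1% C)
  is reproducible with `converted_base_composition` given an mm10 or hg38
  FASTA (place one at `data/reference/genome.fa` to enable the
  corresponding check); the packaged synthetic genome reproduces the
  qualitative T-rich/C-poor profile only.
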