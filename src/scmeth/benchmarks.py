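"""End-to-end validation benchmarks on synthetic ground truth.

Two headline checks: read-to-allele assignment precision on an artificial
heterozygous diploid genome, and recovery of X-inactivation structure by
the SNP-free NMF route.  Both generate their inputs, run the full method,
and score against the simulator's truth tags.
"""

from __future__ import annotations

import dataclasses

from . import arm
from .simulate import (SimConfig, emit_reads, generate_cells,
                       generate_diploid, generate_reference,
                       score_xci_recovery, simulate_xci_cohort)
from . import xci as xci_mod


def haplotag_benchmark(seed: int = 1, genome_mb: float = 5.0,
                       depth: float = 8.0, error_rate: float = 0.001) -> dict:
    """Precision of read-to-allele assignment against simulator truth.

    An artificial diploid genome (default 5 Mb, ~1 het SNV per 600 bp)
    yields directional bisulfite read pairs (default ~200k pairs at 8x)
    with a low base error rate.  The known (unphased) SNV positions feed
    strict deduplication, deconversion-based read-backed phasing, and
    majority-vote haplotagging with 10/5 trimming and the 7-mismatch
    filter; precision is the fraction of assigned reads whose implied
    allele matches the truth tag.
    """
    auto = int(genome_mb * 1e6 * 0.4)
    cfg = SimConfig(
        seed=seed,
        autosomes={"chr1": auto, "chr2": auto},
        chrx_size=int(genome_mb * 1e6 * 0.2),
        n_cells=1, depth=depth, error_rate=error_rate,
        s_phase_fraction=0.0, g2_fraction=0.0, doublet_rate=0.0,
        mapq_low_fraction=0.0)
    ref = generate_reference(cfg)
    diploid = generate_diploid(ref, cfg)
    cells = generate_cells(ref, diploid, cfg)
    reads = emit_reads(cells[0], diploid, ref, cfg)

    unphased = [dataclasses.replace(s, hap_of_alt=0, phase_set_id=-1)
                for s in diploid.snps]
    deduped = arm.strict_deduplicate(reads)
    phased = arm.phase_variants(deduped, unphased, ref)
    tagged = arm.assign_reads(reads, phased, ref)
    truth = {(s.chrom, s.pos): s.hap_of_alt for s in diploid.snps}
    score = arm.score_haplotag_precision(tagged, phased, truth)
    score["precision_pct"] = 100.0 * score["precision"]
    score["n_reads"] = len(reads)
    score["n_snps"] = len(diploid.snps)
    return score


def xci_nmf_benchmark(seed: int = 1, n_cells: int = 96, n_cgi: int = 240,
                      coverage: float = 0.3) -> dict:
    """R² between NMF-inferred and truth per-locus group-mean methylation.

    A sparse allele-resolved chromosome X cohort (two X-inactivation
    states, local allele labels scrambled per CpG island) goes through the
    rank-2 masked NMF procedure with the stated feature filters and
    majority-vote CpG assignment; the squared Pearson correlation between
    group means under inferred and truth labels (best label permutation)
    is reported.
    """
    cohort = simulate_xci_cohort(n_cells=n_cells, n_cgi=n_cgi,
                                 coverage=coverage, seed=seed)
    result = xci_mod.nmf_xci(cohort.calls, cohort.cgis, seed=seed)
    score = score_xci_recovery(cohort, result)
    score["n_cells"] = n_cells
    score["n_features"] = len(result.feature_table)
    return score
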