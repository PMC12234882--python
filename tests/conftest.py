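"""Shared fixtures: one clean error-free cohort reused across test modules.

The base cohort is all-G1, doublet-free and error-free so that truth-
recovery assertions are exact; tests needing noise, S-phase cells or
doublets build their own smaller cohorts.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from scmeth import arm, methcall
from scmeth.simulate import (SimConfig, emit_reads, generate_cells,
                             generate_diploid, generate_reference)

BASE_CFG = SimConfig(
    seed=7,
    autosomes={"chr1": 500_000},
    chrx_size=300_000,
    n_cells=10,
    depth=5.0,
    error_rate=0.0,
    s_phase_fraction=0.0,
    g2_fraction=0.0,
    doublet_rate=0.0,
    mapq_low_fraction=0.0,
    dup_rate=0.02,
    strict_dup_rate=0.01,
    hemi_base=0.02,
    hemi_slope=0.10,
)


@pytest.fixture(scope="session")
def base_cfg() -> SimConfig:
    return dataclasses.replace(BASE_CFG)


@pytest.fixture(scope="session")
def base_ref(base_cfg):
    return generate_reference(base_cfg)


@pytest.fixture(scope="session")
def base_diploid(base_ref, base_cfg):
    return generate_diploid(base_ref, base_cfg)


@pytest.fixture(scope="session")
def base_cells(base_ref, base_diploid, base_cfg):
    return generate_cells(base_ref, base_diploid, base_cfg)


@pytest.fixture(scope="session")
def base_reads(base_cells, base_diploid, base_ref, base_cfg):
    return {c.cell_id: emit_reads(c, base_diploid, base_ref, base_cfg)
            for c in base_cells}


@pytest.fixture(scope="session")
def base_calls(base_reads, base_ref):
    flat = [r for rs in base_reads.values() for r in rs]
    return methcall.call_methylation(flat, base_ref)


@pytest.fixture(scope="session")
def base_tagged(base_reads, base_diploid, base_ref):
    """Reads haplotagged against the truth-phased SNP catalog."""
    flat = [r for rs in base_reads.values() for r in rs]
    return arm.assign_reads(flat, base_diploid.snps, base_ref)


@pytest.fixture(scope="session")
def base_arm_calls(base_tagged, base_ref, base_diploid):
    patched = arm.patch_reference(base_ref, base_diploid.snps)
    return arm.call_arm(base_tagged, patched, base_diploid.snps)


@pytest.fixture(scope="session")
def base_states(base_arm_calls):
    return arm.two_strand_states(base_arm_calls)


@pytest.fixture(scope="session")
def s_phase_cohort():
    """Cohort with S, G1 and G2 cells at default-size genome statistics."""
    from scmeth import arm, qc
    from scmeth.simulate import (SimConfig, emit_reads, generate_cells,
                                 generate_diploid, generate_reference)
    cfg = SimConfig(seed=17, autosomes={"chr1": 1_500_000},
                    chrx_size=1_000_000, n_cells=18, depth=3.0,
                    error_rate=0.0, s_phase_fraction=0.45, g2_fraction=0.0,
                    doublet_rate=0.0, mapq_low_fraction=0.0)
    ref = generate_reference(cfg)
    dip = generate_diploid(ref, cfg)
    cells = generate_cells(ref, dip, cfg)
    reads = {c.cell_id: emit_reads(c, dip, ref, cfg) for c in cells}
    flat = [r for rs in reads.values() for r in rs]
    tagged = arm.assign_reads(flat, dip.snps, ref)
    patched = arm.patch_reference(ref, dip.snps)
    arm_calls = arm.call_arm(tagged, patched, dip.snps)
    from scmeth.replication import (bin_read_counts, classify_phase,
                                    replication_scores, rpmm_normalize)
    counts = bin_read_counts(reads, {c: len(s)
                                     for c, s in ref.chromosomes.items()})
    rp = rpmm_normalize(counts, coarse_bin_size=500_000,
                        ideal_sd_range=(0, np.inf), coarse_sd_max=np.inf)
    scores = replication_scores(ref.repliseq)
    d_by_cell = qc.discordance_by_cell(arm_calls)
    cells_df = pd.DataFrame({
        "cell": [c.cell_id for c in cells],
        "arm_discordance": [d_by_cell.get(c.cell_id) for c in cells]})
    phases = classify_phase(cells_df, rp.corrected, scores)
    return dict(cfg=cfg, ref=ref, cells=cells, rp=rp, scores=scores,
                phases=phases, arm_calls=arm_calls)

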