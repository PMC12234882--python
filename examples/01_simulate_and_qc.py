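"""Simulate a small single-cell bisulfite cohort and inspect per-cell QC.

Builds a 650 kb diploid genome with phased het SNVs, emits directional
bisulfite reads for 8 cells (including possible doublets), extracts
methylation calls, and prints the discordance metric D per cell.
D near 0 marks clean single cells; a doublet mixes two epigenomes and
pushes allele-resolved D above the 2% exclusion threshold.
"""

from scmeth import arm, methcall, qc
from scmeth.simulate import (SimConfig, emit_reads, generate_cells,
                             generate_diploid, generate_reference)

cfg = SimConfig(seed=11, autosomes={"chr1": 400_000}, chrx_size=250_000,
                n_cells=8, depth=5.0, doublet_rate=0.15)
ref = generate_reference(cfg)
diploid = generate_diploid(ref, cfg)
cells = generate_cells(ref, diploid, cfg)
reads = {c.cell_id: emit_reads(c, diploid, ref, cfg) for c in cells}
flat = [r for rs in reads.values() for r in rs]

calls = methcall.call_methylation(flat, ref)
tagged = arm.assign_reads(flat, diploid.snps, ref)
arm_calls = arm.call_arm(tagged, arm.patch_reference(ref, diploid.snps),
                         diploid.snps)

print(f"{len(diploid.snps)} het SNVs, {len(flat)} reads, "
      f"{len(calls)} methylation calls\n")
print("cell      truth            summarized D  allele-resolved D  doublet?")
d_sum = qc.discordance_by_cell(calls)
d_arm = qc.discordance_by_cell(arm_calls)
for c in cells:
    label = f"{c.cell_type}/{c.phase}" + (" doublet" if c.is_doublet else "")
    flag = "yes" if d_arm.get(c.cell_id, 0) > 0.02 else "no"
    print(f"{c.cell_id}  {label:16s} {d_sum[c.cell_id]:.4f}        "
          f"{d_arm.get(c.cell_id, float('nan')):.4f}             {flag}")
print("\nSummarized D folds in allele differences and hemi-methylation; "
      "allele-resolved D isolates errors and cell mixing, which is why the "
      "doublet filter uses it.")
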