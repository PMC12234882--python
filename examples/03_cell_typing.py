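"""Cell typing three ways: marker-region scores, promoters, masked NMF.

A cell type is hypomethylated in its own marker regions, so the mean β in
each type's region set classifies cells directly; promoter differential
methylation refines the groups; and rank-2 masked NMF recovers them with
no supervision at all.
"""

from scmeth import celltype, methcall
from scmeth.simulate import (SimConfig, emit_reads, generate_cells,
                             generate_diploid, generate_reference)

cfg = SimConfig(seed=5, autosomes={"chr1": 400_000}, chrx_size=200_000,
                n_cells=10, depth=5.0, doublet_rate=0.0)
ref = generate_reference(cfg)
diploid = generate_diploid(ref, cfg)
cells = generate_cells(ref, diploid, cfg)
reads = [r for c in cells for r in emit_reads(c, diploid, ref, cfg)]
calls = methcall.call_methylation(reads, ref)

scores = celltype.celltype_scores(calls, ref.celltype_regions)
labels = celltype.classify_cells(scores, gi_col="GI", t_col="T")
print("cell      GI score  T score   label            truth")
for c in cells:
    row = scores.loc[c.cell_id]
    print(f"{c.cell_id}  {row['GI']:.3f}     {row['T']:.3f}     "
          f"{labels[c.cell_id]:16s} {c.cell_type}")

cmap = celltype.nmf_cell_map(calls, seed=0)
print(f"\nmasked NMF over {len(cmap.loci)} variable CpGs "
      f"({cmap.result.n_iter} iterations):")
agree = sum(1 for c in cells
            if cmap.labels[c.cell_id]
            == cmap.labels[[d.cell_id for d in cells
                            if d.cell_type == c.cell_type][0]])
print(f"  factor assignment groups {agree}/{len(cells)} cells with their "
      "own type — unsupervised recovery of the marker-based classes.")
solo = celltype.solo_wcgw_score(calls, ref.solo_wcgw)
print(f"\nmean solo-WCGW methylation {solo.mean():.3f} "
      "(tracks cumulative cell divisions; lower = older lineage)")
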