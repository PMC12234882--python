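"""Cell-type assignment from methylation calls.

Three complementary routes, in increasing order of model freedom:
supervised scores over cell-type-specific hypomethylated regions (a cell is
hypomethylated in its own type's marker regions), promoter differential
methylation with hierarchical clustering, and unsupervised sparse masked
rank-2 NMF over variable CpGs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import IntervalSet, cpg_positions
from .nmf import NMFResult, masked_nmf, prepare_beta_matrix

logger = logging.getLogger(__name__)

CLASSIFY_THRESHOLD = 0.65


def celltype_scores(calls: pd.DataFrame, region_sets: dict) -> pd.DataFrame:
    """Mean β of covered CpGs in each type's marker regions, per cell.

    Returns a cells × types DataFrame; NaN where a cell covers no CpG of a
    set.  Empty region sets are omitted.
    """
    cols = {}
    for t, regions in region_sets.items():
        if not isinstance(regions, IntervalSet):
            regions = IntervalSet(regions)
        if len(regions) == 0:
            continue
        masks = []
        for chrom, sub in calls.groupby("chrom"):
            inside = regions.contains(chrom, sub["pos"].to_numpy())
            masks.append(sub.index[inside])
        idx = np.concatenate(masks) if masks else np.array([], dtype=int)
        sub = calls.loc[idx]
        cols[t] = sub.groupby("cell")["beta"].mean()
    out = pd.DataFrame(cols)
    return out.reindex(sorted(calls["cell"].unique()))


def classify_cells(scores: pd.DataFrame, gi_col: str = "GI", t_col: str = "T",
                   threshold: float = CLASSIFY_THRESHOLD) -> pd.Series:
    """Quadrant classification on the GI-epithelial and Blood-T scores.

    A cell type is hypomethylated in its own marker regions, so GI < t and
    T > t reads "GI epithelial"; both low marks a mixed-type doublet.
    """
    labels = {}
    for cell, row in scores.iterrows():
        gi, tc = row.get(gi_col), row.get(t_col)
        if gi is None or tc is None or np.isnan(gi) or np.isnan(tc):
            labels[cell] = "Unclassified"
        elif gi < threshold and tc > threshold:
            labels[cell] = "GI epithelial"
        elif gi > threshold and tc < threshold:
            labels[cell] = "Lymphocyte"
        elif gi < threshold and tc < threshold:
            labels[cell] = "Doublet"
        else:
            labels[cell] = "Other"
    return pd.Series(labels, name="label")


# --------------------------------------------------------------------------
# promoter methylation
# --------------------------------------------------------------------------


@dataclass
class PromoterAnalysis:
    matrix: pd.DataFrame        # cells x promoters, mean beta
    visual_set: list            # promoter names passing the display filters
    linkage: np.ndarray | None  # Ward linkage over cells (visual set)
    tests: pd.DataFrame         # per-promoter differential tests


def promoter_intervals(genes: pd.DataFrame, up: int = 1500,
                       down: int = 200) -> pd.DataFrame:
    """TSS −up/+down windows, strand-aware."""
    rows = []
    for g in genes.itertuples():
        if g.strand == "+":
            s, e = g.start - up, g.start + down
        else:
            s, e = g.end - down, g.end + up
        rows.append((g.chrom, max(0, s), e, g.name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def promoter_analysis(calls: pd.DataFrame, genes: pd.DataFrame,
                      groups: dict | pd.Series | None = None,
                      ref=None, cgi: IntervalSet | None = None,
                      up: int = 1500, down: int = 200,
                      min_cpg_fraction: float = 0.25,
                      min_cell_fraction: float = 0.60, min_sd: float = 0.2,
                      cgi_min_overlap: int = 200) -> PromoterAnalysis:
    """Per-promoter mean β, display-set filters, Ward clustering and
    group-wise t-tests with Benjamini–Hochberg correction.

    The display set keeps promoters with more than ``min_cpg_fraction`` of
    their CpGs covered in at least ``min_cell_fraction`` of cells and a
    cross-cell SD above ``min_sd``.  Tests are unpaired two-sided t-tests
    between the two groups, skipped when either group has fewer than two
    covered cells.
    """
    proms = promoter_intervals(genes, up, down)
    n_cpgs_total = {}
    if ref is not None:
        seqs = getattr(ref, "chromosomes", ref)
        cp_cache = {c: cpg_positions(s) for c, s in seqs.items()}
        for p in proms.itertuples():
            cp = cp_cache.get(p.chrom)
            n_cpgs_total[p.name] = int(((cp >= p.start) & (cp < p.end)).sum()) \
                if cp is not None else 0

    cells = sorted(calls["cell"].unique())
    mean_beta: dict[str, pd.Series] = {}
    n_cpg_cov: dict[str, pd.Series] = {}
    for chrom, sub in calls.groupby("chrom"):
        local = proms[proms.chrom == chrom]
        iv = IntervalSet([(p.chrom, p.start, p.end) for p in local.itertuples()])
        idx = iv.interval_index(chrom, sub["pos"].to_numpy())
        hit = idx >= 0
        if not hit.any():
            continue
        tmp = sub.loc[hit].copy()
        names = local.sort_values(["start", "end"])["name"].to_numpy()
        tmp["promoter"] = names[idx[hit]]
        g = tmp.groupby(["promoter", "cell"])
        for (prom, cell), grp in g:
            mean_beta.setdefault(prom, pd.Series(dtype=float))[cell] = \
                grp["beta"].mean()
            n_cpg_cov.setdefault(prom, pd.Series(dtype=float))[cell] = \
                grp["pos"].nunique()

    matrix = pd.DataFrame(mean_beta).reindex(cells)

    visual = []
    for prom in matrix.columns:
        col = matrix[prom]
        if n_cpgs_total:
            total = max(1, n_cpgs_total.get(prom, 0))
            cov = n_cpg_cov[prom].reindex(cells).fillna(0) / total
            frac_cells = float((cov > min_cpg_fraction).mean())
        else:
            frac_cells = float(col.notna().mean())
        if frac_cells >= min_cell_fraction and col.std() > min_sd:
            visual.append(prom)

    linkage = None
    if len(visual) >= 2 and len(cells) >= 2:
        sub = matrix[visual]
        filled = sub.fillna(sub.mean())
        linkage = sch.linkage(filled.to_numpy(), method="ward")

    tests = pd.DataFrame(columns=["promoter", "mean_a", "mean_b", "t", "p",
                                  "p_adj", "n_calls", "cgi"])
    if groups is not None:
        groups = pd.Series(groups)
        levels = sorted(groups.dropna().unique())
        if len(levels) != 2:
            raise ValueError("promoter tests need exactly two groups")
        ga = groups[groups == levels[0]].index
        gb = groups[groups == levels[1]].index
        rows = []
        for prom in matrix.columns:
            a = matrix.loc[matrix.index.intersection(ga), prom].dropna()
            b = matrix.loc[matrix.index.intersection(gb), prom].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            t, p = stats.ttest_ind(a, b)
            rows.append((prom, a.mean(), b.mean(), float(t), float(p),
                         int(len(a) + len(b))))
        if rows:
            tests = pd.DataFrame(rows, columns=["promoter", "mean_a", "mean_b",
                                                "t", "p", "n_calls"])
            tests["p_adj"] = multipletests(tests["p"], method="fdr_bh")[1]
            tests["cgi"] = False
            if cgi is not None:
                lookup = proms.set_index("name")
                for i, prom in enumerate(tests["promoter"]):
                    row = lookup.loc[prom]
                    ov = _overlap_bp(cgi, row.chrom, row.start, row.end)
                    tests.loc[i, "cgi"] = ov >= cgi_min_overlap

    return PromoterAnalysis(matrix=matrix, visual_set=visual, linkage=linkage,
                            tests=tests)


def _overlap_bp(regions: IntervalSet, chrom: str, start: int, end: int) -> int:
    total = 0
    for c, s, e in regions.intervals(chrom):
        total += max(0, min(e, end) - max(s, start))
    return total


# --------------------------------------------------------------------------
# NMF cell map
# --------------------------------------------------------------------------


@dataclass
class CellMap:
    result: NMFResult
    cells: list
    loci: pd.DataFrame          # chrom, pos of selected CpGs
    labels: pd.Series           # per-cell argmax factor
    degenerate: bool


def nmf_cell_map(calls: pd.DataFrame, seed: int = 0,
                 coverage_percentile: float = 25.0,
                 sd_percentile: float = 67.0,
                 min_cpgs: int = 10) -> CellMap:
    """Rank-2 embedding of cells from raw β values at variable CpGs.

    CpGs above the 25th percentile of cell-coverage count and the 67th
    percentile of cross-cell SD are selected; each cell contributes a
    stacked [β; 1−β] vector with missing entries masked; columns are
    sum-normalized and log-transformed before masked rank-2 NMF.  Cells are
    labeled by their argmax factor loading.
    """
    if calls["cell"].nunique() < 2:
        raise ValueError("need at least 2 cells")
    mat = calls.pivot_table(index=["chrom", "pos"], columns="cell",
                            values="beta", aggfunc="mean")
    coverage = mat.notna().sum(axis=1).to_numpy()
    sd = mat.std(axis=1).to_numpy()
    cov_thr = np.percentile(coverage, coverage_percentile)
    sd_thr = np.nanpercentile(sd, sd_percentile)
    # >= : at high depth the coverage distribution saturates at n_cells and
    # the 25th percentile ties the maximum; strict > would empty the set
    keep = (coverage >= cov_thr) & (sd >= sd_thr)
    if keep.sum() < min_cpgs:
        raise ValueError(
            f"only {int(keep.sum())} CpGs pass selection (need {min_cpgs})")
    sel = mat.loc[keep]
    B = sel.to_numpy()
    mask = ~np.isnan(B)
    X, M = prepare_beta_matrix(np.nan_to_num(B), mask)
    res = masked_nmf(X, M, rank=2, seed=seed)
    cells = list(sel.columns)
    labels = pd.Series(res.col_assignments, index=cells, name="factor")
    counts = labels.value_counts()
    degenerate = len(counts) < 2
    if degenerate:
        logger.warning("NMF cell map degenerate: all cells on one factor")
    loci = sel.index.to_frame(index=False)
    return CellMap(result=res, cells=cells, loci=loci, labels=labels,
                   degenerate=degenerate)


def solo_wcgw_score(calls: pd.DataFrame, solo_positions: dict) -> pd.Series:
    """Per-cell mean β over solo-WCGW CpGs in partially methylated domains.

    Methylation loss at these isolated A/T-flanked CpGs tracks cumulative
    cell divisions.  Cells with no covered solo-WCGW CpG are absent.
    """
    picks = []
    for chrom, sub in calls.groupby("chrom"):
        pos = solo_positions.get(chrom)
        if pos is None or len(pos) == 0:
            continue
        picks.append(sub[np.isin(sub["pos"].to_numpy(), pos)])
    if not picks:
        return pd.Series(dtype=float, name="solo_wcgw")
    merged = pd.concat(picks)
    return merged.groupby("cell")["beta"].mean().rename("solo_wcgw")
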