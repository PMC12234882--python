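"""Read-count normalization, replication timing, cell-cycle phase, ploidy.

Copy number in a single cell is read from binned read counts: reads per
million mapped (RPMM) in 50 kb bins, bias-corrected by per-bin median RPMM
across "ideal" (uniform-coverage) cells.  Replication timing scores 1
(earliest) to 16 (latest) come from 16-fraction repli-seq profiles;
S-phase cells betray themselves with excess reads in early-replicating
bins plus elevated allele-resolved discordance from not-yet-remethylated
daughter strands.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy import stats

from .core import Read

logger = logging.getLogger(__name__)

VERY_EARLY_FRACTION = 0.335   # S-phase call threshold on normalized reads
S_PHASE_MAX_D = 0.03          # allele-resolved discordance cap for S
TIMING_GROUPS = {
    "very_early": (2, 4), "early": (5, 8), "late": (9, 12),
    "very_late": (13, 14),
}
EXCLUDED_SCORES = (1, 15, 16)


def bin_read_counts(reads_by_cell: dict, chrom_sizes: dict,
                    bin_size: int = 50_000, min_mapq: int = 40
                    ) -> pd.DataFrame:
    """Wide cells × (chrom, bin_start) read-count matrix."""
    bins = []
    for chrom, size in sorted(chrom_sizes.items()):
        for b in range(size // bin_size):
            bins.append((chrom, b * bin_size))
    index = pd.MultiIndex.from_tuples(bins, names=["chrom", "bin_start"])
    out = {}
    for cell, reads in reads_by_cell.items():
        counts = {b: 0 for b in bins}
        for r in reads:
            if r.is_duplicate or r.mapq < min_mapq:
                continue
            key = (r.chrom, (r.start // bin_size) * bin_size)
            if key in counts:
                counts[key] += 1
        out[cell] = [counts[b] for b in bins]
    return pd.DataFrame(out, index=index).T.sort_index()


@dataclass
class RPMMResult:
    rpmm: pd.DataFrame           # cells x bins, raw RPMM
    corrected: pd.DataFrame      # after per-bin correction
    factors: pd.Series           # per-bin correction factor
    excluded_bins: list
    ideal_cells: list


def rpmm_normalize(counts: pd.DataFrame,
                   extreme_percentiles: tuple = (5.0, 95.0),
                   extreme_cell_fraction: float = 0.75,
                   max_missing: float = 0.10,
                   coarse_bin_size: int = 5_000_000,
                   bin_size: int = 50_000,
                   coarse_sd_max: float = 2.5,
                   ideal_sd_range: tuple = (1.0, 1.75)) -> RPMMResult:
    """RPMM normalization with ideal-cell per-bin bias correction.

    Bins with RPMM outside the cell's 5th–95th percentile in more than 75%
    of cells, or with more than 10% missing data, are excluded.  Ideal
    cells have a near-uniform read distribution: coarse (5 Mb) bins with
    within-bin RPMM SD < 2.5 are kept and the SD of their means must fall
    in (1, 1.75).  Each bin's correction factor is its median RPMM across
    ideal cells; with zero ideal cells the all-cell median is used instead,
    with a prominent warning.
    """
    totals = counts.sum(axis=1)
    rpmm = counts.mul(1e6 / totals.replace(0, np.nan), axis=0)

    lo = rpmm.quantile(extreme_percentiles[0] / 100, axis=1)
    hi = rpmm.quantile(extreme_percentiles[1] / 100, axis=1)
    extreme = rpmm.lt(lo, axis=0) | rpmm.gt(hi, axis=0)
    excluded = extreme.mean(axis=0) > extreme_cell_fraction
    excluded |= rpmm.isna().mean(axis=0) > max_missing
    excluded_bins = list(rpmm.columns[excluded])
    rpmm = rpmm.loc[:, ~excluded.to_numpy()]

    # ideal cells: uniform coarse-grained read distribution
    coarse_of = pd.MultiIndex.from_tuples(
        [(c, (b // coarse_bin_size) * coarse_bin_size) for c, b in rpmm.columns])
    ideal = []
    for cell in rpmm.index:
        row = rpmm.loc[cell]
        grp = row.groupby(coarse_of)
        sd = grp.std().fillna(0.0)
        means = grp.mean()[sd < coarse_sd_max]
        if len(means) == 0:
            continue
        whole_sd = float(means.std()) if len(means) > 1 else 0.0
        if ideal_sd_range[0] < whole_sd < ideal_sd_range[1]:
            ideal.append(cell)
    if ideal:
        factors = rpmm.loc[ideal].median(axis=0)
    else:
        logger.warning(
            "no ideal cells found; falling back to all-cell median per bin")
        factors = rpmm.median(axis=0)
    factors = factors.replace(0, np.nan)
    corrected = rpmm.div(factors, axis=1)
    return RPMMResult(rpmm=rpmm, corrected=corrected, factors=factors,
                      excluded_bins=excluded_bins, ideal_cells=ideal)


def replication_scores(repliseq: pd.DataFrame) -> pd.DataFrame:
    """Timing score per 50 kb bin from 16-fraction repli-seq profiles.

    Score = the score-weighted mean of the indices of the three highest
    fractions, rounded to the nearest integer; bins scoring 1, 15, or 16
    (and all-zero bins) are excluded; the rest partition into very_early
    (2–4), early (5–8), late (9–12), very_late (13–14).
    """
    frac_cols = [f"s{i}" for i in range(1, 17)]
    S = repliseq[frac_cols].to_numpy(dtype=float)
    if np.any(S < 0):
        raise ValueError("negative repli-seq fraction scores")
    rows = []
    for i in range(len(S)):
        s = S[i]
        if s.sum() == 0:
            continue
        top3 = np.argsort(-s, kind="stable")[:3]
        idx = top3 + 1  # fraction indices are 1-based
        w = s[top3]
        score = math.floor(float((idx * w).sum() / w.sum()) + 0.5)
        if score in EXCLUDED_SCORES:
            continue
        group = next(g for g, (a, b) in TIMING_GROUPS.items()
                     if a <= score <= b)
        rows.append((repliseq["chrom"].iat[i], repliseq["bin_start"].iat[i],
                     score, group))
    return pd.DataFrame(rows, columns=["chrom", "bin_start", "score", "group"])


def very_early_fraction(corrected_row: pd.Series,
                        scores: pd.DataFrame) -> float:
    """Fraction of normalized reads in very-early bins, over grouped bins
    only (excluded scores 1/15/16 enter neither numerator nor denominator).
    """
    keyed = scores.set_index(["chrom", "bin_start"])
    common = corrected_row.index.intersection(keyed.index)
    vals = corrected_row.loc[common]
    groups = keyed.loc[common, "group"]
    total = float(np.nansum(vals))
    if total == 0:
        return float("nan")
    ve = float(np.nansum(vals[(groups == "very_early").to_numpy()]))
    return ve / total


def classify_phase(cells: pd.DataFrame, corrected: pd.DataFrame,
                   scores: pd.DataFrame,
                   ve_threshold: float = VERY_EARLY_FRACTION,
                   doublet_d: float = S_PHASE_MAX_D) -> pd.DataFrame:
    """Cell-cycle phase calls from read distribution and ARM discordance.

    ``cells`` needs columns cell, arm_discordance.  S-phase: very-early
    read fraction > 33.5% and D < 3%; doublet: D > 3%; pG2: even read
    distribution but D above the G1 band (median + 3×MAD of provisional-G1
    discordances); else G1.  Missing D limits the call to G1/S and flags it.
    """
    df = cells.set_index("cell").copy()
    df["very_early_fraction"] = [
        very_early_fraction(corrected.loc[c], scores) if c in corrected.index
        else np.nan for c in df.index]
    d = df["arm_discordance"]
    ve = df["very_early_fraction"]

    phase = pd.Series("G1", index=df.index, dtype=object)
    flagged = d.isna()
    if flagged.any():
        logger.warning("%d cells missing discordance; G1/S call only",
                       int(flagged.sum()))
    phase[(ve > ve_threshold)] = "S"
    phase[(~flagged) & (d > doublet_d)] = "doublet"
    phase[(~flagged) & (ve > ve_threshold) & (d < doublet_d)] = "S"

    provisional_g1 = (~flagged) & (ve <= ve_threshold) & (d <= doublet_d)
    if provisional_g1.sum() >= 3:
        g1d = d[provisional_g1]
        band = g1d.median() + 3 * stats.median_abs_deviation(g1d)
        pg2 = provisional_g1 & (d > band)
        phase[pg2] = "pG2"
    df["phase"] = phase
    df["d_missing"] = flagged
    return df.reset_index()


def estimate_ploidy(corrected_row: pd.Series, g2: bool = False,
                    grid_points: int = 512) -> pd.Series:
    """Per-bin ploidy from the mode of the normalized read-count density.

    Kernel density with Silverman bandwidth; counts are divided by the mode
    and multiplied by 2 (mode ≤ 1.1, not G2) or 4 (mode > 1.1 or G2 —
    i.e. when most of the genome is replicated).
    """
    vals = corrected_row.dropna().to_numpy(dtype=float)
    if len(vals) < 3 or np.allclose(vals, vals[0]):
        raise ValueError("degenerate read-count density")
    kde = stats.gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(0, vals.max() * 1.05, grid_points)
    mode = float(grid[np.argmax(kde(grid))])
    if mode <= 0:
        raise ValueError("degenerate read-count density (mode at zero)")
    mult = 4.0 if (g2 or mode > 1.1) else 2.0
    return corrected_row / mode * mult


def replication_meth_profile(calls: pd.DataFrame, ploidy: pd.Series,
                             rpmm_row: pd.Series, bin_size: int = 50_000,
                             min_measurements: int = 15) -> pd.DataFrame:
    """Methylation-state distribution by estimated ploidy for one cell.

    β values (from CpGs covered ≥ 2×) discretize into unmethylated (β = 0),
    partially methylated (0 < β < 1) and methylated (β = 1) per 50 kb bin;
    bins with fewer than 15 measurements are dropped, the rest grouped by
    rounded ploidy.  Each bin's weight is its RPMM share of the cell total.
    """
    sub = calls[calls["n_total"] >= 2].copy()
    if len(sub) == 0:
        return pd.DataFrame(columns=["ploidy", "u", "partial", "m",
                                     "n", "weight"])
    sub["bin_start"] = (sub["pos"] // bin_size) * bin_size
    sub["state"] = np.select(
        [sub["beta"] == 0, sub["beta"] == 1], ["u", "m"], default="partial")
    total_rpmm = float(np.nansum(rpmm_row))
    rows = []
    for (chrom, b), grp in sub.groupby(["chrom", "bin_start"]):
        if len(grp) < min_measurements:
            continue
        key = (chrom, b)
        if key not in ploidy.index or pd.isna(ploidy.loc[key]):
            continue
        p = int(round(float(ploidy.loc[key])))
        w = float(rpmm_row.get(key, 0.0)) / total_rpmm if total_rpmm else 0.0
        cnt = grp["state"].value_counts()
        rows.append((p, cnt.get("u", 0), cnt.get("partial", 0),
                     cnt.get("m", 0), len(grp), w))
    df = pd.DataFrame(rows, columns=["ploidy", "u", "partial", "m",
                                     "n", "weight"])
    if len(df) == 0:
        return df
    out = df.groupby("ploidy", as_index=False).agg(
        u=("u", "sum"), partial=("partial", "sum"), m=("m", "sum"),
        n=("n", "sum"), weight=("weight", "sum"))
    for c in ("u", "partial", "m"):
        out[c + "_frac"] = out[c] / out["n"]
    return out


def timing_state_distribution(states: pd.DataFrame, scores: pd.DataFrame,
                              bin_size: int = 50_000,
                              cell_groups: dict | None = None) -> pd.DataFrame:
    """Two-strand state fractions per replication-timing score.

    ``states`` comes from arm.two_strand_states on G1 cells.  Fractions of
    sym_meth / hemi / sym_unmeth per retained timing score (2–14), and per
    cell group when given.  Scores with zero states are absent.
    """
    keyed = scores.set_index(["chrom", "bin_start"])["score"]
    df = states.copy()
    df["bin_start"] = (df["pos"] // bin_size) * bin_size
    df["score"] = [keyed.get((c, b), np.nan)
                   for c, b in zip(df["chrom"], df["bin_start"])]
    df = df.dropna(subset=["score"])
    df["score"] = df["score"].astype(int)
    df["group"] = [cell_groups.get(c, "all") for c in df["cell"]] \
        if cell_groups else "all"
    rows = []
    for (group, score), grp in df.groupby(["group", "score"]):
        n = len(grp)
        cnt = grp["state"].value_counts()
        rows.append((group, score,
                     cnt.get("sym_meth", 0) / n, cnt.get("hemi", 0) / n,
                     cnt.get("sym_unmeth", 0) / n, n))
    return pd.DataFrame(rows, columns=["group", "score", "sym_meth", "hemi",
                                       "sym_unmeth", "n"])


def cnv_cluster(corrected: pd.DataFrame, k: int,
                coarse_bin_size: int = 500_000,
                very_early_fractions: pd.Series | None = None,
                min_ve_fraction: float = 0.24,
                cpgs_covered: pd.Series | None = None,
                min_cpgs: int | None = None) -> dict:
    """Ward clustering of cells on coarse-binned corrected read counts.

    Optional pre-filters drop cells with an uneven read distribution
    (< 24% very-early reads) or too few CpGs covered.  Returns cluster
    labels (1..k) and the linkage matrix.
    """
    keep = pd.Series(True, index=corrected.index)
    if very_early_fractions is not None:
        keep &= very_early_fractions.reindex(corrected.index) >= min_ve_fraction
    if cpgs_covered is not None and min_cpgs is not None:
        keep &= cpgs_covered.reindex(corrected.index) >= min_cpgs
    mat = corrected.loc[keep]
    if len(mat) < 3:
        raise ValueError("need at least 3 cells for CNV clustering")
    coarse = pd.MultiIndex.from_tuples(
        [(c, (b // coarse_bin_size) * coarse_bin_size) for c, b in mat.columns])
    avg = mat.T.groupby(coarse).mean().T
    filled = avg.fillna(avg.mean())
    Z = sch.linkage(filled.to_numpy(), method="ward")
    labels = pd.Series(sch.fcluster(Z, t=k, criterion="maxclust"),
                       index=avg.index, name="cluster")
    return {"labels": labels, "linkage": Z, "matrix": avg}
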