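"""X-inactivation epigenetics from allele-resolved chromosome X calls.

The inactive X carries hypermethylated CpG islands, so per-cell per-allele
CGI means call the inactive allele directly when chromosome-scale phasing
is available.  Without phased SNPs, rank-2 masked NMF over per-(CpG, local
allele) β features bipartitions both the cells (two X-inactivation states)
and the features (two methylation-derived alleles) — SNP-free whole-
chromosome allele inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .core import IntervalSet
from .nmf import NMFResult, masked_nmf, prepare_beta_matrix

logger = logging.getLogger(__name__)

MIN_CALLS_PER_ALLELE = 50
MIN_FEATURE_OBS = 100
XCI_MARGIN = 0.2  # separation of allele means below which the call is ambiguous


# --------------------------------------------------------------------------
# direct (phased-SNP) X-inactivation calls
# --------------------------------------------------------------------------


def call_xci(arm_calls: pd.DataFrame, cgis: IntervalSet,
             min_calls: int = MIN_CALLS_PER_ALLELE,
             margin: float = XCI_MARGIN) -> pd.DataFrame:
    """Per-cell inactive-allele call from allele-resolved CGI methylation.

    Mean β of CpG-island CpGs on chromosome X per allele; the inactive X is
    the allele with the higher mean when the separation exceeds ``margin``,
    otherwise ambiguous (opposite-state doublets land here).  Cells with
    fewer than ``min_calls`` calls on either allele are removed.
    """
    x = arm_calls[(arm_calls["chrom"] == "chrX")
                  & (arm_calls["allele"].isin([1, 2]))]
    if len(x) == 0:
        return pd.DataFrame(columns=["cell", "mean1", "mean2", "n1", "n2",
                                     "inactive_allele"])
    inside = cgis.contains("chrX", x["pos"].to_numpy())
    x = x.loc[inside]
    rows = []
    for cell, grp in x.groupby("cell"):
        per = grp.groupby("allele")["beta"].agg(["mean", "size"])
        if not {1, 2}.issubset(per.index):
            continue
        n1, n2 = int(per.loc[1, "size"]), int(per.loc[2, "size"])
        if n1 < min_calls or n2 < min_calls:
            continue
        m1, m2 = float(per.loc[1, "mean"]), float(per.loc[2, "mean"])
        if abs(m1 - m2) < margin:
            inactive = "ambiguous"
        else:
            inactive = 1 if m1 > m2 else 2
        rows.append((cell, m1, m2, n1, n2, inactive))
    return pd.DataFrame(rows, columns=["cell", "mean1", "mean2", "n1", "n2",
                                       "inactive_allele"])


def build_x_features(ref, promoter_up: int = 1500, promoter_down_cgi: int = 1000,
                     promoter_down: int = 200, shore: int = 500) -> dict:
    """The four chromosome X feature sets summarized on Xa/Xi.

    CGI promoters (CGIs within TSS −1.5 kb/+1 kb), non-promoter CGIs,
    non-CGI promoters (TSS −1.5 kb/+200 bp without a nearby CGI), and CGIs
    with ±500 bp shores.
    """
    genes = ref.genes[ref.genes.chrom == "chrX"]
    tss_windows = []
    noncgi_prom = []
    for g in genes.itertuples():
        tss = g.start if g.strand == "+" else g.end
        if g.strand == "+":
            w = (tss - promoter_up, tss + promoter_down_cgi)
            p = (tss - promoter_up, tss + promoter_down)
        else:
            w = (tss - promoter_down_cgi, tss + promoter_up)
            p = (tss - promoter_down, tss + promoter_up)
        tss_windows.append(w)
        noncgi_prom.append(p)
    cgi_prom, nonprom_cgi, shores = [], [], []
    for c, s, e in ref.cgi.intervals("chrX"):
        is_prom = any(s < we and ws < e for ws, we in tss_windows)
        (cgi_prom if is_prom else nonprom_cgi).append((c, s, e))
        shores.append((c, max(0, s - shore), e + shore))
    has_cgi = [any(s < pe and ps < e for _, s, e in cgi_prom + nonprom_cgi)
               for ps, pe in noncgi_prom]
    noncgi = [("chrX", max(0, s), e) for (s, e), h in
              zip(noncgi_prom, has_cgi) if not h]
    return {
        "cgi_promoters": IntervalSet(cgi_prom),
        "nonpromoter_cgis": IntervalSet(nonprom_cgi),
        "noncgi_promoters": IntervalSet(noncgi),
        "cgi_shores": IntervalSet(shores),
    }


def xa_xi_summary(xci_calls: pd.DataFrame, arm_calls: pd.DataFrame,
                  feature_sets: dict,
                  min_obs: int = MIN_FEATURE_OBS) -> pd.DataFrame:
    """Pooled Xa/Xi mean β per feature across confidently-called cells.

    Each cell's calls are oriented by its inactive-allele call; features
    with fewer than ``min_obs`` methylation calls are dropped.
    """
    confident = xci_calls[xci_calls["inactive_allele"].isin([1, 2])]
    if len(confident) == 0:
        raise ValueError("no confidently XCI-called cells")
    inactive = dict(zip(confident["cell"], confident["inactive_allele"]))
    x = arm_calls[(arm_calls["chrom"] == "chrX")
                  & arm_calls["cell"].isin(inactive)
                  & arm_calls["allele"].isin([1, 2])].copy()
    x["xi"] = [allele == inactive[cell]
               for cell, allele in zip(x["cell"], x["allele"])]
    rows = []
    for name, regions in feature_sets.items():
        if not isinstance(regions, IntervalSet):
            regions = IntervalSet(regions)
        idx = regions.interval_index("chrX", x["pos"].to_numpy())
        hit = idx >= 0
        sub = x.loc[hit].copy()
        sub["feature"] = idx[hit]
        ivs = list(regions.intervals("chrX"))
        for f, grp in sub.groupby("feature"):
            if len(grp) < min_obs:
                continue
            xa = grp.loc[~grp["xi"], "beta"]
            xi = grp.loc[grp["xi"], "beta"]
            _, s, e = ivs[int(f)]
            rows.append((name, s, e, float(xa.mean()) if len(xa) else np.nan,
                         float(xi.mean()) if len(xi) else np.nan, len(grp)))
    return pd.DataFrame(rows, columns=["set", "start", "end", "xa_mean",
                                       "xi_mean", "n_obs"])


def metagene_profile(genes: pd.DataFrame, arm_calls: pd.DataFrame,
                     xci_calls: pd.DataFrame, flank: int = 5000,
                     body_bins: int = 50, flank_bins: int = 25,
                     span: float = 0.2, min_calls: int = MIN_FEATURE_OBS,
                     xa_max: float = 0.25, xi_min: float = 0.25,
                     promoter_up: int = 1500, promoter_down: int = 200
                     ) -> pd.DataFrame:
    """Binned Xa/Xi methylation across genes subject to X-inactivation.

    Qualifying genes have ≥ ``min_calls`` promoter calls with Xa mean
    < 0.25 and Xi mean > 0.25.  Gene bodies are scaled to a common
    coordinate with ±5 kb absolute flanks; body bins are weighted by gene
    length; the profile is loess-smoothed (span 0.2).  Returns an empty
    frame when no gene qualifies.
    """
    confident = xci_calls[xci_calls["inactive_allele"].isin([1, 2])]
    inactive = dict(zip(confident["cell"], confident["inactive_allele"]))
    x = arm_calls[(arm_calls["chrom"] == "chrX")
                  & arm_calls["cell"].isin(inactive)
                  & arm_calls["allele"].isin([1, 2])].copy()
    if len(x) == 0:
        return pd.DataFrame(columns=["bin", "region", "xa", "xi"])
    x["xi"] = [a == inactive[c] for c, a in zip(x["cell"], x["allele"])]
    pos = x["pos"].to_numpy()

    total_bins = body_bins + 2 * flank_bins
    acc = np.zeros((total_bins, 2))    # weighted beta sums (xa, xi)
    wsum = np.zeros((total_bins, 2))
    n_genes = 0
    for g in genes[genes.chrom == "chrX"].itertuples():
        tss = g.start if g.strand == "+" else g.end
        if g.strand == "+":
            ps, pe = tss - promoter_up, tss + promoter_down
        else:
            ps, pe = tss - promoter_down, tss + promoter_up
        prom = x[(pos >= ps) & (pos < pe)]
        if len(prom) < min_calls:
            continue
        xa_mean = prom.loc[~prom["xi"], "beta"].mean()
        xi_mean = prom.loc[prom["xi"], "beta"].mean()
        if not (xa_mean < xa_max and xi_mean > xi_min):
            continue
        n_genes += 1
        glen = g.end - g.start
        w_body = float(glen)
        sub = x[(pos >= g.start - flank) & (pos < g.end + flank)]
        for row in sub.itertuples():
            p = row.pos
            if p < g.start:
                frac = (p - (g.start - flank)) / flank
                b = int(frac * flank_bins)
            elif p >= g.end:
                frac = (p - g.end) / flank
                b = flank_bins + body_bins + int(frac * flank_bins)
            else:
                frac = (p - g.start) / glen
                b = flank_bins + int(frac * body_bins)
            b = min(max(b, 0), total_bins - 1)
            w = w_body if flank_bins <= b < flank_bins + body_bins else 1.0
            col = 1 if row.xi else 0
            acc[b, col] += w * row.beta
            wsum[b, col] += w
        if g.strand == "-":
            pass  # bins already oriented 5'->3' via TSS handling above
    if n_genes == 0:
        return pd.DataFrame(columns=["bin", "region", "xa", "xi"])
    with np.errstate(invalid="ignore"):
        prof = acc / wsum
    out = pd.DataFrame({
        "bin": np.arange(total_bins),
        "region": ["upstream"] * flank_bins + ["body"] * body_bins
                  + ["downstream"] * flank_bins,
        "xa": prof[:, 0], "xi": prof[:, 1],
    })
    for col in ("xa", "xi"):
        y = out[col].to_numpy()
        okm = ~np.isnan(y)
        if okm.sum() >= 5:
            sm = lowess(y[okm], out["bin"].to_numpy()[okm], frac=span,
                        return_sorted=False)
            y = y.copy()
            y[okm] = sm
            out[col + "_smooth"] = y
        else:
            out[col + "_smooth"] = y
    return out


# --------------------------------------------------------------------------
# SNP-free NMF allele inference
# --------------------------------------------------------------------------


@dataclass
class XCINMF:
    result: NMFResult
    cells: list
    cell_groups: pd.Series         # per-cell argmax factor (0/1)
    allele_of_local1: dict         # pos -> "A"/"B" for local allele 1
    feature_table: pd.DataFrame    # retained features with scaled loadings


def nmf_xci(arm_calls: pd.DataFrame, cgis: IntervalSet, seed: int = 0,
            max_cgi_distance: int = 500, factor_percentile: float = 95.0,
            scaled_range: tuple = (0.05, 0.85),
            min_features: int = 20) -> XCINMF:
    """SNP-free chromosome X allele inference by masked rank-2 NMF.

    Every allele-resolved chrX CpG contributes one β and one complement
    feature per local allele (up to 4 features per CpG).  After the shared
    complement/normalize/log transform and factorization: features > 500 bp
    from a CGI are dropped, features with either factor loading above that
    factor's 95th percentile are dropped, loadings are scaled to max 1, and
    features with scaled loading outside [0.05, 0.85] (0.75 preset for
    human fibroblasts) in *both* factors are dropped.  Each feature joins
    its argmax factor; each CpG's local allele 1 is assigned to NMF allele
    A or B by majority vote over its features, ties discarded.  Cells are
    grouped by argmax loading.
    """
    x = arm_calls[(arm_calls["chrom"] == "chrX")
                  & arm_calls["allele"].isin([1, 2])]
    if len(x) == 0:
        raise ValueError("no allele-resolved chrX calls")
    mat = x.pivot_table(index=["pos", "allele"], columns="cell",
                        values="beta", aggfunc="mean")
    B = mat.to_numpy()
    mask = ~np.isnan(B)
    X, M = prepare_beta_matrix(np.nan_to_num(B), mask)
    ok_rows = M.any(axis=1)
    ok_cols = M.any(axis=0)
    X, M = X[ok_rows][:, ok_cols], M[ok_rows][:, ok_cols]
    cells = [c for c, k in zip(mat.columns, ok_cols) if k]
    res = masked_nmf(X, M, rank=2, seed=seed)

    n_loci = len(mat)
    loci = mat.index.to_frame(index=False)  # pos, allele per base row
    kept_loci = loci.loc[np.flatnonzero(ok_rows[:n_loci] | ok_rows[n_loci:])]
    # feature bookkeeping: rows of X are [beta block; complement block]
    feat = pd.concat([
        loci.assign(kind="meth"), loci.assign(kind="comp")
    ], ignore_index=True)
    feat = feat.loc[ok_rows].reset_index(drop=True)
    feat["w0"] = res.W[:, 0]
    feat["w1"] = res.W[:, 1]

    dist = cgis.nearest_distance("chrX", feat["pos"].to_numpy())
    keep = dist <= max_cgi_distance
    for col in ("w0", "w1"):
        thr = np.percentile(feat[col], factor_percentile)
        keep &= feat[col].to_numpy() <= thr
    feat = feat.loc[keep].copy()
    for col in ("w0", "w1"):
        mx = feat[col].max()
        feat["s" + col[1]] = feat[col] / (mx if mx > 0 else 1.0)
    lo, hi = scaled_range
    in_range = ((feat["s0"].between(lo, hi))
                | (feat["s1"].between(lo, hi)))
    feat = feat.loc[in_range].copy()
    if len(feat) < min_features:
        raise ValueError(f"only {len(feat)} features retained "
                         f"(need {min_features})")
    feat["factor"] = (feat["s1"] > feat["s0"]).astype(int)

    # majority vote per CpG: which factor-allele does local allele 1 carry?
    votes: dict[int, int] = {}
    counts: dict[int, list] = {}
    for row in feat.itertuples():
        # a meth feature of local allele h votes h -> its argmax factor;
        # a comp feature votes h -> the other factor; map to allele 1
        v = row.factor if row.kind == "meth" else 1 - row.factor
        if row.allele == 2:
            v = 1 - v
        rec = counts.setdefault(int(row.pos), [0, 0])
        rec[v] += 1
    allele_map = {}
    for p, (a, b) in counts.items():
        if a == b:
            continue  # tie: CpG discarded
        allele_map[p] = "A" if a > b else "B"

    cell_groups = pd.Series(res.col_assignments, index=cells, name="group")
    return XCINMF(result=res, cells=cells, cell_groups=cell_groups,
                  allele_of_local1=allele_map, feature_table=feat)


def transfer_alleles(allele_map: dict, arm_calls: pd.DataFrame) -> pd.DataFrame:
    """Phase another cohort's calls through an NMF-derived allele map.

    ``allele_map`` gives the NMF allele of local allele 1 per CpG (local
    labels must come from the same phasing as the reference cohort).  Calls
    at CpGs absent from the map stay unassigned.  Returns per-cell,
    per-NMF-allele call counts and mean β.
    """
    x = arm_calls[(arm_calls["chrom"] == "chrX")
                  & arm_calls["allele"].isin([1, 2])].copy()
    labels = []
    for row in x.itertuples():
        a1 = allele_map.get(int(row.pos))
        if a1 is None:
            labels.append(None)
        elif row.allele == 1:
            labels.append(a1)
        else:
            labels.append("B" if a1 == "A" else "A")
    x["nmf_allele"] = labels
    assigned = x.dropna(subset=["nmf_allele"])
    out = (assigned.groupby(["cell", "nmf_allele"], as_index=False)
           .agg(n_calls=("beta", "size"), mean_beta=("beta", "mean")))
    return out


# --------------------------------------------------------------------------
# CGI variability and differential methylation
# --------------------------------------------------------------------------


def cgi_matrix(calls: pd.DataFrame, cgis: IntervalSet, ref=None,
               min_cpg_fraction: float = 0.30) -> pd.DataFrame:
    """Cells × CGIs mean β, discarding cell/CGI pairs covering ≤ 30% of the
    island's CpGs (when ``ref`` provides CpG counts)."""
    from .core import cpg_positions as _cpgs
    rows = []
    ivs = list(cgis.intervals())
    cpg_count = {}
    if ref is not None:
        seqs = getattr(ref, "chromosomes", ref)
        cache = {c: _cpgs(s) for c, s in seqs.items()}
        for c, s, e in ivs:
            cp = cache.get(c)
            cpg_count[(c, s, e)] = int(((cp >= s) & (cp < e)).sum()) \
                if cp is not None else 0
    for chrom, sub in calls.groupby("chrom"):
        idx = cgis.interval_index(chrom, sub["pos"].to_numpy())
        hit = idx >= 0
        tmp = sub.loc[hit].copy()
        local = [(c, s, e) for c, s, e in ivs if c == chrom]
        tmp["cgi"] = [f"{local[i][0]}:{local[i][1]}-{local[i][2]}"
                      for i in idx[hit]]
        tmp["key"] = [local[i] for i in idx[hit]]
        for (cell, cgi), grp in tmp.groupby(["cell", "cgi"]):
            key = grp["key"].iat[0]
            if cpg_count:
                total = max(1, cpg_count.get(key, 0))
                if grp["pos"].nunique() / total <= min_cpg_fraction:
                    continue
            rows.append((cell, cgi, grp["beta"].mean()))
    df = pd.DataFrame(rows, columns=["cell", "cgi", "beta"])
    return df.pivot_table(index="cell", columns="cgi", values="beta")


def differential_cgi(matrix: pd.DataFrame, clusters: pd.Series,
                     sd_min: float = 0.2, max_missing: float = 0.2,
                     p_threshold: float = 0.01,
                     delta_min: float = 0.15) -> dict:
    """Variable and cluster-differential CpG islands.

    Variable: cross-cell SD > 0.2 with < 20% missing data.  Differential:
    per cluster, two-tailed t-test vs all other clusters, kept at
    BH-adjusted p < 0.01 and |Δβ| > 0.15.  Clusters of fewer than two
    cells are skipped.
    """
    sd = matrix.std()
    missing = matrix.isna().mean()
    variable = list(matrix.columns[(sd > sd_min) & (missing < max_missing)])

    clusters = pd.Series(clusters)
    rows = []
    for cl in sorted(clusters.dropna().unique()):
        inside = clusters[clusters == cl].index
        outside = clusters[clusters != cl].index
        for cgi in matrix.columns:
            a = matrix.loc[matrix.index.intersection(inside), cgi].dropna()
            b = matrix.loc[matrix.index.intersection(outside), cgi].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            t, p = stats.ttest_ind(a, b)
            rows.append((cgi, cl, float(a.mean() - b.mean()), float(t),
                         float(p)))
    tests = pd.DataFrame(rows, columns=["cgi", "cluster", "delta", "t", "p"])
    if len(tests):
        tests["p_adj"] = multipletests(tests["p"], method="fdr_bh")[1]
        tests["differential"] = ((tests["p_adj"] < p_threshold)
                                 & (tests["delta"].abs() > delta_min))
    else:
        tests["p_adj"] = []
        tests["differential"] = []
    return {"variable": variable, "tests": tests,
            "differential": sorted(tests.loc[tests.get("differential",
                                                       pd.Series(dtype=bool)),
                                             "cgi"].unique())
            if len(tests) else []}


def xci_variability(allele_cgi_beta: pd.DataFrame,
                    groups: dict | None = None) -> pd.DataFrame:
    """Cross-cell SD of per-allele CGI β per feature (and per group).

    ``allele_cgi_beta`` is long: cell, feature, allele, beta.  Features
    observed in fewer than 3 cells get NaN.  High chrX SD relative to
    autosomes diagnoses a mixed X-inactivation population; its loss at late
    passage marks drift toward a single state.
    """
    df = allele_cgi_beta.copy()
    df["group"] = [groups.get(c, "all") for c in df["cell"]] if groups \
        else "all"
    rows = []
    for (group, feature, allele), grp in df.groupby(
            ["group", "feature", "allele"]):
        sd = float(grp["beta"].std()) if len(grp) >= 3 else np.nan
        rows.append((group, feature, allele, sd, len(grp)))
    return pd.DataFrame(rows, columns=["group", "feature", "allele", "sd",
                                       "n_cells"])
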