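"""Per-cell quality statistics.

The central quantity is the depth-normalized methylation discordance

    D = [ sum_i d_i * 2^i / (2^i - 2) ] / [ sum_i n_i ],   i >= 2,

where n_i is the number of CpG sites covered exactly i times and d_i how
many of those are discordant (0 < beta < 1).  The 2^i/(2^i-2) factor is the
reciprocal of the probability of observing discordance when the i calls
assort at random, so D converges to 1 for randomly assorting calls at any
depth mix and to 0 for perfectly concordant cells.  Elevated D marks
S-phase cells (hemi-methylation behind the replication fork) and, at higher
values, doublets.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import CellQC, Read, merge_intervals

logger = logging.getLogger(__name__)

DOUBLET_THRESHOLD = 0.02   # exclusion threshold on allele-resolved D
DOUBLET_BAND = 0.03        # upper band separating doublets from pG2/S
MIN_CPG_FRACTION = 0.20
MAX_READS = {"human": 55_000_000, "mouse": 80_000_000}


def discordance(calls: pd.DataFrame) -> float:
    """Discordance metric D from a per-site call table (needs n_total, beta).

    Only sites covered more than once contribute; returns NaN when no such
    site exists.  Works on plain or allele-resolved calls: rows are treated
    as independent sites, so pass allele-resolved calls to measure
    allele-resolved discordance.
    """
    depth = calls["n_total"].to_numpy()
    beta = calls["beta"].to_numpy()
    keep = depth >= 2
    if not keep.any():
        return float("nan")
    depth, beta = depth[keep], beta[keep]
    disc = (beta > 0) & (beta < 1)
    num = 0.0
    for i in np.unique(depth):
        d_i = int(np.sum(disc & (depth == i)))
        num += d_i * (2.0 ** i) / (2.0 ** i - 2.0)
    return num / len(depth)


def discordance_by_cell(calls: pd.DataFrame) -> pd.Series:
    return calls.groupby("cell").apply(discordance, include_groups=False)


def flag_doublets(cellqcs: Sequence[CellQC],
                  threshold: float = DOUBLET_THRESHOLD) -> list[CellQC]:
    """Flag cells whose allele-resolved discordance exceeds the threshold.

    Cells without a computed D are left unflagged with a warning.
    """
    for qc in cellqcs:
        d = qc.arm_discordance
        if d is None or np.isnan(d):
            logger.warning("cell %s has no discordance value; not flagged",
                           qc.cell_id)
            continue
        qc.doublet = d > threshold
    return list(cellqcs)


def exclude_low_efficiency(cellqcs: Sequence[CellQC], genome_cpg_count: int,
                           species: str | None = None,
                           max_reads: int | None = None,
                           min_cpg_fraction: float = MIN_CPG_FRACTION
                           ) -> list[CellQC]:
    """Flag cells covering too few CpGs or sequenced past the species cap."""
    if max_reads is None:
        if species not in MAX_READS:
            raise ValueError(
                "unknown species: give max_reads explicitly or species in "
                f"{sorted(MAX_READS)}")
        max_reads = MAX_READS[species]
    for qc in cellqcs:
        frac = qc.n_cpg_covered / max(1, genome_cpg_count)
        qc.low_efficiency = frac < min_cpg_fraction or qc.total_reads > max_reads
    return list(cellqcs)


# --------------------------------------------------------------------------
# anomalous high-coverage regions
# --------------------------------------------------------------------------


def _window_counts(reads: Iterable[Read], chrom_sizes: dict,
                   window: int, step: int) -> dict:
    """Per-chromosome read counts for tiled windows (>=50% overlap rule)."""
    counts = {c: np.zeros(max(0, (size - window) // step + 1), dtype=np.int64)
              for c, size in chrom_sizes.items()}
    half = window // 2
    for r in reads:
        if r.chrom not in counts:
            continue
        arr = counts[r.chrom]
        if len(arr) == 0:
            continue
        # window [w, w+window) overlaps read [s, e) by >= window/2
        lo_w = r.start - half        # min(e, w+window) - max(s, w) >= half
        hi_w = r.end - half          # solved for w on a window/step lattice
        first = int(np.ceil(max(0, lo_w) / step))
        last = min(len(arr) - 1, hi_w // step)
        if last >= first:
            arr[first:last + 1] += 1
    return counts


def _flag_cell_windows(counts: np.ndarray, upper_q: float, lower_q: float,
                       merge_gap: int, step: int) -> np.ndarray:
    """Windows above the cell's upper percentile, extended while above the
    lower percentile, with flagged runs closer than merge_gap merged."""
    if len(counts) == 0:
        return np.zeros(0, dtype=bool)
    hi = np.percentile(counts, upper_q)   # linear interpolation (type 7)
    lo = np.percentile(counts, lower_q)
    flagged = counts > hi                 # strict >: ties are "not above"
    above_lo = counts > lo
    # extend each flagged run outward while the lower threshold is exceeded
    out = flagged.copy()
    idx = np.flatnonzero(flagged)
    for start in idx:
        j = start - 1
        while j >= 0 and above_lo[j] and not out[j]:
            out[j] = True
            j -= 1
        j = start + 1
        while j < len(out) and above_lo[j] and not out[j]:
            out[j] = True
            j += 1
    # merge flagged windows <= merge_gap bp apart
    runs = _runs(out)
    for (s1, e1), (s2, _) in zip(runs[:-1], runs[1:]):
        if (s2 - e1) * step <= merge_gap:
            out[e1:s2] = True
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index runs of True values."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(len(mask))
    return list(zip(starts, ends))


def find_anomalous_regions(reads_by_cell: dict, chrom_sizes: dict,
                           window: int = 100, step: int = 50,
                           upper_q: float = 80.0, lower_q: float = 67.0,
                           merge_gap: int = 250, cell_fraction: float = 0.9,
                           join_gap: int = 250) -> list[tuple[str, int, int]]:
    """Regions of anomalously high coverage shared across cells.

    100 bp windows tiled every 50 bp; a read counts in a window iff it
    overlaps at least half of it.  Per cell, windows above the cell's 80th
    count percentile are flagged and extended while above the 67th; flagged
    windows <= 250 bp apart merge.  A window is anomalous iff flagged in
    more than 90% of cells; anomalous regions closer than 250 bp are joined.
    Output is deterministic and invariant to cell ordering.
    """
    cells = sorted(reads_by_cell)
    if not cells:
        return []
    votes = {c: np.zeros(max(0, (size - window) // step + 1), dtype=np.int64)
             for c, size in chrom_sizes.items()}
    for cell in cells:
        counts = _window_counts(reads_by_cell[cell], chrom_sizes, window, step)
        for chrom, arr in counts.items():
            flagged = _flag_cell_windows(arr, upper_q, lower_q, merge_gap, step)
            votes[chrom][flagged] += 1
    regions = []
    n = len(cells)
    for chrom in sorted(votes):
        anomalous = votes[chrom] > cell_fraction * n
        for s, e in _runs(anomalous):
            regions.append((chrom, s * step, (e - 1) * step + window))
    if not regions:
        return []
    return merge_intervals(regions, max_gap=join_gap)


# --------------------------------------------------------------------------
# pairwise concordance
# --------------------------------------------------------------------------


def pairwise_concordance(calls: pd.DataFrame) -> pd.DataFrame:
    """Hamming distance between cells over co-covered, binary-state CpGs.

    Only calls with beta exactly 0 or 1 enter; the distance between two
    cells is the fraction of co-covered sites whose binary states differ.
    Entries with no shared site are NaN; the diagonal is 0.
    """
    binary = calls[(calls["beta"] == 0) | (calls["beta"] == 1)]
    mat = binary.pivot_table(index=["chrom", "pos"], columns="cell",
                             values="beta", aggfunc="first")
    cells = list(mat.columns)
    X = mat.to_numpy()
    n = len(cells)
    out = np.full((n, n), np.nan)
    for i in range(n):
        out[i, i] = 0.0
        for j in range(i + 1, n):
            both = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
            if both.sum() < 1:
                continue
            d = float(np.mean(X[both, i] != X[both, j]))
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=cells, columns=cells)
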