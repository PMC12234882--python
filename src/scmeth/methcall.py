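"""Per-CpG methylation extraction from directional bisulfite reads.

A read reports the strand it was templated from: on original-top (OT) reads
a C at a CpG cytosine means methylated and a T unmethylated; original-bottom
(OB) reads carry the mirror evidence at the paired G.  Read ends are trimmed
(default 10 bp at 5', 5 bp at 3') before counting, since random-priming ends
carry methylation bias.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import OB, OT, IntervalSet, Read, cpg_positions

logger = logging.getLogger(__name__)

DEFAULT_TRIM5 = 10
DEFAULT_TRIM3 = 5
DEFAULT_MIN_MAPQ = 40


def _seq_arrays(ref) -> dict:
    """Accept a ReferenceGenome or a plain chrom -> sequence dict."""
    chromosomes = getattr(ref, "chromosomes", ref)
    return {c: np.frombuffer(s.encode(), dtype=np.uint8)
            for c, s in chromosomes.items()}


def _keep(read: Read, min_mapq: int) -> bool:
    return not read.is_duplicate and read.mapq >= min_mapq


def call_methylation(reads: Iterable[Read], ref, trim5: int = DEFAULT_TRIM5,
                     trim3: int = DEFAULT_TRIM3,
                     min_mapq: int = DEFAULT_MIN_MAPQ,
                     merge_cg: bool = False,
                     track_phase_sets: bool = False) -> pd.DataFrame:
    """Pile up per-CpG, per-strand methylation counts.

    Duplicate and low-MAPQ reads are skipped; bases inside the trim zones do
    not count.  With ``track_phase_sets`` each output row carries the union
    of phase sets of contributing reads (used by allele-resolved filtering).

    Returns a DataFrame with columns cell, chrom, pos, strand, allele,
    n_meth, n_total, beta (pos is the top-strand C of the CpG; allele is 0
    for unassigned reads).
    """
    seqs = _seq_arrays(ref)
    cpgs = {c: cpg_positions(a.tobytes().decode()) for c, a in seqs.items()}
    n_rejected = 0

    cells, chroms, poss, strands, alleles, meths, psets = \
        [], [], [], [], [], [], []
    for read in reads:
        if not _keep(read, min_mapq):
            continue
        if read.chrom not in seqs or read.end > len(seqs[read.chrom]):
            n_rejected += 1
            continue
        lo, hi = read.trimmed_span(trim5, trim3)
        if hi <= lo:
            continue
        cp = cpgs[read.chrom]
        rb = np.frombuffer(read.seq.encode(), dtype=np.uint8)
        if read.bs_strand == OT:
            sel = cp[np.searchsorted(cp, lo):np.searchsorted(cp, hi)]
            bases = rb[sel - read.start]
            meth = bases == ord("C")
            informative = meth | (bases == ord("T"))
            strand = "top"
        else:
            # evidence sits on the G at pos+1
            sel = cp[np.searchsorted(cp, lo - 1):np.searchsorted(cp, hi - 1)]
            gpos = sel + 1
            ok = (gpos >= read.start) & (gpos < read.end)
            sel, gpos = sel[ok], gpos[ok]
            bases = rb[gpos - read.start]
            meth = bases == ord("G")
            informative = meth | (bases == ord("A"))
            strand = "bottom"
        n = int(informative.sum())
        if n == 0:
            continue
        cells.append(read.cell)
        chroms.append(read.chrom)
        strands.append(strand)
        alleles.append(read.haplotype or 0)
        poss.append(sel[informative])
        meths.append(meth[informative])
        if track_phase_sets:
            psets.append(frozenset(read.phase_sets))

    if n_rejected:
        logger.warning("rejected %d reads beyond chromosome bounds", n_rejected)

    if poss:
        lens = np.array([len(p) for p in poss])
        obs = pd.DataFrame({
            "cell": np.repeat(cells, lens),
            "chrom": np.repeat(chroms, lens),
            "pos": np.concatenate(poss),
            "strand": np.repeat(strands, lens),
            "allele": np.repeat(alleles, lens),
            "meth": np.concatenate(meths).astype(np.int64),
        })
        if track_phase_sets:
            obs["phase_sets"] = np.repeat(np.array(psets, dtype=object), lens)
        agg = {"n_meth": ("meth", "sum"), "n_total": ("meth", "size")}
        if track_phase_sets:
            agg["phase_sets"] = ("phase_sets",
                                 lambda s: frozenset().union(*s))
        df = obs.groupby(["cell", "chrom", "pos", "strand", "allele"],
                         as_index=False).agg(**agg)
    else:
        df = pd.DataFrame(columns=["cell", "chrom", "pos", "strand",
                                   "allele", "n_meth", "n_total"]
                          + (["phase_sets"] if track_phase_sets else []))
    if merge_cg and len(df):
        df = merge_cg_calls(df)
    df = df.sort_values(["cell", "chrom", "pos", "strand", "allele"],
                        ignore_index=True)
    df["beta"] = np.where(df["n_total"] > 0, df["n_meth"] / df["n_total"], np.nan)
    return df


def merge_cg_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Combine top/bottom-strand calls of the same CpG and same allele.

    Merging never crosses alleles (an assigned-top with unassigned-bottom
    pair stays separate), preserving hemi-methylation signal for
    allele-resolved analyses.
    """
    agg = {"n_meth": "sum", "n_total": "sum"}
    if "phase_sets" in calls.columns:
        agg["phase_sets"] = lambda s: frozenset().union(*s)
    out = (calls.groupby(["cell", "chrom", "pos", "allele"], as_index=False)
           .agg(agg))
    out["strand"] = "merged"
    out["beta"] = out["n_meth"] / out["n_total"]
    return out


def _cpy_sites(seqs: dict) -> dict:
    """Sorted positions of CpY-context cytosines per chrom and strand.

    Top strand: C followed by C or T.  Bottom strand: the cytosine shows as
    the G at pos, its 3' neighbour (bottom-strand) is the complement of
    ref[pos-1], so CpY context means ref[pos-1] in {A, G}.
    """
    out = {}
    for c, arr in seqs.items():
        top = np.flatnonzero((arr[:-1] == ord("C"))
                             & np.isin(arr[1:], [ord("C"), ord("T")]))
        bottom = np.flatnonzero((arr[1:] == ord("G"))
                                & np.isin(arr[:-1], [ord("A"), ord("G")])) + 1
        out[c] = {OT: top, OB: bottom}
    return out


def cpy_retention_per_read(reads: Sequence[Read], ref,
                           trim5: int = DEFAULT_TRIM5,
                           trim3: int = DEFAULT_TRIM3) -> np.ndarray:
    """Number of CpY (CpC or CpT context) retention events per read."""
    seqs = _seq_arrays(ref)
    sites = _cpy_sites(seqs)
    out = np.zeros(len(reads), dtype=np.int64)
    for i, read in enumerate(reads):
        if read.chrom not in seqs or read.end > len(seqs[read.chrom]):
            continue
        lo, hi = read.trimmed_span(trim5, trim3)
        if hi <= lo:
            continue
        pos = sites[read.chrom][read.bs_strand]
        sel = pos[np.searchsorted(pos, lo):np.searchsorted(pos, hi)]
        if len(sel) == 0:
            continue
        rb = np.frombuffer(read.seq.encode(), dtype=np.uint8)
        retained = ord("C") if read.bs_strand == OT else ord("G")
        out[i] = int((rb[sel - read.start] == retained).sum())
    return out


def _retention_events(read: Read, seqs: dict, trim5: int, trim3: int):
    """(context base, retained?) for every informative non-CpG cytosine."""
    arr = seqs.get(read.chrom)
    empty = (np.array([], dtype=np.uint8), np.array([], dtype=bool))
    if arr is None or read.end > len(arr):
        return empty
    lo, hi = read.trimmed_span(trim5, trim3)
    if hi <= lo:
        return empty
    rb = np.frombuffer(read.seq.encode(), dtype=np.uint8)
    span = np.arange(lo, hi)
    refb = arr[span]
    if read.bs_strand == OT:
        is_c = (refb == ord("C")) & (span + 1 < len(arr))
        pos = span[is_c]
        nxt = arr[np.minimum(pos + 1, len(arr) - 1)]
        non_cpg = nxt != ord("G")
        pos, ctx = pos[non_cpg], nxt[non_cpg]
        base = rb[pos - read.start]
        keep = (base == ord("C")) | (base == ord("T"))
        return ctx[keep], (base[keep] == ord("C"))
    else:
        is_g = (refb == ord("G")) & (span - 1 >= 0)
        pos = span[is_g]
        prv = arr[np.maximum(pos - 1, 0)]
        non_cpg = prv != ord("C")
        pos, prv = pos[non_cpg], prv[non_cpg]
        # context base on the bottom strand is the complement of ref[pos-1]
        comp = np.full(len(prv), ord("N"), dtype=np.uint8)
        for a, b in zip(b"ACGT", b"TGCA"):
            comp[prv == a] = b
        base = rb[pos - read.start]
        keep = (base == ord("G")) | (base == ord("A"))
        return comp[keep], (base[keep] == ord("G"))


def cpy_retention(reads: Sequence[Read], ref, trim5: int = DEFAULT_TRIM5,
                  trim3: int = DEFAULT_TRIM3,
                  min_mapq: int = DEFAULT_MIN_MAPQ) -> pd.DataFrame:
    """Per-cell retention rates at CpA, CpC, CpT; CpY = mean(CpC, CpT).

    Retention = unconverted C / informative C per context; a rate with no
    informative cytosines is reported as NaN.
    """
    seqs = _seq_arrays(ref)
    acc: dict[str, dict[str, list]] = {}
    for read in reads:
        if not _keep(read, min_mapq):
            continue
        ctx, state = _retention_events(read, seqs, trim5, trim3)
        cell = acc.setdefault(read.cell, {"A": [0, 0], "C": [0, 0], "T": [0, 0]})
        for b, name in ((ord("A"), "A"), (ord("C"), "C"), (ord("T"), "T")):
            m = ctx == b
            cell[name][0] += int(state[m].sum())
            cell[name][1] += int(m.sum())
    rows = []
    for cell, d in sorted(acc.items()):
        rates = {}
        for name in "ACT":
            ret, tot = d[name]
            rates[name] = ret / tot if tot else np.nan
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cpy = np.nanmean([rates["C"], rates["T"]])
        rows.append((cell, rates["A"], rates["C"], rates["T"], float(cpy)))
    return pd.DataFrame(rows, columns=["cell", "CpA", "CpC", "CpT", "CpY"])


def filter_retention_reads(reads: Sequence[Read], ref,
                           max_cpy_retention: int = 1) -> list[Read]:
    """Drop reads with more than ``max_cpy_retention`` CpY retention events.

    Default 1 is the alignment-polishing filter (">1 event" removed); the
    strict variant used for cross-protocol comparisons is
    ``max_cpy_retention=0`` (">=1 event" removed).
    """
    counts = cpy_retention_per_read(reads, ref)
    return [r for r, c in zip(reads, counts) if c <= max_cpy_retention]


def summarize_regions(calls: pd.DataFrame, regions, min_calls: int = 1,
                      min_fraction_covered: float = 0.0,
                      ref=None) -> pd.DataFrame:
    """Mean β over covered CpGs per cell × region.

    Regions failing the coverage thresholds are dropped; a region with no
    covered CpGs is absent from the output.  ``min_fraction_covered`` needs
    ``ref`` to count the CpGs each region contains.
    """
    if not isinstance(regions, IntervalSet):
        regions = IntervalSet(regions)
    if len(calls) == 0 or len(regions) == 0:
        return pd.DataFrame(columns=["cell", "chrom", "start", "end",
                                     "mean_beta", "n_calls", "n_cpgs"])
    region_rows = list(regions.intervals())
    cpg_in_region = None
    if min_fraction_covered > 0:
        if ref is None:
            raise ValueError("min_fraction_covered requires ref")
        seqs = _seq_arrays(ref)
        cpg_in_region = {}
        for c, s, e in region_rows:
            cp = cpg_positions(seqs[c].tobytes().decode())
            cpg_in_region[(c, s, e)] = int(((cp >= s) & (cp < e)).sum())

    pieces = []
    for chrom, sub in calls.groupby("chrom"):
        idx = regions.interval_index(chrom, sub["pos"].to_numpy())
        hit = idx >= 0
        if not hit.any():
            continue
        sub = sub.loc[hit].copy()
        local = [(c, s, e) for c, s, e in region_rows if c == chrom]
        sub["start"] = [local[i][1] for i in idx[hit]]
        sub["end"] = [local[i][2] for i in idx[hit]]
        pieces.append(sub)
    if not pieces:
        return pd.DataFrame(columns=["cell", "chrom", "start", "end",
                                     "mean_beta", "n_calls", "n_cpgs"])
    merged = pd.concat(pieces)
    out = (merged.groupby(["cell", "chrom", "start", "end"], as_index=False)
           .agg(mean_beta=("beta", "mean"), n_calls=("beta", "size"),
                n_cpgs=("pos", "nunique")))
    out = out[out["n_calls"] >= min_calls]
    if cpg_in_region is not None:
        frac = [out_row.n_cpgs / max(1, cpg_in_region[(out_row.chrom,
                                                       out_row.start,
                                                       out_row.end)])
                for out_row in out.itertuples()]
        out = out[np.array(frac) >= min_fraction_covered]
    return out.reset_index(drop=True)
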