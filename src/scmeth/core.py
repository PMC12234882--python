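"""Core data containers shared across the pipeline.

Coordinates are 0-based, half-open everywhere in memory.  BED-style output
stays 0-based; VCF output is 1-based.  A CpG is always addressed by the
position of the C on the top (reference) strand; the paired G sits at
``cpg_pos + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: parent-strand labels for directional bisulfite reads: "OT" reads report the
#: original top strand (C -> T conversion), "OB" the original bottom strand
#: (G -> A conversion in top-strand coordinates).
OT = "OT"
OB = "OB"


@dataclass
class Read:
    """One aligned directional bisulfite read (stored in reference orientation).

    ``seq`` is the read sequence written in top-strand coordinates, so it can
    be compared base-by-base against the reference slice at ``start``.
    Truth fields (``true_allele``, ``cell``) are simulator scoring tags; the
    analysis modules never read ``true_allele``.
    """

    name: str
    chrom: str
    start: int
    seq: str
    bs_strand: str  # OT or OB
    cell: str = ""
    mapq: int = 60
    is_duplicate: bool = False
    is_read2: bool = False
    is_reverse: bool = False
    mate_start: int | None = None
    true_allele: int | None = None
    haplotype: int | None = None  # filled in by arm.assign_reads
    phase_sets: tuple = ()
    primary_phase_set: int | None = None

    @property
    def end(self) -> int:
        return self.start + len(self.seq)

    def trimmed_span(self, trim5: int, trim3: int) -> tuple[int, int]:
        """Reference interval remaining after 5'/3' read-end trimming.

        The 5' end of the sequenced read is the left end for forward reads
        and the right end for reverse reads.
        """
        if self.is_reverse:
            lo, hi = self.start + trim3, self.end - trim5
        else:
            lo, hi = self.start + trim5, self.end - trim3
        return lo, max(lo, hi)


@dataclass(frozen=True)
class HetSNP:
    """Phased (or to-be-phased) biallelic heterozygous SNV."""

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    phase_set_id: int = -1
    hap_of_alt: int = 0  # 1 or 2 once phased, 0 if unphased
    cpg_effect: str = "neutral"  # creates | destroys | neutral

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class CellQC:
    """Per-cell quality summary."""

    cell_id: str
    discordance: float | None = None
    arm_discordance: float | None = None
    n_cpg_covered: int = 0
    total_reads: int = 0
    very_early_read_fraction: float | None = None
    doublet: bool = False
    low_efficiency: bool = False
    phase: str | None = None  # G1 | S | pG2 | doublet


class IntervalSet:
    """Sorted, non-overlapping-or-not interval collection per chromosome.

    Lightweight wrapper over numpy arrays supporting fast point membership
    and overlap queries; sufficient for the annotation tracks used here.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in intervals:
            if e < s:
                raise ValueError(f"interval end < start: {chrom}:{s}-{e}")
            by_chrom.setdefault(chrom, []).append((int(s), int(e)))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._order: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            self._starts[chrom] = np.array([s for s, _ in ivs], dtype=np.int64)
            self._ends[chrom] = np.array([e for _, e in ivs], dtype=np.int64)

    def __len__(self) -> int:
        return sum(len(v) for v in self._starts.values())

    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def intervals(self, chrom: str | None = None):
        chroms = [chrom] if chrom is not None else self.chroms()
        for c in chroms:
            if c not in self._starts:
                continue
            for s, e in zip(self._starts[c], self._ends[c]):
                yield c, int(s), int(e)

    def contains(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean mask: which positions fall inside any interval.

        Assumes intervals on a chromosome do not overlap (true for all
        generated annotation tracks).
        """
        positions = np.asarray(positions)
        if chrom not in self._starts or len(positions) == 0:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(self._starts[chrom], positions, side="right") - 1
        ok = idx >= 0
        res = np.zeros(len(positions), dtype=bool)
        res[ok] = positions[ok] < self._ends[chrom][idx[ok]]
        return res

    def interval_index(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Index of the covering interval per position, -1 if none."""
        positions = np.asarray(positions)
        out = np.full(len(positions), -1, dtype=np.int64)
        if chrom not in self._starts or len(positions) == 0:
            return out
        idx = np.searchsorted(self._starts[chrom], positions, side="right") - 1
        ok = (idx >= 0) & (positions < self._ends[chrom][np.clip(idx, 0, None)])
        out[ok] = idx[ok]
        return out

    def nearest_distance(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Distance from each position to the nearest interval (0 if inside)."""
        positions = np.asarray(positions, dtype=np.int64)
        if chrom not in self._starts or len(positions) == 0:
            return np.full(len(positions), np.iinfo(np.int64).max)
        starts, ends = self._starts[chrom], self._ends[chrom]
        idx = np.searchsorted(starts, positions, side="right")
        dist = np.full(len(positions), np.iinfo(np.int64).max)
        has_prev = idx > 0
        prev_end = ends[np.clip(idx - 1, 0, None)]
        dist[has_prev] = np.maximum(positions[has_prev] - prev_end[has_prev] + 1, 0)
        has_next = idx < len(starts)
        nxt = starts[np.clip(idx, None, len(starts) - 1)]
        d_next = np.maximum(nxt - positions, 0)
        dist[has_next] = np.minimum(dist[has_next], d_next[has_next])
        inside = self.contains(chrom, positions)
        dist[inside] = 0
        return dist


def merge_intervals(
    intervals: Sequence[tuple[str, int, int]], max_gap: int = 0
) -> list[tuple[str, int, int]]:
    """Merge intervals closer than ``max_gap`` (gap < max_gap joins; gap == 0
    i.e. touching always joins)."""
    out: list[tuple[str, int, int]] = []
    for chrom in sorted({c for c, _, _ in intervals}):
        ivs = sorted((s, e) for c, s, e in intervals if c == chrom)
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s - cur_e <= max_gap:
                cur_e = max(cur_e, e)
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append((chrom, cur_s, cur_e))
    return out


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def cpg_positions(seq: str) -> np.ndarray:
    """0-based positions of the C of every CG dinucleotide."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def calls_frame(records: Iterable[dict]) -> pd.DataFrame:
    """Build a methylation-call DataFrame with canonical columns."""
    df = pd.DataFrame.from_records(
        records,
        columns=["cell", "chrom", "pos", "strand", "allele", "n_meth", "n_total"],
    )
    if len(df):
        df["beta"] = df["n_meth"] / df["n_total"]
    else:
        df["beta"] = pd.Series(dtype=float)
    return df
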