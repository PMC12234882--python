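"""Allele-resolved methylation under bisulfite ambiguity.

Bisulfite conversion collapses C to T on the original-top strand and G to A
on the original-bottom strand, so naive read-backed phasing misreads
conversion as variation.  The chain implemented here: strict single-end
deduplication -> de-novo het SNV discovery from pseudo-bulk piles ->
"deconversion" of reads (every base replaced by the reference except
unambiguous SNP evidence) -> local read-backed phasing into phase sets ->
majority-vote haplotagging -> methylation calling against a patched
reference containing all possible CpGs, with three discard rules protecting
against SNP-induced artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import OB, OT, HetSNP, IntervalSet, Read
from . import methcall

logger = logging.getLogger(__name__)

_BASE_IDX = {ord(b): i for i, b in enumerate("ACGT")}
_A, _C, _G, _T = (ord(c) for c in "ACGT")

TRIM_LEFT = 10
TRIM_RIGHT = 5
MAX_MISMATCHES = 7  # reads with >= this many mismatches are excluded


class SnpTable:
    """Fast per-chromosome lookup over a SNP list."""

    def __init__(self, snps: Sequence[HetSNP]):
        self.snps = list(snps)
        self.by_chrom: dict[str, np.ndarray] = {}
        self._gidx: dict[str, np.ndarray] = {}
        order: dict[str, list] = {}
        for g, s in enumerate(self.snps):
            order.setdefault(s.chrom, []).append((s.pos, g))
        for chrom, pairs in order.items():
            pairs.sort()
            self.by_chrom[chrom] = np.array([p for p, _ in pairs], dtype=np.int64)
            self._gidx[chrom] = np.array([g for _, g in pairs], dtype=np.int64)

    def in_span(self, chrom: str, lo: int, hi: int) -> np.ndarray:
        """Global SNP indices with lo <= pos < hi."""
        pos = self.by_chrom.get(chrom)
        if pos is None:
            return np.array([], dtype=np.int64)
        a, b = np.searchsorted(pos, [lo, hi])
        return self._gidx[chrom][a:b]


def _seq_arrays(ref) -> dict:
    chromosomes = getattr(ref, "chromosomes", ref)
    return {c: np.frombuffer(s.encode(), dtype=np.uint8)
            for c, s in chromosomes.items()}


# --------------------------------------------------------------------------
# strict deduplication
# --------------------------------------------------------------------------


def strict_deduplicate(reads: Iterable[Read]) -> list[Read]:
    """Re-mark duplicates in single-end mode after unpairing.

    Random re-priming can generate pairs whose first reads share a start but
    whose mates differ — pair-aware tools miss these.  Mate links are
    cleared, the read number is appended to the name, and every read beyond
    the first sharing (chrom, start, strand) is flagged as duplicate.
    """
    out = []
    seen: set[tuple] = set()
    for r in sorted(reads, key=lambda r: (r.chrom, r.start, r.is_read2, r.name)):
        c = replace(r, name=f"{r.name}/{2 if r.is_read2 else 1}",
                    mate_start=None)
        key = (c.chrom, c.start, c.bs_strand, c.is_reverse)
        if key in seen:
            c.is_duplicate = True
        else:
            seen.add(key)
        out.append(c)
    return out


# --------------------------------------------------------------------------
# mismatch counting and SNP evidence
# --------------------------------------------------------------------------


def count_mismatches(read: Read, seqs: dict) -> int:
    """Mismatches against the (unpatched) reference, excluding conversion-
    consistent changes (C->T on OT reads, G->A on OB reads) and Ns."""
    arr = seqs[read.chrom]
    rb = np.frombuffer(read.seq.encode(), dtype=np.uint8)
    ref = arr[read.start:read.end]
    mm = rb != ref
    if read.bs_strand == OT:
        mm &= ~((ref == _C) & (rb == _T))
    else:
        mm &= ~((ref == _G) & (rb == _A))
    mm &= rb != ord("N")
    return int(mm.sum())


def _support(base: int, snp: HetSNP, bs_strand: str) -> str | None:
    """Which allele a read base supports: 'ref', 'alt', ambiguous (None) or
    an error ('')."""
    def obs(allele: str) -> tuple:
        if bs_strand == OT and allele == "C":
            return ("C", "T")
        if bs_strand == OB and allele == "G":
            return ("G", "A")
        return (allele,)

    b = chr(base)
    hits = [lab for lab, allele in (("ref", snp.ref_allele),
                                    ("alt", snp.alt_allele))
            if b in obs(allele)]
    if len(hits) == 1:
        return hits[0]
    if len(hits) == 2:
        return None
    return ""


def snp_evidence(read: Read, snps: SnpTable, trim_left: int = TRIM_LEFT,
                 trim_right: int = TRIM_RIGHT) -> list[tuple[int, bool]]:
    """Unambiguous (snp index, is_alt) evidence inside the trimmed span."""
    lo, hi = read.trimmed_span(trim_left, trim_right)
    idx = snps.in_span(read.chrom, lo, hi)
    rb = np.frombuffer(read.seq.encode(), dtype=np.uint8)
    out = []
    for g in idx:
        snp = snps.snps[int(g)]
        sup = _support(int(rb[snp.pos - read.start]), snp, read.bs_strand)
        if sup in ("ref", "alt"):
            out.append((int(g), sup == "alt"))
    return out


def deconvert_read(read: Read, ref, snps: Sequence[HetSNP] | SnpTable) -> str:
    """Strip bisulfite ambiguity for phasing.

    Rule 1: inserted bases that are conversion-ambiguous (T on the C->T
    strand, A on the G->A strand) become N — vacuous here since reads carry
    no indels.  Rule 2: at known het SNPs, ambiguous bases become N and
    informative bases the supported allele base.  Rule 3: every other base
    becomes the reference base.  Idempotent by construction.
    """
    if read.bs_strand not in (OT, OB):
        raise ValueError(f"unknown parent strand: {read.bs_strand!r}")
    table = snps if isinstance(snps, SnpTable) else SnpTable(snps)
    seqs = _seq_arrays(ref)
    out = seqs[read.chrom][read.start:read.end].copy()
    rb = np.frombuffer(read.seq.encode(), dtype=np.uint8)
    for g in table.in_span(read.chrom, read.start, read.end):
        snp = table.snps[int(g)]
        i = snp.pos - read.start
        sup = _support(int(rb[i]), snp, read.bs_strand)
        if sup == "ref":
            out[i] = ord(snp.ref_allele)
        elif sup == "alt":
            out[i] = ord(snp.alt_allele)
        else:
            out[i] = ord("N")
    return out.tobytes().decode()


# --------------------------------------------------------------------------
# variant discovery
# --------------------------------------------------------------------------


def discover_variants(reads: Sequence[Read], ref,
                      trim_left: int = TRIM_LEFT, trim_right: int = TRIM_RIGHT,
                      max_mismatches: int = MAX_MISMATCHES,
                      min_mapq: int = 40, min_alt_reads: int = 2,
                      af_range: tuple = (0.25, 0.75),
                      mapq_bin: int = 500, min_bin_mapq: float = 45.0,
                      min_cells: int = 5, min_cell_fraction: float = 0.05
                      ) -> list[HetSNP]:
    """De-novo heterozygous SNV discovery from strictly-deduplicated reads.

    Pseudo-bulk piles are built from trimmed, <=mismatch-filtered reads;
    only conversion-unambiguous base evidence counts (a T on an OT read
    never supports a C/T call, a read A on OB never a G/A call).  Kept sites
    have pseudo-bulk alt frequency inside ``af_range`` and a quorum of
    supporting cells (>= max(min_cells, min_cell_fraction x n_cells), a cell
    supporting iff it has >= 1 unambiguous alt read), and do not sit in a
    500 bp bin whose mean read MAPQ is below 45.
    """
    cells = sorted({r.cell for r in reads})
    if not cells:
        raise ValueError("no cells in read set")
    quorum = max(min_cells, int(np.ceil(min_cell_fraction * len(cells))))
    seqs = _seq_arrays(ref)

    usable = []
    bin_mapq_sum: dict[str, np.ndarray] = {}
    bin_mapq_n: dict[str, np.ndarray] = {}
    for c, arr in seqs.items():
        nb = len(arr) // mapq_bin + 1
        bin_mapq_sum[c] = np.zeros(nb)
        bin_mapq_n[c] = np.zeros(nb, dtype=np.int64)
    for r in reads:
        if r.is_duplicate or r.chrom not in seqs or r.end > len(seqs[r.chrom]):
            continue
        b = r.start // mapq_bin
        bin_mapq_sum[r.chrom][b] += r.mapq
        bin_mapq_n[r.chrom][b] += 1
        if r.mapq < min_mapq:
            continue
        if count_mismatches(r, seqs) >= max_mismatches:
            continue
        usable.append(r)

    candidates: list[HetSNP] = []
    for chrom, arr in seqs.items():
        # unambiguous per-base evidence piles: OT contributes A/C/G, OB A?/no:
        # on OT a T is ambiguous wherever C is in play; on OB an A likewise.
        ev = np.zeros((len(arr), 4), dtype=np.int32)
        for r in usable:
            if r.chrom != chrom:
                continue
            lo, hi = r.trimmed_span(trim_left, trim_right)
            if hi <= lo:
                continue
            rb = np.frombuffer(r.seq.encode(), dtype=np.uint8)[lo - r.start:
                                                               hi - r.start]
            span = np.arange(lo, hi)
            valid = np.isin(rb, (_A, _C, _G, _T))
            if r.bs_strand == OT:
                valid &= rb != _T
            else:
                valid &= rb != _A
            np.add.at(ev, (span[valid],
                           np.searchsorted(np.array([_A, _C, _G, _T]),
                                           rb[valid])), 1)
        ref_idx = np.full(len(arr), -1)
        for b, i in _BASE_IDX.items():
            ref_idx[arr == b] = i
        alt_ev = ev.copy()
        ok = ref_idx >= 0
        alt_ev[np.arange(len(arr))[ok], ref_idx[ok]] = 0
        best_alt = alt_ev.argmax(axis=1)
        best_n = alt_ev.max(axis=1)
        cand = np.flatnonzero((best_n >= min_alt_reads) & ok)
        mean_mapq = np.divide(bin_mapq_sum[chrom],
                              np.maximum(bin_mapq_n[chrom], 1))
        for pos in cand:
            if mean_mapq[pos // mapq_bin] < min_bin_mapq:
                continue
            refb = chr(arr[pos])
            altb = "ACGT"[best_alt[pos]]
            n_alt = int(ev[pos, best_alt[pos]])
            n_ref = int(ev[pos, ref_idx[pos]])
            if n_alt + n_ref == 0:
                continue
            af = n_alt / (n_alt + n_ref)
            if not (af_range[0] <= af <= af_range[1]):
                continue
            ctx = arr[max(0, pos - 1):pos + 2].tobytes().decode()
            off = 1 if pos > 0 else 0
            alt_ctx = ctx[:off] + altb + ctx[off + 1:]
            delta = alt_ctx.count("CG") - ctx.count("CG")
            effect = ("creates" if delta > 0
                      else "destroys" if delta < 0 else "neutral")
            candidates.append(HetSNP(chrom, int(pos), refb, altb,
                                     cpg_effect=effect))

    # quorum: cells with >= 1 unambiguous alt read per candidate
    table = SnpTable(candidates)
    support: dict[int, set] = {}
    for r in usable:
        for g, is_alt in snp_evidence(r, table, trim_left, trim_right):
            if is_alt:
                support.setdefault(g, set()).add(r.cell)
    return [s for g, s in enumerate(candidates)
            if len(support.get(g, ())) >= quorum]


def patch_reference(ref, snps: Sequence[HetSNP]) -> dict:
    """Apply CpG-creating alternate alleles so every possible CpG exists."""
    chromosomes = dict(getattr(ref, "chromosomes", ref))
    by_pos: dict[tuple, HetSNP] = {}
    for s in snps:
        if s.cpg_effect != "creates":
            continue
        key = (s.chrom, s.pos)
        if key in by_pos and by_pos[key].alt_allele != s.alt_allele:
            raise ValueError(f"conflicting overlapping SNPs at {key}")
        by_pos[key] = s
    arrays = {c: bytearray(seq.encode()) for c, seq in chromosomes.items()}
    for (chrom, pos), s in by_pos.items():
        arrays[chrom][pos] = ord(s.alt_allele)
    return {c: bytes(a).decode() for c, a in arrays.items()}


# --------------------------------------------------------------------------
# local phasing
# --------------------------------------------------------------------------


class _UnionFindParity:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.parity = [0] * n  # parity relative to parent

    def find(self, x: int) -> tuple[int, int]:
        if self.parent[x] == x:
            return x, 0
        root, p = self.find(self.parent[x])
        self.parent[x] = root
        self.parity[x] ^= p
        return root, self.parity[x]

    def union(self, x: int, y: int, rel: int) -> bool:
        rx, px = self.find(x)
        ry, py = self.find(y)
        if rx == ry:
            return (px ^ py) == rel
        self.parent[ry] = rx
        self.parity[ry] = px ^ py ^ rel
        return True


def phase_variants(reads: Sequence[Read], snps: Sequence[HetSNP],
                   ref=None, trim_left: int = TRIM_LEFT,
                   trim_right: int = TRIM_RIGHT,
                   max_mismatches: int = MAX_MISMATCHES,
                   min_link_weight: int = 2) -> list[HetSNP]:
    """Read-backed local phasing into phase sets.

    SNP pairs co-observed on a fragment (mates pooled) vote cis or trans;
    edges are resolved greedily in decreasing majority-weight order over a
    union-find with parity.  Equal cis/trans support breaks the edge, and
    edges whose net majority weight |cis − trans| falls below
    ``min_link_weight`` are not trusted either — both are the same
    discard-on-ambiguity stance (a single erroneous fragment must not be
    able to join or mis-orient a phase set).  SNPs never linked become
    singleton phase sets.  Returns new HetSNPs with phase_set_id and
    hap_of_alt filled in.
    """
    table = SnpTable(snps)
    seqs = _seq_arrays(ref) if ref is not None else None

    frag_ev: dict[str, dict[int, bool]] = {}
    for r in reads:
        if r.is_duplicate:
            continue
        if seqs is not None and count_mismatches(r, seqs) >= max_mismatches:
            continue
        base = r.name.rsplit("/", 1)[0]
        d = frag_ev.setdefault(f"{r.cell}\t{base}", {})
        for g, is_alt in snp_evidence(r, table, trim_left, trim_right):
            if g in d and d[g] != is_alt:
                d[g] = None  # internal conflict: drop this SNP's evidence
            elif g not in d:
                d[g] = is_alt

    edges: dict[tuple, list] = {}
    for ev in frag_ev.values():
        items = [(g, a) for g, a in ev.items() if a is not None]
        for i in range(len(items)):
            for j in range(i + 1, len(items)):
                (g1, a1), (g2, a2) = items[i], items[j]
                key = (min(g1, g2), max(g1, g2))
                rec = edges.setdefault(key, [0, 0])
                rec[0 if a1 == a2 else 1] += 1

    uf = _UnionFindParity(len(table.snps))
    ordered = sorted(edges.items(),
                     key=lambda kv: (-abs(kv[1][0] - kv[1][1]), kv[0]))
    for (g1, g2), (cis, trans) in ordered:
        if abs(cis - trans) < min_link_weight:
            continue  # tie or weak link: leave unlinked
        uf.union(g1, g2, 0 if cis > trans else 1)

    phased = []
    roots: dict[int, int] = {}
    for g, s in enumerate(table.snps):
        root, parity = uf.find(g)
        ps = roots.setdefault(root, len(roots))
        phased.append(replace(s, phase_set_id=ps, hap_of_alt=1 + parity))
    return phased


# --------------------------------------------------------------------------
# haplotagging
# --------------------------------------------------------------------------


def assign_reads(reads: Sequence[Read], phased_snps: Sequence[HetSNP], ref,
                 trim_left: int = TRIM_LEFT, trim_right: int = TRIM_RIGHT,
                 max_mismatches: int = MAX_MISMATCHES) -> list[Read]:
    """Majority-vote haplotype assignment, mates pooled.

    Reads are trimmed before evidence extraction and excluded outright at
    >= ``max_mismatches`` mismatches.  The haplotype is the majority vote
    over informative SNPs of the phase set contributing the most evidence;
    a cross-set tie, an in-set vote tie, or zero informative SNPs leaves
    the read unassigned.  Tags land on the original (un-deconverted) reads.
    """
    table = SnpTable(phased_snps)
    seqs = _seq_arrays(ref)

    groups: dict[str, list[Read]] = {}
    out: list[Read] = []
    for r in reads:
        c = replace(r)
        out.append(c)
        if c.is_duplicate:
            continue
        if count_mismatches(c, seqs) >= max_mismatches:
            continue
        base = c.name.rsplit("/", 1)[0]
        groups.setdefault(f"{c.cell}\t{base}", []).append(c)

    for members in groups.values():
        votes: dict[int, list] = {}  # phase set -> [hap1 votes, hap2 votes]
        touched: set[int] = set()
        for r in members:
            for g, is_alt in snp_evidence(r, table, trim_left, trim_right):
                snp = table.snps[g]
                hap = snp.hap_of_alt if is_alt else 3 - snp.hap_of_alt
                rec = votes.setdefault(snp.phase_set_id, [0, 0])
                rec[hap - 1] += 1
                touched.add(snp.phase_set_id)
        hap, primary = _resolve_votes(votes)
        for r in members:
            r.phase_sets = tuple(sorted(touched))
            r.haplotype = hap
            r.primary_phase_set = primary


    return out


def _resolve_votes(votes: dict) -> tuple[int | None, int | None]:
    if not votes:
        return None, None
    sized = sorted(votes.items(), key=lambda kv: (-(kv[1][0] + kv[1][1]), kv[0]))
    if len(sized) > 1 and (sized[0][1][0] + sized[0][1][1]
                           == sized[1][1][0] + sized[1][1][1]):
        return None, None  # tie between phase sets
    ps, (v1, v2) = sized[0]
    if v1 == v2:
        return None, ps
    return (1 if v1 > v2 else 2), ps


# --------------------------------------------------------------------------
# allele-resolved calls and two-strand states
# --------------------------------------------------------------------------


def call_arm(tagged_reads: Sequence[Read], patched_ref,
             phased_snps: Sequence[HetSNP], unpatched_ref=None,
             trim5: int = TRIM_LEFT, trim3: int = TRIM_RIGHT,
             min_mapq: int = 40) -> pd.DataFrame:
    """Allele-resolved methylation calls with the three discard rules.

    Calling runs against the patched reference (all possible CpGs present).
    Discards: (1) calls at a CpG-creating or -destroying SNP on the allele
    lacking the CpG; (2) calls whose contributing reads span multiple phase
    sets; (3) CpGs where both bases are SNPs.
    """
    tagged = [r for r in tagged_reads if r.haplotype is not None]
    calls = methcall.call_methylation(tagged, patched_ref, trim5=trim5,
                                      trim3=trim3, min_mapq=min_mapq,
                                      track_phase_sets=True)
    if len(calls) == 0:
        return calls

    # rule 2: multiple phase sets contributed
    keep = calls["phase_sets"].map(len) <= 1
    calls = calls[keep]

    # rule 1: per-(chrom, cpg_pos) allele lacking the CpG
    invalid: set[tuple] = set()
    snp_pos: dict[str, set] = {}
    seqs = _seq_arrays(patched_ref)
    for s in phased_snps:
        snp_pos.setdefault(s.chrom, set()).add(s.pos)
        if s.cpg_effect not in ("creates", "destroys"):
            continue
        arr = seqs[s.chrom]
        cpg_at = []
        if s.pos + 1 < len(arr) and chr(arr[s.pos + 1]) == "G":
            cpg_at.append(s.pos)
        if s.pos >= 1 and chr(arr[s.pos - 1]) == "C":
            cpg_at.append(s.pos - 1)
        if s.cpg_effect == "creates":
            lacking = 3 - s.hap_of_alt if s.hap_of_alt else None
        else:
            lacking = s.hap_of_alt if s.hap_of_alt else None
        if lacking is None:
            continue
        for p in cpg_at:
            invalid.add((s.chrom, p, lacking))

    mask1 = [
        (row.chrom, row.pos, row.allele) not in invalid
        for row in calls.itertuples()
    ]
    calls = calls[mask1]

    # rule 3: both bases of the CpG are SNPs
    mask3 = [
        not (row.pos in snp_pos.get(row.chrom, ())
             and row.pos + 1 in snp_pos.get(row.chrom, ()))
        for row in calls.itertuples()
    ]
    return calls[mask3].reset_index(drop=True)


def two_strand_states(arm_calls: pd.DataFrame) -> pd.DataFrame:
    """Classify CpG dyads with both strands of the same allele covered.

    Returns rows (cell, chrom, pos, allele, state) with state sym_meth /
    hemi / sym_unmeth.  Loci with an intra-strand conflict (0 < beta < 1 on
    either strand) or discordant phase sets between strands are excluded;
    single-strand loci are skipped silently.
    """
    df = arm_calls[arm_calls["strand"].isin(["top", "bottom"])]
    keys = ["cell", "chrom", "pos", "allele"]
    cols = keys + ["beta"] + (["phase_sets"] if "phase_sets" in df.columns
                              else [])
    top = df.loc[df["strand"] == "top", cols]
    bottom = df.loc[df["strand"] == "bottom", cols]
    both = top.merge(bottom, on=keys, suffixes=("_t", "_b"))
    clean = (both["beta_t"].isin([0.0, 1.0]) & both["beta_b"].isin([0.0, 1.0]))
    if "phase_sets" in df.columns:
        same_ps = [
            (not pt) or (not pb) or pt == pb
            for pt, pb in zip(both["phase_sets_t"], both["phase_sets_b"])]
        clean &= np.array(same_ps, dtype=bool) if len(both) else True
    both = both.loc[clean]
    state = np.where(
        (both["beta_t"] == 1.0) & (both["beta_b"] == 1.0), "sym_meth",
        np.where((both["beta_t"] == 0.0) & (both["beta_b"] == 0.0),
                 "sym_unmeth", "hemi"))
    out = both[keys].copy()
    out["state"] = state
    return out.reset_index(drop=True)


def tfbs_hemimeth(states: pd.DataFrame, tfbs_sets: dict,
                  cell_groups: dict, min_events: int = 250) -> pd.DataFrame:
    """Per cell-group, per TFBS set: fractions of symmetric-methylation and
    hemi-methylation events overlapping the set.

    Hemi fraction is read against methylation fraction because absolute
    hemi-methylation tracks overall TFBS methylation.  Sets with <=
    ``min_events`` overlapping events in either class are dropped.
    """
    rows = []
    groups = sorted(set(cell_groups.values()))
    for group in groups:
        cells = {c for c, g in cell_groups.items() if g == group}
        sub = states[states["cell"].isin(cells)]
        if len(sub) == 0:
            logger.warning("cell group %s has no two-strand states", group)
            continue
        meth = sub[sub["state"] == "sym_meth"]
        hemi = sub[sub["state"] == "hemi"]
        for name, regions in tfbs_sets.items():
            if not isinstance(regions, IntervalSet):
                regions = IntervalSet(regions)
            n_meth = _overlap_count(meth, regions)
            n_hemi = _overlap_count(hemi, regions)
            if n_meth <= min_events or n_hemi <= min_events:
                continue
            rows.append((group, name,
                         n_meth / max(1, len(meth)),
                         n_hemi / max(1, len(hemi)),
                         n_meth, n_hemi))
    return pd.DataFrame(rows, columns=["group", "tfbs_set", "meth_fraction",
                                       "hemi_fraction", "n_meth", "n_hemi"])


def _overlap_count(df: pd.DataFrame, regions: IntervalSet) -> int:
    n = 0
    for chrom, sub in df.groupby("chrom"):
        n += int(regions.contains(chrom, sub["pos"].to_numpy()).sum())
    return n


# --------------------------------------------------------------------------
# truth scoring (simulation only)
# --------------------------------------------------------------------------


def score_haplotag_precision(tagged_reads: Sequence[Read],
                             phased_snps: Sequence[HetSNP],
                             true_hap_of_alt: dict) -> dict:
    """Precision of read-to-allele assignment against simulator truth tags.

    Phase-set labels are arbitrary, so each set is oriented to the truth by
    majority vote over its member SNPs; an assigned read is correct when its
    haplotype, mapped through the set orientation, matches the read's true
    allele.  Returns precision, counts and the number of oriented sets.
    """
    members: dict[int, list[HetSNP]] = {}
    for s in phased_snps:
        members.setdefault(s.phase_set_id, []).append(s)
    orient: dict[int, int] = {}
    for ps, snps_ in members.items():
        agree = sum(1 for s in snps_
                    if true_hap_of_alt.get((s.chrom, s.pos)) == s.hap_of_alt)
        disagree = sum(1 for s in snps_
                       if (s.chrom, s.pos) in true_hap_of_alt) - agree
        orient[ps] = 1 if agree >= disagree else -1

    n_assigned = n_correct = 0
    for r in tagged_reads:
        if r.haplotype is None or r.true_allele is None or r.is_duplicate:
            continue
        if r.primary_phase_set not in orient:
            continue
        implied = r.haplotype if orient[r.primary_phase_set] == 1 \
            else 3 - r.haplotype
        n_assigned += 1
        n_correct += int(implied == r.true_allele)
    precision = n_correct / n_assigned if n_assigned else float("nan")
    return {"precision": precision, "n_assigned": n_assigned,
            "n_correct": n_correct, "n_phase_sets": len(orient)}
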