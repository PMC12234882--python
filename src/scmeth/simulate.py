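"""Synthetic single-cell whole-genome bisulfite data with known ground truth.

Emulates a small diploid genome (autosomes + one chrX) carrying phased
heterozygous SNVs, per-cell / per-allele / per-strand CpG methylation states
structured by cell type, X-inactivation, and replication timing, and emits
pre-aligned directional bisulfite reads.  Reads carry the true allele in a
scoring-only field that downstream analysis never consults.

Hemi-methylation arises two ways, mirroring semi-conservative replication of
5-methylcytosine: residual hemi sites in G1 cells (probability increasing
with replication-timing score) and unremethylated daughter strands in
replicated regions of S-phase cells.  S-phase cells replicate 50 kb bins in
replication-timing order up to the cell's progress, doubling copy number
there.  Doublets are unions of two cells' read sets.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import OB, OT, HetSNP, IntervalSet, Read, cpg_positions, merge_intervals

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(c) for c in "ACGT")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------


@dataclass
class SimConfig:
    """All knobs of the generator.  Defaults define the study conditions."""

    seed: int = 0

    # genome geometry
    autosomes: dict = field(default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000})
    chrx_size: int = 1_000_000
    bin_size: int = 50_000

    # annotation density
    cgi_spacing: int = 20_000
    cgi_min_len: int = 400
    cgi_max_len: int = 1200
    gene_spacing: int = 15_000
    n_celltype_regions: int = 40
    celltype_region_len: int = 1000
    n_specific_promoters: int = 25
    tfbs_sets: tuple = ("TF_A", "TF_B", "TF_C", "TF_D")
    tfbs_sites_per_set: int = 150
    tfbs_site_len: int = 200
    n_escapee_cgis: int = 2

    # diploid truth
    snp_density: float = 1.0 / 600.0
    cpg_creating_snp_fraction: float = 0.15

    # cohort composition
    n_cells: int = 64
    cell_type_mixture: dict = field(default_factory=lambda: {"GI": 0.5, "T": 0.5})
    xci_mixture: float = 0.5  # probability allele 1 is the inactive X
    s_phase_fraction: float = 0.15
    g2_fraction: float = 0.05
    doublet_rate: float = 0.05
    s_progress_range: tuple = (0.2, 0.8)

    # methylation truth levels (probability a CpG state is M)
    background_meth: float = 0.80
    cgi_meth: float = 0.05
    xi_cgi_meth: float = 0.90
    own_region_meth: float = 0.12
    other_region_meth: float = 0.88
    solo_wcgw_meth: float = 0.60
    allele_meth_diff: float = 0.02  # rate of allele-specific state flips
    xa_promoter_meth: float = 0.08
    xi_promoter_meth: float = 0.70
    xa_genebody_meth: float = 0.85
    xi_genebody_meth: float = 0.70

    # hemi-methylation model (monotone in replication-timing score 1..16)
    hemi_base: float = 0.005
    hemi_slope: float = 0.02
    s_unremeth_base: float = 0.035
    s_unremeth_slope: float = 0.015
    g2_unremeth: float = 0.015
    tfbs_hemi_boost: dict = field(default_factory=lambda: {"TF_A": "GI"})
    tfbs_hemi_boost_prob: float = 0.15

    # read emission
    read_length: int = 100
    depth: float = 6.0
    error_rate: float = 0.001
    frag_extra_max: int = 200
    dup_rate: float = 0.02
    strict_dup_rate: float = 0.01
    mapq_low_fraction: float = 0.01

    def validate(self) -> None:
        rates = {
            "snp_density": self.snp_density,
            "error_rate": self.error_rate,
            "doublet_rate": self.doublet_rate,
            "s_phase_fraction": self.s_phase_fraction,
            "g2_fraction": self.g2_fraction,
        }
        if self.snp_density <= 0:
            raise ValueError("snp_density must be > 0")
        for name, r in rates.items():
            if not (0 <= r <= 1):
                raise ValueError(f"{name} out of [0,1]: {r}")
        total = sum(self.cell_type_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"cell_type_mixture weights sum to {total}, expected 1")
        for name, size in self.chrom_sizes().items():
            if size < 2 * self.bin_size:
                raise ValueError(
                    f"chromosome {name} ({size} bp) shorter than 2 x bin size"
                )

    def chrom_sizes(self) -> dict:
        sizes = dict(self.autosomes)
        sizes["chrX"] = self.chrx_size
        return sizes


# --------------------------------------------------------------------------
# reference genome
# --------------------------------------------------------------------------


@dataclass
class ReferenceGenome:
    chromosomes: dict  # name -> uppercase DNA string
    cgi: IntervalSet
    genes: pd.DataFrame  # chrom, start, end, strand, name, specific_type
    celltype_regions: dict  # type -> IntervalSet
    tfbs: dict  # set name -> IntervalSet
    solo_wcgw: dict  # chrom -> positions array
    pmds: IntervalSet
    repliseq: pd.DataFrame  # chrom, bin_start + s1..s16 columns
    true_timing: dict  # chrom -> float array per bin (simulator truth)
    bin_size: int
    escapee_cgi_idx: tuple = ()  # interval indices on chrX left unmethylated on Xi

    _cpg_cache: dict = field(default_factory=dict, repr=False)

    def cpgs(self, chrom: str) -> np.ndarray:
        if chrom not in self._cpg_cache:
            self._cpg_cache[chrom] = cpg_positions(self.chromosomes[chrom])
        return self._cpg_cache[chrom]

    def n_cpgs(self) -> int:
        return sum(len(self.cpgs(c)) for c in self.chromosomes)

    def seq_array(self, chrom: str) -> np.ndarray:
        return np.frombuffer(self.chromosomes[chrom].encode(), dtype=np.uint8)

    def promoters(self, up: int = 1500, down: int = 200) -> pd.DataFrame:
        """Strand-aware promoter windows around each TSS."""
        rows = []
        for g in self.genes.itertuples():
            if g.strand == "+":
                s, e = g.start - up, g.start + down
            else:
                s, e = g.end - down, g.end + up
            size = len(self.chromosomes[g.chrom])
            rows.append((g.chrom, max(0, s), min(size, e), g.strand, g.name,
                         g.specific_type))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand",
                                           "name", "specific_type"])


def _random_sequence(rng, length: int) -> np.ndarray:
    # A/T-rich background with CpG depletion, as in mammalian genomes
    seq = rng.choice(_BASES, size=length, p=[0.30, 0.20, 0.20, 0.30])
    cg = np.flatnonzero((seq[:-1] == _C) & (seq[1:] == _G))
    kill = cg[rng.random(len(cg)) < 0.7]
    seq[kill] = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=len(kill))
    return seq


def _plant_cgi(rng, seq: np.ndarray, start: int, end: int) -> None:
    block = rng.choice(_BASES, size=end - start, p=[0.16, 0.34, 0.34, 0.16])
    # force CG dinucleotides roughly every 8 bp
    for p in range(0, end - start - 1, 8):
        block[p] = _C
        block[p + 1] = _G
    seq[start:end] = block


def _disjoint_intervals(rng, size: int, n: int, length: int,
                        occupied: list) -> list:
    """Place n intervals of given length avoiding previously placed ones."""
    out = []
    tries = 0
    while len(out) < n and tries < 50 * n:
        tries += 1
        s = int(rng.integers(0, size - length))
        e = s + length
        if any(s < oe and os_ < e for os_, oe in occupied):
            continue
        occupied.append((s, e))
        out.append((s, e))
    return out


def generate_reference(config: SimConfig) -> ReferenceGenome:
    """Deterministically build the genome and all annotation tracks."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(1)[0])

    sizes = config.chrom_sizes()
    chromosomes: dict[str, str] = {}
    cgi_list: list[tuple[str, int, int]] = []
    gene_rows = []
    tfbs_lists: dict[str, list] = {name: [] for name in config.tfbs_sets}
    ct_lists: dict[str, list] = {t: [] for t in config.cell_type_mixture}
    true_timing: dict[str, np.ndarray] = {}
    repli_rows = []
    escapee_idx: list[int] = []

    for chrom, size in sizes.items():
        seq = _random_sequence(rng, size)

        # genes first (TSS positions define where chrX CGIs go)
        pos = int(rng.integers(2000, config.gene_spacing))
        chrom_genes = []
        while pos + 10_000 < size - 2000:
            glen = int(rng.integers(2000, 8000))
            strand = "+" if rng.random() < 0.5 else "-"
            chrom_genes.append((chrom, pos, pos + glen, strand))
            pos += glen + int(rng.integers(config.gene_spacing // 2,
                                           config.gene_spacing * 3 // 2))
        for i, (c, s, e, strand) in enumerate(chrom_genes):
            gene_rows.append((c, s, e, strand, f"{c}_g{i}", ""))

        # CpG islands: at every chrX gene TSS, at half of autosomal TSSs,
        # plus free-standing islands at the configured spacing
        cgi_here: list[tuple[int, int]] = []
        for c, s, e, strand in chrom_genes:
            tss = s if strand == "+" else e
            if chrom == "chrX" or rng.random() < 0.5:
                L = int(rng.integers(config.cgi_min_len, config.cgi_max_len))
                a = max(0, tss - L // 2)
                cgi_here.append((a, min(size, a + L)))
        pos = int(rng.integers(0, config.cgi_spacing))
        while pos + config.cgi_max_len < size:
            if rng.random() < 0.5:
                L = int(rng.integers(config.cgi_min_len, config.cgi_max_len))
                if not any(pos < e and s < pos + L for s, e in cgi_here):
                    cgi_here.append((pos, pos + L))
            pos += int(rng.integers(config.cgi_spacing // 2,
                                    config.cgi_spacing * 3 // 2))
        cgi_here = [(s, e) for _, s, e in
                    merge_intervals([(chrom, s, e) for s, e in cgi_here])]
        for s, e in cgi_here:
            _plant_cgi(rng, seq, s, e)
            cgi_list.append((chrom, s, e))
        if chrom == "chrX" and config.n_escapee_cgis:
            n_x = len(cgi_here)
            k = min(config.n_escapee_cgis, n_x)
            escapee_idx = sorted(
                int(i) for i in rng.choice(n_x, size=k, replace=False))

        occupied = [(s, e) for s, e in cgi_here]
        if chrom != "chrX":
            for t in ct_lists:
                for s, e in _disjoint_intervals(
                        rng, size, config.n_celltype_regions // max(1, len(sizes) - 1),
                        config.celltype_region_len, occupied):
                    ct_lists[t].append((chrom, s, e))
            for name in tfbs_lists:
                for s, e in _disjoint_intervals(
                        rng, size, config.tfbs_sites_per_set // max(1, len(sizes) - 1),
                        config.tfbs_site_len, occupied):
                    tfbs_lists[name].append((chrom, s, e))

        # replication timing: smooth wave over bins with jitter
        n_bins = size // config.bin_size
        phase = rng.random() * 2 * np.pi
        i = np.arange(n_bins)
        period = min(40.0, max(4.0, float(n_bins)))  # full early->late sweep
        # span 2..14 so the retained very-early share (scores 2-4) lands
        # near 0.31, an early-skewed composition on which the 33.5%
        # very-early read-fraction rule separates S-phase from G1 cells
        t = 2.0 + 12.0 * (0.5 + 0.5 * np.sin(2 * np.pi * i / period + phase))
        t = np.clip(t + rng.normal(0, 0.4, n_bins), 1.0, 16.0)
        true_timing[chrom] = t
        k = np.arange(1, 17)
        scores = np.exp(-((k[None, :] - t[:, None]) ** 2) / (2 * 1.2 ** 2)) * 10.0
        for b in range(n_bins):
            repli_rows.append((chrom, b * config.bin_size, *scores[b]))

        chromosomes[chrom] = seq.tobytes().decode()

    genes = pd.DataFrame(gene_rows, columns=["chrom", "start", "end", "strand",
                                             "name", "specific_type"])
    # tag cell-type-specific promoters on autosomal genes
    auto_genes = genes.index[genes.chrom != "chrX"].to_numpy()
    rng.shuffle(auto_genes)
    types = list(config.cell_type_mixture)
    k = config.n_specific_promoters
    for ti, t in enumerate(types):
        chosen = auto_genes[ti * k:(ti + 1) * k]
        genes.loc[chosen, "specific_type"] = t

    repliseq = pd.DataFrame(
        repli_rows, columns=["chrom", "bin_start"] + [f"s{i}" for i in range(1, 17)])

    ref = ReferenceGenome(
        chromosomes=chromosomes,
        cgi=IntervalSet(cgi_list),
        genes=genes,
        celltype_regions={t: IntervalSet(v) for t, v in ct_lists.items()},
        tfbs={n: IntervalSet(v) for n, v in tfbs_lists.items()},
        solo_wcgw={},
        pmds=IntervalSet([]),
        repliseq=repliseq,
        true_timing=true_timing,
        bin_size=config.bin_size,
        escapee_cgi_idx=tuple(escapee_idx),
    )

    # PMDs = latest-replicating quintile of bins; solo-WCGW CpGs live there
    pmd_ivs = []
    for chrom, t in true_timing.items():
        thr = np.quantile(t, 0.8)
        for b in np.flatnonzero(t >= thr):
            pmd_ivs.append((chrom, int(b) * config.bin_size,
                            (int(b) + 1) * config.bin_size))
    ref.pmds = IntervalSet(merge_intervals(pmd_ivs)) if pmd_ivs else IntervalSet([])
    for chrom in chromosomes:
        arr = ref.seq_array(chrom)
        cp = ref.cpgs(chrom)
        inside = ref.pmds.contains(chrom, cp)
        w = (cp > 0) & (cp + 2 < len(arr))
        flank_ok = np.zeros(len(cp), dtype=bool)
        fl = cp[w]
        flank_ok[w] = (np.isin(arr[fl - 1], [_A, _T])
                       & np.isin(arr[fl + 2], [_A, _T]))
        # solo: no neighbouring CpG within 35 bp
        solo = np.ones(len(cp), dtype=bool)
        if len(cp) > 1:
            solo[1:] &= np.diff(cp) > 35
            solo[:-1] &= np.diff(cp) > 35
        ref.solo_wcgw[chrom] = cp[inside & flank_ok & solo]
    return ref


# --------------------------------------------------------------------------
# diploid truth
# --------------------------------------------------------------------------


@dataclass
class DiploidTruth:
    snps: list  # of HetSNP with truth hap_of_alt
    allele_seqs: dict  # (chrom, allele) -> str
    _cpg_cache: dict = field(default_factory=dict, repr=False)

    def snp_positions(self, chrom: str) -> np.ndarray:
        return np.array([s.pos for s in self.snps if s.chrom == chrom],
                        dtype=np.int64)

    def allele_cpgs(self, chrom: str, allele: int) -> np.ndarray:
        key = (chrom, allele)
        if key not in self._cpg_cache:
            self._cpg_cache[key] = cpg_positions(self.allele_seqs[key])
        return self._cpg_cache[key]

    def allele_array(self, chrom: str, allele: int) -> np.ndarray:
        return np.frombuffer(self.allele_seqs[(chrom, allele)].encode(),
                             dtype=np.uint8)


def generate_diploid(ref: ReferenceGenome, config: SimConfig) -> DiploidTruth:
    """Scatter phased heterozygous SNVs at the configured density."""
    if config.snp_density <= 0:
        raise ValueError("snp_density must be > 0")
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(2)[1])

    snps: list[HetSNP] = []
    allele_seqs: dict[tuple, np.ndarray] = {}
    for ci, (chrom, seq) in enumerate(ref.chromosomes.items()):
        arr = ref.seq_array(chrom)
        hits = np.flatnonzero(rng.random(len(arr) - 2) < config.snp_density) + 1
        # forbid adjacent SNPs (SNVs only; keeps per-site logic biallelic)
        if len(hits) > 1:
            hits = hits[np.concatenate(([True], np.diff(hits) > 1))]
        a1 = arr.copy()
        a2 = arr.copy()
        for pos in hits:
            pos = int(pos)
            refb = chr(arr[pos])
            alt = None
            if rng.random() < config.cpg_creating_snp_fraction:
                # try to create a CpG: put a C before a G, or a G after a C
                if chr(arr[pos + 1]) == "G" and refb != "C":
                    alt = "C"
                elif chr(arr[pos - 1]) == "C" and refb != "G":
                    alt = "G"
            if alt is None:
                choices = [b for b in "ACGT" if b != refb]
                alt = choices[int(rng.integers(0, 3))]
            ctx_ref = seq[pos - 1:pos + 2]
            ctx_alt = ctx_ref[0] + alt + ctx_ref[2]
            delta = _local_cg(ctx_alt) - _local_cg(ctx_ref)
            effect = "creates" if delta > 0 else ("destroys" if delta < 0
                                                  else "neutral")
            hap = 1 if rng.random() < 0.5 else 2
            snps.append(HetSNP(chrom, pos, refb, alt, phase_set_id=ci,
                               hap_of_alt=hap, cpg_effect=effect))
            (a1 if hap == 1 else a2)[pos] = ord(alt)
        allele_seqs[(chrom, 1)] = a1.tobytes().decode()
        allele_seqs[(chrom, 2)] = a2.tobytes().decode()
    return DiploidTruth(snps=snps, allele_seqs=allele_seqs)


def _local_cg(ctx: str) -> int:
    return sum(1 for i in range(len(ctx) - 1) if ctx[i:i + 2] == "CG")


# --------------------------------------------------------------------------
# per-cell truth
# --------------------------------------------------------------------------


@dataclass
class CellTruth:
    cell_id: str
    cell_type: str
    xci_allele: int  # which allele of chrX is INACTIVE
    phase: str  # G1 | S | G2
    progress: float  # S-phase progress in (0,1); 0 for G1, 1 for G2
    # (chrom, allele) -> dict of strand state arrays over allele CpG index
    # keys: top, bottom (parental duplex), daughter_top, daughter_bottom
    states: dict = field(default_factory=dict)
    replicated: dict = field(default_factory=dict)  # chrom -> bool array per bin
    is_doublet: bool = False
    partner: "CellTruth | None" = None


def _bin_of(positions: np.ndarray, bin_size: int) -> np.ndarray:
    return positions // bin_size


def _meth_probability(ref: ReferenceGenome, diploid: DiploidTruth,
                      config: SimConfig, chrom: str, allele: int,
                      cell_type: str, inactive: bool,
                      promoters: pd.DataFrame) -> np.ndarray:
    """Per-CpG probability of the methylated state for one allele."""
    cp = diploid.allele_cpgs(chrom, allele)
    p = np.full(len(cp), config.background_meth)

    for t, regions in ref.celltype_regions.items():
        mask = regions.contains(chrom, cp)
        p[mask] = config.own_region_meth if t == cell_type else config.other_region_meth

    prom = promoters[promoters.chrom == chrom]
    for row in prom.itertuples():
        if not row.specific_type:
            continue
        mask = (cp >= row.start) & (cp < row.end)
        p[mask] = (config.xa_promoter_meth if row.specific_type == cell_type
                   else 0.90)

    if chrom in ref.solo_wcgw and len(ref.solo_wcgw[chrom]):
        mask = np.isin(cp, ref.solo_wcgw[chrom])
        p[mask] = config.solo_wcgw_meth

    if chrom == "chrX":
        genes = ref.genes[ref.genes.chrom == "chrX"]
        for row in genes.itertuples():
            body = (cp >= row.start) & (cp < row.end)
            p[body] = config.xi_genebody_meth if inactive else config.xa_genebody_meth
        for row in prom.itertuples():
            mask = (cp >= row.start) & (cp < row.end)
            p[mask] = config.xi_promoter_meth if inactive else config.xa_promoter_meth

    # interval_index is per-chromosome, so indices are chrX-local on chrX
    cgi_idx = ref.cgi.interval_index(chrom, cp)
    in_cgi = cgi_idx >= 0
    p[in_cgi] = config.cgi_meth
    if chrom == "chrX" and inactive:
        meth_mask = in_cgi & ~np.isin(cgi_idx, list(ref.escapee_cgi_idx))
        p[meth_mask] = config.xi_cgi_meth
    return p


def generate_cells(ref: ReferenceGenome, diploid: DiploidTruth,
                   config: SimConfig) -> list[CellTruth]:
    """Draw the cohort: cell types, XCI states, cycle phases, truth states."""
    config.validate()
    root = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(root.spawn(3)[2])
    promoters = ref.promoters()

    types = list(config.cell_type_mixture)
    weights = np.array([config.cell_type_mixture[t] for t in types])

    def one_cell(cell_id: str) -> CellTruth:
        ctype = types[int(rng.choice(len(types), p=weights))]
        xci = 1 if rng.random() < config.xci_mixture else 2
        u = rng.random()
        if u < config.s_phase_fraction:
            phase, progress = "S", float(rng.uniform(*config.s_progress_range))
        elif u < config.s_phase_fraction + config.g2_fraction:
            phase, progress = "G2", 1.0
        else:
            phase, progress = "G1", 0.0
        cell = CellTruth(cell_id, ctype, xci, phase, progress)
        _fill_states(cell, ref, diploid, config, rng, promoters)
        return cell

    cells = []
    for i in range(config.n_cells):
        cell = one_cell(f"cell{i:03d}")
        if rng.random() < config.doublet_rate:
            cell.is_doublet = True
            cell.partner = one_cell(cell.cell_id + "_partner")
            cell.partner.cell_id = cell.cell_id
        cells.append(cell)
    return cells


def _fill_states(cell: CellTruth, ref: ReferenceGenome, diploid: DiploidTruth,
                 config: SimConfig, rng, promoters: pd.DataFrame) -> None:
    # global replication order over all bins (earliest timing first)
    order = []
    for chrom, t in ref.true_timing.items():
        for b, score in enumerate(t):
            order.append((score, chrom, b))
    order.sort()
    n_bins = len(order)
    if cell.phase == "G1":
        n_rep = 0
    elif cell.phase == "S":
        n_rep = int(round(cell.progress * n_bins))
    else:
        n_rep = n_bins
    replicated = {chrom: np.zeros(len(t), dtype=bool)
                  for chrom, t in ref.true_timing.items()}
    for score, chrom, b in order[:n_rep]:
        replicated[chrom][b] = True
    cell.replicated = replicated

    boost_sets = {name: target for name, target in config.tfbs_hemi_boost.items()
                  if target == cell.cell_type}

    for chrom in ref.chromosomes:
        timing = ref.true_timing[chrom]
        # one shared random field per chromosome: where the two alleles have
        # equal methylation probability their states agree, except for a
        # small allele-specific flip rate — alleles are mostly concordant
        u = rng.random(len(ref.chromosomes[chrom]))
        for allele in (1, 2):
            cp = diploid.allele_cpgs(chrom, allele)
            inactive = (chrom == "chrX" and allele == cell.xci_allele)
            p = _meth_probability(ref, diploid, config, chrom, allele,
                                  cell.cell_type, inactive, promoters)
            state = (u[cp] < p).astype(np.uint8)
            flip = rng.random(len(cp)) < config.allele_meth_diff
            state[flip] ^= 1
            top = state.copy()
            bottom = state.copy()

            bins = np.clip(_bin_of(cp, config.bin_size), 0, len(timing) - 1)
            score = timing[bins]
            p_hemi = config.hemi_base + config.hemi_slope * (score - 1.0) / 15.0
            for name in boost_sets:
                p_hemi = p_hemi + config.tfbs_hemi_boost_prob * ref.tfbs[
                    name].contains(chrom, cp)
            hemi = (state == 1) & (rng.random(len(cp)) < p_hemi)
            pick_top = rng.random(len(cp)) < 0.5
            top[hemi & pick_top] = 0
            bottom[hemi & ~pick_top] = 0

            entry = {"top": top, "bottom": bottom}
            if cell.phase in ("S", "G2"):
                if cell.phase == "S":
                    p_un = np.clip(config.s_unremeth_base
                                   + config.s_unremeth_slope * (score - 1.0) / 15.0,
                                   0, 1)
                else:
                    p_un = np.full(len(cp), config.g2_unremeth)
                lag_b = rng.random(len(cp)) < p_un
                lag_t = rng.random(len(cp)) < p_un
                daughter_bottom = np.where((top == 1) & lag_b, 0, top)
                daughter_top = np.where((bottom == 1) & lag_t, 0, bottom)
                entry["daughter_top"] = daughter_top.astype(np.uint8)
                entry["daughter_bottom"] = daughter_bottom.astype(np.uint8)
            cell.states[(chrom, allele)] = entry


# --------------------------------------------------------------------------
# read emission
# --------------------------------------------------------------------------


def _converted_strands(diploid: DiploidTruth, chrom: str, allele: int,
                       entry: dict) -> dict:
    """Bisulfite-converted template arrays per strand of each duplex."""
    arr = diploid.allele_array(chrom, allele)
    cp = diploid.allele_cpgs(chrom, allele)
    out = {}
    c_pos = np.flatnonzero(arr == _C)
    g_pos = np.flatnonzero(arr == _G)
    for key in ("top", "daughter_top"):
        if key not in entry:
            continue
        conv = arr.copy()
        conv[c_pos] = _T  # every C converts...
        keep = cp[entry[key] == 1]  # ...except methylated CpG cytosines
        conv[keep] = _C
        out[key] = conv
    for key in ("bottom", "daughter_bottom"):
        if key not in entry:
            continue
        conv = arr.copy()
        conv[g_pos] = _A
        keep = cp[entry[key] == 1] + 1
        conv[keep[keep < len(conv)]] = _G
        out[key] = conv
    return out


def emit_reads(cell: CellTruth, diploid: DiploidTruth, ref: ReferenceGenome,
               config: SimConfig, rng=None) -> list[Read]:
    """Sample directional paired reads from the cell's strand states.

    Fragment positions are weighted by local copy number (replicated bins in
    S-phase carry twice the weight).  Returns reads for the cell and, for a
    doublet, its partner's reads under the same cell id.
    """
    if rng is None:
        # per-cell stream derived from (seed, stage, cell id); stable across
        # processes and independent of call order
        rng = np.random.default_rng(np.random.SeedSequence(
            (config.seed, 4, zlib.crc32(cell.cell_id.encode()))))
    if config.depth <= 0:
        warnings.warn("zero read depth: emitting no reads")
        return []

    reads: list[Read] = []
    serial = 0
    rl = config.read_length
    for chrom, seq in ref.chromosomes.items():
        size = len(seq)
        n_bins = max(1, size // config.bin_size)
        rep = cell.replicated.get(chrom, np.zeros(n_bins, dtype=bool))
        weights = np.where(rep[:n_bins], 2.0, 1.0)
        weights = weights / weights.sum()

        n_pairs = int(round(config.depth * size / (2.0 * rl)))
        if n_pairs == 0:
            continue
        frag_bins = rng.choice(n_bins, size=n_pairs, p=weights)
        offs = rng.integers(0, config.bin_size, size=n_pairs)
        starts = np.minimum(frag_bins * config.bin_size + offs, size - 2 * rl - 1)
        extra = rng.integers(0, config.frag_extra_max, size=n_pairs)
        ends = np.minimum(starts + 2 * rl + extra, size)
        alleles = rng.integers(1, 3, size=n_pairs)
        duplex_pick = rng.random(n_pairs)
        strand_pick = rng.random(n_pairs)
        err_counts = rng.binomial(rl, config.error_rate, size=(n_pairs, 2))
        dup_draw = rng.random(n_pairs)
        sdup_draw = rng.random(n_pairs)
        lowq_draw = rng.random(n_pairs)

        conv_cache: dict[int, dict] = {}
        for allele in (1, 2):
            conv_cache[allele] = _converted_strands(
                diploid, chrom, allele, cell.states[(chrom, allele)])

        for i in range(n_pairs):
            s, e = int(starts[i]), int(ends[i])
            allele = int(alleles[i])
            conv = conv_cache[allele]
            b = int(frag_bins[i])
            has_daughter = "daughter_top" in conv and rep[min(b, len(rep) - 1)]
            if has_daughter:
                # duplex 1 = (parent top, daughter bottom); duplex 2 = mirror
                if duplex_pick[i] < 0.5:
                    top_key, bottom_key = "top", "daughter_bottom"
                else:
                    top_key, bottom_key = "daughter_top", "bottom"
            else:
                top_key, bottom_key = "top", "bottom"
            if strand_pick[i] < 0.5:
                bs, template = OT, conv[top_key]
            else:
                bs, template = OB, conv[bottom_key]

            name = f"{cell.cell_id}:{chrom}:{serial}"
            serial += 1
            pair = _make_pair(name, cell.cell_id, chrom, s, e, rl, template,
                              bs, allele, err_counts[i], rng)
            if lowq_draw[i] < config.mapq_low_fraction:
                for r in pair:
                    r.mapq = int(rng.integers(0, 40))
                    r.start = int(rng.integers(0, size - rl))
                    r.mate_start = None
            reads.extend(pair)
            if dup_draw[i] < config.dup_rate:
                for r in pair:
                    d = Read(**{**r.__dict__})
                    d.name = name + ":dup"
                    d.is_duplicate = True
                    reads.append(d)
            if sdup_draw[i] < config.strict_dup_rate:
                # re-primed molecule: same R1 start, different R2 start
                e2 = min(s + 2 * rl + int(rng.integers(0, config.frag_extra_max)),
                         size)
                if e2 != e:
                    pair2 = _make_pair(name + ":rp", cell.cell_id, chrom, s, e2,
                                       rl, template, bs, allele,
                                       rng.binomial(rl, config.error_rate, 2), rng)
                    reads.extend(pair2)

    if cell.is_doublet and cell.partner is not None:
        reads.extend(emit_reads(cell.partner, diploid, ref, config, rng))
    return reads


def _make_pair(name, cell_id, chrom, s, e, rl, template, bs, allele,
               err_counts, rng) -> list[Read]:
    out = []
    spans = [(s, s + rl, False), (e - rl, e, True)]
    for k, (a, b, is_r2) in enumerate(spans):
        frag = template[a:b].copy()
        n_err = int(err_counts[k])
        if n_err:
            pos = rng.integers(0, rl, size=n_err)
            subs = rng.integers(1, 4, size=n_err)
            frag[pos] = _BASES[(np.searchsorted(_BASES, frag[pos]) + subs) % 4]
        rev = is_r2 if bs == OT else not is_r2
        out.append(Read(
            name=name, chrom=chrom, start=a, seq=frag.tobytes().decode(),
            bs_strand=bs, cell=cell_id, is_read2=is_r2, is_reverse=rev,
            mate_start=spans[1 - k][0], true_allele=allele))
    return out


# --------------------------------------------------------------------------
# converted-genome base composition
# --------------------------------------------------------------------------


def converted_base_composition(genome) -> dict:
    """Base proportions of the in-silico bisulfite-converted genome.

    Counts dinucleotides, then converts every C to T except cytosines in CpG
    context.  ``genome`` may be a ReferenceGenome, a dict of sequences, or a
    single sequence string.
    """
    if isinstance(genome, ReferenceGenome):
        seqs = list(genome.chromosomes.values())
    elif isinstance(genome, dict):
        seqs = list(genome.values())
    else:
        seqs = [genome]
    if not seqs or all(len(s) == 0 for s in seqs):
        raise ValueError("empty genome")
    counts = {b: 0 for b in "ACGT"}
    for seq in seqs:
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        counts["A"] += int((arr == _A).sum())
        counts["G"] += int((arr == _G).sum())
        c_mask = arr == _C
        cpg_c = int((c_mask[:-1] & (arr[1:] == _G)).sum())
        counts["C"] += cpg_c
        counts["T"] += int((arr == _T).sum()) + int(c_mask.sum()) - cpg_c
    total = sum(counts.values())
    if total == 0:
        raise ValueError("genome contains no A/C/G/T bases")
    return {b: counts[b] / total for b in "ACGT"}


# --------------------------------------------------------------------------
# direct allele-resolved XCI cohort (no read simulation)
# --------------------------------------------------------------------------


@dataclass
class XCICohort:
    """Synthetic allele-resolved chrX methylation cohort with truth labels."""

    calls: pd.DataFrame  # cell, chrom, pos, allele (local label), beta, ...
    cgis: IntervalSet
    local_allele_1_global: dict  # pos -> global allele (1/2) of local label 1
    cell_xci: dict  # cell -> inactive global allele (1/2)


def simulate_xci_cohort(n_cells: int = 96, n_cgi: int = 240,
                        cpgs_per_cgi: int = 8, coverage: float = 0.3,
                        beta_noise: float = 0.05, xci_mixture: float = 0.5,
                        seed: int = 0,
                        inherit: "XCICohort | None" = None) -> XCICohort:
    """Sparse per-cell allele-resolved CpG-island β values on chrX.

    Each CGI is an independent local phase set, so the local allele labels
    1/2 are randomly permuted per CGI relative to the global alleles —
    exactly the situation the NMF-based allele inference has to untangle.
    Passing ``inherit`` reuses another cohort's local-allele labeling, as
    two passages phased against the same SNP catalog would share.
    """
    rng = np.random.default_rng(seed)
    cell_ids = [f"cell{i:03d}" for i in range(n_cells)]
    cell_xci = {c: (1 if rng.random() < xci_mixture else 2) for c in cell_ids}

    records = []
    cgi_ivs = []
    local_map = {}
    pos0 = 1000
    for g in range(n_cgi):
        start = pos0 + g * 2000
        positions = start + np.arange(cpgs_per_cgi) * 40
        cgi_ivs.append(("chrX", start - 100, int(positions[-1]) + 100))
        flip = rng.random() < 0.5  # local label 1 -> global allele
        for p in positions:
            if inherit is not None:
                local_map[int(p)] = inherit.local_allele_1_global.get(
                    int(p), 2 if flip else 1)
            else:
                local_map[int(p)] = 2 if flip else 1
        for cell in cell_ids:
            inactive = cell_xci[cell]
            for p in positions:
                for local in (1, 2):
                    if rng.random() >= coverage:
                        continue
                    glob = local_map[int(p)] if local == 1 else 3 - local_map[int(p)]
                    base = 0.92 if glob == inactive else 0.05
                    beta = float(np.clip(base + rng.normal(0, beta_noise), 0, 1))
                    records.append((cell, "chrX", int(p), "merged", local, beta))
    calls = pd.DataFrame(records, columns=["cell", "chrom", "pos", "strand",
                                           "allele", "beta"])
    calls["n_total"] = 1
    calls["n_meth"] = calls["beta"]
    return XCICohort(calls=calls, cgis=IntervalSet(cgi_ivs),
                     local_allele_1_global=local_map, cell_xci=cell_xci)


def score_xci_recovery(cohort: XCICohort, result) -> dict:
    """R² between NMF-derived and ground-truth per-locus group-mean β.

    For every (CpG, allele, cell-group) triple the mean β across cells is
    computed twice: with the truth allele map and XCI states, and with the
    NMF allele map and cell groups.  NMF labels are arbitrary up to one
    joint permutation (swapping factors flips both the cell groups and the
    allele labels), so the better of the two permutations is reported,
    together with cell-group and CpG-allele agreement rates.
    """
    calls = cohort.calls

    def labelled_means(cell_group: dict, allele_of_local1: dict):
        g = calls["cell"].map(cell_group)
        a1 = calls["pos"].map(allele_of_local1)
        flipped = a1.map({"A": "B", "B": "A"})
        a = a1.where(calls["allele"] == 1, flipped)
        df = pd.DataFrame({"pos": calls["pos"], "a": a, "g": g,
                           "beta": calls["beta"]}).dropna()
        return df.groupby(["pos", "a", "g"])["beta"].mean()

    truth_groups = {c: ("g1" if x == 1 else "g2")
                    for c, x in cohort.cell_xci.items()}
    truth_alleles = {p: ("A" if x == 1 else "B")
                     for p, x in cohort.local_allele_1_global.items()}
    t = labelled_means(truth_groups, truth_alleles)

    best = {"r2": -1.0}
    for swap in (False, True):
        groups = {c: ("g2" if (int(g) == 1) != swap else "g1")
                  for c, g in result.cell_groups.items()}
        alleles = {p: (a if not swap else ("B" if a == "A" else "A"))
                   for p, a in result.allele_of_local1.items()}
        i = labelled_means(groups, alleles)
        j = pd.concat([t.rename("t"), i.rename("i")], axis=1,
                      join="inner").dropna()
        if len(j) < 3:
            continue
        r2 = float(np.corrcoef(j["t"], j["i"])[0, 1] ** 2)
        if r2 > best["r2"]:
            group_agree = float(np.mean(
                [groups.get(c) == truth_groups.get(c) for c in groups]))
            allele_agree = float(np.mean(
                [alleles[p] == truth_alleles.get(p) for p in alleles]))
            best = {"r2": r2, "n_loci": len(j), "group_agreement": group_agree,
                    "allele_agreement": allele_agree}
    return best
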