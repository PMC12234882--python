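"""Standard-format plumbing: FASTA, SAM, VCF, BED, call tables.

Simulator truth tags ride in SAM auxiliary fields (ZA true allele, ZC
cell) that the analysis side never reads; haplotags use HP and phase sets
PS, mirroring common haplotagging conventions.  BED output is 0-based
half-open; VCF is 1-based.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd
import pysam
from pyfaidx import Fasta

from .core import OB, OT, HetSNP, Read


def write_fasta(chromosomes: dict, path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in chromosomes.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str) -> dict:
    fa = Fasta(path)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def _header(chrom_sizes: dict) -> dict:
    return {"HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": n} for c, n in chrom_sizes.items()]}


def write_sam(reads: Sequence[Read], chrom_sizes: dict, path: str) -> None:
    """Coordinate-sorted plain-text SAM with truth and haplotype tags."""
    header = _header(chrom_sizes)
    order = {c: i for i, c in enumerate(chrom_sizes)}
    with pysam.AlignmentFile(path, "w", header=pysam.AlignmentHeader.from_dict(
            header)) as out:
        for r in sorted(reads, key=lambda r: (order.get(r.chrom, 1e9),
                                              r.start, r.name)):
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.reference_id = order[r.chrom]
            a.reference_start = r.start
            a.mapping_quality = r.mapq
            a.cigarstring = f"{len(r.seq)}M"
            a.query_sequence = r.seq
            flag = 0
            if r.mate_start is not None:
                flag |= 0x1 | 0x2
                flag |= 0x80 if r.is_read2 else 0x40
                a.next_reference_id = order[r.chrom]
                a.next_reference_start = r.mate_start
            if r.is_reverse:
                flag |= 0x10
            if r.is_duplicate:
                flag |= 0x400
            a.flag = flag
            tags = [("YD", "f" if r.bs_strand == OT else "r"),
                    ("ZC", r.cell)]
            if r.true_allele is not None:
                tags.append(("ZA", int(r.true_allele)))
            if r.haplotype is not None:
                tags.append(("HP", int(r.haplotype)))
            if r.primary_phase_set is not None:
                tags.append(("PS", int(r.primary_phase_set)))
            a.set_tags(tags)
            out.write(a)


def read_sam(path: str) -> list[Read]:
    out = []
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            tags = dict(a.get_tags())
            out.append(Read(
                name=a.query_name, chrom=a.reference_name,
                start=a.reference_start, seq=a.query_sequence,
                bs_strand=OT if tags.get("YD", "f") == "f" else OB,
                cell=tags.get("ZC", ""), mapq=a.mapping_quality,
                is_duplicate=a.is_duplicate, is_read2=a.is_read2,
                is_reverse=a.is_reverse,
                mate_start=a.next_reference_start if a.is_paired else None,
                true_allele=tags.get("ZA"), haplotype=tags.get("HP"),
                primary_phase_set=tags.get("PS")))
    return out


def write_vcf(snps: Sequence[HetSNP], chrom_sizes: dict, path: str,
              sample: str = "sample") -> None:
    """Phased biallelic SNVs; GT encodes hap_of_alt, PS the phase set."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, n in chrom_sizes.items():
            fh.write(f"##contig=<ID={c},length={n}>\n")
        fh.write('##INFO=<ID=CPG,Number=1,Type=String,'
                 'Description="CpG effect of the alternate allele">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=PS,Number=1,Type=Integer,'
                 'Description="Phase set">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for s in sorted(snps, key=lambda s: (s.chrom, s.pos)):
            if s.hap_of_alt == 1:
                gt = "1|0"
            elif s.hap_of_alt == 2:
                gt = "0|1"
            else:
                gt = "0/1"
            fmt, val = ("GT:PS", f"{gt}:{s.phase_set_id}") \
                if s.phase_set_id >= 0 else ("GT", gt)
            fh.write(f"{s.chrom}\t{s.pos + 1}\t.\t{s.ref_allele}\t"
                     f"{s.alt_allele}\t.\tPASS\tCPG={s.cpg_effect}\t"
                     f"{fmt}\t{val}\n")


def read_vcf(path: str) -> list[HetSNP]:
    """Biallelic SNVs only; multiallelic records are skipped with a warning."""
    import warnings

    out = []
    with pysam.VariantFile(path) as fh:
        for rec in fh:
            if len(rec.alts or ()) != 1 or len(rec.ref) != 1 \
                    or len(rec.alts[0]) != 1:
                warnings.warn(f"skipping non-biallelic-SNV record at "
                              f"{rec.chrom}:{rec.pos}")
                continue
            hap = 0
            ps = -1
            for sample in rec.samples.values():
                gt = sample.get("GT")
                if gt in ((1, 0), (0, 1)) and sample.phased:
                    hap = 1 if gt == (1, 0) else 2
                ps = sample.get("PS", -1) if sample.get("PS") is not None else -1
                break
            try:
                effect = rec.info.get("CPG", "neutral")
            except (KeyError, ValueError):  # CPG absent from the header
                effect = "neutral"
            out.append(HetSNP(rec.chrom, rec.pos - 1, rec.ref, rec.alts[0],
                              phase_set_id=ps, hap_of_alt=hap,
                              cpg_effect=effect))
    return out


def write_bed(intervals: Iterable[tuple], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def read_bed(path: str) -> list[tuple[str, int, int]]:
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end < start:
                raise ValueError(f"{path}:{ln}: BED end < start")
            out.append((chrom, start, end))
    return out


def write_calls(calls: pd.DataFrame, path: str) -> None:
    df = calls.copy()
    if "phase_sets" in df.columns:
        df["phase_sets"] = df["phase_sets"].map(
            lambda s: ",".join(str(x) for x in sorted(s)))
    df.to_csv(path, sep="\t", index=False)


def read_calls(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "phase_sets" in df.columns:
        df["phase_sets"] = df["phase_sets"].map(
            lambda s: frozenset(int(x) for x in str(s).split(","))
            if pd.notna(s) and str(s) else frozenset())
    return df
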