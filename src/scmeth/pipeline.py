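"""Pipeline orchestration: configuration, stage ordering, provenance.

Stages run in dependency order simulate -> methcall -> qc -> arm ->
{celltype, replication, xci}; each stage writes its tables plus a
provenance JSON (config hash, seed, package version).  The configuration
file is a single YAML document with per-stage sections; every threshold
appears by name so the parameter-to-config mapping stays greppable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import warnings

import numpy as np
import pandas as pd
import yaml

from . import __version__, arm, celltype, io, methcall, qc, replication, xci
from .core import CellQC, IntervalSet
from .simulate import (SimConfig, converted_base_composition, emit_reads,
                       generate_cells, generate_diploid, generate_reference)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "outdir": "scmeth_out",
    "stages": ["simulate", "methcall", "qc", "arm", "celltype",
               "replication", "xci"],
    "simulate": {},  # SimConfig field overrides
    "methcall": {"trim5": 10, "trim3": 5, "min_mapq": 40,
                 "max_cpy_retention": 1},
    "qc": {"doublet_threshold": 0.02, "doublet_band": 0.03,
           "min_cpg_fraction": 0.20, "species": "mouse"},
    "arm": {"discover_snps": False, "trim_left": 10, "trim_right": 5,
            "max_mismatches": 7},
    "celltype": {"nmf_seed": 0, "classify_threshold": 0.65},
    "replication": {"very_early_fraction": 0.335, "s_phase_max_d": 0.03,
                    "coarse_bin_size": 1_000_000,
                    "ideal_sd_range": [0.0, float("inf")]},
    "xci": {"min_calls": 50, "margin": 0.2, "nmf_seed": 0,
            "scaled_range": [0.05, 0.85]},
}


def load_config(path: str | None = None, **overrides) -> dict:
    """Load and validate a pipeline config; unknown keys are rejected."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    user = {}
    if path:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    user.update(overrides)
    for key, val in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config key: {key}")
        if isinstance(cfg[key], dict):
            known = set(cfg[key]) | (
                {f.name for f in dataclasses.fields(SimConfig)}
                if key == "simulate" else set())
            for sub in val:
                if sub not in known:
                    raise ValueError(f"unknown config key: {key}.{sub}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _provenance(outdir: str, stage: str, cfg: dict) -> None:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    meta = {"stage": stage, "seed": cfg["seed"],
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "scmeth_version": __version__}
    with open(os.path.join(outdir, f"{stage}.provenance.json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def run_pipeline(config: dict | str | None = None, **overrides) -> dict:
    """Run the configured stages end-to-end; returns in-memory artifacts.

    ``config`` may be a dict (as from load_config), a YAML path, or None
    for defaults.  Raises an actionable error naming the stage when an
    upstream artifact is missing.
    """
    if isinstance(config, (str, os.PathLike)):
        cfg = load_config(config, **overrides)
    elif config is None:
        cfg = load_config(**overrides)
    else:
        cfg = json.loads(json.dumps(config))
        for k, v in overrides.items():
            cfg[k] = v
    outdir = cfg["outdir"]
    os.makedirs(outdir, exist_ok=True)
    stages = cfg["stages"]
    art: dict = {"config": cfg}

    def need(name: str, stage: str):
        if name not in art:
            raise RuntimeError(
                f"stage '{stage}' needs missing upstream artifact '{name}' "
                f"(did the producing stage run?)")
        return art[name]

    if "simulate" in stages:
        sim = SimConfig(seed=cfg["seed"], **cfg["simulate"])
        ref = generate_reference(sim)
        diploid = generate_diploid(ref, sim)
        cells = generate_cells(ref, diploid, sim)
        reads = {c.cell_id: emit_reads(c, diploid, ref, sim) for c in cells}
        art.update(sim=sim, ref=ref, diploid=diploid, cells=cells,
                   reads=reads)
        io.write_fasta(ref.chromosomes, os.path.join(outdir, "genome.fa"))
        io.write_vcf(diploid.snps, sim.chrom_sizes(),
                     os.path.join(outdir, "truth_snps.vcf"))
        io.write_bed(ref.cgi.intervals(), os.path.join(outdir, "cgi.bed"))
        ref.repliseq.to_csv(os.path.join(outdir, "repliseq.tsv"), sep="\t",
                            index=False)
        truth = [{"cell": c.cell_id, "type": c.cell_type, "xci": c.xci_allele,
                  "phase": c.phase, "progress": c.progress,
                  "doublet": c.is_doublet} for c in cells]
        with open(os.path.join(outdir, "cell_truth.json"), "w") as fh:
            json.dump(truth, fh, indent=1)
        comp = converted_base_composition(ref)
        with open(os.path.join(outdir, "converted_composition.json"), "w") as fh:
            json.dump(comp, fh, indent=1)
        _provenance(outdir, "simulate", cfg)

    if "methcall" in stages:
        reads = need("reads", "methcall")
        ref = need("ref", "methcall")
        mc = cfg["methcall"]
        polished = {
            cell: methcall.filter_retention_reads(
                [r for r in rs if not r.is_duplicate
                 and r.mapq >= mc["min_mapq"]],
                ref, mc["max_cpy_retention"])
            for cell, rs in reads.items()}
        all_reads = [r for rs in polished.values() for r in rs]
        calls = methcall.call_methylation(all_reads, ref, trim5=mc["trim5"],
                                          trim3=mc["trim3"],
                                          min_mapq=mc["min_mapq"])
        retention = methcall.cpy_retention(all_reads, ref)
        art.update(polished=polished, calls=calls, retention=retention)
        io.write_calls(calls, os.path.join(outdir, "calls.tsv"))
        retention.to_csv(os.path.join(outdir, "retention.tsv"), sep="\t",
                         index=False)
        _provenance(outdir, "methcall", cfg)

    if "qc" in stages:
        if "calls" not in art:
            warnings.warn("qc running without methcall output")
        calls = need("calls", "qc")
        ref = need("ref", "qc")
        reads = need("polished", "qc")
        qcs = []
        for cell in sorted(reads):
            sub = calls[calls["cell"] == cell]
            qcs.append(CellQC(
                cell_id=cell, discordance=qc.discordance(sub),
                n_cpg_covered=int(sub["pos"].nunique()),
                total_reads=len(reads[cell])))
        anomalous = qc.find_anomalous_regions(
            reads, {c: len(s) for c, s in ref.chromosomes.items()})
        art.update(cellqc=qcs, anomalous=anomalous)
        io.write_bed(anomalous, os.path.join(outdir, "anomalous.bed"))
        _provenance(outdir, "qc", cfg)

    if "arm" in stages:
        reads = need("polished", "arm")
        ref = need("ref", "arm")
        ac = cfg["arm"]
        flat = [r for rs in reads.values() for r in rs]
        if ac["discover_snps"]:
            deduped = arm.strict_deduplicate(flat)
            snps = arm.discover_variants(deduped, ref)
            phased = arm.phase_variants(deduped, snps, ref)
        else:
            # known-SNP mode: a database of phased variants (here the
            # simulator truth) provides chromosome-scale phase sets, as a
            # strain-cross SNP catalog would
            diploid = need("diploid", "arm")
            phased = list(diploid.snps)
        live = [r for rs in reads.values() for r in rs]
        tagged = arm.assign_reads(live, phased, ref,
                                  trim_left=ac["trim_left"],
                                  trim_right=ac["trim_right"],
                                  max_mismatches=ac["max_mismatches"])
        patched = arm.patch_reference(ref, phased)
        arm_calls = arm.call_arm(tagged, patched, phased)
        states = arm.two_strand_states(arm_calls)
        art.update(phased_snps=phased, tagged=tagged, arm_calls=arm_calls,
                   two_strand=states)
        io.write_vcf(phased, {c: len(s) for c, s in ref.chromosomes.items()},
                     os.path.join(outdir, "phased_snps.vcf"))
        io.write_calls(arm_calls, os.path.join(outdir, "arm_calls.tsv"))
        # fold allele-resolved discordance back into the QC table
        if "cellqc" in art:
            # strand-resolved, allele-resolved discordance: hemi-methylation
            # stays invisible (different strands are different records);
            # S-phase parent/daughter conflicts and doublets do register
            for q in art["cellqc"]:
                sub = arm_calls[arm_calls["cell"] == q.cell_id]
                q.arm_discordance = qc.discordance(sub) if len(sub) else None
            qc.flag_doublets(art["cellqc"], cfg["qc"]["doublet_threshold"])
            pd.DataFrame([dataclasses.asdict(q) for q in art["cellqc"]]).to_csv(
                os.path.join(outdir, "cellqc.tsv"), sep="\t", index=False)
        _provenance(outdir, "arm", cfg)

    if "celltype" in stages:
        calls = need("calls", "celltype")
        ref = need("ref", "celltype")
        scores = celltype.celltype_scores(calls, ref.celltype_regions)
        labels = celltype.classify_cells(
            scores, gi_col=sorted(ref.celltype_regions)[0],
            t_col=sorted(ref.celltype_regions)[-1],
            threshold=cfg["celltype"]["classify_threshold"])
        cmap = None
        try:
            cmap = celltype.nmf_cell_map(calls, seed=cfg["celltype"]["nmf_seed"])
        except ValueError as exc:
            logger.warning("NMF cell map skipped: %s", exc)
        solo = celltype.solo_wcgw_score(calls, ref.solo_wcgw)
        art.update(celltype_scores=scores, celltype_labels=labels,
                   cell_map=cmap, solo_wcgw=solo)
        scores.to_csv(os.path.join(outdir, "celltype_scores.tsv"), sep="\t")
        labels.to_csv(os.path.join(outdir, "celltype_labels.tsv"), sep="\t")
        _provenance(outdir, "celltype", cfg)

    if "replication" in stages:
        reads = need("polished", "replication")
        ref = need("ref", "replication")
        rc = cfg["replication"]
        counts = replication.bin_read_counts(
            reads, {c: len(s) for c, s in ref.chromosomes.items()},
            bin_size=ref.bin_size)
        rp = replication.rpmm_normalize(
            counts, coarse_bin_size=rc["coarse_bin_size"],
            ideal_sd_range=tuple(rc["ideal_sd_range"]))
        scores = replication.replication_scores(ref.repliseq)
        qcs = art.get("cellqc", [])
        cells_df = pd.DataFrame(
            {"cell": [q.cell_id for q in qcs],
             "arm_discordance": [q.arm_discordance for q in qcs]}) \
            if qcs else pd.DataFrame(
                {"cell": list(reads), "arm_discordance": np.nan})
        phases = replication.classify_phase(
            cells_df, rp.corrected, scores,
            ve_threshold=rc["very_early_fraction"],
            doublet_d=rc["s_phase_max_d"])
        art.update(rpmm=rp, repli_scores=scores, phases=phases)
        phases.to_csv(os.path.join(outdir, "phases.tsv"), sep="\t",
                      index=False)
        _provenance(outdir, "replication", cfg)

    if "xci" in stages:
        arm_calls = need("arm_calls", "xci")
        ref = need("ref", "xci")
        xc = cfg["xci"]
        xcalls = xci.call_xci(arm_calls, ref.cgi, min_calls=xc["min_calls"],
                              margin=xc["margin"])
        summary = None
        if len(xcalls) and (xcalls["inactive_allele"].isin([1, 2])).any():
            summary = xci.xa_xi_summary(xcalls, arm_calls,
                                        xci.build_x_features(ref))
        nmf_res = None
        try:
            nmf_res = xci.nmf_xci(arm_calls, ref.cgi, seed=xc["nmf_seed"],
                                  scaled_range=tuple(xc["scaled_range"]))
        except ValueError as exc:
            logger.warning("chrX NMF skipped: %s", exc)
        art.update(xci_calls=xcalls, xa_xi=summary, xci_nmf=nmf_res)
        xcalls.to_csv(os.path.join(outdir, "xci_calls.tsv"), sep="\t",
                      index=False)
        _provenance(outdir, "xci", cfg)

    return art


def validate_formats(paths: dict) -> dict:
    """Coordinate sanity / sortedness / dialect checks on input files.

    ``paths`` maps format name (fasta, sam, vcf, bed) to a path.  Returns a
    per-file report; malformed records raise with the offending line.
    """
    report = {}
    if "fasta" in paths:
        seqs = io.read_fasta(paths["fasta"])
        report["fasta"] = {"chromosomes": len(seqs),
                           "bases": sum(len(s) for s in seqs.values())}
    if "bed" in paths:
        ivs = io.read_bed(paths["bed"])  # raises on end < start
        report["bed"] = {"intervals": len(ivs)}
    if "sam" in paths:
        reads = io.read_sam(paths["sam"])
        by_chrom: dict[str, int] = {}
        for r in reads:
            if r.start < by_chrom.get(r.chrom, -1):
                raise ValueError(
                    f"SAM not coordinate-sorted at {r.chrom}:{r.start}")
            by_chrom[r.chrom] = r.start
        report["sam"] = {"reads": len(reads), "sorted": True}
    if "vcf" in paths:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            snps = io.read_vcf(paths["vcf"])
        report["vcf"] = {"snvs": len(snps),
                         "skipped_multiallelic": len(caught)}
    return report
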