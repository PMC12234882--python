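"""Bisulfite-aware allele resolution: dedup, deconversion, phasing, calls."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from scmeth import arm
from scmeth.arm import (SnpTable, assign_reads, call_arm, count_mismatches,
                        deconvert_read, discover_variants, patch_reference,
                        phase_variants, score_haplotag_precision,
                        strict_deduplicate, tfbs_hemimeth, two_strand_states)
from scmeth.core import OB, OT, HetSNP, IntervalSet, Read

REF = {"chr1": "ATTACGTTAATTAACGATTTTACGAATTTTTACCTAGGTA"}


def _read(seq, start=0, bs=OT, name="r", cell="c", **kw):
    return Read(name=name, chrom="chr1", start=start, seq=seq, bs_strand=bs,
                cell=cell, **kw)


class TestStrictDedup:
    def test_same_r1_start_different_r2_start_flagged(self):
        # two re-primed pairs: first-in-pair reads share a start, mates differ
        pairs = [
            _read("A" * 10, start=0, name="p1", mate_start=30),
            _read("A" * 10, start=30, name="p1", is_read2=True, mate_start=0,
                  is_reverse=True),
            _read("A" * 10, start=0, name="p2", mate_start=25),
            _read("A" * 10, start=25, name="p2", is_read2=True, mate_start=0,
                  is_reverse=True),
        ]
        out = strict_deduplicate(pairs)
        r1s = [r for r in out if r.start == 0]
        assert sum(r.is_duplicate for r in r1s) == 1
        # mates at distinct starts survive; names carry the read number
        assert all(r.mate_start is None for r in out)
        assert all(r.name.endswith(("/1", "/2")) for r in out)

    def test_unique_starts_untouched(self):
        reads = [_read("A" * 10, start=i * 20, name=f"r{i}") for i in range(4)]
        assert sum(r.is_duplicate for r in strict_deduplicate(reads)) == 0

    def test_triplicate_start_flags_two(self):
        reads = [_read("A" * 10, start=0, name=f"r{i}") for i in range(3)]
        assert sum(r.is_duplicate for r in strict_deduplicate(reads)) == 2


class TestDeconversion:
    SNP_CT = HetSNP("chr1", 4, "C", "T")    # C/T SNP at a CpG C
    SNP_AC = HetSNP("chr1", 9, "A", "C")    # A/C SNP

    def test_ct_snp_t_on_ct_strand_is_ambiguous(self):
        seq = REF["chr1"][:40].replace("C", "T")
        out = deconvert_read(_read(seq), REF, [self.SNP_CT])
        assert out[4] == "N"

    def test_ac_snp_t_supports_c(self):
        # a T at an A/C SNP on the C->T strand can only be a converted C
        seq = list(REF["chr1"][:40].replace("C", "T"))
        seq[9] = "T"
        out = deconvert_read(_read("".join(seq)), REF, [self.SNP_AC])
        assert out[9] == "C"

    def test_sequencing_error_replaced_by_reference(self):
        seq = list(REF["chr1"][:40])
        seq[20] = "G"  # non-SNP mismatch
        out = deconvert_read(_read("".join(seq)), REF, [self.SNP_AC])
        assert out[20] == REF["chr1"][20]

    def test_idempotent(self):
        seq = REF["chr1"][:40].replace("C", "T")
        once = deconvert_read(_read(seq), REF, [self.SNP_AC])
        twice = deconvert_read(_read(once), REF, [self.SNP_AC])
        assert once == twice

    def test_unknown_strand_rejected(self):
        r = _read("ATTA")
        r.bs_strand = "??"
        with pytest.raises(ValueError):
            deconvert_read(r, REF, [])

    def test_ob_strand_a_at_ga_snp_is_ambiguous(self):
        snp = HetSNP("chr1", 37, "G", "A")
        seq = REF["chr1"][:40].replace("G", "A")
        out = deconvert_read(_read(seq, bs=OB), REF, [snp])
        assert out[37] == "N"


def test_mismatch_count_excludes_conversion():
    seqs = {c: np.frombuffer(s.encode(), dtype=np.uint8)
            for c, s in REF.items()}
    fully_converted = REF["chr1"].replace("C", "T")
    assert count_mismatches(_read(fully_converted), seqs) == 0
    assert count_mismatches(_read(fully_converted, bs=OB), seqs) > 0
    two_errors = "GG" + REF["chr1"][2:]
    assert count_mismatches(_read(two_errors), seqs) == 2


class TestPhasing:
    def _fragments(self, links, n=5):
        """Reads covering SNPs at 100 and 200 with given (a1, a2) alleles."""
        snps = [HetSNP("chr1", 100, "A", "G"), HetSNP("chr1", 200, "A", "G")]
        ref = {"chr1": "A" * 300}
        reads = []
        for i, (a1, a2) in enumerate(links * n):
            seq = list("A" * 60)  # covers only the SNP at 100
            seq[100 - 80] = a1
            reads.append(_read("".join(seq), start=80, name=f"f{i}"))
            seq2 = list("A" * 60)  # covers only the SNP at 200
            seq2[200 - 160] = a2
            reads.append(_read("".join(seq2), start=160, name=f"f{i}",
                               is_read2=True))
        return reads, snps, ref

    def test_cis_pair_shares_phase_set(self):
        reads, snps, ref = self._fragments([("G", "G"), ("A", "A")])
        phased = phase_variants(reads, snps, ref)
        assert phased[0].phase_set_id == phased[1].phase_set_id
        assert phased[0].hap_of_alt == phased[1].hap_of_alt

    def test_trans_pair_shares_set_with_opposite_haps(self):
        reads, snps, ref = self._fragments([("G", "A"), ("A", "G")])
        phased = phase_variants(reads, snps, ref)
        assert phased[0].phase_set_id == phased[1].phase_set_id
        assert phased[0].hap_of_alt != phased[1].hap_of_alt

    def test_unlinked_snp_becomes_singleton_set(self):
        snps = [HetSNP("chr1", 100, "A", "G"), HetSNP("chr1", 200, "A", "G")]
        ref = {"chr1": "A" * 300}
        seq = list("A" * 50)
        seq[20] = "G"
        reads = [_read("".join(seq), start=80, name="x")] * 3
        phased = phase_variants(reads, snps, ref)
        assert phased[0].phase_set_id != phased[1].phase_set_id
        assert all(s.hap_of_alt == 1 for s in phased)

    def test_balanced_conflict_leaves_sets_apart(self):
        reads, snps, ref = self._fragments([("G", "G"), ("G", "A")], n=4)
        phased = phase_variants(reads, snps, ref)
        assert phased[0].phase_set_id != phased[1].phase_set_id


class TestAssignment:
    def test_concordant_votes_assign(self, base_reads, base_diploid,
                                     base_ref):
        tagged = [r for r in assign_reads(base_reads["cell000"][:400],
                                          base_diploid.snps, base_ref)
                  if r.haplotype is not None]
        assert tagged
        assert {r.haplotype for r in tagged} <= {1, 2}

    def test_conflicting_votes_unassigned(self):
        snps = [HetSNP("chr1", 10, "A", "G", phase_set_id=0, hap_of_alt=1),
                HetSNP("chr1", 30, "A", "G", phase_set_id=0, hap_of_alt=1)]
        ref = {"chr1": "A" * 100}
        seq = list("A" * 60)
        seq[10], seq[30] = "G", "A"  # one alt, one ref: 1-1 tie
        out = assign_reads([_read("".join(seq), start=0)], snps, ref,
                           trim_left=0, trim_right=0)
        assert out[0].haplotype is None

    def test_high_mismatch_reads_excluded(self):
        snps = [HetSNP("chr1", 10, "A", "G", phase_set_id=0, hap_of_alt=1)]
        ref = {"chr1": "A" * 100}
        seq = list("A" * 60)
        seq[10] = "G"
        for i in range(40, 48):
            seq[i] = "C"  # 8 non-conversion mismatches
        out = assign_reads([_read("".join(seq))], snps, ref)
        assert out[0].haplotype is None

    def test_error_free_full_sweep_precision_is_one(
            self, base_tagged, base_diploid):
        truth = {(s.chrom, s.pos): s.hap_of_alt for s in base_diploid.snps}
        score = score_haplotag_precision(base_tagged, base_diploid.snps,
                                         truth)
        assert score["n_assigned"] > 5000
        assert score["precision"] == 1.0


class TestDiscovery:
    def _cohort(self):
        cfg_kw = dict(autosomes={"chr1": 250_000}, chrx_size=120_000,
                      n_cells=10, depth=5.0, error_rate=0.0,
                      s_phase_fraction=0.0, g2_fraction=0.0,
                      doublet_rate=0.0, mapq_low_fraction=0.0)
        from scmeth.simulate import (SimConfig, emit_reads, generate_cells,
                                     generate_diploid, generate_reference)
        cfg = SimConfig(seed=31, **cfg_kw)
        ref = generate_reference(cfg)
        dip = generate_diploid(ref, cfg)
        cells = generate_cells(ref, dip, cfg)
        reads = [r for c in cells for r in emit_reads(c, dip, ref, cfg)]
        return ref, dip, strict_deduplicate(reads)

    def test_planted_het_snps_recovered(self):
        ref, dip, reads = self._cohort()
        found = discover_variants(reads, ref)
        truth = {(s.chrom, s.pos, s.ref_allele, s.alt_allele)
                 for s in dip.snps}
        hits = sum(1 for s in found
                   if (s.chrom, s.pos, s.ref_allele, s.alt_allele) in truth)
        assert hits / max(1, len(found)) > 0.95   # precision
        assert hits / len(dip.snps) > 0.5         # recall at 5x depth

    def test_af_window_rejects_rare_variants(self):
        ref = {"chr1": "A" * 1000}
        reads = []
        for cell in range(10):
            for i in range(20):
                seq = list("A" * 100)
                if cell < 1 and i < 2:
                    seq[50] = "G"  # AF 0.01: somatic-like
                reads.append(_read("".join(seq), start=0,
                                   name=f"c{cell}r{i}", cell=f"c{cell}"))
        found = discover_variants(reads, ref)
        assert found == []

    def test_low_mapq_bins_rejected(self):
        ref = {"chr1": "A" * 1000}
        reads = []
        for cell in range(10):
            for i in range(10):
                seq = list("A" * 100)
                seq[50] = "G" if i % 2 else "A"   # AF 0.5 het
                reads.append(_read("".join(seq), start=0, mapq=60,
                                   name=f"c{cell}r{i}", cell=f"c{cell}"))
        assert len(discover_variants(reads, ref)) == 1
        # same pile but the bin's mean MAPQ drops to 40 < 45
        low = [dataclasses.replace(r, mapq=40) for r in reads]
        assert discover_variants(low, ref) == []


class TestPatchReference:
    def test_cpg_creating_alt_applied(self):
        snps = [HetSNP("chr1", 3, "A", "C", cpg_effect="creates")]
        ref = {"chr1": "ATTAGTTA"}
        out = patch_reference(ref, snps)
        assert out["chr1"] == "ATTCGTTA"

    def test_neutral_snp_leaves_reference(self):
        snps = [HetSNP("chr1", 3, "A", "T", cpg_effect="neutral")]
        assert patch_reference({"chr1": "ATTAGTTA"}, snps)["chr1"] == \
            "ATTAGTTA"

    def test_patched_cpg_count_monotone(self, base_ref, base_diploid):
        from scmeth.core import cpg_positions
        patched = patch_reference(base_ref, base_diploid.snps)
        for chrom, seq in base_ref.chromosomes.items():
            assert len(cpg_positions(patched[chrom])) >= \
                len(cpg_positions(seq))

    def test_conflicting_snps_rejected(self):
        snps = [HetSNP("chr1", 3, "A", "C", cpg_effect="creates"),
                HetSNP("chr1", 3, "A", "G", cpg_effect="creates")]
        with pytest.raises(ValueError, match="conflicting"):
            patch_reference({"chr1": "ATTAGTTA"}, snps)


class TestArmCalls:
    def _setup(self):
        # ref: CpG at 4; SNP at 4 (C/T) destroys it on hap 1 (alt T)
        ref = {"chr1": "ATTACGTTAATTAACGATTTTACGAATTTTTACCTAGGTA"}
        snps = [HetSNP("chr1", 4, "C", "T", phase_set_id=0, hap_of_alt=1,
                       cpg_effect="destroys")]
        return ref, snps

    def test_call_on_allele_without_cpg_discarded(self):
        ref, snps = self._setup()
        seq = ref["chr1"].replace("C", "T")
        r1 = _read(seq, name="a", haplotype=1, phase_sets=(0,))
        r2 = _read(seq, name="b", haplotype=2, phase_sets=(0,))
        calls = call_arm([r1, r2], ref, snps, trim5=0, trim3=0)
        at4 = calls[calls["pos"] == 4]
        assert set(at4["allele"]) == {2}   # hap 1 (alt T) lacks the CpG

    def test_multi_phase_set_calls_discarded(self):
        ref, snps = self._setup()
        seq = ref["chr1"].replace("C", "T")
        r = _read(seq, name="a", haplotype=1, phase_sets=(0, 1))
        calls = call_arm([r], ref, snps, trim5=0, trim3=0)
        assert len(calls) == 0

    def test_double_snp_cpg_discarded(self):
        ref, _ = self._setup()
        snps = [HetSNP("chr1", 14, "C", "A", phase_set_id=0, hap_of_alt=1,
                       cpg_effect="destroys"),
                HetSNP("chr1", 15, "G", "A", phase_set_id=0, hap_of_alt=1,
                       cpg_effect="destroys")]
        seq = ref["chr1"].replace("C", "T")
        r = _read(seq, name="a", haplotype=2, phase_sets=(0,))
        calls = call_arm([r], ref, snps, trim5=0, trim3=0)
        assert 14 not in set(calls["pos"])

    def test_ordinary_cpg_kept_with_allele(self):
        ref, snps = self._setup()
        seq = ref["chr1"].replace("C", "T")
        r = _read(seq, name="a", haplotype=2, phase_sets=(0,))
        calls = call_arm([r], ref, snps, trim5=0, trim3=0)
        assert 22 in set(calls["pos"])
        assert (calls["allele"] == 2).all()

    def test_arm_beta_matches_truth(self, base_arm_calls, base_cells,
                                    base_diploid):
        """Error-free ARM beta equals the planted per-allele strand truth
        at every kept locus."""
        cell = base_cells[0]
        sub = base_arm_calls[(base_arm_calls["cell"] == cell.cell_id)
                             & (base_arm_calls["chrom"] == "chr1")
                             & (base_arm_calls["strand"] == "top")]
        checked = 0
        for allele in (1, 2):
            cp = base_diploid.allele_cpgs("chr1", allele)
            st = dict(zip(cp.tolist(),
                          cell.states[("chr1", allele)]["top"].tolist()))
            for row in sub[sub["allele"] == allele].itertuples():
                if row.pos in st:
                    assert row.beta == float(st[row.pos])
                    checked += 1
        assert checked > 500


class TestTwoStrandStates:
    def _calls(self, rows):
        df = pd.DataFrame(rows, columns=["cell", "chrom", "pos", "strand",
                                         "allele", "n_meth", "n_total"])
        df["beta"] = df["n_meth"] / df["n_total"]
        return df

    def test_classification(self):
        calls = self._calls([
            ("c", "chr1", 10, "top", 1, 1, 1),
            ("c", "chr1", 10, "bottom", 1, 0, 1),    # hemi
            ("c", "chr1", 20, "top", 1, 1, 1),
            ("c", "chr1", 20, "bottom", 1, 1, 1),    # sym_meth
            ("c", "chr1", 30, "top", 1, 0, 2),
            ("c", "chr1", 30, "bottom", 1, 0, 1),    # sym_unmeth
            ("c", "chr1", 40, "top", 1, 1, 2),       # intra-strand conflict
            ("c", "chr1", 40, "bottom", 1, 1, 1),
            ("c", "chr1", 50, "top", 1, 1, 1),       # single strand: skipped
        ])
        states = two_strand_states(calls)
        by_pos = states.set_index("pos")["state"]
        assert by_pos.loc[10] == "hemi"
        assert by_pos.loc[20] == "sym_meth"
        assert by_pos.loc[30] == "sym_unmeth"
        assert 40 not in by_pos.index and 50 not in by_pos.index

    def test_state_conservation(self, base_states):
        counts = base_states["state"].value_counts()
        assert counts.sum() == len(base_states)
        assert set(counts.index) <= {"sym_meth", "hemi", "sym_unmeth"}
        assert counts.get("hemi", 0) > 0


class TestTfbsHemimeth:
    def _states(self, n_in_set, n_out, state, cell="c"):
        rows = [(cell, "chr1", 100 + i, 1, state) for i in range(n_in_set)]
        rows += [(cell, "chr1", 10_000 + i, 1, state) for i in range(n_out)]
        return pd.DataFrame(rows, columns=["cell", "chrom", "pos", "allele",
                                           "state"])

    def test_sparse_sets_dropped(self):
        states = pd.concat([self._states(200, 300, "hemi"),
                            self._states(300, 300, "sym_meth")])
        tf = {"TF_low": IntervalSet([("chr1", 100, 400)])}
        out = tfbs_hemimeth(states, tf, {"c": "g"}, min_events=250)
        assert len(out) == 0   # 200 hemi events <= 250

    def test_fractions_reported_above_threshold(self):
        states = pd.concat([self._states(300, 300, "hemi"),
                            self._states(300, 300, "sym_meth")])
        tf = {"TF": IntervalSet([("chr1", 100, 400)])}
        out = tfbs_hemimeth(states, tf, {"c": "g"}, min_events=250)
        assert len(out) == 1
        assert out.iloc[0]["hemi_fraction"] == pytest.approx(0.5)

    def test_planted_enrichment_recovered(self, base_states, base_ref,
                                          base_cells, base_cfg):
        """The TFBS set planted hemi-rich in one cell type shows a higher
        hemi share than methylation share in that type's cells."""
        groups = {c.cell_id: c.cell_type for c in base_cells}
        boosted_set, boosted_type = next(iter(
            base_cfg.tfbs_hemi_boost.items()))
        out = tfbs_hemimeth(base_states, base_ref.tfbs, groups,
                            min_events=10)
        row = out[(out["group"] == boosted_type)
                  & (out["tfbs_set"] == boosted_set)]
        others = out[(out["group"] == boosted_type)
                     & (out["tfbs_set"] != boosted_set)]
        assert len(row) == 1
        ratio = row.iloc[0]["hemi_fraction"] / row.iloc[0]["meth_fraction"]
        other_ratios = others["hemi_fraction"] / others["meth_fraction"]
        assert ratio > other_ratios.max()
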