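"""RPMM normalization, timing scores, phase calls, ploidy, CNV clusters."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from scmeth import replication
from scmeth.replication import (bin_read_counts, classify_phase, cnv_cluster,
                                estimate_ploidy, replication_meth_profile,
                                replication_scores, rpmm_normalize,
                                timing_state_distribution,
                                very_early_fraction)


def _counts(n_cells=10, n_bins=40, seed=0, bias=None, mean=200.0):
    rng = np.random.default_rng(seed)
    cols = pd.MultiIndex.from_tuples([("chr1", i * 50_000)
                                      for i in range(n_bins)],
                                     names=["chrom", "bin_start"])
    X = rng.poisson(mean, size=(n_cells, n_bins)).astype(float)
    if bias is not None:
        X[:, bias[0]] *= bias[1]
    return pd.DataFrame(X, index=[f"c{i}" for i in range(n_cells)],
                        columns=cols)


class TestRPMM:
    def test_rpmm_conservation(self):
        counts = _counts()
        res = rpmm_normalize(counts, coarse_bin_size=500_000,
                             ideal_sd_range=(0, np.inf), coarse_sd_max=np.inf)
        kept = counts[res.rpmm.columns]
        expected = kept.sum(axis=1) * 1e6 / counts.sum(axis=1)
        assert np.allclose(res.rpmm.sum(axis=1), expected)

    def test_planted_bias_removed(self):
        """A 2x mappability-like bias shared by all cells vanishes after the
        per-bin median correction (percentile exclusion disabled so the
        correction itself is exercised)."""
        counts = _counts(bias=(5, 2.0))
        res = rpmm_normalize(counts, coarse_bin_size=500_000,
                             ideal_sd_range=(0, np.inf), coarse_sd_max=np.inf,
                             extreme_cell_fraction=1.01)
        corrected = res.corrected
        biased = corrected[("chr1", 5 * 50_000)]
        others = corrected.drop(columns=[("chr1", 5 * 50_000)])
        ratio = biased.mean() / others.mean(axis=1).mean()
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_bins_with_missing_data_excluded(self):
        counts = _counts()
        counts.iloc[:3, 7] = np.nan  # 30% missing in bin 7
        res = rpmm_normalize(counts, coarse_bin_size=500_000,
                             ideal_sd_range=(0, np.inf), coarse_sd_max=np.inf)
        assert ("chr1", 7 * 50_000) in res.excluded_bins

    def test_no_ideal_cells_falls_back_with_warning(self, caplog):
        counts = _counts()
        with caplog.at_level("WARNING"):
            res = rpmm_normalize(counts, ideal_sd_range=(0.0, 1e-9))
        assert res.ideal_cells == []
        assert "no ideal cells" in caplog.text


class TestReplicationScores:
    def _repli(self, rows):
        df = pd.DataFrame(rows, columns=[f"s{i}" for i in range(1, 17)])
        df.insert(0, "bin_start", [i * 50_000 for i in range(len(df))])
        df.insert(0, "chrom", "chr1")
        return df

    def test_weighted_top3_hand_case(self):
        # top-3 fractions at indices 3,4,5 with scores 2,3,1:
        # round(23/6) = 4 -> very_early
        row = [0.0] * 16
        row[2], row[3], row[4] = 2.0, 3.0, 1.0
        out = replication_scores(self._repli([row]))
        assert out.iloc[0]["score"] == 4
        assert out.iloc[0]["group"] == "very_early"

    @pytest.mark.parametrize("idx,expected_excluded", [
        (0, True), (14, True), (15, True), (7, False)])
    def test_extreme_scores_excluded(self, idx, expected_excluded):
        row = [0.0] * 16
        row[idx] = 5.0
        out = replication_scores(self._repli([row]))
        assert (len(out) == 0) is expected_excluded
        if not expected_excluded:
            assert out.iloc[0]["score"] == idx + 1
            assert out.iloc[0]["group"] == "early"

    def test_all_zero_bin_excluded(self):
        out = replication_scores(self._repli([[0.0] * 16]))
        assert len(out) == 0


class TestClassifyPhase:
    SCORES = pd.DataFrame({
        "chrom": ["chr1"] * 4,
        "bin_start": [0, 50_000, 100_000, 150_000],
        "score": [3, 6, 10, 13],
        "group": ["very_early", "early", "late", "very_late"]})

    def _corrected(self, ve_frac):
        cols = pd.MultiIndex.from_tuples(
            [("chr1", b) for b in self.SCORES["bin_start"]],
            names=["chrom", "bin_start"])
        rest = (1 - ve_frac) / 3
        return pd.DataFrame([[ve_frac, rest, rest, rest]], index=["c"],
                            columns=cols)

    @pytest.mark.parametrize("ve,d,expected", [
        (0.40, 0.01, "S"),
        (0.25, 0.005, "G1"),
        (0.40, 0.05, "doublet"),
    ])
    def test_threshold_quadrants(self, ve, d, expected):
        cells = pd.DataFrame({"cell": ["c"], "arm_discordance": [d]})
        out = classify_phase(cells, self._corrected(ve), self.SCORES)
        assert out.iloc[0]["phase"] == expected

    def test_very_early_fraction_ignores_excluded_bins(self):
        corrected = self._corrected(0.25)
        scores = self.SCORES.iloc[:3]  # the very_late bin drops out
        f = very_early_fraction(corrected.loc["c"], scores)
        assert f == pytest.approx(0.25 / 0.75)



class TestSimulatedCohort:
    def test_s_phase_sensitivity_and_specificity(self, s_phase_cohort):
        truth = {c.cell_id: c.phase for c in s_phase_cohort["cells"]}
        called = s_phase_cohort["phases"].set_index("cell")["phase"]
        tp = sum(1 for c, p in truth.items() if p == "S" and called[c] == "S")
        fn = sum(1 for c, p in truth.items() if p == "S" and called[c] != "S")
        fp = sum(1 for c, p in truth.items() if p != "S" and called[c] == "S")
        tn = sum(1 for c, p in truth.items() if p != "S" and called[c] != "S")
        assert tp / max(1, tp + fn) >= 0.9, (truth, called.to_dict())
        assert tn / max(1, tn + fp) >= 0.9

    def test_g1_ploidy_recovery(self, s_phase_cohort):
        """At least 95% of a G1 cell's bins estimate within 0.5 of 2n."""
        truth = {c.cell_id: c.phase for c in s_phase_cohort["cells"]}
        rp = s_phase_cohort["rp"]
        done = 0
        for cell, phase in truth.items():
            if phase != "G1":
                continue
            ploidy = estimate_ploidy(rp.corrected.loc[cell])
            ok = np.abs(ploidy.dropna() - 2.0) < 0.5
            assert ok.mean() >= 0.95
            done += 1
        assert done >= 3

    def test_s_cell_replicated_bins_near_4n(self, s_phase_cohort):
        cells = {c.cell_id: c for c in s_phase_cohort["cells"]}
        rp = s_phase_cohort["rp"]
        checked = 0
        for cell_id, cell in cells.items():
            if cell.phase != "S" or not (0.35 < cell.progress < 0.65):
                continue
            ploidy = estimate_ploidy(rp.corrected.loc[cell_id])
            rep_vals, unrep_vals = [], []
            for (chrom, b), v in ploidy.dropna().items():
                rep = cell.replicated[chrom][b // 50_000]
                (rep_vals if rep else unrep_vals).append(v)
            if len(rep_vals) > 5 and len(unrep_vals) > 5:
                assert abs(np.median(rep_vals) - 4) < 0.75
                assert abs(np.median(unrep_vals) - 2) < 0.75
                checked += 1
        assert checked >= 1

    def test_s_cell_partial_methylation_enriched_in_4n(self, s_phase_cohort):
        """Newly replicated (4n) bins carry more intermediate methylation
        than unreplicated (2n) bins in the same cell."""
        from scmeth.methcall import merge_cg_calls
        cells = {c.cell_id: c for c in s_phase_cohort["cells"]}
        rp = s_phase_cohort["rp"]
        arm_calls = s_phase_cohort["arm_calls"]
        checked = 0
        for cell_id, cell in cells.items():
            if cell.phase != "S" or not (0.3 < cell.progress < 0.7):
                continue
            calls = merge_cg_calls(
                arm_calls[arm_calls["cell"] == cell_id])
            ploidy = estimate_ploidy(rp.corrected.loc[cell_id])
            prof = replication_meth_profile(calls, ploidy,
                                            rp.rpmm.loc[cell_id],
                                            min_measurements=10)
            by_p = prof.set_index("ploidy")
            if {2, 4}.issubset(by_p.index):
                assert by_p.loc[4, "partial_frac"] > by_p.loc[2, "partial_frac"]
                checked += 1
        assert checked >= 1


class TestPloidy:
    def test_g2_flag_forces_tetraploid_branch(self):
        rng = np.random.default_rng(0)
        cols = pd.MultiIndex.from_tuples([("chr1", i * 50_000)
                                          for i in range(60)])
        row = pd.Series(rng.normal(1.0, 0.05, 60), index=cols)
        assert estimate_ploidy(row).median() == pytest.approx(2.0, abs=0.2)
        assert estimate_ploidy(row, g2=True).median() == \
            pytest.approx(4.0, abs=0.4)

    def test_degenerate_density_rejected(self):
        row = pd.Series([1.0] * 10)
        with pytest.raises(ValueError):
            estimate_ploidy(row)


class TestMethProfile:
    def _calls(self, n, beta, bin_start=0):
        return pd.DataFrame({
            "cell": "c", "chrom": "chr1",
            "pos": np.arange(bin_start + 10, bin_start + 10 + n * 30, 30),
            "beta": beta, "n_total": 2, "n_meth": [int(2 * b) for b in
                                                   [beta] * n]})

    def test_sparse_bins_dropped(self):
        ploidy = pd.Series({("chr1", 0): 2.0})
        rpmm = pd.Series({("chr1", 0): 10.0})
        prof = replication_meth_profile(self._calls(10, 1.0), ploidy, rpmm,
                                        min_measurements=15)
        assert len(prof) == 0
        prof = replication_meth_profile(self._calls(20, 1.0), ploidy, rpmm,
                                        min_measurements=15)
        assert prof.iloc[0]["m_frac"] == 1.0


class TestTimingStates:
    def test_hemi_fraction_monotone_when_planted(self, base_states,
                                                 base_ref):
        scores = replication_scores(base_ref.repliseq)
        dist = timing_state_distribution(base_states, scores)
        lo = dist[dist["score"] <= 6]["hemi"].mean()
        hi = dist[dist["score"] >= 11]["hemi"].mean()
        assert hi > lo

    def test_zero_hemi_simulation_gives_zero(self):
        states = pd.DataFrame({
            "cell": ["c"] * 4, "chrom": ["chr1"] * 4,
            "pos": [10, 60_000, 110_000, 160_000], "allele": [1] * 4,
            "state": ["sym_meth", "sym_unmeth", "sym_meth", "sym_unmeth"]})
        scores = pd.DataFrame({
            "chrom": ["chr1"] * 4,
            "bin_start": [0, 50_000, 100_000, 150_000],
            "score": [3, 6, 10, 13],
            "group": ["very_early", "early", "late", "very_late"]})
        dist = timing_state_distribution(states, scores)
        assert (dist["hemi"] == 0).all()


class TestCNVCluster:
    def _matrix(self, n_normal=14, n_del=6, seed=0):
        rng = np.random.default_rng(seed)
        cols = pd.MultiIndex.from_tuples(
            [(c, i * 50_000) for c in ("chr1", "chr8") for i in range(40)],
            names=["chrom", "bin_start"])
        X = rng.normal(1.0, 0.05, size=(n_normal + n_del, 80))
        X[n_normal:, 40:] *= 0.5   # chr8 deletion subclone
        return pd.DataFrame(X, index=[f"c{i}" for i in range(n_normal + n_del)],
                            columns=cols)

    def test_planted_deletion_subclone_recovered(self):
        mat = self._matrix()
        res = cnv_cluster(mat, k=2, coarse_bin_size=500_000)
        labels = res["labels"]
        assert labels.iloc[:14].nunique() == 1
        assert labels.iloc[14:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]

    def test_homogeneous_population_lacks_cluster_structure(self):
        """A diploid population without subclones shows no separation in
        the dendrogram: the final merge height is comparable to earlier
        merges, unlike the planted-deletion case."""
        rng = np.random.default_rng(1)
        cols = pd.MultiIndex.from_tuples([("chr1", i * 50_000)
                                          for i in range(40)])
        X = rng.normal(1.0, 0.05, size=(12, 40))
        mat = pd.DataFrame(X, index=[f"c{i}" for i in range(12)],
                           columns=cols)
        flat = cnv_cluster(mat, k=2, coarse_bin_size=500_000)["linkage"]
        deleted = cnv_cluster(self._matrix(), k=2,
                              coarse_bin_size=500_000)["linkage"]
        ratio_flat = flat[-1, 2] / flat[-2, 2]
        ratio_del = deleted[-1, 2] / deleted[-2, 2]
        assert ratio_del > 3 * ratio_flat

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            cnv_cluster(self._matrix(n_normal=1, n_del=1), k=2)
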