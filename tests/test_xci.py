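"""X-inactivation: direct calls, Xa/Xi summaries, SNP-free NMF inference."""

import numpy as np
import pandas as pd
import pytest

from scmeth import xci
from scmeth.core import IntervalSet
from scmeth.simulate import simulate_xci_cohort, score_xci_recovery
from scmeth.xci import (build_x_features, call_xci, cgi_matrix,
                        differential_cgi, metagene_profile, nmf_xci,
                        transfer_alleles, xa_xi_summary, xci_variability)


def _arm_calls(records):
    df = pd.DataFrame(records, columns=["cell", "pos", "allele", "beta"])
    df["chrom"] = "chrX"
    df["strand"] = "merged"
    df["n_total"] = 1
    df["n_meth"] = df["beta"]
    return df


CGIS = IntervalSet([("chrX", 0, 10_000)])


class TestCallXCI:
    def _cohort(self, n=60, m1=0.05, m2=0.62):
        rec = []
        for i in range(n):
            rec.append(("c", 10 * i, 1, m1))
            rec.append(("c", 10 * i, 2, m2))
        return _arm_calls(rec)

    def test_higher_cgi_mean_is_inactive(self):
        out = call_xci(self._cohort(), CGIS)
        assert out.iloc[0]["inactive_allele"] == 2
        assert out.iloc[0]["mean1"] == pytest.approx(0.05)

    def test_cells_below_min_calls_removed(self):
        out = call_xci(self._cohort(n=30), CGIS, min_calls=50)
        assert len(out) == 0

    def test_opposite_doublet_is_ambiguous(self):
        # both alleles intermediate: a pair of cells with opposite states
        out = call_xci(self._cohort(m1=0.45, m2=0.50), CGIS)
        assert out.iloc[0]["inactive_allele"] == "ambiguous"

    def test_simulated_cells_recover_truth(self, base_arm_calls, base_cells,
                                           base_ref):
        out = call_xci(base_arm_calls, base_ref.cgi).set_index("cell")
        truth = {c.cell_id: c.xci_allele for c in base_cells}
        called = 0
        for cell, row in out.iterrows():
            if row["inactive_allele"] in (1, 2):
                assert row["inactive_allele"] == truth[cell]
                called += 1
        assert called >= len(out) * 0.9 and called > 3


class TestXaXiSummary:
    def test_planted_xi_methylated_cgi(self):
        rec = []
        for i in range(10):
            cell = f"c{i}"
            for p in range(0, 2000, 20):
                rec.append((cell, p, 1, 0.05))
                rec.append((cell, p, 2, 0.9))
        calls = _arm_calls(rec)
        xcalls = call_xci(calls, CGIS)
        out = xa_xi_summary(xcalls, calls, {"cgi": CGIS})
        assert out.iloc[0]["xa_mean"] == pytest.approx(0.05, abs=0.01)
        assert out.iloc[0]["xi_mean"] == pytest.approx(0.9, abs=0.01)

    def test_sparse_features_dropped(self):
        rec = [(f"c{i}", p, a, 0.9 if a == 2 else 0.05)
               for i in range(3) for p in range(0, 1200, 20) for a in (1, 2)]
        calls = _arm_calls(rec)
        xcalls = call_xci(calls, CGIS)
        assert len(xcalls) == 3
        sparse = IntervalSet([("chrX", 0, 100)])  # 3 cells x 5 pos x 2 < 100
        out = xa_xi_summary(xcalls, calls, {"sparse": sparse})
        assert len(out) == 0

    def test_no_confident_cells_rejected(self):
        calls = _arm_calls([("c", 10, 1, 0.5), ("c", 10, 2, 0.5)])
        xcalls = pd.DataFrame({"cell": ["c"], "inactive_allele":
                               ["ambiguous"]})
        with pytest.raises(ValueError):
            xa_xi_summary(xcalls, calls, {"cgi": CGIS})


class TestMetagene:
    GENES = pd.DataFrame({
        "chrom": ["chrX"], "start": [20_000], "end": [30_000],
        "strand": ["+"], "name": ["gX"], "specific_type": [""]})

    def _calls(self, xi_promoter=0.9, xa_body=0.85, xi_body=0.7):
        rec = []
        for i in range(12):
            cell = f"c{i}"
            for p in range(0, 2000, 20):     # CGI: orient the XCI call
                rec.append((cell, p, 1, 0.05))
                rec.append((cell, p, 2, 0.9))
            for p in range(18_500, 20_200, 25):   # promoter
                rec.append((cell, p, 1, 0.05))
                rec.append((cell, p, 2, xi_promoter))
            for p in range(20_200, 30_000, 40):   # gene body
                rec.append((cell, p, 1, xa_body))
                rec.append((cell, p, 2, xi_body))
        return _arm_calls(rec)

    def test_no_qualifying_genes_is_empty(self):
        calls = self._calls(xi_promoter=0.1)  # Xi promoter unmethylated
        xcalls = call_xci(calls, CGIS)
        out = metagene_profile(self.GENES, calls, xcalls)
        assert len(out) == 0

    def test_xi_exceeds_xa_at_tss_and_xa_higher_in_body(self):
        calls = self._calls()
        xcalls = call_xci(calls, CGIS)
        out = metagene_profile(self.GENES, calls, xcalls)
        assert len(out) > 0
        up = out[out["region"] == "upstream"]
        body = out[out["region"] == "body"]
        assert np.nanmean(up["xi"]) > np.nanmean(up["xa"])
        assert np.nanmean(body["xa"]) > np.nanmean(body["xi"])


@pytest.fixture(scope="module")
def xci_cohort():
    cohort = simulate_xci_cohort(n_cells=80, n_cgi=200, coverage=0.3, seed=3)
    result = nmf_xci(cohort.calls, cohort.cgis, seed=3)
    return cohort, result


class TestNMFXCI:
    def test_groups_and_alleles_recover_truth(self, xci_cohort):
        cohort, result = xci_cohort
        score = score_xci_recovery(cohort, result)
        assert score["group_agreement"] == 1.0
        assert score["allele_agreement"] >= 0.99
        assert score["r2"] >= 0.99

    def test_far_from_cgi_features_excluded(self, xci_cohort):
        cohort, result = xci_cohort
        dist = cohort.cgis.nearest_distance(
            "chrX", result.feature_table["pos"].to_numpy())
        assert (dist <= 500).all()

    def test_scaled_loadings_within_band_in_some_factor(self, xci_cohort):
        _, result = xci_cohort
        ft = result.feature_table
        in_band = (ft["s0"].between(0.05, 0.85) | ft["s1"].between(0.05, 0.85))
        assert in_band.all()

    def test_label_symmetry(self, xci_cohort):
        """Factor labels are arbitrary: a different NMF seed may swap them,
        but the recovery score is permutation-invariant."""
        cohort, result = xci_cohort
        alt = nmf_xci(cohort.calls, cohort.cgis, seed=11)
        s1 = score_xci_recovery(cohort, result)
        s2 = score_xci_recovery(cohort, alt)
        assert abs(s1["r2"] - s2["r2"]) < 0.02

    def test_too_few_features_rejected(self):
        tiny = simulate_xci_cohort(n_cells=6, n_cgi=2, coverage=0.5, seed=0)
        with pytest.raises(ValueError):
            nmf_xci(tiny.calls, tiny.cgis, seed=0, min_features=1000)


class TestTransfer:
    def test_transfer_preserves_balanced_allele_counts(self, xci_cohort):
        cohort, result = xci_cohort
        out = transfer_alleles(result.allele_of_local1, cohort.calls)
        per_allele = out.groupby("nmf_allele")["n_calls"].sum()
        ratio = per_allele.min() / per_allele.max()
        assert ratio > 0.8  # both alleles present at similar copy number

    def test_planted_drift_all_cells_methylated_on_one_allele(self,
                                                              xci_cohort):
        """A later-passage population fixed for one XCI state shows high
        mean beta on a single NMF allele in every cell."""
        cohort, result = xci_cohort
        drift = simulate_xci_cohort(n_cells=20, n_cgi=200, coverage=0.3,
                                    xci_mixture=1.0, seed=9, inherit=cohort)
        out = transfer_alleles(result.allele_of_local1, drift.calls)
        piv = out.pivot(index="cell", columns="nmf_allele",
                        values="mean_beta")
        hi = piv.max(axis=1)
        lo = piv.min(axis=1)
        assert (hi > 0.7).all() and (lo < 0.3).all()
        # and it is the same allele in every cell
        assert piv.idxmax(axis=1).nunique() == 1

    def test_unmapped_cpgs_stay_unassigned(self):
        calls = _arm_calls([("c", 999_999, 1, 0.5)])
        out = transfer_alleles({}, calls)
        assert len(out) == 0


class TestDifferentialCGI:
    def _matrix(self, delta=0.5, seed=0):
        rng = np.random.default_rng(seed)
        cells = [f"c{i}" for i in range(60)]
        data = {}
        data["cgi_diff"] = np.concatenate([
            rng.normal(0.2 + delta, 0.05, 20), rng.normal(0.2, 0.05, 40)])
        data["cgi_small"] = np.concatenate([
            rng.normal(0.30, 0.03, 20), rng.normal(0.20, 0.03, 40)])
        data["cgi_flat"] = rng.normal(0.5, 0.02, 60)
        mat = pd.DataFrame(data, index=cells).clip(0, 1)
        clusters = pd.Series(["a"] * 20 + ["b"] * 40, index=cells)
        return mat, clusters

    def test_planted_difference_called(self):
        mat, clusters = self._matrix()
        out = differential_cgi(mat, clusters)
        assert "cgi_diff" in out["differential"]

    def test_small_delta_not_differential(self):
        # delta 0.10 < 0.15 floor regardless of p-value
        mat, clusters = self._matrix()
        out = differential_cgi(mat, clusters)
        assert "cgi_small" not in out["differential"]

    def test_high_missingness_not_variable(self):
        mat, clusters = self._matrix()
        mat.loc[mat.index[:20], "cgi_diff"] = np.nan  # 33% missing
        out = differential_cgi(mat, clusters)
        assert "cgi_diff" not in out["variable"]

    def test_cgi_matrix_coverage_filter(self, base_arm_calls, base_ref):
        mat = cgi_matrix(base_arm_calls[base_arm_calls["chrom"] == "chrX"],
                         base_ref.cgi, ref=base_ref)
        assert mat.notna().sum().sum() > 0


class TestVariability:
    def test_mixed_xci_population_has_high_chrx_sd(self):
        rng = np.random.default_rng(0)
        rec = []
        for i in range(30):
            state = i % 2  # 50/50 XCI mixture
            for f in range(10):
                beta_x = 0.9 if state else 0.05
                rec.append((f"c{i}", f"chrX_cgi{f}", 1,
                            float(np.clip(beta_x + rng.normal(0, 0.03), 0, 1))))
                rec.append((f"c{i}", f"auto_cgi{f}", 1,
                            float(np.clip(0.1 + rng.normal(0, 0.03), 0, 1))))
        df = pd.DataFrame(rec, columns=["cell", "feature", "allele", "beta"])
        out = xci_variability(df)
        x_sd = out[out["feature"].str.startswith("chrX")]["sd"].mean()
        a_sd = out[out["feature"].str.startswith("auto")]["sd"].mean()
        assert x_sd > 5 * a_sd

    def test_single_cell_sd_missing(self):
        df = pd.DataFrame([("c1", "f", 1, 0.5)],
                          columns=["cell", "feature", "allele", "beta"])
        out = xci_variability(df)
        assert np.isnan(out.iloc[0]["sd"])


def test_build_x_features_partitions_cgis(base_ref):
    feats = build_x_features(base_ref)
    n_prom = len(feats["cgi_promoters"])
    n_nonprom = len(feats["nonpromoter_cgis"])
    n_x_cgis = sum(1 for _ in base_ref.cgi.intervals("chrX"))
    assert n_prom + n_nonprom == n_x_cgis
    assert len(feats["cgi_shores"]) == n_x_cgis
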