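"""Tumor-cohort validation: activation groups, probe methylation, global proxy."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

import ddicscreen as ds
from ddicscreen.tumor import activation_groups


class TestActivationGroups:
    def test_ordered_input_matches_quantile_oracle(self):
        vals = pd.Series(np.arange(1.0, 101.0), index=[f"s{i}" for i in range(100)])
        g = ds.activation_groups(vals)
        q20, q80 = np.quantile(vals, [0.2, 0.8])
        assert g.rule_used == "quantile"
        assert g.activating == set(vals.index[vals > q80])
        assert g.nonactivating == set(vals.index[vals < q20])
        assert not (g.activating & g.nonactivating)

    def test_fallback_when_q80_below_1(self):
        vals = pd.Series(0.0, index=[f"s{i}" for i in range(50)])
        vals.iloc[[3, 17, 42]] = 5.0
        g = ds.activation_groups(vals)
        assert g.rule_used == "fallback"
        assert g.activating == {"s3", "s17", "s42"}
        assert len(g.nonactivating) == 47

    def test_random_vector_matches_sort_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            vals = pd.Series(rng.gamma(1.0, 5.0, 60), index=[f"s{i}" for i in range(60)])
            g = ds.activation_groups(vals)
            srt = np.sort(vals.to_numpy())
            q20 = srt[11] + 0.8 * (srt[12] - srt[11])  # linear interpolation at h=11.8
            q80 = srt[47] + 0.2 * (srt[48] - srt[47])
            if q80 >= 1.0:
                assert g.activating == set(vals.index[vals > q80])
                assert g.nonactivating == set(vals.index[vals < q20])

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            ds.activation_groups(pd.Series([1.0, 2.0, 3.0]))


@pytest.fixture(scope="module")
def small_cohort():
    manifest = pd.DataFrame(
        {"chromosome": ["chr1", "chr1", "chr1", "chr2", "chrX"],
         "pos": [100, 300, 700, 500, 100],
         "autosomal": [True, True, True, True, False]},
        index=pd.Index(["p1", "p2", "p3", "p4", "px"], name="probe_id"),
    )
    betas = pd.DataFrame(
        {"t1": [0.2, 0.5, 0.8, 0.9, 0.95], "t2": [0.3, 0.4, np.nan, 0.8, 0.95],
         "n1": [0.9, 0.8, 0.75, 0.9, 0.95], "n2": [0.85, 0.9, 0.69, 0.95, 0.95]},
        index=manifest.index,
    )
    expr = ds.ExpressionMatrix(
        pd.DataFrame({"t1": [5.0], "t2": [0.1], "n1": [0.0], "n2": [0.0]}, index=["g"])
    )
    clinical = pd.DataFrame(
        {"sample_class": ["tumor", "tumor", "normal", "normal"],
         "grade": [2.0, 3.0, np.nan, np.nan],
         "survival_time": [100.0, 200.0, np.nan, np.nan],
         "event": [1.0, 0.0, np.nan, np.nan]},
        index=["t1", "t2", "n1", "n2"],
    )
    return ds.TumorCohort(expr, betas, manifest, clinical)


class TestPromoterProbeMethylation:
    def test_mean_over_in_window_probes(self, small_cohort):
        # TSS 400: window [0, 800) holds p1, p2, p3
        pm = ds.promoter_probe_methylation(small_cohort, "chr1", 400)
        assert pm["t1"] == pytest.approx(np.mean([0.2, 0.5, 0.8]))
        # missing beta dropped per sample
        assert pm["t2"] == pytest.approx(np.mean([0.3, 0.4]))

    def test_single_probe(self, small_cohort):
        pm = ds.promoter_probe_methylation(small_cohort, "chr2", 500)
        assert pm["t1"] == pytest.approx(0.9)

    def test_no_probe_in_window_is_missing(self, small_cohort):
        pm = ds.promoter_probe_methylation(small_cohort, "chr9", 400)
        assert pm.isna().all()


class TestGlobalProbeSelection:
    def test_each_rule_is_strict_and_autosomal_only(self, small_cohort):
        normals = small_cohort.probe_betas[["n1", "n2"]]
        sel = ds.select_global_probes(small_cohort.manifest, normals)
        # p3 fails (0.69 in n2); px is chrX; p1/p2/p4 pass
        assert set(sel) == {"p1", "p2", "p4"}

    def test_mean_rule_admits_borderline(self, small_cohort):
        normals = small_cohort.probe_betas[["n1", "n2"]]
        sel = ds.select_global_probes(small_cohort.manifest, normals, rule="mean")
        assert "p3" in set(sel)  # mean 0.72 > 0.7

    def test_selection_shrinks_as_threshold_rises(self, small_cohort):
        normals = small_cohort.probe_betas[["n1", "n2"]]
        prev = None
        for thr in (0.5, 0.7, 0.8):
            sel = set(ds.select_global_probes(small_cohort.manifest, normals, min_beta=thr))
            if prev is not None:
                assert sel <= prev
            prev = sel

    def test_no_qualifying_probe_errors(self, small_cohort):
        with pytest.raises(ValueError, match="threshold"):
            ds.select_global_probes(
                small_cohort.manifest, small_cohort.probe_betas[["n1", "n2"]],
                min_beta=0.99,
            )


class TestGlobalProxy:
    def test_all_ones(self):
        betas = pd.DataFrame(1.0, index=["p1", "p2"], columns=["s1", "s2"])
        proxy = ds.global_methylation_level(betas, pd.Index(["p1", "p2"]))
        assert (proxy == 1.0).all()

    def test_invariant_to_probe_order_and_all_missing_probes(self):
        rng = np.random.default_rng(5)
        betas = pd.DataFrame(rng.random((10, 4)),
                             index=[f"p{i}" for i in range(10)],
                             columns=list("abcd"))
        probes = pd.Index([f"p{i}" for i in range(10)])
        a = ds.global_methylation_level(betas, probes)
        b = ds.global_methylation_level(betas.iloc[::-1], probes[::-1])
        pd.testing.assert_series_equal(a, b.reindex(a.index))
        with_missing = pd.concat(
            [betas, pd.DataFrame(np.nan, index=["pm"], columns=betas.columns)]
        )
        c = ds.global_methylation_level(with_missing, probes.append(pd.Index(["pm"])))
        pd.testing.assert_series_equal(a, c)

    def test_normals_alone_give_25pct_hypomethylated(self):
        # q25 with linear interpolation: exactly a quarter of samples below
        means = pd.Series(np.arange(1, 101) / 101.0, index=[f"n{i}" for i in range(100)])
        hypo, cutoff = ds.call_hypomethylated(means, means)
        assert hypo.mean() == pytest.approx(0.25, abs=0.01)

    def test_proxy_tracks_planted_demethylation(self, genome, tumor_cohort_truth):
        cohort, truth = tumor_cohort_truth
        probes = ds.select_global_probes(
            cohort.manifest, cohort.probe_betas[cohort.normal_samples]
        )
        proxy = ds.global_methylation_level(
            cohort.probe_betas[cohort.tumor_samples], probes
        )
        rho, _ = ss.spearmanr(truth.h, proxy)
        assert rho <= -0.95


class TestPromoterVsGlobal:
    def test_identical_group_means_give_t0(self):
        pm = pd.Series(np.linspace(0, 1, 40), index=[f"s{i}" for i in range(40)])
        proxy = pd.Series(0.8, index=pm.index)
        res = ds.promoter_vs_global_association(pm, proxy)
        assert res["t"] == pytest.approx(0.0)

    def test_small_subgroup_is_na_with_reason(self):
        pm = pd.Series([0.5] * 3 + [np.nan] * 37, index=[f"s{i}" for i in range(40)])
        res = ds.promoter_vs_global_association(pm, pd.Series(0.8, index=pm.index))
        assert np.isnan(res["t"]) and res["reason"]

    def test_planted_coupling_detected(self, genome, tumor_cohort_truth):
        cohort, truth = tumor_cohort_truth
        gt = genome.truth
        tumors = cohort.tumor_samples
        probes = ds.select_global_probes(
            cohort.manifest, cohort.probe_betas[cohort.normal_samples]
        )
        proxy = ds.global_methylation_level(cohort.probe_betas[tumors], probes)
        with_probes = gt.index[
            gt["truth_class"].str.startswith("DDIC") & (gt["n_promoter_probes"] > 0)
        ]
        for gene in with_probes[:10]:
            pm = ds.promoter_probe_methylation(
                cohort, gt.loc[gene, "chromosome"], int(gt.loc[gene, "tss"])
            )
            res = ds.promoter_vs_global_association(pm[tumors], proxy)
            assert res["t"] > 0 and res["p"] < 1e-3

    def test_null_type_one_error_calibrated(self, clinical_cohort):
        _sc, genome, cohort, _truth = clinical_cohort
        gt = genome.truth
        tumors = cohort.tumor_samples
        probes = ds.select_global_probes(
            cohort.manifest, cohort.probe_betas[cohort.normal_samples]
        )
        proxy = ds.global_methylation_level(cohort.probe_betas[tumors], probes)
        nulls = gt.index[(gt["truth_class"] == "null_expressed")
                         & (gt["n_promoter_probes"] > 0)]
        ps = []
        for gene in nulls:
            pm = ds.promoter_probe_methylation(
                cohort, gt.loc[gene, "chromosome"], int(gt.loc[gene, "tss"])
            )
            res = ds.promoter_vs_global_association(pm[tumors], proxy)
            if np.isfinite(res["p"]):
                ps.append(res["p"])
        rate = float(np.mean(np.asarray(ps) < 0.05))
        assert 0.0 <= rate <= 0.10


class TestBinning:
    def test_single_bin_holds_everyone(self):
        proxy = pd.Series([0.7, 0.8], index=["a", "b"])
        pm = pd.DataFrame({"a": [0.5], "b": [0.6]}, index=["g"])
        out = ds.bin_by_global_methylation(
            proxy, [0.6, 0.9], pm, pd.Series({"g": "CG"})
        )
        assert out["n_samples"].iloc[0] == 2

    def test_all_methylated_cohort_means_one(self):
        proxy = pd.Series([0.65, 0.75, 0.85], index=list("abc"))
        pm = pd.DataFrame(1.0, index=["g1", "g2"], columns=list("abc"))
        out = ds.bin_by_global_methylation(
            proxy, [0.6, 0.7, 0.8, 0.9], pm, pd.Series({"g1": "CG", "g2": "SE"})
        )
        assert np.allclose(out["mean_promoter_meth"], 1.0)

    def test_nonmonotone_edges_rejected(self):
        with pytest.raises(ValueError):
            ds.bin_by_global_methylation(
                pd.Series([0.7]), [0.6, 0.9, 0.8], pd.DataFrame(), pd.Series(dtype=object)
            )

    def test_sensitive_categories_demethylate_in_milder_bins(
        self, genome, tumor_cohort_truth
    ):
        cohort, _truth = tumor_cohort_truth
        gt = genome.truth
        tumors = cohort.tumor_samples
        probes = ds.select_global_probes(
            cohort.manifest, cohort.probe_betas[cohort.normal_samples]
        )
        proxy = ds.global_methylation_level(cohort.probe_betas[tumors], probes)
        genes = gt.index[gt["truth_class"].isin(["DDIC_CG", "DDIC_GI", "DDIC_SE"])
                         & (gt["n_promoter_probes"] > 0)]
        pm = pd.DataFrame({
            g: ds.promoter_probe_methylation(
                cohort, gt.loc[g, "chromosome"], int(gt.loc[g, "tss"])
            )[tumors]
            for g in genes
        }).T
        labels = gt.loc[genes, "truth_class"].str.replace("DDIC_", "", regex=False)
        out = ds.bin_by_global_methylation(proxy, [0.60, 0.70, 0.77, 0.90], pm, labels)
        pivot = out.pivot(index="program", columns="bin", values="mean_promoter_meth")
        mid = pivot["[0.7,0.77)"]
        # in the intermediate bin the high-sensitivity programs are already
        # demethylated while the germline program is not
        assert mid["GI"] < mid["CG"] and mid["SE"] < mid["CG"]


class TestTfGating:
    def test_demethylated_but_silent_tumors_flagged(self, genome, tumor_cohort_truth):
        cohort, truth = tumor_cohort_truth
        gt = genome.truth
        tumors = cohort.tumor_samples
        gated = gt.index[gt["tf_gated"].astype(bool) & (gt["n_promoter_probes"] > 0)]
        assert len(gated) > 0
        for gene in gated:
            pm = ds.promoter_probe_methylation(
                cohort, gt.loc[gene, "chromosome"], int(gt.loc[gene, "tss"])
            )
            flagged = set(ds.flag_demethylated_silent(
                pm[tumors], cohort.expression.data.loc[gene, tumors]
            ))
            expected = set(truth.demethylated.columns[
                truth.demethylated.loc[gene] & ~truth.tf_positive
            ])
            assert len(expected) > 0
            assert flagged == expected
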