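"""Unit tests for the five-stage selection procedure."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ddicscreen as ds
from ddicscreen.screen import (
    classify_by_correlation,
    filter_activated_in_lines,
    filter_repressed_in_normal,
    merge_tss_groups,
    select_non_ddic,
    structural_check,
)


def tx(tid, tss, strand="+", chrom="chr1", gene=None):
    return ds.TranscriptModel(tid, gene or tid, chrom, strand, tss)


def expr_matrix(rows: dict, samples=("a", "b")):
    return ds.ExpressionMatrix(pd.DataFrame(rows, index=list(samples)).T, units="TPM")


class TestMergeTssGroups:
    def test_within_50bp_merges_with_5prime_reference(self):
        groups, gx = merge_tss_groups(
            [tx("t1", 1000), tx("t2", 1030)], expr_matrix({"t1": [1, 2], "t2": [3, 4]})
        )
        assert len(groups) == 1
        assert groups[0].reference_tss == 1000
        np.testing.assert_allclose(gx.iloc[0], [4, 6])

    def test_exactly_50bp_does_not_merge(self):
        groups, _ = merge_tss_groups(
            [tx("t1", 1000), tx("t2", 1050)], expr_matrix({"t1": [1, 1], "t2": [1, 1]})
        )
        assert len(groups) == 2

    def test_single_linkage_chaining(self):
        groups, gx = merge_tss_groups(
            [tx("t1", 1000), tx("t2", 1040), tx("t3", 1080)],
            expr_matrix({"t1": [1, 0], "t2": [2, 5], "t3": [4, 1]}),
        )
        assert len(groups) == 1
        np.testing.assert_allclose(gx.iloc[0], [7, 6])  # element-wise manual sum

    def test_reference_tss_is_5prime_on_minus_strand(self):
        groups, _ = merge_tss_groups(
            [tx("t1", 1000, "-"), tx("t2", 1030, "-")],
            expr_matrix({"t1": [1, 1], "t2": [1, 1]}),
        )
        assert groups[0].reference_tss == 1030

    def test_different_strand_or_chrom_never_merge(self):
        groups, _ = merge_tss_groups(
            [tx("t1", 1000, "+"), tx("t2", 1010, "-"), tx("t3", 1000, "+", chrom="chr2")],
            expr_matrix({"t1": [1, 1], "t2": [1, 1], "t3": [1, 1]}),
        )
        assert len(groups) == 3

    def test_unknown_expression_rows_warn(self):
        with pytest.warns(UserWarning, match="excluded"):
            merge_tss_groups(
                [tx("t1", 1000)], expr_matrix({"t1": [1, 1], "ghost": [9, 9]})
            )

    def test_brute_force_clustering_oracle(self):
        rng = np.random.default_rng(11)
        tss = sorted(int(p) for p in rng.choice(100_000, size=40, replace=False))
        models = [tx(f"t{i}", p) for i, p in enumerate(tss)]
        groups, _ = merge_tss_groups(
            models, expr_matrix({f"t{i}": [1.0, 1.0] for i in range(40)})
        )
        # oracle: count chains by scanning successive gaps
        expected = 1 + sum(b - a >= 50 for a, b in zip(tss, tss[1:]))
        assert len(groups) == expected


class TestNormalRepressionFilter:
    def frame(self, expr, meth):
        idx = [f"g{i}" for i in range(len(expr))]
        cols = ["lung", "AT2"]
        return (pd.DataFrame(expr, index=idx, columns=cols),
                pd.DataFrame(meth, index=idx, columns=cols))

    def test_boundaries(self):
        expr, meth = self.frame(
            [[0.5, 0.2], [0.5, 0.2], [1.0, 0.2], [0.5, 0.2]],
            [[0.8, 0.7], [0.59, 0.9], [0.9, 0.9], [np.nan, 0.9]],
        )
        ok = filter_repressed_in_normal(expr, meth)
        # survives; meth below 60% fails; TPM at 1 fails; MISSING fails
        assert ok.tolist() == [True, False, False, False]

    def test_missing_reference_column_errors(self):
        with pytest.raises(ValueError):
            filter_repressed_in_normal(
                pd.DataFrame(index=["g"]), pd.DataFrame(index=["g"])
            )


class TestActivationFilter:
    def lines(self, expr, meth):
        idx = ["g"]
        cols = [f"L{i}" for i in range(len(expr))]
        return (pd.DataFrame([expr], index=idx, columns=cols),
                pd.DataFrame([meth], index=idx, columns=cols))

    def test_extreme_compliant(self):
        expr = [0.0] * 25 + [5.0]
        meth = [0.9] * 25 + [0.1]
        e, m = self.lines(expr, meth)
        assert filter_activated_in_lines(e, m).iloc[0] == "pass"

    def test_max_expression_below_2_fails_activation(self):
        expr = [0.0] * 25 + [1.9]
        meth = [0.9] * 25 + [0.1]
        e, m = self.lines(expr, meth)
        assert filter_activated_in_lines(e, m).iloc[0] == "activation"

    def test_min_meth_not_below_040_fails_range(self):
        expr = [0.0] * 25 + [5.0]
        meth = list(np.linspace(0.41, 0.95, 26))
        e, m = self.lines(expr, meth)
        assert filter_activated_in_lines(e, m).iloc[0] == "methylation_range"

    def test_needs_two_repressed_lines(self):
        expr = [0.05] + [3.0] * 25  # q10 over 26 lines still > 0.1
        meth = [0.9] * 13 + [0.1] * 13
        e, m = self.lines(expr, meth)
        assert filter_activated_in_lines(e, m).iloc[0] == "activation"

    def test_quantile_uses_linear_interpolation(self):
        expr = [0.0, 0.0, 0.1, 0.2] + [5.0] * 22
        e, m = self.lines(expr, [0.9] * 25 + [0.1])
        q10 = np.quantile(np.array(expr), 0.10)
        assert (filter_activated_in_lines(e, m).iloc[0] == "pass") == (q10 <= 0.1)


class TestCorrelationStage:
    def test_planted_anticorrelation_is_ddic(self):
        rng = np.random.default_rng(1)
        meth = np.concatenate([rng.uniform(0.7, 0.95, 13), rng.uniform(0.05, 0.3, 13)])
        expr = np.where(meth > 0.5, 0.01, 30.0)
        e = pd.DataFrame([expr], index=["g"])
        m = pd.DataFrame([meth], index=["g"])
        out = classify_by_correlation(e, m)
        assert bool(out.loc["g", "ddic"]) and out.loc["g", "r"] <= -0.4

    def test_constant_methylation_rejected(self):
        e = pd.DataFrame([np.linspace(0, 30, 26)], index=["g"])
        m = pd.DataFrame([[0.5] * 26], index=["g"])
        out = classify_by_correlation(e, m)
        assert not bool(out.loc["g", "ddic"]) and np.isnan(out.loc["g", "r"])

    def test_six_pairs_rejected_regardless_of_r(self):
        meth = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1] + [np.nan] * 20
        expr = [0.0, 0.1, 0.0, 20.0, 30.0, 25.0] + [1.0] * 20
        out = classify_by_correlation(
            pd.DataFrame([expr], index=["g"]), pd.DataFrame([meth], index=["g"])
        )
        assert out.loc["g", "n_paired"] == 6
        assert not bool(out.loc["g", "ddic"])


class TestNonDdicSelection:
    def base_inputs(self, r_target="zero", gtex=0.1):
        rng = np.random.default_rng(2)
        expr = np.concatenate([np.full(13, 0.01), np.full(13, 20.0)])
        if r_target == "zero":
            meth = np.full(26, 0.85)
            meth[:13] += rng.normal(0, 0.01, 13)
            meth[13:] += rng.normal(0, 0.01, 13)
        else:  # strongly negative
            meth = np.where(expr > 1, 0.1, 0.9)
        e = pd.DataFrame([expr], index=["g"])
        m = pd.DataFrame([meth], index=["g"])
        s = lambda v: pd.Series({"g": v})
        return {"gene_transcript_counts": {"g": 1}, "gtex_medians": s(gtex),
                "roadmap_lung_tpm": s(0.2), "at2_tpm": s(0.2),
                "line_expr": e, "line_meth": m}

    def test_uncorrelated_activated_gene_is_nonddic(self):
        out = select_non_ddic(**self.base_inputs())
        assert out.loc["g", "status"] == "nonDDIC"

    def test_intermediate_r_is_neither(self):
        # r around -0.25: outside both the DDIC and the no-correlation band
        rng = np.random.default_rng(4)
        inputs = self.base_inputs()
        expr = inputs["line_expr"].iloc[0].to_numpy()
        x = np.log2(expr + 1.0)
        noise = rng.normal(0, 1, 26)
        noise -= np.polyval(np.polyfit(x, noise, 1), x)  # orthogonal noise
        m = -0.25 * (x - x.mean()) / x.std() + noise / noise.std() * np.sqrt(1 - 0.25**2)
        m = 0.5 + 0.05 * m
        inputs["line_meth"] = pd.DataFrame([m], index=["g"])
        out = select_non_ddic(**inputs)
        assert abs(out.loc["g", "r"] + 0.25) < 1e-9
        assert out.loc["g", "status"] == "excluded"

    def test_gtex_median_at_06_excluded(self):
        out = select_non_ddic(**self.base_inputs(gtex=0.6))
        assert out.loc["g", "status"] == "excluded"

    def test_multi_transcript_gene_rejected(self):
        inputs = self.base_inputs()
        inputs["gene_transcript_counts"] = {"g": 2}
        with pytest.raises(ValueError, match="multi-transcript"):
            select_non_ddic(**inputs)


class TestStructuralCheck:
    @pytest.mark.parametrize(
        "tpm,signal,expected",
        [(5.0, 10.0, (True, "consistent")),
         (5.0, 0.0, (False, "expression without mapped signal")),
         (5.0, None, (True, "not evaluated"))],
    )
    def test_verdicts(self, tpm, signal, expected):
        assert structural_check(tpm, signal) == expected


class TestScreenBookkeeping:
    def test_stage_counts_sum_to_non_ddic_total(self, screen_result):
        rec = screen_result.records
        n_rejected = (rec["status"] == "rejected").sum()
        stage_sum = rec.loc[rec["status"] == "rejected", "stage"].value_counts().sum()
        assert stage_sum == n_rejected
        assert (rec.loc[rec["status"] == "rejected", "stage"] != "none").all()
        att = screen_result.attrition
        assert att["input_groups"] == att["DDIC"] + n_rejected

    def test_ddic_records_satisfy_gates(self, screen_result):
        rec = screen_result.records
        ddic = rec[rec["status"] == "DDIC"]
        assert (ddic["r"] <= -0.4).all()
        assert (ddic["p"] < 0.05).all()
        assert (ddic["n_paired"] >= 7).all()
        assert (ddic["p_adj"] >= ddic["p"] - 1e-15).all()
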