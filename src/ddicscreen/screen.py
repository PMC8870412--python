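"""Five-stage screen for demethylation-induced transcripts.

The screen takes a panel of tumor cell lines with matched expression (TPM)
and promoter CpG methylation, plus normal-tissue references (lung tissue
and alveolar type II cells), and classifies each promoter group as:

* ``DDIC`` -- silent and methylated in the normal references, activated in
  at least one cell line, promoter demethylated in at least one line, and
  expression inversely correlated with promoter methylation
  (r <= -0.4, p < 0.05, over >= 7 paired lines);
* ``nonDDIC`` -- ectopically activated without expression/methylation
  coupling (-0.1 <= r <= 0.1); the control class; or
* ``rejected`` with the stage that removed it.

Stages are applied in order: TSS merging, repression in normal references,
activation in cell lines (expression then methylation range), inverse
correlation, and an advisory structural consistency check standing in for
manual genome-browser curation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import ScreenConfig
from .core import (
    CpGMethylationTrack,
    ExpressionMatrix,
    pearson_with_p,
    promoter_region,
    promoter_methylation_level,
    TranscriptModel,
)
from .stats import bh_adjust

STAGES = ("none", "normal_repression", "activation", "methylation_range",
          "correlation", "structural")


@dataclass
class MergedPromoterGroup:
    """Transcripts whose TSS chain together at < tss_merge_bp spacing.

    Expression of the members is summed; the reference TSS is the 5'-most
    member TSS given the strand.
    """

    group_id: str
    member_transcript_ids: list[str]
    gene_ids: list[str]
    chromosome: str
    strand: str
    reference_tss: int


@dataclass
class DDICRecord:
    group_id: str
    status: str                      # DDIC | nonDDIC | rejected
    rejection_stage: str             # one of STAGES
    r: float = np.nan
    p: float = np.nan
    p_adj: float = np.nan
    n_paired: int = 0


def merge_tss_groups(
    transcripts: Sequence[TranscriptModel],
    expression: ExpressionMatrix,
    config: ScreenConfig = ScreenConfig(),
) -> tuple[list[MergedPromoterGroup], pd.DataFrame]:
    """Merge transcripts whose TSS lie < ``tss_merge_bp`` apart.

    Merging is single-linkage chaining on (chromosome, strand): sorted TSS
    positions with successive gaps strictly below the threshold join one
    group, so a group may span more than the threshold end to end.  Returns
    the groups and a group x sample frame of summed TPM.

    Expression rows that match no transcript model are excluded with a
    warning; transcripts without an expression row contribute zero with a
    warning.
    """
    model_ids = {t.transcript_id for t in transcripts}
    from .io import warn_unmatched

    warn_unmatched(set(expression.data.index), model_ids, "expression rows")
    absent = model_ids - set(expression.data.index)
    if absent:
        warnings.warn(
            f"{len(absent)} transcripts have no expression row; treated as zero",
            stacklevel=2,
        )

    groups: list[MergedPromoterGroup] = []
    by_key: dict[tuple[str, str], list[TranscriptModel]] = {}
    for t in transcripts:
        by_key.setdefault((t.chromosome, t.strand), []).append(t)

    rows = []
    for (chrom, strand), members in sorted(by_key.items()):
        members = sorted(members, key=lambda t: t.tss)
        chain: list[TranscriptModel] = []
        chains: list[list[TranscriptModel]] = []
        for t in members:
            if chain and t.tss - chain[-1].tss < config.tss_merge_bp:
                chain.append(t)
            else:
                if chain:
                    chains.append(chain)
                chain = [t]
        if chain:
            chains.append(chain)
        for chain in chains:
            tss_values = [t.tss for t in chain]
            ref_tss = min(tss_values) if strand == "+" else max(tss_values)
            gid = chain[0].transcript_id if len(chain) == 1 else (
                chain[0].transcript_id + "+%d" % (len(chain) - 1))
            group = MergedPromoterGroup(
                group_id=gid,
                member_transcript_ids=[t.transcript_id for t in chain],
                gene_ids=sorted({t.gene_id for t in chain}),
                chromosome=chrom,
                strand=strand,
                reference_tss=ref_tss,
            )
            groups.append(group)
            expr = np.zeros(len(expression.data.columns))
            for t in chain:
                if t.transcript_id in expression.data.index:
                    expr = expr + expression.data.loc[t.transcript_id].to_numpy(dtype=float)
            rows.append(pd.Series(expr, index=expression.data.columns, name=gid))
    group_expr = pd.DataFrame(rows) if rows else pd.DataFrame(columns=expression.data.columns)
    return groups, group_expr


def group_expression(
    groups: Sequence[MergedPromoterGroup], expression: ExpressionMatrix
) -> pd.DataFrame:
    """Sum an arbitrary expression matrix over already-formed groups."""
    rows = []
    for g in groups:
        expr = np.zeros(len(expression.data.columns))
        for tid in g.member_transcript_ids:
            if tid in expression.data.index:
                expr = expr + expression.data.loc[tid].to_numpy(dtype=float)
        rows.append(pd.Series(expr, index=expression.data.columns, name=g.group_id))
    return pd.DataFrame(rows)


def group_promoter_matrix(
    groups: Sequence[MergedPromoterGroup],
    tracks: Mapping[str, CpGMethylationTrack],
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Group x sample promoter methylation levels (NaN where MISSING)."""
    out = np.full((len(groups), len(tracks)), np.nan)
    sample_ids = list(tracks)
    for j, sid in enumerate(sample_ids):
        track = tracks[sid]
        for i, g in enumerate(groups):
            region = promoter_region(
                g.group_id, g.chromosome, g.reference_tss, config.promoter_flank_bp
            )
            out[i, j] = promoter_methylation_level(
                track, region, min_cpgs=config.min_cpgs, min_coverage=config.min_coverage
            )
    return pd.DataFrame(out, index=[g.group_id for g in groups], columns=sample_ids)


def filter_repressed_in_normal(
    normal_expr: pd.DataFrame,
    normal_meth: pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
) -> pd.Series:
    """Keep groups silent and promoter-methylated in every normal reference.

    ``normal_expr`` and ``normal_meth`` are group x reference frames (one
    column per reference, e.g. lung tissue and AT2 cells).  Survival
    requires, in every reference, TPM below the repression threshold and
    promoter methylation >= methylated_min; a MISSING methylation level
    fails conservatively.
    """
    if normal_expr.shape[1] == 0 or normal_meth.shape[1] == 0:
        raise ValueError("at least one normal reference column is required")
    repressed = (normal_expr < config.repressed_tpm).all(axis=1)
    meth = normal_meth.reindex(normal_expr.index)
    methylated = (meth >= config.methylated_min).all(axis=1) & meth.notna().all(axis=1)
    return repressed & methylated


def _activation_expression_ok(line_expr: pd.DataFrame, config: ScreenConfig) -> pd.Series:
    """Expression half of the cell-line activation filter.

    The transcript must be repressed in at least ``min_repressed_lines``
    lines (per-line TPM <= q10_repressed_tpm), its 10th expression
    percentile across lines must be <= q10_repressed_tpm, and its maximum
    must reach the positive threshold.
    """
    vals = line_expr.to_numpy(dtype=float)
    q10 = np.quantile(vals, 0.10, axis=1)  # linear interpolation
    n_rep = (vals <= config.q10_repressed_tpm).sum(axis=1)
    ok = (
        (q10 <= config.q10_repressed_tpm)
        & (n_rep >= config.min_repressed_lines)
        & (vals.max(axis=1) >= config.expressed_tpm)
    )
    return pd.Series(ok, index=line_expr.index)


def filter_activated_in_lines(
    line_expr: pd.DataFrame,
    line_meth: pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
) -> pd.Series:
    """Stage verdict per group: ``pass``, ``activation`` or ``methylation_range``.

    Expression must show repression in some lines plus activation in at
    least one; promoter methylation (over non-MISSING lines) must span the
    demethylated and methylated states (min < demeth_max, max >
    methylated_min).
    """
    if line_expr.shape[1] < 2:
        raise ValueError("need at least 2 cell lines")
    expr_ok = _activation_expression_ok(line_expr, config)
    meth = line_meth.reindex(line_expr.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mmin = np.nanmin(meth.to_numpy(dtype=float), axis=1)
        mmax = np.nanmax(meth.to_numpy(dtype=float), axis=1)
    meth_ok = pd.Series(
        (mmin < config.demeth_max) & (mmax > config.methylated_min), index=line_expr.index
    )
    verdict = pd.Series("pass", index=line_expr.index, dtype=object)
    verdict[~meth_ok] = "methylation_range"
    verdict[~expr_ok] = "activation"  # expression failures take precedence
    return verdict


def classify_by_correlation(
    line_expr: pd.DataFrame,
    line_meth: pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Per-group Pearson r between log2(TPM+1) expression and promoter beta.

    Returns a frame with columns r, p, p_adj, n_paired and a boolean
    ``ddic`` column: r <= ddic_r_max, gated p below ddic_p_max, and at least
    ``min_paired`` complete pairs.  Adjusted p-values (Benjamini-Hochberg
    over all groups reaching this stage) are always reported; whether the
    gate uses the raw or adjusted value follows ``config.p_gate``.
    """
    records = []
    meth = line_meth.reindex(line_expr.index)
    for gid in line_expr.index:
        x = np.log2(line_expr.loc[gid].to_numpy(dtype=float) + 1.0)
        y = meth.loc[gid].to_numpy(dtype=float)
        r, p, n = pearson_with_p(x, y)
        records.append((gid, r, p, n))
    out = pd.DataFrame(records, columns=["group_id", "r", "p", "n_paired"])
    out = out.set_index("group_id")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    gate_p = out["p"] if config.p_gate == "raw" else out["p_adj"]
    out["ddic"] = (
        (out["n_paired"] >= config.min_paired)
        & (out["r"] <= config.ddic_r_max)
        & (gate_p < config.ddic_p_max)
    )
    out["ddic"] = out["ddic"].fillna(False)
    return out


def structural_check(
    tpm_max: float, body_signal: float | None
) -> tuple[bool, str]:
    """Advisory consistency check standing in for manual browser curation.

    Fails only when a transcript is called expressed while no read signal
    maps over its body, which indicates inconsistent quantification.  When
    no signal summary is supplied the check passes with reason
    ``not evaluated``.
    """
    if body_signal is None:
        return True, "not evaluated"
    if tpm_max >= 1.0 and body_signal == 0:
        return False, "expression without mapped signal"
    return True, "consistent"


@dataclass
class ScreenResult:
    groups: list[MergedPromoterGroup]
    records: pd.DataFrame           # one row per group
    attrition: dict[str, int] = field(default_factory=dict)

    @property
    def ddic_ids(self) -> list[str]:
        return list(self.records.index[self.records["status"] == "DDIC"])


def run_screen(
    transcripts: Sequence[TranscriptModel],
    line_expression: ExpressionMatrix,
    line_tracks: Mapping[str, CpGMethylationTrack],
    normal_expression: ExpressionMatrix,
    normal_tracks: Mapping[str, CpGMethylationTrack],
    config: ScreenConfig = ScreenConfig(),
    body_signal: pd.DataFrame | None = None,
) -> ScreenResult:
    """Run the full DDIC screen.

    ``normal_expression`` / ``normal_tracks`` hold one column/track per
    normal reference (lung tissue, AT2 cells).  ``body_signal`` optionally
    carries a per-group, per-line coverage summary over the transcript body
    for the advisory structural check.
    """
    groups, line_expr = merge_tss_groups(transcripts, line_expression, config)
    gid_index = [g.group_id for g in groups]
    line_meth = group_promoter_matrix(groups, line_tracks, config)
    normal_expr = group_expression(groups, normal_expression)
    normal_meth = group_promoter_matrix(groups, normal_tracks, config)

    status = pd.Series("rejected", index=gid_index, dtype=object)
    stage = pd.Series("none", index=gid_index, dtype=object)

    ok_normal = filter_repressed_in_normal(normal_expr, normal_meth, config)
    stage[~ok_normal] = "normal_repression"

    survivors = ok_normal[ok_normal].index
    verdict = filter_activated_in_lines(
        line_expr.loc[survivors], line_meth.loc[survivors], config
    )
    stage[verdict.index[verdict == "activation"]] = "activation"
    stage[verdict.index[verdict == "methylation_range"]] = "methylation_range"

    survivors = verdict.index[verdict == "pass"]
    corr = classify_by_correlation(line_expr.loc[survivors], line_meth.loc[survivors], config)
    stage[corr.index[~corr["ddic"]]] = "correlation"

    ddic_ids = corr.index[corr["ddic"]]
    status[ddic_ids] = "DDIC"

    # advisory structural surrogate for manual curation
    if body_signal is not None:
        for gid in list(ddic_ids):
            sig = body_signal.loc[gid] if gid in body_signal.index else None
            passed, _reason = structural_check(
                float(line_expr.loc[gid].max()),
                None if sig is None else float(np.asarray(sig, dtype=float).sum()),
            )
            if not passed:
                status[gid] = "rejected"
                stage[gid] = "structural"

    records = pd.DataFrame(
        {"status": status, "stage": stage,
         "r": np.nan, "p": np.nan, "p_adj": np.nan, "n_paired": 0},
        index=pd.Index(gid_index, name="group_id"),
    )
    records.loc[corr.index, ["r", "p", "p_adj", "n_paired"]] = corr[
        ["r", "p", "p_adj", "n_paired"]
    ]
    records["gene_ids"] = [",".join(g.gene_ids) for g in groups]
    records.loc[records["status"] == "DDIC", "stage"] = "none"

    attrition = {
        "input_groups": len(groups),
        **{
            s: int((records["stage"] == s).sum())
            for s in STAGES
            if s != "none"
        },
        "DDIC": int((records["status"] == "DDIC").sum()),
    }
    return ScreenResult(groups=groups, records=records, attrition=attrition)


def select_non_ddic(
    gene_transcript_counts: Mapping[str, int],
    gtex_medians: pd.Series,
    roadmap_lung_tpm: pd.Series,
    at2_tpm: pd.Series,
    line_expr: pd.DataFrame,
    line_meth: pd.DataFrame,
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Select the uncorrelated control class (nonDDIC) among candidate genes.

    Candidates must arise from single-transcript genes (no alternative
    promoters); passing one with several transcripts raises.  A gene is
    nonDDIC when it is repressed in normal lung by three sources (GTEx lung
    median < 0.5 TPM, lung tissue reference < 1 TPM, AT2 < 1 TPM), shows
    the cell-line activation pattern on expression, and its
    expression/promoter-methylation correlation sits in the no-correlation
    band (|r| <= 0.1 by default) with enough paired lines.
    """
    multi = [g for g in line_expr.index if gene_transcript_counts.get(g, 1) > 1]
    if multi:
        raise ValueError(f"multi-transcript genes passed to nonDDIC selection: {multi[:3]}")
    expr_ok = _activation_expression_ok(line_expr, config)
    repressed = (
        (gtex_medians.reindex(line_expr.index) < config.gtex_median_max)
        & (roadmap_lung_tpm.reindex(line_expr.index) < config.repressed_tpm)
        & (at2_tpm.reindex(line_expr.index) < config.repressed_tpm)
    )
    corr = classify_by_correlation(line_expr, line_meth, config)
    lo, hi = config.nonddic_r_band
    in_band = (corr["r"] >= lo) & (corr["r"] <= hi) & (
        corr["n_paired"] >= config.min_paired
    )
    out = corr[["r", "p", "p_adj", "n_paired"]].copy()
    out["status"] = np.where(
        repressed.fillna(False) & expr_ok & in_band.fillna(False), "nonDDIC", "excluded"
    )
    return out
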