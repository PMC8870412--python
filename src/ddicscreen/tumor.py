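"""Tumor-cohort validation on expression + methylation-array data.

The in-vivo validation works on a joint container of bulk RNA-seq TPM,
Infinium-style probe betas, a probe manifest and clinical covariates.  The
analyses mirror the cell-line screen at cohort scale:

* per-gene activation groups from expression quantiles (q20 / q80, with a
  >= 1 TPM fallback when the gene is rarely expressed);
* promoter methylation from array probes within TSS +/- 400 bp;
* per-gene Pearson correlation of expression and promoter methylation;
* a global-methylation proxy: the mean beta over autosomal probes that are
  constitutively methylated (> 0.7) in every normal sample;
* association between local promoter demethylation and global
  hypomethylation (Welch t-test between promoter-methylated and
  promoter-demethylated tumor subgroups);
* binning of tumors by the global proxy to order gene categories by their
  demethylation sensitivity.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import ExpressionMatrix, pearson_with_p, promoter_region


@dataclass
class TumorCohort:
    """Joint expression / probe-beta / clinical container.

    ``clinical`` is indexed by sample with columns ``sample_class``
    ("tumor" | "normal"), ``grade`` (1, 1.5, 2, 2.5, 3, 4 or NaN),
    ``survival_time`` (days) and ``event`` (1 = death observed).
    """

    expression: ExpressionMatrix
    probe_betas: pd.DataFrame       # probe x sample, values in [0,1] or NaN
    manifest: pd.DataFrame          # probe_id-indexed: chromosome, pos, autosomal
    clinical: pd.DataFrame

    def __post_init__(self) -> None:
        stray = set(self.probe_betas.index) - set(self.manifest.index)
        if stray:
            raise ValueError(f"probes absent from manifest: {sorted(stray)[:3]}")

    @property
    def tumor_samples(self) -> list[str]:
        cls = self.clinical["sample_class"]
        return [s for s in self.expression.sample_ids if cls.get(s) == "tumor"]

    @property
    def normal_samples(self) -> list[str]:
        cls = self.clinical["sample_class"]
        return [s for s in self.expression.sample_ids if cls.get(s) == "normal"]


@dataclass
class ActivationGroups:
    """Per-gene tumor partition used by the clinical association tests."""

    gene_id: str
    activating: set[str]
    nonactivating: set[str]
    rule_used: str                  # "quantile" | "fallback"

    def __post_init__(self) -> None:
        if self.activating & self.nonactivating:
            raise ValueError("activation groups must be disjoint")


def activation_groups(
    gene_tpm: pd.Series, q_low: float = 0.20, q_high: float = 0.80,
    fallback_tpm: float = 1.0,
) -> ActivationGroups:
    """Partition tumors into activating / non-activating for one gene.

    Default rule: activating = TPM > q80, non-activating = TPM < q20
    (quantiles with linear interpolation).  When q80 falls below 1 TPM the
    quantiles are uninformative and the fallback applies: activating =
    TPM >= 1, non-activating = the rest.
    """
    if len(gene_tpm) < 5:
        raise ValueError("need at least 5 tumor samples")
    vals = gene_tpm.to_numpy(dtype=float)
    hi = np.quantile(vals, q_high)
    if hi < fallback_tpm:
        act = set(gene_tpm.index[vals >= fallback_tpm])
        non = set(gene_tpm.index[vals < fallback_tpm])
        return ActivationGroups(str(gene_tpm.name), act, non, "fallback")
    lo = np.quantile(vals, q_low)
    act = set(gene_tpm.index[vals > hi])
    non = set(gene_tpm.index[vals < lo])
    return ActivationGroups(str(gene_tpm.name), act, non, "quantile")


def promoter_probe_methylation(
    cohort: TumorCohort,
    chromosome: str,
    tss: int,
    flank: int = 400,
) -> pd.Series:
    """Per-sample mean beta over probes within TSS +/- ``flank``.

    Returns an all-NaN series when no probe falls in the window (genes
    without promoter probes are MISSING, not zero).  Missing betas are
    dropped per sample.
    """
    region = promoter_region("promoter", chromosome, tss, flank)
    m = cohort.manifest
    in_window = (
        (m["chromosome"] == region.chromosome)
        & (m["pos"] >= region.start)
        & (m["pos"] < region.end)
    )
    probes = m.index[in_window].intersection(cohort.probe_betas.index)
    if len(probes) == 0:
        return pd.Series(np.nan, index=cohort.probe_betas.columns)
    return cohort.probe_betas.loc[probes].mean(axis=0, skipna=True)


def expr_meth_correlation_per_gene(
    cohort: TumorCohort,
    gene: str,
    promoter_meth: pd.Series,
    samples: Sequence[str] | None = None,
    transform: str = "log2p1",
) -> tuple[float, float, int]:
    """Pearson r between expression and promoter methylation across tumors.

    Expression is log2(TPM+1)-transformed by default (``transform="raw"``
    disables this); pairs with a missing value on either side are dropped.
    """
    samples = list(samples) if samples is not None else cohort.tumor_samples
    x = cohort.expression.data.loc[gene, samples].to_numpy(dtype=float)
    if transform == "log2p1":
        x = np.log2(x + 1.0)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    y = promoter_meth.reindex(samples).to_numpy(dtype=float)
    return pearson_with_p(x, y)


def select_global_probes(
    manifest: pd.DataFrame,
    normal_betas: pd.DataFrame,
    min_beta: float = 0.7,
    rule: str = "each",
) -> pd.Index:
    """Probes constitutively methylated in normal samples (the global proxy set).

    Only autosomal probes are eligible (X/Y probes would pick up
    X-inactivation differences between sexes).  ``rule="each"`` demands
    beta > ``min_beta`` in every normal sample; ``rule="mean"`` demands the
    cross-sample mean exceed it.  Raising ``min_beta`` can only shrink the
    set.
    """
    if normal_betas.shape[1] < 1:
        raise ValueError("need at least one normal sample")
    if rule not in ("each", "mean"):
        raise ValueError(f"unknown rule {rule!r}")
    autosomal = manifest.index[manifest["autosomal"]].intersection(normal_betas.index)
    vals = normal_betas.loc[autosomal]
    if rule == "each":
        keep = (vals > min_beta).all(axis=1) & vals.notna().all(axis=1)
    else:
        keep = vals.mean(axis=1, skipna=True) > min_beta
    selected = autosomal[keep.to_numpy()]
    if len(selected) == 0:
        raise ValueError(
            f"no probe exceeds beta {min_beta} in all normals; review the threshold"
        )
    return selected


def global_methylation_level(
    probe_betas: pd.DataFrame, probe_set: pd.Index
) -> pd.Series:
    """Per-sample mean beta over the proxy probe set (missing betas dropped)."""
    if len(probe_set) == 0:
        raise ValueError("empty probe set")
    return probe_betas.loc[probe_set].mean(axis=0, skipna=True)


def call_hypomethylated(
    tumor_means: pd.Series, normal_means: pd.Series
) -> tuple[pd.Series, float]:
    """Flag tumors whose proxy mean falls below q25 of the normal means.

    Returns (boolean series over tumors, the normal q25 cutoff).
    """
    cutoff = float(np.quantile(normal_means.to_numpy(dtype=float), 0.25))
    return tumor_means < cutoff, cutoff


def promoter_vs_global_association(
    promoter_meth: pd.Series,
    global_proxy: pd.Series,
    q_low: float = 0.20,
    q_high: float = 0.80,
    equal_var: bool = False,
) -> dict:
    """Does promoter demethylation track global hypomethylation?

    Tumors are split by the gene's promoter methylation into a methylated
    subgroup M (>= q80) and a demethylated subgroup U (<= q20), and the
    global proxy means are compared with a t-test (Welch by default).  The
    statistic is signed as mean(M) - mean(U), so a promoter whose
    demethylation coincides with global hypomethylation yields a positive
    association.  Returns NaN with a reason when a subgroup has < 2
    samples.
    """
    vals = promoter_meth.dropna()
    if len(vals) < 5:
        return {"t": np.nan, "p": np.nan, "mean_meth": np.nan,
                "mean_demeth": np.nan, "reason": "too few samples"}
    hi = np.quantile(vals, q_high)
    lo = np.quantile(vals, q_low)
    group_m = global_proxy.reindex(vals.index[vals >= hi]).dropna()
    group_u = global_proxy.reindex(vals.index[vals <= lo]).dropna()
    if len(group_m) < 2 or len(group_u) < 2:
        return {"t": np.nan, "p": np.nan, "mean_meth": np.nan,
                "mean_demeth": np.nan, "reason": "subgroup below 2 samples"}
    if group_m.var(ddof=1) == 0 and group_u.var(ddof=1) == 0:
        # degenerate constant groups: identical means are a null result
        t, p = (0.0, 1.0) if group_m.mean() == group_u.mean() else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(group_m, group_u, equal_var=equal_var)
    return {
        "t": float(t),
        "p": float(p),
        "mean_meth": float(group_m.mean()),
        "mean_demeth": float(group_u.mean()),
        "reason": "",
    }


def bin_by_global_methylation(
    global_proxy: pd.Series,
    bin_edges: Sequence[float],
    promoter_meth_by_gene: pd.DataFrame,
    labels: pd.Series,
    normal_proxy: pd.Series | None = None,
    normal_meth_by_gene: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-program mean promoter methylation within global-methylation bins.

    ``bin_edges`` must be strictly monotone; samples are assigned to
    half-open bins [e_i, e_{i+1}).  ``promoter_meth_by_gene`` is gene x
    sample.  For each bin and program the value is the mean over the
    program's genes of each gene's mean promoter beta in that bin; empty
    bins are reported with n = 0.  Normal samples, when given, are
    summarized as one extra ``normal`` row.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or not (
        np.all(np.diff(edges) > 0) or np.all(np.diff(edges) < 0)
    ):
        raise ValueError("bin_edges must be strictly monotone with >= 2 values")
    if edges[0] > edges[-1]:
        edges = edges[::-1]
    rows = []

    def summarize(bin_name, samples):
        meth = promoter_meth_by_gene if bin_name != "normal" else normal_meth_by_gene
        for program in sorted(labels.dropna().unique()):
            genes = labels.index[labels == program]
            sub = meth.loc[meth.index.intersection(genes), samples]
            per_gene = sub.mean(axis=1, skipna=True)
            rows.append(
                (bin_name, program, float(per_gene.mean()) if len(samples) else np.nan,
                 len(samples))
            )

    assignments = pd.cut(global_proxy, bins=edges, right=False, include_lowest=False)
    for interval in assignments.cat.categories:
        samples = list(global_proxy.index[assignments == interval])
        summarize(f"[{interval.left:g},{interval.right:g})", samples)
    if normal_proxy is not None and normal_meth_by_gene is not None:
        summarize("normal", list(normal_proxy.index))
    return pd.DataFrame(rows, columns=["bin", "program", "mean_promoter_meth", "n_samples"])


def flag_demethylated_silent(
    promoter_meth: pd.Series,
    gene_tpm: pd.Series,
    demeth_max: float = 0.40,
    expressed_tpm: float = 2.0,
) -> pd.Index:
    """Tumors with a demethylated promoter but no transcriptional induction.

    These are the samples where demethylation alone was insufficient --
    the signature of a gene whose activation additionally requires a
    transcription factor.
    """
    demeth = promoter_meth < demeth_max
    silent = gene_tpm.reindex(promoter_meth.index) < expressed_tpm
    return promoter_meth.index[(demeth & silent).fillna(False)]
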