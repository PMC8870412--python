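"""Tissue-specificity profiling and expression-program assignment.

Genes that pass the demethylation-induction screen are profiled across a
panel of normal tissues (median TPM per tissue), clustered (Ward linkage,
Euclidean distance on log2(TPM+1) medians), and assigned to one of five
programs:

* ``CG``  -- cancer-germline: maximal expression in testis;
* ``GI``  -- gastrointestinal: maximal in small intestine / colon;
* ``SE``  -- stratified epithelium: maximal in esophagus / skin / vagina;
* ``Low`` -- below 2 TPM in every tissue (assigned before clustering and
  independent of it);
* ``Other`` -- every remaining cluster.

Cluster-to-program labeling is automated: a cluster takes a program's
label when its mean profile attains its maximum in one of that program's
marker tissues.  The marker sets are configuration, not code.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .core import CpGMethylationTrack, ExpressionMatrix, promoter_methylation_level, promoter_region

DEFAULT_MARKERS: dict[str, frozenset[str]] = {
    "CG": frozenset({"testis"}),
    "GI": frozenset({"small_intestine", "colon"}),
    "SE": frozenset({"esophagus", "skin", "vagina"}),
}

LOW_TPM = 2.0


@dataclass
class TissueExpressionProfile:
    """Gene x tissue matrix of median TPM across samples."""

    medians: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.medians.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.medians.columns)


def median_tissue_expression(
    expr: ExpressionMatrix, tissue_of_sample: Mapping[str, str]
) -> TissueExpressionProfile:
    """Median TPM per gene per tissue.

    Every sample must be mapped to a tissue; tissues that end up with zero
    samples are dropped with a warning.
    """
    unmapped = [s for s in expr.sample_ids if s not in tissue_of_sample]
    if unmapped:
        raise ValueError(f"samples without tissue label: {unmapped[:3]}")
    tissues = pd.Series({s: tissue_of_sample[s] for s in expr.sample_ids})
    medians = expr.data.T.groupby(tissues).median().T
    declared = set(tissue_of_sample.values())
    empty = declared - set(medians.columns)
    if empty:
        warnings.warn(f"tissues with zero samples dropped: {sorted(empty)}")
    return TissueExpressionProfile(medians)


def cluster_genes(
    profile: TissueExpressionProfile,
    k: int | None = None,
    height: float | None = None,
    transform: str = "log2p1",
) -> tuple[pd.Series, np.ndarray]:
    """Ward / Euclidean agglomerative clustering of gene tissue profiles.

    Distances are computed on log2(TPM+1)-transformed medians by default
    (``transform="raw"`` uses the medians as-is).  Cut either at ``k``
    clusters or at a dendrogram ``height``.  Returns (labels, linkage
    matrix).  A constant matrix yields a single cluster with a warning.
    """
    if len(profile.gene_ids) < 2:
        raise ValueError("need at least 2 genes to cluster")
    if transform not in ("log2p1", "raw"):
        raise ValueError(f"unknown transform {transform!r}")
    X = profile.medians.to_numpy(dtype=float)
    if transform == "log2p1":
        X = np.log2(X + 1.0)
    if np.ptp(X) == 0:
        warnings.warn("constant expression matrix: single cluster")
        return pd.Series(1, index=profile.medians.index), np.empty((0, 4))
    Z = hierarchy.linkage(X, method="ward")
    if k is not None:
        labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    elif height is not None:
        labels = hierarchy.fcluster(Z, t=height, criterion="distance")
    else:
        raise ValueError("provide either k or height")
    return pd.Series(labels, index=profile.medians.index, name="cluster"), Z


@dataclass
class ProgramAssignment:
    labels: pd.Series        # gene -> CG | GI | SE | Other | Low
    clusters: pd.Series      # gene -> cluster id
    cluster_labels: dict[int, str]


def assign_programs(
    profile: TissueExpressionProfile,
    clusters: pd.Series,
    markers: Mapping[str, frozenset[str]] | None = None,
    low_tpm: float = LOW_TPM,
) -> ProgramAssignment:
    """Label genes with their expression program.

    ``Low`` is decided gene-by-gene from the 2 TPM ceiling and overrides
    whatever cluster the gene fell into.  Each remaining cluster is labeled
    with the program whose marker tissue hosts the maximum of the cluster's
    mean log2(TPM+1) profile, or ``Other`` when that maximum lies outside
    every marker set.  Marker sets must not overlap.
    """
    markers = dict(markers or DEFAULT_MARKERS)
    seen: set[str] = set()
    for label, tissues in markers.items():
        if seen & set(tissues):
            raise ValueError(f"marker tissue sets overlap at program {label!r}")
        seen |= set(tissues)
    unknown = seen - set(profile.tissue_ids)
    if unknown:
        warnings.warn(f"marker tissues absent from the profile: {sorted(unknown)}")

    logm = np.log2(profile.medians + 1.0)
    cluster_labels: dict[int, str] = {}
    for cid in sorted(clusters.unique()):
        member_genes = clusters.index[clusters == cid]
        mean_profile = logm.loc[member_genes].mean(axis=0)
        top_tissue = mean_profile.idxmax()
        label = "Other"
        for program, tissues in markers.items():
            if top_tissue in tissues:
                label = program
                break
        cluster_labels[int(cid)] = label

    labels = clusters.map(lambda c: cluster_labels[int(c)]).astype(object)
    low = profile.medians.max(axis=1) < low_tpm
    labels[low.reindex(labels.index).fillna(False)] = "Low"
    labels.name = "program"
    return ProgramAssignment(labels=labels, clusters=clusters, cluster_labels=cluster_labels)


def promoter_cpg_density(
    regions: Sequence,
    cpg_positions: Mapping[str, np.ndarray],
    labels: pd.Series | None = None,
) -> tuple[pd.Series, pd.DataFrame | None]:
    """CpG count per promoter window, plus a per-program mean +/- SD summary.

    ``cpg_positions`` maps chromosome -> sorted array of CpG (C) positions.
    The count covers [start, end).  When ``labels`` is given the summary
    frame has one row per program with columns mean, sd, n.
    """
    counts = {}
    for region in regions:
        pos = np.asarray(cpg_positions.get(region.chromosome, ()), dtype=np.int64)
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        counts[region.transcript_id] = int(hi - lo)
    counts = pd.Series(counts, name="n_cpgs")
    if labels is None:
        return counts, None
    joined = pd.DataFrame({"n_cpgs": counts, "program": labels.reindex(counts.index)})
    summary = joined.groupby("program")["n_cpgs"].agg(mean="mean", sd="std", n="size")
    return counts, summary


def cross_tissue_meth_expr_table(
    regions: Sequence,
    tissue_tracks: Mapping[str, CpGMethylationTrack],
    profile: TissueExpressionProfile,
    gene_of_region: Mapping[str, str] | None = None,
    min_cpgs: int = 3,
    min_coverage: int = 2,
) -> pd.DataFrame:
    """Long table pairing promoter methylation and expression per tissue.

    One row per (gene, tissue) with columns ``promoter_meth`` (mean beta
    over the window, NaN when MISSING) and ``median_tpm``.  Used to check
    that a tissue-restricted gene is demethylated exactly where it is
    expressed.
    """
    rows = []
    for region in regions:
        gene = (gene_of_region or {}).get(region.transcript_id, region.transcript_id)
        for tissue, track in tissue_tracks.items():
            meth = promoter_methylation_level(
                track, region, min_cpgs=min_cpgs, min_coverage=min_coverage
            )
            tpm = (
                float(profile.medians.at[gene, tissue])
                if gene in profile.medians.index and tissue in profile.medians.columns
                else np.nan
            )
            rows.append((gene, tissue, meth, tpm))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "promoter_meth", "median_tpm"])
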