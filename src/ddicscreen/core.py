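"""Domain types and shared numerics.

Coordinates are 0-based half-open throughout the package; 1-based inputs
(array probe manifests) are converted on read.  Methylation beta values are
fractions in [0, 1].  Missing quantities (a promoter without enough
qualifying CpGs, an undefined correlation) are represented as NaN, never as
an exception: MISSING is a value.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

MISSING = float("nan")

EXPRESSED_TPM = 2.0   # positive call
REPRESSED_TPM = 1.0   # negative call


@dataclass(frozen=True)
class TranscriptModel:
    """One promoter-bearing transcript, the unit of screening.

    ``tss`` is the 0-based position of the transcription start site.
    ``referenced`` distinguishes annotated transcripts from variants
    discovered upstream of this package.
    """

    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    tss: int
    referenced: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be non-negative")


@dataclass(frozen=True)
class PromoterRegion:
    """Symmetric window around a TSS (0-based half-open)."""

    transcript_id: str
    chromosome: str
    start: int
    end: int


def promoter_region(
    transcript_id: str, chromosome: str, tss: int, flank: int = 400
) -> PromoterRegion:
    """Window of ``flank`` bp on each side of the TSS, clipped at zero.

    The window is symmetric irrespective of strand; strand only matters for
    choosing the reference TSS when merging nearby start sites.
    """
    return PromoterRegion(transcript_id, chromosome, max(0, tss - flank), tss + flank)


class CpGMethylationTrack:
    """Per-sample CpG methylation calls.

    Holds one row per CpG with columns ``chrom``, ``pos``, ``beta`` and
    ``coverage`` (float; NaN when the source format carries no read counts).
    Rows are kept sorted by (chrom, pos) and indexed per chromosome for fast
    window queries.
    """

    def __init__(self, sample_id: str, calls: pd.DataFrame):
        expected = ["chrom", "pos", "beta", "coverage"]
        missing = [c for c in expected if c not in calls.columns]
        if missing:
            raise ValueError(f"calls frame missing columns {missing}")
        calls = calls[expected].sort_values(["chrom", "pos"], kind="mergesort")
        calls = calls.reset_index(drop=True)
        bad = calls["beta"][(calls["beta"] < 0) | (calls["beta"] > 1)]
        if len(bad):
            raise ValueError(f"beta outside [0,1]: {bad.iloc[0]}")
        dup = calls.duplicated(subset=["chrom", "pos"])
        if dup.any():
            raise ValueError("duplicate CpG position after strand merging")
        self.sample_id = sample_id
        self.calls = calls
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in calls.groupby("chrom", sort=False):
            self._index[str(chrom)] = (
                sub["pos"].to_numpy(dtype=np.int64),
                sub["beta"].to_numpy(dtype=float),
                sub["coverage"].to_numpy(dtype=float),
            )

    def __len__(self) -> int:
        return len(self.calls)

    @property
    def has_coverage(self) -> bool:
        return bool(np.isfinite(self.calls["coverage"]).any()) if len(self) else False

    def window(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        """(betas, coverages) of CpGs with start <= pos < end."""
        entry = self._index.get(chrom)
        if entry is None:
            return np.empty(0), np.empty(0)
        pos, beta, cov = entry
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return beta[lo:hi], cov[lo:hi]


@dataclass
class ExpressionMatrix:
    """Features x samples expression table with a declared unit."""

    data: pd.DataFrame
    units: str = "TPM"

    def __post_init__(self) -> None:
        if self.units not in ("TPM", "FPKM"):
            raise ValueError(f"units must be TPM or FPKM, got {self.units!r}")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


def fpkm_to_tpm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample column to sum to 1e6 (FPKM -> TPM).

    Within-sample rank order of features is preserved; zero entries stay
    zero.  An all-zero sample column is an error naming the sample, since no
    proportion can be formed for it.
    """
    if matrix.units != "FPKM":
        raise ValueError(f"expected FPKM input, got {matrix.units}")
    sums = matrix.data.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero expression column: {zero.index[0]!r}")
    tpm = matrix.data.div(sums, axis=1) * 1e6
    return ExpressionMatrix(tpm, units="TPM")


def call_expression_status(tpm: float, *, positive_min: float = EXPRESSED_TPM,
                           negative_max: float = REPRESSED_TPM) -> str:
    """Three-way expression call: positive (>= 2 TPM), negative (< 1 TPM),
    indeterminate in between."""
    if tpm < 0:
        raise ValueError("TPM must be non-negative")
    if tpm >= positive_min:
        return "positive"
    if tpm < negative_max:
        return "negative"
    return "indeterminate"


def promoter_methylation_level(
    track: CpGMethylationTrack,
    region: PromoterRegion,
    *,
    min_cpgs: int = 3,
    min_coverage: int = 2,
) -> float:
    """Unweighted mean beta over qualifying CpGs in the promoter window.

    A CpG qualifies when its coverage is at least ``min_coverage``; calls
    without coverage information (NaN coverage) are always admitted, so the
    coverage filter only applies where the data can support it.  Returns NaN
    (MISSING) when fewer than ``min_cpgs`` CpGs qualify.
    """
    betas, covs = track.window(region.chromosome, region.start, region.end)
    ok = ~(covs < min_coverage)  # NaN coverage compares False -> admitted
    betas = betas[ok]
    if len(betas) < min_cpgs:
        return MISSING
    return float(betas.mean())


def pearson_with_p(x: Iterable[float], y: Iterable[float]) -> tuple[float, float, int]:
    """Pearson r with two-sided p, after pairwise deletion of missing values.

    Returns ``(r, p, n)`` where n is the number of complete pairs.  When
    n < 3 or either vector is constant the correlation is undefined and
    ``(nan, nan, n)`` is returned.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = int(mask.sum())
    if n < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return MISSING, MISSING, n
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n
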