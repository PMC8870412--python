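"""Readers and writers for the plain-text formats the pipeline consumes.

Supported formats:

* transcript models -- 6-column TSV (transcript_id, gene_id, chromosome,
  tss, strand, referenced) or BED6;
* CpG methylation -- 4-column bedGraph (chrom, start, end, percent) or
  Bismark coverage (chrom, start, end, percent, count_methylated,
  count_unmethylated);
* expression matrices -- TSV, first column feature id, header row samples;
* Infinium-style probe manifests -- TSV with 1-based positions, converted
  to the package's 0-based convention on read;
* clinical tables -- TSV with sample class, grade, survival time, event.

Forward/reverse bisulfite calls at complementary CpG positions (p and p+1
on the same chromosome) are merged on read by coverage-weighted average and
assigned to the C of the + strand, so a track holds one call per CpG site.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CpGMethylationTrack, ExpressionMatrix, TranscriptModel

SEX_CHROMOSOMES = {"chrX", "chrY", "X", "Y"}


# ---------------------------------------------------------------------------
# transcript models

def read_transcripts(path: str | Path) -> list[TranscriptModel]:
    """Read the 6-column transcript TSV (with header)."""
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"transcript_id", "gene_id", "chromosome", "tss", "strand", "referenced"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        TranscriptModel(
            transcript_id=str(r.transcript_id),
            gene_id=str(r.gene_id),
            chromosome=str(r.chromosome),
            strand=str(r.strand),
            tss=int(r.tss),
            referenced=bool(r.referenced),
        )
        for r in df.itertuples(index=False)
    ]


def write_transcripts(transcripts: list[TranscriptModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (t.transcript_id, t.gene_id, t.chromosome, t.tss, t.strand, t.referenced)
            for t in transcripts
        ],
        columns=["transcript_id", "gene_id", "chromosome", "tss", "strand", "referenced"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_transcripts_bed6(path: str | Path) -> list[TranscriptModel]:
    """Import BED6: the TSS is ``start`` on + and ``end - 1`` on -.

    BED has no gene column, so the name field doubles as both transcript and
    gene id.
    """
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "#")):
            continue
        parts = line.split("\t")
        if len(parts) < 6:
            raise ValueError(f"{path}:{lineno}: expected 6 BED columns")
        chrom, start, end, name, _score, strand = parts[:6]
        tss = int(start) if strand == "+" else int(end) - 1
        out.append(TranscriptModel(name, name, chrom, strand, tss))
    return out


# ---------------------------------------------------------------------------
# methylation tracks

def _merge_strand_pairs(df: pd.DataFrame) -> pd.DataFrame:
    """Merge calls at complementary positions (p, p+1) onto p.

    Pairing is greedy from the left within each chromosome, so a run
    p, p+1, p+2 merges (p, p+1) and leaves p+2 alone; re-reading a merged
    track is therefore a no-op.
    """
    pieces = []
    for chrom, sub in df.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        beta = sub["beta"].to_numpy(dtype=float)
        cov = sub["coverage"].to_numpy(dtype=float)
        keep_pos, keep_beta, keep_cov = [], [], []
        i = 0
        while i < len(pos):
            if i + 1 < len(pos) and pos[i + 1] == pos[i] + 1:
                b1, b2, c1, c2 = beta[i], beta[i + 1], cov[i], cov[i + 1]
                if np.isfinite(c1) and np.isfinite(c2) and (c1 + c2) > 0:
                    merged_beta = (b1 * c1 + b2 * c2) / (c1 + c2)
                    merged_cov = c1 + c2
                else:
                    merged_beta = (b1 + b2) / 2.0
                    merged_cov = np.nansum([c1, c2]) if (
                        np.isfinite(c1) or np.isfinite(c2)) else np.nan
                keep_pos.append(pos[i])
                keep_beta.append(merged_beta)
                keep_cov.append(merged_cov)
                i += 2
            else:
                keep_pos.append(pos[i])
                keep_beta.append(beta[i])
                keep_cov.append(cov[i])
                i += 1
        pieces.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": keep_pos, "beta": keep_beta, "coverage": keep_cov}
            )
        )
    if not pieces:
        return df
    return pd.concat(pieces, ignore_index=True)


def read_methylation_track(
    path: str | Path, dialect: str, sample_id: str | None = None
) -> CpGMethylationTrack:
    """Read a per-sample CpG track.

    ``dialect`` must be ``"bedgraph"`` (4 columns, value is a percent,
    0-based half-open intervals, no coverage) or ``"bismark"`` (Bismark
    coverage format: chrom, start, end, percent, count_methylated,
    count_unmethylated; positions taken as given).  Percent values outside
    [0, 100] and malformed lines raise ``ValueError`` naming the line.
    """
    if dialect not in ("bedgraph", "bismark"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    sample_id = sample_id or path.stem
    chroms: list[str] = []
    positions: list[int] = []
    betas: list[float] = []
    covs: list[float] = []
    n_fields = 4 if dialect == "bedgraph" else 6
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("track", "#")):
            continue
        parts = line.split()
        if len(parts) < n_fields:
            raise ValueError(f"{path}:{lineno}: expected {n_fields} fields, got {len(parts)}")
        try:
            chrom = parts[0]
            pos = int(parts[1])
            percent = float(parts[3])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed line: {exc}") from None
        if not 0.0 <= percent <= 100.0:
            raise ValueError(f"{path}:{lineno}: methylation percent outside [0,100]: {percent}")
        if dialect == "bismark":
            try:
                n_meth, n_unmeth = int(parts[4]), int(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed counts: {exc}") from None
            if n_meth < 0 or n_unmeth < 0:
                raise ValueError(f"{path}:{lineno}: negative read count")
            cov = float(n_meth + n_unmeth)
            beta = n_meth / cov if cov > 0 else percent / 100.0
        else:
            cov = np.nan
            beta = percent / 100.0
        chroms.append(chrom)
        positions.append(pos)
        betas.append(beta)
        covs.append(cov)
    calls = pd.DataFrame(
        {"chrom": pd.Series(chroms, dtype=str),
         "pos": pd.Series(positions, dtype=np.int64),
         "beta": betas, "coverage": covs}
    )
    calls = calls.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    calls = _merge_strand_pairs(calls)
    return CpGMethylationTrack(sample_id, calls)


def write_methylation_track(
    track: CpGMethylationTrack, path: str | Path, dialect: str
) -> None:
    """Write a track back out in either dialect.

    Bismark counts are reconstructed as ``round(beta * coverage)``
    methylated reads, which inverts the read-side division exactly, so a
    read -> write -> read cycle is the identity.
    """
    if dialect not in ("bedgraph", "bismark"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = []
    for row in track.calls.itertuples(index=False):
        pct = row.beta * 100.0
        if dialect == "bedgraph":
            lines.append(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t{pct:.17g}")
        else:
            cov = row.coverage
            if not np.isfinite(cov):
                raise ValueError(
                    "cannot write bismark coverage format for a track without coverage"
                )
            n_meth = int(round(row.beta * cov))
            n_unmeth = int(cov) - n_meth
            lines.append(
                f"{row.chrom}\t{row.pos}\t{row.pos}\t{pct:.17g}\t{n_meth}\t{n_unmeth}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# expression matrices

def read_expression(path: str | Path, units: str = "TPM") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df, units=units)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# probe manifests, beta tables, clinical tables

def read_probe_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest TSV (probe_id, chromosome, pos_1based) -> indexed frame.

    Positions are converted to 0-based; an ``autosomal`` column is derived
    from the chromosome name.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    required = {"probe_id", "chromosome", "pos_1based"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate probe ids")
    out = pd.DataFrame(
        {
            "chromosome": df["chromosome"].astype(str).to_numpy(),
            "pos": df["pos_1based"].astype(np.int64).to_numpy() - 1,
        },
        index=pd.Index(df["probe_id"].astype(str), name="probe_id"),
    )
    out["autosomal"] = ~out["chromosome"].isin(SEX_CHROMOSOMES)
    return out


def write_probe_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "probe_id": manifest.index,
            "chromosome": manifest["chromosome"].to_numpy(),
            "pos_1based": manifest["pos"].to_numpy() + 1,
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_beta_table(path: str | Path) -> pd.DataFrame:
    """Probe x sample beta matrix; values in [0,1] or empty (missing)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    vals = df.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if len(finite) and ((finite < 0).any() or (finite > 1).any()):
        raise ValueError(f"{path}: beta values outside [0,1]")
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical TSV indexed by sample: sample_class, grade, survival_time, event."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    required = {"sample_class", "grade", "survival_time", "event"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def warn_unmatched(ids_present: set[str], ids_expected: set[str], what: str) -> None:
    extra = ids_present - ids_expected
    if extra:
        warnings.warn(
            f"{len(extra)} {what} not found in the transcript models; excluded "
            f"(e.g. {sorted(extra)[:3]})",
            stacklevel=3,
        )
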