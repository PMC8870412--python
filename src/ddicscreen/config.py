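"""Screen configuration.

All thresholds of the cell-line screen live in a single frozen dataclass so
that a run is fully described by one object, and so that property tests can
tighten individual thresholds and check monotonicity of the selection.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds and parameters of the demethylation-induction screen.

    Methylation levels are beta fractions in [0, 1]; expression values are
    TPM.  Defaults reproduce the published screening procedure: promoters are
    TSS +/- 400 bp windows, a promoter is "methylated" at beta >= 0.60 and
    "demethylated" at beta < 0.40, expression is called positive at >= 2 TPM
    and negative below 1 TPM, and the inverse-correlation gate is
    r <= -0.4 at p < 0.05 over at least 7 paired cell lines.
    """

    tss_merge_bp: int = 50
    promoter_flank_bp: int = 400
    min_cpgs: int = 3
    min_coverage: int = 2
    methylated_min: float = 0.60
    demeth_max: float = 0.40
    expressed_tpm: float = 2.0
    repressed_tpm: float = 1.0
    q10_repressed_tpm: float = 0.1
    min_repressed_lines: int = 2
    min_paired: int = 7
    ddic_r_max: float = -0.4
    ddic_p_max: float = 0.05
    nonddic_r_band: tuple[float, float] = (-0.1, 0.1)
    gtex_median_max: float = 0.5
    # p-value gate at the correlation stage: "raw" gates on the unadjusted
    # p; "bh" gates on the Benjamini-Hochberg adjusted value.  Both columns
    # are always reported.
    p_gate: str = "raw"

    def __post_init__(self) -> None:
        if not (0.0 <= self.demeth_max < self.methylated_min <= 1.0):
            raise ValueError(
                "require 0 <= demeth_max < methylated_min <= 1, got "
                f"{self.demeth_max} / {self.methylated_min}"
            )
        if self.repressed_tpm > self.expressed_tpm:
            raise ValueError("repressed_tpm must not exceed expressed_tpm")
        lo, hi = self.nonddic_r_band
        if lo > hi:
            raise ValueError("nonddic_r_band must be (low, high)")
        if self.p_gate not in ("raw", "bh"):
            raise ValueError(f"unknown p_gate {self.p_gate!r}")
        if not 0.0 <= self.ddic_p_max <= 1.0:
            raise ValueError("ddic_p_max must be a probability")


def _coerce(name: str, raw: str, target_type):
    if target_type is int:
        return int(raw)
    if target_type is float:
        return float(raw)
    if target_type is str:
        return raw
    # tuple[float, float] -- comma separated pair
    parts = [p for p in raw.replace("(", "").replace(")", "").split(",") if p]
    if len(parts) != 2:
        raise ValueError(f"key {name}: expected two comma-separated values, got {raw!r}")
    return (float(parts[0]), float(parts[1]))


def load_config(path: str | Path) -> ScreenConfig:
    """Load a ScreenConfig from a plain-text ``key=value`` file.

    Blank lines and ``#`` comments are ignored.  Unknown keys raise
    ``ValueError`` rather than being silently dropped.
    """
    valid = {f.name: f for f in dataclasses.fields(ScreenConfig)}
    overrides = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key not in valid:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        ftype = valid[key].type
        py_type = {"int": int, "float": float, "str": str}.get(str(ftype), tuple)
        overrides[key] = _coerce(key, raw, py_type)
    return ScreenConfig(**overrides)


def save_config(config: ScreenConfig, path: str | Path) -> None:
    lines = []
    for f in dataclasses.fields(config):
        value = getattr(config, f.name)
        if isinstance(value, tuple):
            value = ",".join(str(v) for v in value)
        lines.append(f"{f.name}={value}")
    Path(path).write_text("\n".join(lines) + "\n")
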