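"""Synthetic cohorts with planted ground truth.

Every pipeline stage is testable without external downloads: this module
fabricates a cell-line panel (expression + per-line CpG methylation), a
normal-tissue panel, and a tumor cohort with array probes and clinical
covariates, all from a single seeded scenario, and returns a sidecar with
the planted truth (which genes are demethylation-induced, which tumors are
demethylated, which clinical effects exist).

The noise model is deliberately minimal: methylation states are Beta
distributed (methylated ~ Beta(17, 3), mean 0.85; demethylated ~
Beta(3, 17), mean 0.15), expression is lognormal (active median 20 TPM,
silent median 0.05 TPM, sigma = 1 on the log2 scale), and sequencing
coverage is Poisson.  Tumor-wide demethylation is a per-tumor factor
h ~ Uniform(0, 0.4) subtracted from background probe betas; a gene's
promoter demethylates when h times its demethylation sensitivity exceeds a
gene-specific threshold, which reproduces the ordering where
high-sensitivity gene categories demethylate already at mild genome-wide
hypomethylation.  Genes may additionally be gated on a simulated
transcription factor: their expression turns on only when the promoter is
demethylated AND the factor is expressed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import CpGMethylationTrack, ExpressionMatrix, TranscriptModel

DDIC_CLASSES = ("DDIC_CG", "DDIC_GI", "DDIC_SE", "DDIC_Other", "DDIC_Low")
TRUTH_CLASSES = DDIC_CLASSES + ("nonDDIC", "null_silent", "null_expressed")

MARKERS = {
    "DDIC_CG": ("testis",),
    "DDIC_GI": ("small_intestine", "colon"),
    "DDIC_SE": ("esophagus", "skin", "vagina"),
}
EXTRA_TISSUES = ("stomach", "liver", "heart", "brain")

TF_GENE = "TF1"


@dataclass(frozen=True)
class GeneSpec:
    """Planted truth for one simulated gene."""

    gene_id: str
    truth_class: str
    marker_tissues: tuple[str, ...] = ()
    demeth_sensitivity: float = 1.0
    tf_gated: bool = False
    grade_or: float = 1.0
    survival_hr: float = 1.0

    def __post_init__(self) -> None:
        if self.truth_class not in TRUTH_CLASSES:
            raise ValueError(f"unknown truth class {self.truth_class!r}")
        if not 0.0 < self.demeth_sensitivity <= 1.0:
            raise ValueError("demeth_sensitivity must be in (0, 1]")
        if self.grade_or <= 0 or self.survival_hr <= 0:
            raise ValueError("grade_or and survival_hr must be positive")

    @property
    def transcript_id(self) -> str:
        return f"{self.gene_id}_t1"

    @property
    def is_ddic(self) -> bool:
        return self.truth_class in DDIC_CLASSES


def screen_gene_plan(
    n_cg: int = 20, n_gi: int = 5, n_se: int = 5, n_other: int = 4,
    n_low: int = 6, n_nonddic: int = 40, n_null_silent: int = 60,
    n_null_expressed: int = 60,
) -> list[GeneSpec]:
    """Default plan: 40 demethylation-induced genes across tissue programs,
    40 uncorrelated activated controls, 120 null genes."""
    plan: list[GeneSpec] = []

    def add(cls, n, **kw):
        for i in range(n):
            plan.append(GeneSpec(f"{cls}_{i:03d}", cls, **kw))

    add("DDIC_CG", n_cg, marker_tissues=MARKERS["DDIC_CG"], demeth_sensitivity=0.5)
    gated = [i < (n_gi + 1) // 2 for i in range(n_gi)]
    for i in range(n_gi):
        plan.append(GeneSpec(
            f"DDIC_GI_{i:03d}", "DDIC_GI", marker_tissues=MARKERS["DDIC_GI"],
            demeth_sensitivity=0.9, tf_gated=gated[i],
        ))
    add("DDIC_SE", n_se, marker_tissues=MARKERS["DDIC_SE"], demeth_sensitivity=0.85)
    for i in range(n_other):
        tissues = (EXTRA_TISSUES[i % 4], EXTRA_TISSUES[(i + 1) % 4])
        plan.append(GeneSpec(
            f"DDIC_Other_{i:03d}", "DDIC_Other", marker_tissues=tissues,
            demeth_sensitivity=0.7,
        ))
    add("DDIC_Low", n_low, demeth_sensitivity=0.7)
    add("nonDDIC", n_nonddic)
    add("null_silent", n_null_silent)
    add("null_expressed", n_null_expressed)
    return plan


def program_gene_plan(
    n_cg: int = 44, n_gi: int = 7, n_se: int = 10, n_other: int = 16,
    n_low: int = 26,
) -> list[GeneSpec]:
    """Plan for tissue-program recovery: only demethylation-induced genes,
    with the published category proportions."""
    return screen_gene_plan(
        n_cg=n_cg, n_gi=n_gi, n_se=n_se, n_other=n_other, n_low=n_low,
        n_nonddic=0, n_null_silent=0, n_null_expressed=0,
    )


def clinical_gene_plan(n_null: int = 200) -> list[GeneSpec]:
    """Plan for clinical calibration: many null genes plus one planted
    survival effect (hazard ratio 2) and one planted grade effect (OR 3)."""
    plan = screen_gene_plan(
        n_cg=5, n_gi=2, n_se=2, n_other=0, n_low=0,
        n_nonddic=0, n_null_silent=0, n_null_expressed=n_null,
    )
    plan.append(GeneSpec("EFFECT_HR2", "null_expressed", survival_hr=2.0))
    plan.append(GeneSpec("EFFECT_OR3", "null_expressed", grade_or=3.0))
    return plan


@dataclass
class SimulationScenario:
    """Study conditions for the synthetic cohorts.

    Defaults emulate the source study's design: 26 tumor cell lines, a
    tumor cohort of 300 with 32 matched normals, Beta-distributed
    methylation states, lognormal TPM, Poisson(30) coverage, and a
    genome-wide demethylation factor up to 0.4.
    """

    seed: int = 17
    n_cell_lines: int = 26
    n_tumors: int = 300
    n_normals: int = 32
    gene_plan: list[GeneSpec] = field(default_factory=screen_gene_plan)
    beta_meth_state: tuple[float, float] = (17.0, 3.0)
    beta_demeth_state: tuple[float, float] = (3.0, 17.0)
    beta_background: tuple[float, float] = (136.0, 24.0)
    active_expr_median: float = 20.0
    silent_expr_median: float = 0.05
    expr_sigma_log2: float = 1.0
    coverage_mean: float = 30.0
    global_demeth_max: float = 0.4
    n_background_probes: int = 5000
    n_x_probes: int = 50
    probeless_fraction: float = 0.2
    tissues: tuple[str, ...] = (
        "testis", "small_intestine", "colon", "esophagus", "skin", "vagina",
        "lung", "stomach", "liver", "heart", "brain",
    )
    samples_per_tissue: int = 4
    tissue_noise_sigma_log2: float = 0.25
    tf_positive_fraction: float = 0.30
    baseline_hazard_per_day: float = 1.0 / 1500.0
    study_length_days: float = 4000.0
    grade_high_base: float = 0.45

    def __post_init__(self) -> None:
        for shapes in (self.beta_meth_state, self.beta_demeth_state, self.beta_background):
            if min(shapes) <= 0:
                raise ValueError("Beta shape parameters must be positive")
        if self.n_cell_lines < 7:
            raise ValueError("need at least 7 cell lines for the correlation stage")


# ---------------------------------------------------------------------------
# genome


@dataclass
class SyntheticGenome:
    transcripts: list[TranscriptModel]
    cpg_positions: dict[str, np.ndarray]       # chrom -> sorted C positions
    manifest: pd.DataFrame                     # probe_id-indexed
    truth: pd.DataFrame                        # gene_id-indexed sidecar
    promoter_probes: dict[str, list[str]]      # gene -> probe ids in window

    def transcript_of(self, gene_id: str) -> TranscriptModel:
        tid = f"{gene_id}_t1"
        for t in self.transcripts:
            if t.transcript_id == tid:
                return t
        raise KeyError(gene_id)


def generate_genome(scenario: SimulationScenario) -> SyntheticGenome:
    """Lay out one transcript per planted gene, with promoter CpGs and probes.

    Genes are spread over the 22 autosomes, 10 kb apart.  Germline-program
    promoters carry 10-40 CpGs; all other classes carry ~14 (Poisson,
    floored at 3), matching the observation that the somatic-program
    promoters are CpG-poorer.  One to two array probes are placed inside
    each promoter window except for a held-out probeless subset, plus a
    constitutively methylated autosomal background and a small X-chromosome
    control set.
    """
    rng = np.random.default_rng(scenario.seed)
    chroms = [f"chr{i}" for i in range(1, 23)]
    transcripts: list[TranscriptModel] = []
    cpg_positions: dict[str, list[int]] = {c: [] for c in chroms}
    truth_rows = []
    promoter_probes: dict[str, list[str]] = {}
    probe_rows = []
    per_chrom_count: dict[str, int] = {c: 0 for c in chroms}

    for idx, spec in enumerate(scenario.gene_plan):
        chrom = chroms[idx % len(chroms)]
        tss = 1_000_000 + 10_000 * per_chrom_count[chrom]
        per_chrom_count[chrom] += 1
        strand = "+" if idx % 2 == 0 else "-"
        transcripts.append(
            TranscriptModel(spec.transcript_id, spec.gene_id, chrom, strand, tss)
        )
        if spec.truth_class == "DDIC_CG":
            n_cpgs = int(rng.integers(10, 41))
        else:
            n_cpgs = max(3, int(rng.poisson(14)))
        # CpGs on an even grid so strand-merged positions stay >= 2 bp apart
        grid = np.arange(max(0, tss - 400), tss + 400, 2)
        pos = np.sort(rng.choice(grid, size=min(n_cpgs, len(grid)), replace=False))
        cpg_positions[chrom].extend(int(p) for p in pos)

        probeless = rng.random() < scenario.probeless_fraction
        gene_probes: list[str] = []
        if not probeless and len(pos):
            n_probes = int(rng.integers(1, 3))
            probe_pos = rng.choice(pos, size=min(n_probes, len(pos)), replace=False)
            for k, pp in enumerate(np.sort(probe_pos)):
                pid = f"cgP_{spec.gene_id}_{k}"
                probe_rows.append((pid, chrom, int(pp), True))
                gene_probes.append(pid)
        promoter_probes[spec.gene_id] = gene_probes

        truth_rows.append((
            spec.gene_id, spec.transcript_id, spec.truth_class, chrom, tss, strand,
            len(pos), len(gene_probes), ",".join(spec.marker_tissues),
            spec.demeth_sensitivity, spec.tf_gated, spec.grade_or, spec.survival_hr,
            float(rng.uniform(0.05, 0.15)),   # demethylation threshold in tumors
        ))

    for i in range(scenario.n_background_probes):
        chrom = chroms[i % len(chroms)]
        probe_rows.append((f"cgB_{i:06d}", chrom, 50_000_000 + 1_000 * i, True))
    for i in range(scenario.n_x_probes):
        probe_rows.append((f"cgX_{i:04d}", "chrX", 10_000_000 + 1_000 * i, False))

    manifest = pd.DataFrame(
        probe_rows, columns=["probe_id", "chromosome", "pos", "autosomal"]
    ).set_index("probe_id")
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "transcript_id", "truth_class", "chromosome", "tss",
                 "strand", "n_cpgs", "n_promoter_probes", "marker_tissues",
                 "demeth_sensitivity", "tf_gated", "grade_or", "survival_hr",
                 "demeth_threshold"],
    ).set_index("gene_id")
    return SyntheticGenome(
        transcripts=transcripts,
        cpg_positions={c: np.array(sorted(v), dtype=np.int64) for c, v in cpg_positions.items()},
        manifest=manifest,
        truth=truth,
        promoter_probes=promoter_probes,
    )


# ---------------------------------------------------------------------------
# shared draws

def _active_tpm(rng, scenario, size):
    return scenario.active_expr_median * np.exp2(
        rng.normal(0.0, scenario.expr_sigma_log2, size)
    )


def _silent_tpm(rng, scenario, size):
    return scenario.silent_expr_median * np.exp2(
        rng.normal(0.0, scenario.expr_sigma_log2, size)
    )


def _beta(rng, shapes, size):
    return rng.beta(shapes[0], shapes[1], size)


# ---------------------------------------------------------------------------
# cell-line panel


@dataclass
class CellLinePanel:
    expression: ExpressionMatrix              # transcripts x lines (TPM)
    tracks: dict[str, CpGMethylationTrack]    # line -> track
    silent_truth: pd.DataFrame                # gene x line, True where silent


def generate_cell_line_panel(
    scenario: SimulationScenario, genome: SyntheticGenome
) -> CellLinePanel:
    """Expression and promoter methylation for the tumor cell-line panel.

    Demethylation-induced genes are silent and promoter-methylated in a
    random subset of 8-20 lines and active with a demethylated promoter in
    the rest, which plants the inverse expression/methylation coupling.
    Uncorrelated controls toggle expression on the same pattern while their
    promoters stay methylated; their per-line promoter means are then
    residualized against log-expression so the planted sample correlation
    is zero, not merely zero in expectation.  Null genes are uniformly
    silent+methylated or uniformly active+demethylated.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    n = scenario.n_cell_lines
    lines = [f"LUAD_{i + 1:02d}" for i in range(n)]
    expr_rows = {}
    silent_rows = {}
    per_line_calls: dict[str, list[pd.DataFrame]] = {ln: [] for ln in lines}

    for spec in scenario.gene_plan:
        t = genome.transcript_of(spec.gene_id)
        chrom_pos = genome.cpg_positions[t.chromosome]
        window = chrom_pos[(chrom_pos >= t.tss - 400) & (chrom_pos < t.tss + 400)]
        n_cpgs = len(window)

        if spec.truth_class in ("null_silent",):
            silent = np.ones(n, dtype=bool)
        elif spec.truth_class in ("null_expressed",):
            silent = np.zeros(n, dtype=bool)
        else:
            k = int(rng.integers(8, 21))
            silent = np.zeros(n, dtype=bool)
            silent[rng.choice(n, size=k, replace=False)] = True

        expr = np.where(
            silent, _silent_tpm(rng, scenario, n), _active_tpm(rng, scenario, n)
        )

        betas = np.empty((n_cpgs, n))
        if spec.is_ddic:
            meth_cols = silent
        elif spec.truth_class == "null_expressed":
            meth_cols = np.zeros(n, dtype=bool)
        else:  # nonDDIC and null_silent stay methylated throughout
            meth_cols = np.ones(n, dtype=bool)
        betas[:, meth_cols] = _beta(rng, scenario.beta_meth_state, (n_cpgs, int(meth_cols.sum())))
        betas[:, ~meth_cols] = _beta(
            rng, scenario.beta_demeth_state, (n_cpgs, int((~meth_cols).sum()))
        )

        if spec.truth_class == "nonDDIC" and n_cpgs > 0:
            # plant zero sample correlation between promoter mean and
            # log-expression by removing the fitted linear component
            x = np.log2(expr + 1.0)
            m = betas.mean(axis=0)
            xc = x - x.mean()
            denom = float(xc @ xc)
            if denom > 0:
                delta = -(m - m.mean()) @ xc / denom * xc
                betas = np.clip(betas + delta[None, :], 0.0, 1.0)

        coverage = rng.poisson(scenario.coverage_mean, (n_cpgs, n)) + 1
        for j, ln in enumerate(lines):
            per_line_calls[ln].append(
                pd.DataFrame(
                    {"chrom": t.chromosome, "pos": window,
                     "beta": betas[:, j], "coverage": coverage[:, j].astype(float)}
                )
            )
        expr_rows[spec.transcript_id] = expr
        silent_rows[spec.gene_id] = silent

    expression = ExpressionMatrix(
        pd.DataFrame(expr_rows, index=lines).T, units="TPM"
    )
    tracks = {
        ln: CpGMethylationTrack(ln, pd.concat(per_line_calls[ln], ignore_index=True))
        for ln in lines
    }
    silent_truth = pd.DataFrame(silent_rows, index=lines).T
    return CellLinePanel(expression=expression, tracks=tracks, silent_truth=silent_truth)


# ---------------------------------------------------------------------------
# normal-tissue panel


@dataclass
class NormalPanel:
    gtex_expression: ExpressionMatrix          # genes x samples
    tissue_of_sample: dict[str, str]
    reference_expression: ExpressionMatrix     # transcripts x [roadmap_lung, AT2]
    reference_tracks: dict[str, CpGMethylationTrack]
    tissue_tracks: dict[str, CpGMethylationTrack]


def _active_tissues(spec: GeneSpec, all_tissues: Sequence[str]) -> set[str]:
    if spec.truth_class == "null_expressed":
        return set(all_tissues)
    return set(spec.marker_tissues)


def generate_normal_panel(
    scenario: SimulationScenario, genome: SyntheticGenome
) -> NormalPanel:
    """Tissue-restricted expression and demethylation for normal tissues.

    Each demethylation-induced gene is active (median >= 2 TPM) and
    promoter-demethylated only in its marker tissues; lung is always
    silent and methylated for planted genes, so the normal-reference stage
    of the screen passes.  With ``tissue_noise_sigma_log2 = 0`` the panel
    is noiseless: every sample equals the gene's planted tissue level.
    """
    rng = np.random.default_rng(scenario.seed + 2)
    tissues = list(scenario.tissues)
    samples = [(t, f"{t}_{k + 1}") for t in tissues for k in range(scenario.samples_per_tissue)]
    tissue_of_sample = {sid: t for t, sid in samples}
    sigma = scenario.tissue_noise_sigma_log2

    expr_rows = {}
    ref_rows = {}
    tissue_calls: dict[str, list[pd.DataFrame]] = {t: [] for t in tissues}
    ref_calls: dict[str, list[pd.DataFrame]] = {"roadmap_lung": [], "AT2": []}

    for spec in scenario.gene_plan:
        t = genome.transcript_of(spec.gene_id)
        chrom_pos = genome.cpg_positions[t.chromosome]
        window = chrom_pos[(chrom_pos >= t.tss - 400) & (chrom_pos < t.tss + 400)]
        n_cpgs = len(window)
        active_in = _active_tissues(spec, tissues)
        active_level = float(_active_tpm(rng, scenario, 1)[0])
        silent_level = scenario.silent_expr_median

        row = np.empty(len(samples))
        for i, (tissue, _sid) in enumerate(samples):
            level = active_level if tissue in active_in else silent_level
            noise = np.exp2(rng.normal(0.0, sigma)) if sigma > 0 else 1.0
            row[i] = level * noise
        expr_rows[spec.gene_id] = row

        lung_active = "lung" in active_in
        lung_level = active_level if lung_active else silent_level
        noise2 = np.exp2(rng.normal(0.0, sigma, 2)) if sigma > 0 else np.ones(2)
        ref_rows[spec.transcript_id] = lung_level * noise2

        for tissue in tissues:
            state = scenario.beta_demeth_state if tissue in active_in else scenario.beta_meth_state
            tissue_calls[tissue].append(
                pd.DataFrame({"chrom": t.chromosome, "pos": window,
                              "beta": _beta(rng, state, n_cpgs), "coverage": np.nan})
            )
        ref_state = scenario.beta_demeth_state if lung_active else scenario.beta_meth_state
        for ref in ("roadmap_lung", "AT2"):
            cov = (rng.poisson(scenario.coverage_mean, n_cpgs) + 1).astype(float)
            ref_calls[ref].append(
                pd.DataFrame({"chrom": t.chromosome, "pos": window,
                              "beta": _beta(rng, ref_state, n_cpgs), "coverage": cov})
            )

    sample_ids = [sid for _t, sid in samples]
    gtex = ExpressionMatrix(pd.DataFrame(expr_rows, index=sample_ids).T, units="TPM")
    reference = ExpressionMatrix(
        pd.DataFrame(ref_rows, index=["roadmap_lung", "AT2"]).T, units="TPM"
    )
    return NormalPanel(
        gtex_expression=gtex,
        tissue_of_sample=tissue_of_sample,
        reference_expression=reference,
        reference_tracks={
            ref: CpGMethylationTrack(ref, pd.concat(calls, ignore_index=True))
            for ref, calls in ref_calls.items()
        },
        tissue_tracks={
            t: CpGMethylationTrack(t, pd.concat(calls, ignore_index=True))
            for t, calls in tissue_calls.items()
        },
    )


# ---------------------------------------------------------------------------
# tumor cohort


@dataclass
class TumorTruth:
    h: pd.Series                   # per-tumor global demethylation factor
    demethylated: pd.DataFrame     # gene x tumor, True where promoter demethylated
    tf_positive: pd.Series         # per-tumor TF expression state


def generate_tumor_cohort(scenario: SimulationScenario, genome: SyntheticGenome):
    """Tumor cohort with a global hypomethylation gradient and clinical links.

    Per tumor, a demethylation factor h ~ Uniform(0, global_demeth_max) is
    subtracted from the constitutively methylated probe background; a
    gene's promoter switches to the demethylated state when
    h x demeth_sensitivity exceeds its threshold.  Expression turns on
    when the promoter is demethylated and, for factor-gated genes, the
    simulated transcription factor is expressed.  Grade and survival are
    drawn from logistic / exponential models whose odds and hazard are
    multiplied by the planted effect sizes of activated genes.

    Returns ``(TumorCohort, TumorTruth)``.
    """
    from .tumor import TumorCohort  # local import to avoid a cycle

    rng = np.random.default_rng(scenario.seed + 3)
    tumors = [f"TUM_{i + 1:03d}" for i in range(scenario.n_tumors)]
    normals = [f"NL_{i + 1:02d}" for i in range(scenario.n_normals)]
    all_samples = tumors + normals
    n_t, n_n = len(tumors), len(normals)

    h = rng.uniform(0.0, scenario.global_demeth_max, n_t) if scenario.global_demeth_max > 0 \
        else np.zeros(n_t)
    h_all = np.concatenate([h, np.zeros(n_n)])

    manifest = genome.manifest
    beta_rows = {}
    bg_probes = [p for p in manifest.index if p.startswith("cgB_")]
    x_probes = [p for p in manifest.index if p.startswith("cgX_")]
    bg = _beta(rng, scenario.beta_background, (len(bg_probes), len(all_samples)))
    bg = np.clip(bg - h_all[None, :], 0.0, 1.0)
    for i, pid in enumerate(bg_probes):
        beta_rows[pid] = bg[i]
    for pid in x_probes:
        beta_rows[pid] = rng.uniform(0.2, 0.9, len(all_samples))

    tf_on = rng.random(n_t) < scenario.tf_positive_fraction
    expr_rows = {}
    demeth_rows = {}

    for spec in scenario.gene_plan:
        truth = genome.truth.loc[spec.gene_id]
        if spec.is_ddic:
            demeth = h * spec.demeth_sensitivity > truth["demeth_threshold"]
            on = demeth & (tf_on if spec.tf_gated else True)
            expr = np.where(on, _active_tpm(rng, scenario, n_t),
                            _silent_tpm(rng, scenario, n_t))
            expr_normal = _silent_tpm(rng, scenario, n_n)
        elif spec.truth_class == "nonDDIC":
            demeth = np.zeros(n_t, dtype=bool)
            on = rng.random(n_t) < 0.3
            expr = np.where(on, _active_tpm(rng, scenario, n_t),
                            _silent_tpm(rng, scenario, n_t))
            expr_normal = _silent_tpm(rng, scenario, n_n)
        elif spec.truth_class == "null_silent":
            demeth = np.zeros(n_t, dtype=bool)
            expr = _silent_tpm(rng, scenario, n_t)
            expr_normal = _silent_tpm(rng, scenario, n_n)
        else:  # null_expressed: continuous variation independent of methylation
            demeth = np.zeros(n_t, dtype=bool)
            expr = 5.0 * np.exp2(rng.normal(0.0, 2.0, n_t))
            expr_normal = 5.0 * np.exp2(rng.normal(0.0, 2.0, n_n))

        expr_rows[spec.gene_id] = np.concatenate([expr, expr_normal])
        demeth_rows[spec.gene_id] = demeth

        for pid in genome.promoter_probes[spec.gene_id]:
            meth_t = np.where(
                demeth,
                _beta(rng, scenario.beta_demeth_state, n_t),
                _beta(rng, scenario.beta_meth_state, n_t),
            )
            meth_n = _beta(rng, scenario.beta_meth_state, n_n)
            beta_rows[pid] = np.concatenate([meth_t, meth_n])

    expr_rows[TF_GENE] = np.concatenate([
        np.where(tf_on, _active_tpm(rng, scenario, n_t), _silent_tpm(rng, scenario, n_t)),
        _silent_tpm(rng, scenario, n_n),
    ])

    # clinical covariates
    effect_genes = [s for s in scenario.gene_plan if s.grade_or != 1.0 or s.survival_hr != 1.0]
    base_odds = scenario.grade_high_base / (1.0 - scenario.grade_high_base)
    odds = np.full(n_t, base_odds)
    hazard = np.full(n_t, scenario.baseline_hazard_per_day)
    for spec in effect_genes:
        # planted effects act on the upper expression half, so the two
        # exposure groups are balanced by construction
        vals = expr_rows[spec.gene_id][:n_t]
        active = vals >= np.median(vals)
        odds = odds * np.where(active, spec.grade_or, 1.0)
        hazard = hazard * np.where(active, spec.survival_hr, 1.0)
    p_high = odds / (1.0 + odds)
    high = rng.random(n_t) < p_high
    grade = np.where(
        high,
        rng.choice([3.0, 4.0], size=n_t, p=[0.75, 0.25]),
        rng.choice([1.0, 1.5, 2.0, 2.5], size=n_t, p=[0.30, 0.05, 0.60, 0.05]),
    )
    raw_time = rng.exponential(1.0 / hazard)
    event = raw_time <= scenario.study_length_days
    time = np.minimum(raw_time, scenario.study_length_days)

    clinical = pd.DataFrame(
        {
            "sample_class": ["tumor"] * n_t + ["normal"] * n_n,
            "grade": np.concatenate([grade, np.full(n_n, np.nan)]),
            "survival_time": np.concatenate([time, np.full(n_n, np.nan)]),
            "event": np.concatenate([event.astype(float), np.full(n_n, np.nan)]),
        },
        index=pd.Index(all_samples, name="sample_id"),
    )
    cohort = TumorCohort(
        expression=ExpressionMatrix(pd.DataFrame(expr_rows, index=all_samples).T, units="TPM"),
        probe_betas=pd.DataFrame(beta_rows, index=all_samples).T,
        manifest=manifest,
        clinical=clinical,
    )
    truth = TumorTruth(
        h=pd.Series(h, index=tumors, name="h"),
        demethylated=pd.DataFrame(demeth_rows, index=tumors).T,
        tf_positive=pd.Series(tf_on, index=tumors, name="tf_positive"),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# file output


def write_simulation(outdir: str | Path, scenario: SimulationScenario) -> None:
    """Generate all cohorts for a scenario and write them as plain text.

    Layout: transcript models, cell-line expression + Bismark-coverage
    tracks, normal references, the tissue panel (bedGraph tracks), the
    tumor cohort (expression, probe betas, manifest, clinical) and the
    ground-truth sidecar ``truth.tsv``.  Identical scenarios produce
    byte-identical trees.
    """
    from . import io as dio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = generate_genome(scenario)
    panel = generate_cell_line_panel(scenario, genome)
    normal = generate_normal_panel(scenario, genome)
    cohort, tumor_truth = generate_tumor_cohort(scenario, genome)

    dio.write_transcripts(genome.transcripts, outdir / "transcripts.tsv")
    dio.write_expression(panel.expression, outdir / "line_expression.tsv")
    (outdir / "line_meth").mkdir(exist_ok=True)
    for ln, track in panel.tracks.items():
        dio.write_methylation_track(track, outdir / "line_meth" / f"{ln}.cov", "bismark")
    dio.write_expression(normal.reference_expression, outdir / "reference_expression.tsv")
    (outdir / "reference_meth").mkdir(exist_ok=True)
    for ref, track in normal.reference_tracks.items():
        dio.write_methylation_track(track, outdir / "reference_meth" / f"{ref}.cov", "bismark")
    dio.write_expression(normal.gtex_expression, outdir / "gtex_expression.tsv")
    pd.Series(normal.tissue_of_sample, name="tissue").rename_axis("sample_id").to_csv(
        outdir / "gtex_samples.tsv", sep="\t"
    )
    (outdir / "tissue_meth").mkdir(exist_ok=True)
    for tissue, track in normal.tissue_tracks.items():
        dio.write_methylation_track(track, outdir / "tissue_meth" / f"{tissue}.bedgraph", "bedgraph")
    dio.write_expression(cohort.expression, outdir / "tumor_expression.tsv")
    cohort.probe_betas.to_csv(outdir / "probe_betas.tsv", sep="\t", float_format="%.17g")
    dio.write_probe_manifest(cohort.manifest, outdir / "probe_manifest.tsv")
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", float_format="%.17g")
    cpg = pd.DataFrame(
        [(c, p) for c, arr in genome.cpg_positions.items() for p in arr],
        columns=["chrom", "pos"],
    )
    cpg.to_csv(outdir / "cpg_positions.tsv", sep="\t", index=False)
    genome.truth.to_csv(outdir / "truth.tsv", sep="\t", float_format="%.17g")
    panel.silent_truth.to_csv(outdir / "truth_line_silent.tsv", sep="\t")
    tumor_truth.demethylated.to_csv(outdir / "truth_tumor_demeth.tsv", sep="\t")
    tumor_truth.h.rename_axis("sample_id").to_csv(
        outdir / "truth_tumor_h.tsv", sep="\t", float_format="%.17g"
    )
    tumor_truth.tf_positive.rename_axis("sample_id").to_csv(
        outdir / "truth_tumor_tf.tsv", sep="\t"
    )
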