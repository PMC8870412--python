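"""End-to-end convenience workflows tying the generator to the screen.

These helpers run the full cell-line screen and the nonDDIC control
selection on a synthetic study and score the calls against the planted
truth.  They are the same entry points a user would call after loading
real data with :mod:`ddicscreen.io`.
"""
from __future__ import annotations

import pandas as pd

from .config import ScreenConfig
from .screen import (
    ScreenResult,
    group_promoter_matrix,
    merge_tss_groups,
    run_screen,
    select_non_ddic,
)
from .simulate import CellLinePanel, NormalPanel, SyntheticGenome


def _gene_of_transcript(tid: str) -> str:
    return tid.rsplit("_t1", 1)[0]


def screen_synthetic_panel(
    genome: SyntheticGenome,
    cell_panel: CellLinePanel,
    normal_panel: NormalPanel,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Run the five-stage screen on a generated study."""
    return run_screen(
        genome.transcripts,
        cell_panel.expression,
        cell_panel.tracks,
        normal_panel.reference_expression,
        normal_panel.reference_tracks,
        config,
    )


def select_non_ddic_synthetic(
    genome: SyntheticGenome,
    cell_panel: CellLinePanel,
    normal_panel: NormalPanel,
    config: ScreenConfig = ScreenConfig(),
) -> pd.DataFrame:
    """Run the control-class selection on a generated study.

    All generated genes are single-transcript, so every gene is a
    candidate.  Normal-lung repression is checked against the tissue-panel
    GTEx-style medians plus the lung-tissue and AT2 references.
    """
    from .programs import median_tissue_expression

    groups, line_expr = merge_tss_groups(genome.transcripts, cell_panel.expression, config)
    line_meth = group_promoter_matrix(groups, cell_panel.tracks, config)
    line_expr.index = [_gene_of_transcript(t) for t in line_expr.index]
    line_meth.index = [_gene_of_transcript(t) for t in line_meth.index]

    profile = median_tissue_expression(
        normal_panel.gtex_expression, normal_panel.tissue_of_sample
    )
    ref = normal_panel.reference_expression.data.rename(index=_gene_of_transcript)
    counts = {g: 1 for g in line_expr.index}
    return select_non_ddic(
        counts,
        profile.medians["lung"],
        ref["roadmap_lung"],
        ref["AT2"],
        line_expr,
        line_meth,
        config,
    )


def score_against_truth(
    truth: pd.DataFrame,
    screen_records: pd.DataFrame,
    nonddic_records: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Sensitivity and false-call rates of the screen vs planted truth."""
    called_ddic = {
        _gene_of_transcript(gid)
        for gid in screen_records.index[screen_records["status"] == "DDIC"]
    }
    ddic_true = set(truth.index[truth["truth_class"].str.startswith("DDIC")])
    null_true = set(truth.index[truth["truth_class"].str.startswith("null")])
    out = {
        "ddic_sensitivity": len(called_ddic & ddic_true) / len(ddic_true)
        if ddic_true else float("nan"),
        "null_false_ddic_rate": len(called_ddic & null_true) / len(null_true)
        if null_true else float("nan"),
    }
    if nonddic_records is not None:
        called_non = set(nonddic_records.index[nonddic_records["status"] == "nonDDIC"])
        non_true = set(truth.index[truth["truth_class"] == "nonDDIC"])
        out["nonddic_sensitivity"] = (
            len(called_non & non_true) / len(non_true) if non_true else float("nan")
        )
        out["nonddic_false_rate"] = (
            len(called_non - non_true) / max(1, len(called_non))
        )
    return out
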