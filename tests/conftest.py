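"""Shared fixtures: one synthetic study per session, seed 17 throughout."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import ddicscreen as ds


@pytest.fixture(scope="session")
def scenario():
    return ds.SimulationScenario(seed=17)


@pytest.fixture(scope="session")
def genome(scenario):
    return ds.generate_genome(scenario)


@pytest.fixture(scope="session")
def cell_panel(scenario, genome):
    return ds.generate_cell_line_panel(scenario, genome)


@pytest.fixture(scope="session")
def normal_panel(scenario, genome):
    return ds.generate_normal_panel(scenario, genome)


@pytest.fixture(scope="session")
def tumor_cohort_truth(scenario, genome):
    return ds.generate_tumor_cohort(scenario, genome)


@pytest.fixture(scope="session")
def screen_result(genome, cell_panel, normal_panel):
    return ds.run_screen(
        genome.transcripts,
        cell_panel.expression,
        cell_panel.tracks,
        normal_panel.reference_expression,
        normal_panel.reference_tracks,
    )


@pytest.fixture(scope="session")
def clinical_cohort():
    sc = ds.SimulationScenario(seed=17, gene_plan=ds.clinical_gene_plan(200))
    genome = ds.generate_genome(sc)
    cohort, truth = ds.generate_tumor_cohort(sc, genome)
    return sc, genome, cohort, truth


def make_track(rows, sample_id="s"):
    """Convenience: build a track from (chrom, pos, beta, coverage) tuples."""
    return ds.CpGMethylationTrack(
        sample_id,
        pd.DataFrame(rows, columns=["chrom", "pos", "beta", "coverage"]),
    )
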