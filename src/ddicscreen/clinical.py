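"""Clinical association tests and induction-frequency comparisons.

Activation groups (from expression quantiles in the tumor cohort) are
tested against tumor grade (chi-squared on the grade contingency table)
and overall survival (log-rank, with a log2 median-survival ratio as the
effect size).  Both tests require at least 15 tumors per group; smaller
comparisons are reported as non-evaluable rather than silently skipped.
Induction frequencies under a demethylating agent are compared between
gene categories with Fisher's exact test.  P-values are adjusted per test
family with Benjamini-Hochberg.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .stats import bh_adjust
from .tumor import ActivationGroups

MIN_GROUP = 15
VALID_GRADES = {1.0, 1.5, 2.0, 2.5, 3.0, 4.0}


@dataclass
class AssociationResult:
    gene_id: str
    test: str                    # chi_squared_grade | logrank_survival | fisher_induction
    statistic: float
    p: float
    effect: float                # chi2 stat, log2 median ratio, or odds ratio
    n_group1: int
    n_group2: int
    evaluable: bool
    reason: str = ""
    p_adj: float = np.nan


def harmonize_grades(raw_grades: pd.Series) -> pd.Series:
    """Collapse half-grades: 1.5 -> 1 and 2.5 -> 2; missing stays missing."""
    vals = raw_grades.astype(float)
    bad = vals.dropna()[~vals.dropna().isin(VALID_GRADES)]
    if len(bad):
        raise ValueError(f"grade outside {sorted(VALID_GRADES)}: {bad.iloc[0]}")
    return vals.replace({1.5: 1.0, 2.5: 2.0})


def grade_association(groups: ActivationGroups, grades: pd.Series) -> AssociationResult:
    """Chi-squared test of grade distribution between activation groups.

    ``grades`` must already be harmonized.  Samples with a missing grade
    are excluded from this test only.  Grade levels absent from both
    groups are dropped from the contingency table.
    """
    g = grades.dropna()
    act = [s for s in groups.activating if s in g.index]
    non = [s for s in groups.nonactivating if s in g.index]
    if len(act) < MIN_GROUP or len(non) < MIN_GROUP:
        return AssociationResult(
            groups.gene_id, "chi_squared_grade", np.nan, np.nan, np.nan,
            len(act), len(non), False, f"group below {MIN_GROUP} samples",
        )
    levels = sorted(set(g.loc[act]) | set(g.loc[non]))
    table = np.array(
        [[int((g.loc[act] == lv).sum()) for lv in levels],
         [int((g.loc[non] == lv).sum()) for lv in levels]]
    )
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return AssociationResult(
            groups.gene_id, "chi_squared_grade", 0.0, 1.0, 0.0,
            len(act), len(non), True, "single grade level",
        )
    chi2, p, _dof, _exp = stats.chi2_contingency(table, correction=False)
    return AssociationResult(
        groups.gene_id, "chi_squared_grade", float(chi2), float(p), float(chi2),
        len(act), len(non), True,
    )


def _km_median(times: np.ndarray, events: np.ndarray, study_length: float) -> float:
    """Kaplan-Meier median; the study length stands in when never reached."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    med = kmf.median_survival_time_
    if not np.isfinite(med):
        return float(study_length)
    return float(med)


def survival_association(
    groups: ActivationGroups,
    survival_time: pd.Series,
    event: pd.Series,
    study_length: float,
) -> AssociationResult:
    """Log-rank test between activation groups, with a median-ratio effect.

    The effect size is log2(median survival of the activating group /
    median of the non-activating group); a Kaplan-Meier curve that never
    crosses 0.5 contributes the study length as its median.  Swapping the
    group labels flips the sign of the effect.
    """
    ok = survival_time.notna() & event.notna()
    act = [s for s in groups.activating if s in survival_time.index and ok.get(s, False)]
    non = [s for s in groups.nonactivating if s in survival_time.index and ok.get(s, False)]
    if len(act) < MIN_GROUP or len(non) < MIN_GROUP:
        return AssociationResult(
            groups.gene_id, "logrank_survival", np.nan, np.nan, np.nan,
            len(act), len(non), False, f"group below {MIN_GROUP} samples",
        )
    t1 = survival_time.loc[act].to_numpy(dtype=float)
    e1 = event.loc[act].to_numpy(dtype=float)
    t2 = survival_time.loc[non].to_numpy(dtype=float)
    e2 = event.loc[non].to_numpy(dtype=float)
    if e1.sum() + e2.sum() == 0:
        return AssociationResult(
            groups.gene_id, "logrank_survival", np.nan, np.nan, np.nan,
            len(act), len(non), False, "no events observed",
        )
    res = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    med_act = _km_median(t1, e1, study_length)
    med_non = _km_median(t2, e2, study_length)
    effect = float(np.log2(med_act / med_non))
    return AssociationResult(
        groups.gene_id, "logrank_survival", float(res.test_statistic),
        float(res.p_value), effect, len(act), len(non), True,
    )


def induction_frequency(
    de_calls: pd.Series, program_labels: pd.Series
) -> pd.DataFrame:
    """Fraction of genes upregulated by a demethylating agent, per program.

    ``de_calls`` maps gene -> True (significantly upregulated) / False.
    """
    joined = pd.DataFrame(
        {"up": de_calls.astype(bool), "program": program_labels.reindex(de_calls.index)}
    ).dropna(subset=["program"])
    out = joined.groupby("program")["up"].agg(n_up="sum", n_total="size")
    out["fraction_up"] = out["n_up"] / out["n_total"]
    return out


def compare_to_nonddic(
    counts: pd.DataFrame, reference: str = "nonDDIC"
) -> list[AssociationResult]:
    """Fisher's exact 2x2 of each program's induction counts vs the control class.

    ``counts`` is the output of :func:`induction_frequency` and must
    contain the reference row.  Programs with zero genes come back
    non-evaluable.
    """
    if reference not in counts.index:
        raise ValueError(f"reference category {reference!r} missing")
    ref_up = int(counts.at[reference, "n_up"])
    ref_total = int(counts.at[reference, "n_total"])
    results = []
    for program in counts.index:
        if program == reference:
            continue
        n_up = int(counts.at[program, "n_up"])
        n_total = int(counts.at[program, "n_total"])
        if n_total == 0 or ref_total == 0:
            results.append(AssociationResult(
                str(program), "fisher_induction", np.nan, np.nan, np.nan,
                n_total, ref_total, False, "empty category",
            ))
            continue
        table = [[n_up, n_total - n_up], [ref_up, ref_total - ref_up]]
        odds, p = stats.fisher_exact(table)
        results.append(AssociationResult(
            str(program), "fisher_induction", float(odds), float(p), float(odds),
            n_total, ref_total, True,
        ))
    return results


def adjust_family(results: list[AssociationResult]) -> list[AssociationResult]:
    """BH-adjust p-values within one family of tests (in place)."""
    p = np.array([r.p for r in results], dtype=float)
    adj = bh_adjust(p)
    for r, a in zip(results, adj):
        r.p_adj = float(a) if np.isfinite(a) else np.nan
    return results


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.gene_id, r.test, r.statistic, r.p, r.p_adj, r.effect,
             r.n_group1, r.n_group2, r.evaluable, r.reason)
            for r in results
        ],
        columns=["gene_id", "test", "statistic", "p", "p_adj", "effect",
                 "n_group1", "n_group2", "evaluable", "reason"],
    )
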