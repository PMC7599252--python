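"""Patient drug-resistance scoring, responder/non-responder median
split, and concordance with mutation biomarkers.

A patient's predicted resistance score is the sum, over the top-ranked
biomarker pathways, of the patient's standardized pathway activity times
the organoid-derived regression coefficient:

    score(patient) = sum_p Exp(patient, p) * beta(p)

With a single top pathway this is simply activity x coefficient. Since
beta maps activity to IC50 and higher IC50 means resistance, higher
scores predict resistance; responders are the at-or-below-median half
of the cohort.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .activity import PathwayActivityMatrix
from .regression import CoefficientRanking

logger = logging.getLogger("netbiomark")

EXACT_MWU_MAX_N = 20


@dataclass
class PatientScoreTable:
    """Per-patient resistance score, optional responder class, and the
    number of biomarker pathways summed into the score."""

    df: pd.DataFrame  # columns: score, and cls once split
    n_pathways_used: int

    @property
    def scores(self) -> pd.Series:
        return self.df["score"]

    @property
    def classes(self) -> pd.Series:
        if "cls" not in self.df.columns:
            raise ValueError("classes not assigned; call median_split first")
        return self.df["cls"]

    def patients_in(self, cls: str) -> list[str]:
        return list(self.df.index[self.classes == cls])


def score_patients(
    activity: PathwayActivityMatrix,
    ranking: CoefficientRanking,
    n_top: int = 1,
) -> PatientScoreTable:
    """Predicted resistance score per patient from the top ``n_top``
    biomarker pathways. Patient activity should be z-standardized
    within the patient dataset."""
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    feats = ranking.top_features(n_top)
    missing = [f for f in feats if f not in activity.df.index]
    if missing:
        raise KeyError(f"biomarker pathways missing from activity matrix: {missing}")
    betas = np.array([ranking.coefficients[f] for f in feats])
    score = activity.df.loc[feats].T.values @ betas
    df = pd.DataFrame({"score": score}, index=activity.df.columns)
    return PatientScoreTable(df=df, n_pathways_used=n_top)


def median_split(table: PatientScoreTable) -> PatientScoreTable:
    """Classify patients by the midpoint median of their scores:
    score <= median -> responder (lower predicted resistance),
    score > median -> non_responder. Ties at the median go to the
    responder side; identical scores for everyone are an error."""
    scores = table.scores
    if len(scores) < 2:
        raise ValueError("need >= 2 patients to split")
    if scores.nunique() == 1:
        raise ValueError("all scores identical; no separation, cannot split")
    med = float(np.median(scores.values))
    cls = np.where(scores.values <= med, "responder", "non_responder")
    df = table.df.copy()
    df["cls"] = cls
    return PatientScoreTable(df=df, n_pathways_used=table.n_pathways_used)


def mutation_concordance(
    table: PatientScoreTable,
    status: pd.Series,
    alternative: str = "greater",
) -> tuple[float, float]:
    """One-sided Mann-Whitney U test of resistance scores in mutant vs
    wild-type patients.

    ``alternative='greater'`` tests mutant > wild-type (resistance
    mutations, e.g. BRAF V600E under EGFR blockade); ``'less'`` covers
    sensitizing mutations (e.g. ERCC2 under cisplatin). Exact p-value
    for combined n <= 20 without ties, normal approximation with tie
    correction otherwise. Returns (U, p).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    status = status.reindex(table.df.index)
    if status.isna().any():
        raise ValueError("mutation status missing for some patients")
    mut = table.scores[status.astype(bool)].values
    wt = table.scores[~status.astype(bool)].values
    if len(mut) == 0 or len(wt) == 0:
        raise ValueError("both mutant and wild-type groups must be nonempty")
    pooled = np.concatenate([mut, wt])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MWU_MAX_N and not has_ties) else "asymptotic"
    res = mannwhitneyu(mut, wt, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
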