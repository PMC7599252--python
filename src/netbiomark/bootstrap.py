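"""Random-pathway bootstrap: empirical significance of the observed
biomarker's predictive rank against arbitrary feature selection.

Each iteration draws as many random pathways as the proximity filter
retained, retrains the regression on their activities, and walks the
coefficient ranking to find the first pathway that is simultaneously
(i) predictive of treated-patient survival (log-rank p below the
significance level for the median split on that pathway's score) and
(ii) confirmed in the isogenic sensitive/resistant contrast with a
direction consistent with its coefficient's sign. The empirical p-value
is the fraction of iterations achieving a rank at least as good
(numerically <=) as the observed biomarker's rank; iterations in which
no pathway qualifies contribute "absent" and never count as successes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity import PathwayActivityMatrix
from .core_io import ClinicalTable, DoseResponseTable, GeneSetCollection
from .regression import CoefficientRanking, fit_model
from .survival import isogenic_contrast, logrank_test

logger = logging.getLogger("netbiomark")


@dataclass
class BootstrapSummary:
    observed_rank: int | None
    null_ranks: list[int | None]
    empirical_p: float
    n_iter: int

    @property
    def n_absent(self) -> int:
        return sum(r is None for r in self.null_ranks)

    def formatted_p(self) -> str:
        if self.empirical_p == 0:
            return f"< {1.0 / self.n_iter:g}"
        return f"{self.empirical_p:g}"


def empirical_p_from_ranks(
    observed_rank: int | None, null_ranks: list[int | None]
) -> float:
    """Fraction of null iterations achieving a defined rank at least as
    good (numerically <=) as the observed rank; 1.0 when the observed
    biomarker is itself not predictive."""
    if observed_rank is None:
        return 1.0
    return sum(r is not None and r <= observed_rank for r in null_ranks) / len(null_ranks)


def best_predictive_rank(
    ranking: CoefficientRanking,
    patient_activity: PathwayActivityMatrix,
    clinical: ClinicalTable,
    isogenic_activity: PathwayActivityMatrix,
    isogenic_labels: pd.Series,
    alpha_sig: float = 0.05,
    survival_only: bool = False,
) -> int | None:
    """First rank (1 = best) whose pathway predicts treated-patient
    survival and passes the direction-consistent isogenic contrast;
    None (absent) when no pathway qualifies.

    Direction consistency: a positive coefficient maps high activity to
    high IC50 (resistance), so resistant lines should show the higher
    mean activity; a negative coefficient expects the opposite.
    """
    treated = clinical.subset(treated=True)
    # align treated patients with the activity matrix once; the loop
    # below then works on plain arrays (median split on scores is
    # score <= median -> responder, as in patients.median_split)
    treated_ids = [p for p in patient_activity.df.columns if p in set(treated.df.index)]
    if len(treated_ids) < 2:
        raise ValueError("fewer than 2 treated patients overlap the activity matrix")
    act_t = patient_activity.df[treated_ids]
    times = treated.df.loc[treated_ids, "time_days"].to_numpy(float)
    events = treated.df.loc[treated_ids, "event"].to_numpy(int)
    iso_index = set(isogenic_activity.df.index)
    features = sorted(ranking.ranks, key=ranking.ranks.get)
    for feat in features:
        beta = ranking.coefficients[feat]
        if beta == 0 or feat not in act_t.index:
            continue
        scores = act_t.loc[feat].to_numpy(float) * beta
        if np.all(scores == scores[0]):
            continue  # no separation: feature cannot be predictive
        resp = scores <= np.median(scores)
        if resp.all() or not resp.any():
            continue
        try:
            lr = logrank_test((times[resp], events[resp]),
                              (times[~resp], events[~resp]))
        except ValueError:
            continue
        if lr.p >= alpha_sig:
            continue
        if survival_only:
            return ranking.ranks[feat]
        if feat not in iso_index:
            continue
        t, p_iso, direction = isogenic_contrast(isogenic_activity, isogenic_labels, feat)
        expected = "resistant" if beta > 0 else "sensitive"
        if p_iso < alpha_sig and direction == expected:
            return ranking.ranks[feat]
    return None


def bootstrap_empirical_p(
    coll: GeneSetCollection,
    k: int,
    observed_rank: int | None,
    organoid_activity: PathwayActivityMatrix,
    response: DoseResponseTable,
    patient_activity: PathwayActivityMatrix,
    clinical: ClinicalTable,
    isogenic_activity: PathwayActivityMatrix,
    isogenic_labels: pd.Series,
    n_iter: int = 10000,
    alpha_sig: float = 0.05,
    survival_only: bool = False,
    model_kind: str = "ridge",
    seed: int = 0,
) -> BootstrapSummary:
    """Empirical p-value of the observed biomarker's predictive rank.

    Per iteration, ``k`` pathways are drawn uniformly without
    replacement (arbitrary selection, no degree matching — that is the
    point of the control), the model is retrained on their activities
    and the best predictive rank recorded. ``empirical_p`` counts
    iterations whose rank is defined and <= the observed rank; an
    absent observed rank yields empirical_p = 1 by convention. A zero
    count is reported alongside the "< 1/n_iter" convention via
    :meth:`BootstrapSummary.formatted_p`.
    """
    names = sorted(coll.names())
    if k > len(names):
        raise ValueError(f"k={k} exceeds collection size {len(names)}")
    available = [n for n in names if n in organoid_activity.df.index]
    if k > len(available):
        raise ValueError("k exceeds pathways available in the activity matrix")
    rng = np.random.default_rng(seed)
    null_ranks: list[int | None] = []
    for _ in range(n_iter):
        drawn = rng.choice(available, size=k, replace=False).tolist()
        sub = PathwayActivityMatrix(
            organoid_activity.df.loc[drawn], value_scale=organoid_activity.value_scale
        )
        ranking = fit_model(sub, response, kind=model_kind,
                            seed=int(rng.integers(0, 2**31 - 1)))
        null_ranks.append(
            best_predictive_rank(
                ranking, patient_activity, clinical,
                isogenic_activity, isogenic_labels,
                alpha_sig=alpha_sig, survival_only=survival_only,
            )
        )
    if observed_rank is None:
        logger.warning("observed biomarker not predictive; empirical p = 1 by definition")
    p = empirical_p_from_ranks(observed_rank, null_ranks)
    return BootstrapSummary(
        observed_rank=observed_rank, null_ranks=null_ranks,
        empirical_p=p, n_iter=n_iter,
    )
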