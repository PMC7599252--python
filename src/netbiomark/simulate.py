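"""Synthetic pharmacogenomic scenarios with planted structure.

Every input the pipeline consumes can be generated here with known
ground truth: a connected scale-free (or Erdos-Renyi) gene network with
drug targets; a planted pathway whose members sit within a prescribed
hop distance of the targets plus uniformly drawn decoy pathways; an
organoid cohort whose IC50 correlates with the planted pathway's latent
activity at a chosen level; treated and untreated patient cohorts whose
hazard depends on the planted activity only under treatment; and
isogenic sensitive/resistant expression profiles in which resistance
shifts the planted pathway's member genes.

Expression follows a latent-factor model: each pathway carries an
independent standard-normal activity factor per sample, and a gene's
expression is the sum of the factors of the pathways containing it plus
independent Gaussian noise. Rank-based ssGSEA can therefore recover
pathway activity from the generated matrices.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .core_io import (
    ClinicalTable,
    DoseResponseTable,
    DrugTargetMap,
    ExpressionMatrix,
    GeneSetCollection,
    InteractionNetwork,
)

logger = logging.getLogger("netbiomark")

PLANTED = "pathway_planted"
DRUG = "drugX"
MARKER_GENE = "markerA"


@dataclass
class ScenarioConfig:
    """Study conditions for a synthetic scenario.

    Defaults emulate the scale of published organoid screens and
    TCGA-style cohorts: ~10^3-gene network, tens of pathways, ~20
    organoids, ~10^2 treated and ~3x10^2 untreated patients, a strong
    negative activity-IC50 correlation for the planted biomarker, and a
    treatment-specific hazard ratio of 3 between resistance halves.
    """

    n_genes: int = 1000
    network_model: str = "barabasi_albert"  # or "erdos_renyi"
    ba_m: int = 3
    n_pathways: int = 50
    pathway_size_range: tuple[int, int] = (8, 25)
    n_targets: int = 4
    planted_pathway_distance: int = 1
    n_organoids: int = 20
    biomarker_effect: float = -0.9
    noise_sd: float = 0.5
    n_patients_treated: int = 114
    n_patients_untreated: int = 298
    hazard_ratio: float = 3.0
    baseline_hazard_per_day: float = 1.0 / 365.0
    censoring_rate: float = 0.3
    n_isogenic_sensitive: int = 3
    n_isogenic_resistant: int = 9
    isogenic_shift_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes, self.n_pathways, self.n_targets, self.n_organoids,
            self.n_patients_treated, self.n_patients_untreated,
            self.n_isogenic_sensitive, self.n_isogenic_resistant,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if not -1.0 <= self.biomarker_effect <= 1.0:
            raise ValueError("|biomarker_effect| must be <= 1")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be positive")
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ValueError("censoring_rate must be in [0, 1]")


@dataclass
class OrganoidCohort:
    expression: ExpressionMatrix
    response: DoseResponseTable
    latent: pd.DataFrame  # pathway x sample ground-truth activity

    def __iter__(self):
        return iter((self.expression, self.response))


@dataclass
class PatientCohorts:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    latent: pd.DataFrame

    def __iter__(self):
        return iter((self.expression, self.clinical))


@dataclass
class IsogenicSet:
    expression: ExpressionMatrix
    labels: pd.Series  # sample -> 'sensitive' | 'resistant'

    def __iter__(self):
        return iter((self.expression, self.labels))


def _derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    h = np.uint64(1469598103934665603)
    for ch in stage.encode():
        h = np.uint64((int(h) ^ ch) * 1099511628211 % 2**64)
    return int((np.uint64(seed) ^ h) % np.uint64(2**31 - 1))


# ---------------------------------------------------------------------------
# Network, pathways, targets
# ---------------------------------------------------------------------------

def make_network_and_pathways(
    cfg: ScenarioConfig,
) -> tuple[InteractionNetwork, GeneSetCollection, DrugTargetMap]:
    """Connected network with one planted pathway near the drug targets
    and uniformly drawn decoys.

    Each target is guaranteed at least one planted-pathway gene within
    ``planted_pathway_distance`` hops, so the closest distance from the
    targets to the planted pathway is bounded by that distance.
    """
    rng = np.random.default_rng(_derive_seed(cfg.seed, "network"))
    if cfg.network_model == "barabasi_albert":
        g = nx.barabasi_albert_graph(cfg.n_genes, cfg.ba_m,
                                     seed=int(rng.integers(2**31 - 1)))
    elif cfg.network_model == "erdos_renyi":
        g = nx.gnp_random_graph(cfg.n_genes, 6.0 / cfg.n_genes,
                                seed=int(rng.integers(2**31 - 1)))
        giant = max(nx.connected_components(g), key=len)
        g = g.subgraph(giant).copy()
    else:
        raise ValueError(f"unknown network_model {cfg.network_model!r}")
    width = len(str(cfg.n_genes))
    mapping = {old: f"g{i:0{width}d}" for i, old in enumerate(sorted(g.nodes))}
    g = nx.relabel_nodes(g, mapping)
    nx.set_edge_attributes(g, 900, "score")
    net = InteractionNetwork(g)
    nodes = sorted(g.nodes)

    targets = set(rng.choice(nodes, size=cfg.n_targets, replace=False).tolist())

    lo, hi = cfg.pathway_size_range
    planted_size = int(rng.integers(lo, hi + 1))
    balls = {
        t: sorted(nx.single_source_shortest_path_length(
            g, t, cutoff=cfg.planted_pathway_distance))
        for t in sorted(targets)
    }
    pool = sorted(set().union(*balls.values()))
    if len(pool) < lo or len(pool) < len(targets):
        raise ValueError(
            f"planted pathway of size >= {lo} unsatisfiable: only "
            f"{len(pool)} genes within {cfg.planted_pathway_distance} hops of targets"
        )
    planted_size = min(planted_size, len(pool))
    planted: set[str] = set()
    for t in sorted(targets):  # cover every target first
        choices = [n for n in balls[t] if n not in planted]
        if choices:
            planted.add(str(rng.choice(choices)))
    extra = [n for n in pool if n not in planted]
    n_more = min(planted_size - len(planted), len(extra))
    if n_more > 0:
        planted.update(rng.choice(extra, size=n_more, replace=False).tolist())

    sets: dict[str, set[str]] = {PLANTED: planted}
    n_decoys = cfg.n_pathways - 1
    for i in range(n_decoys):
        size = int(rng.integers(lo, hi + 1))
        genes = set(rng.choice(nodes, size=size, replace=False).tolist())
        sets[f"pathway_{i + 1:03d}"] = genes
    coll = GeneSetCollection(sets)
    dmap = DrugTargetMap({DRUG: targets})
    return net, coll, dmap


# ---------------------------------------------------------------------------
# Expression model
# ---------------------------------------------------------------------------

def _expression_from_latent(
    coll: GeneSetCollection,
    genes: list[str],
    latent: pd.DataFrame,
    noise_sd: float,
    rng: np.random.Generator,
    shift: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Gene expression = sum of member-pathway factors + noise
    (+ optional per-gene, per-sample shift)."""
    samples = list(latent.columns)
    X = rng.normal(0.0, max(noise_sd, 1e-12), size=(len(genes), len(samples)))
    gene_idx = {gname: i for i, gname in enumerate(genes)}
    for name in latent.index:
        members = [gene_idx[gname] for gname in coll[name] if gname in gene_idx]
        if members:
            X[members, :] += latent.loc[name].values[None, :]
    df = pd.DataFrame(X, index=genes, columns=samples)
    if shift is not None:
        df = df.add(shift, fill_value=0.0)
    return df


def make_organoid_cohort(
    cfg: ScenarioConfig,
    net: InteractionNetwork,
    coll: GeneSetCollection,
) -> OrganoidCohort:
    """Organoid expression + IC50 with a planted activity-response link.

    IC50 is log-normal: its log is ``effect`` times the planted
    pathway's latent activity plus sqrt(1 - effect^2) independent noise,
    so the rank correlation between planted activity and IC50 is close
    to ``biomarker_effect`` while all decoy activities are independent
    of the response.
    """
    if PLANTED not in coll:
        raise ValueError("collection lacks the planted pathway")
    rng = np.random.default_rng(_derive_seed(cfg.seed, "organoids"))
    samples = [f"org{i + 1:03d}" for i in range(cfg.n_organoids)]
    genes = sorted(net.nodes)
    latent = pd.DataFrame(
        rng.normal(size=(len(coll), cfg.n_organoids)),
        index=sorted(coll.names()), columns=samples,
    )
    expr = _expression_from_latent(coll, genes, latent, cfg.noise_sd, rng)
    rho = cfg.biomarker_effect
    eps = rng.normal(size=cfg.n_organoids)
    log_ic50 = rho * latent.loc[PLANTED].values + np.sqrt(max(0.0, 1 - rho**2)) * eps
    ic50 = pd.Series(np.exp(log_ic50), index=samples, name="ic50")
    return OrganoidCohort(
        expression=ExpressionMatrix(expr, value_scale="raw"),
        response=DoseResponseTable(ic50),
        latent=latent,
    )


def make_patient_cohorts(
    cfg: ScenarioConfig,
    net: InteractionNetwork,
    coll: GeneSetCollection,
) -> PatientCohorts:
    """Treated + untreated patients with treatment-specific hazard.

    In the treated cohort, the resistance-direction half (planted
    activity oriented by the sign of the biomarker effect) has its
    exponential hazard multiplied by ``hazard_ratio``; untreated
    survival is independent of all pathway activities. A binary
    mutation marker correlated with the resistance latent is attached
    for concordance tests. Censored patients (probability
    ``censoring_rate``) are observed for a uniform fraction of their
    event time.
    """
    if PLANTED not in coll:
        raise ValueError("collection lacks the planted pathway")
    rng = np.random.default_rng(_derive_seed(cfg.seed, "patients"))
    n_t, n_u = cfg.n_patients_treated, cfg.n_patients_untreated
    patients = [f"pt_t{i + 1:03d}" for i in range(n_t)] + \
               [f"pt_u{i + 1:03d}" for i in range(n_u)]
    treated_flag = np.array([1] * n_t + [0] * n_u)
    genes = sorted(net.nodes)
    latent = pd.DataFrame(
        rng.normal(size=(len(coll), len(patients))),
        index=sorted(coll.names()), columns=patients,
    )
    expr = _expression_from_latent(coll, genes, latent, cfg.noise_sd, rng)

    direction = 1.0 if cfg.biomarker_effect >= 0 else -1.0
    resist = direction * latent.loc[PLANTED].values  # higher = more resistant
    h0 = cfg.baseline_hazard_per_day
    hazard = np.full(len(patients), h0)
    treated_resist = resist[:n_t]
    high = treated_resist > np.median(treated_resist)
    hazard[:n_t] = np.where(high, h0 * cfg.hazard_ratio, h0)
    t_event = rng.exponential(1.0 / hazard)
    censored = rng.random(len(patients)) < cfg.censoring_rate
    time = np.where(censored, t_event * rng.random(len(patients)), t_event)
    event = (~censored).astype(int)

    # mutation marker enriched in resistance-high patients
    logit = 1.5 * (resist - resist.mean()) / max(resist.std(), 1e-12) - 1.0
    p_mut = 1.0 / (1.0 + np.exp(-logit))
    mutant = rng.random(len(patients)) < p_mut

    clin = pd.DataFrame(
        {
            "time_days": time,
            "event": event,
            "treated": treated_flag,
            f"mutation_{MARKER_GENE}": mutant.astype(int),
        },
        index=pd.Index(patients, name="patient_id"),
    )
    return PatientCohorts(
        expression=ExpressionMatrix(expr, value_scale="raw"),
        clinical=ClinicalTable(clin),
        latent=latent,
    )


def make_isogenic_lines(
    cfg: ScenarioConfig,
    net: InteractionNetwork,
    coll: GeneSetCollection,
) -> IsogenicSet:
    """Isogenic sensitive/resistant expression profiles.

    Because the lines share a common genetic origin, each pathway's
    baseline latent activity is drawn once and shared across all lines;
    line-to-line variation comes from gene-level noise only. Resistant
    lines additionally shift the planted pathway's member genes by
    ``isogenic_shift_sd`` expression standard deviations in the
    resistance direction (down when the biomarker effect is negative),
    leaving all other genes untouched.
    """
    if PLANTED not in coll:
        raise ValueError("collection lacks the planted pathway")
    rng = np.random.default_rng(_derive_seed(cfg.seed, "isogenic"))
    n_s, n_r = cfg.n_isogenic_sensitive, cfg.n_isogenic_resistant
    lines = [f"sens{i + 1:02d}" for i in range(n_s)] + \
            [f"resi{i + 1:02d}" for i in range(n_r)]
    genes = sorted(net.nodes)
    baseline = rng.normal(size=(len(coll), 1))
    latent = pd.DataFrame(
        np.tile(baseline, (1, len(lines))),
        index=sorted(coll.names()), columns=lines,
    )
    direction = 1.0 if cfg.biomarker_effect >= 0 else -1.0
    shift = pd.DataFrame(0.0, index=genes, columns=lines)
    members = sorted(coll[PLANTED])
    shift.loc[members, lines[n_s:]] = direction * cfg.isogenic_shift_sd
    expr = _expression_from_latent(coll, genes, latent, cfg.noise_sd, rng, shift=shift)
    labels = pd.Series(
        ["sensitive"] * n_s + ["resistant"] * n_r, index=lines, name="label"
    )
    return IsogenicSet(expression=ExpressionMatrix(expr, value_scale="raw"), labels=labels)


# ---------------------------------------------------------------------------
# Whole-scenario convenience and file output
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    cfg: ScenarioConfig
    network: InteractionNetwork
    pathways: GeneSetCollection
    drug_targets: DrugTargetMap
    organoids: OrganoidCohort
    patients: PatientCohorts
    isogenic: IsogenicSet


def simulate_scenario(cfg: ScenarioConfig) -> Scenario:
    net, coll, dmap = make_network_and_pathways(cfg)
    return Scenario(
        cfg=cfg,
        network=net,
        pathways=coll,
        drug_targets=dmap,
        organoids=make_organoid_cohort(cfg, net, coll),
        patients=make_patient_cohorts(cfg, net, coll),
        isogenic=make_isogenic_lines(cfg, net, coll),
    )


def write_scenario(scn: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Write every fixture as the plain-text formats core_io reads."""
    from . import core_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "network": outdir / "network.tsv",
        "gmt": outdir / "pathways.gmt",
        "targets": outdir / "targets.tsv",
        "organoid_expr": outdir / "organoid_expression.tsv",
        "ic50": outdir / "organoid_ic50.tsv",
        "patient_expr": outdir / "patient_expression.tsv",
        "clinical": outdir / "clinical.tsv",
        "isogenic_expr": outdir / "isogenic_expression.tsv",
        "isogenic_labels": outdir / "isogenic_labels.tsv",
    }
    core_io.write_edge_list(scn.network, paths["network"])
    core_io.write_gmt(scn.pathways, paths["gmt"])
    core_io.write_drug_targets(scn.drug_targets, paths["targets"])
    core_io.write_expression(scn.organoids.expression, paths["organoid_expr"])
    core_io.write_ic50(scn.organoids.response, paths["ic50"])
    core_io.write_expression(scn.patients.expression, paths["patient_expr"])
    core_io.write_clinical(scn.patients.clinical, paths["clinical"])
    core_io.write_expression(scn.isogenic.expression, paths["isogenic_expr"])
    scn.isogenic.labels.to_frame().to_csv(paths["isogenic_labels"], sep="\t",
                                          index_label="sample")
    return paths
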