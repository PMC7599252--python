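"""Two composite stages over the library: *discovery* (proximity filter
-> pathway activity -> regression -> coefficient ranking) and
*validation* (patient scoring -> median split -> survival / isogenic /
mutation-concordance / bootstrap checks), with a provenance manifest.

Configs are flat dictionaries (YAML-friendly); every file they point at
is a plain-text format from :mod:`netbiomark.core_io`. A single global
seed is fanned out into per-stage derived seeds so each stage is
independently reproducible.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import core_io
from .activity import PathwayActivityMatrix, log2_plus_one, ssgsea_scores, standardize
from .bootstrap import best_predictive_rank, bootstrap_empirical_p
from .patients import median_split, mutation_concordance, score_patients
from .proximity import select_proximal_pathways
from .regression import CoefficientRanking, fit_model
from .simulate import _derive_seed
from .survival import isogenic_contrast, validate_biomarker

logger = logging.getLogger("netbiomark")

DISCOVERY_DEFAULTS = {
    "min_score": 700,
    "alpha": 0.10,
    "n_iter": 1000,
    "min_bin_size": None,
    "model": "ridge",
    "log2p1": False,
    "log10_ic50": False,
    "seed": 7,
    "out_dir": "results",
}

VALIDATION_DEFAULTS = {
    "n_top": 1,
    "log2p1": False,
    "marker_gene": None,
    "marker_alternative": "greater",
    "bootstrap_iterations": 0,
    "alpha_sig": 0.05,
    "seed": 7,
    "out_dir": "results",
}


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_manifest(out_dir: Path, stage: str, config: dict, inputs: dict,
                    counts: dict) -> Path:
    manifest = {
        "tool": "netbiomark",
        "version": __version__,
        "stage": stage,
        "config": {k: v for k, v in config.items()},
        "input_digests": {k: _digest(v) for k, v in inputs.items()},
        "counts": counts,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    path = out_dir / f"{stage}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path


def proximity_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "d_c": [r.d_c for r in records],
            "mu_null": [r.mu_null for r in records],
            "sigma_null": [r.sigma_null for r in records],
            "z": [r.z for r in records],
            "proximal": [int(r.proximal) for r in records],
        },
        index=pd.Index([r.pathway for r in records], name="pathway"),
    )


def _pathway_activity(expr_path, coll, log2p1: bool) -> PathwayActivityMatrix:
    expr = core_io.read_expression(expr_path)
    if log2p1:
        expr = log2_plus_one(expr)
    return standardize(ssgsea_scores(expr, coll))


def run_discovery(config: dict):
    """Discovery: proximal-pathway selection then coefficient ranking.

    Required config keys: network, gmt, targets, drug, organoid_expr,
    ic50, out_dir. Returns (proximity records, CoefficientRanking,
    manifest path) and writes proximity.tsv / coefficients.tsv.
    """
    cfg = {**DISCOVERY_DEFAULTS, **config}
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    net = core_io.largest_connected_component(
        core_io.read_edge_list(cfg["network"], min_score=cfg["min_score"])
    )
    coll = core_io.filter_to_network(core_io.read_gmt(cfg["gmt"]), net)
    dmap = core_io.filter_targets_to_network(
        core_io.read_drug_targets(cfg["targets"]), net
    )
    drug = cfg["drug"]
    if drug not in dmap:
        raise ValueError(f"drug {drug!r} has no in-network targets")

    records = select_proximal_pathways(
        net, dmap[drug], coll, alpha=cfg["alpha"], n_iter=cfg["n_iter"],
        min_bin_size=cfg["min_bin_size"], seed=_derive_seed(seed, "proximity"),
    )
    proximal = [r.pathway for r in records if r.proximal]
    if not proximal:
        raise ValueError(
            f"no proximal pathways at alpha={cfg['alpha']}; nothing to train"
        )

    activity = _pathway_activity(cfg["organoid_expr"], coll, cfg["log2p1"])
    response = core_io.read_ic50(cfg["ic50"])
    response.check_paired(activity)
    usable = [p for p in proximal if p in activity.df.index]
    sub = PathwayActivityMatrix(activity.df.loc[usable], value_scale="zscore")
    ranking = fit_model(sub, response, kind=cfg["model"],
                        seed=_derive_seed(seed, "regression"),
                        log10_ic50=cfg["log10_ic50"])

    prox_df = proximity_frame(records)
    prox_df.to_csv(out_dir / "proximity.tsv", sep="\t")
    ranking.to_frame().to_csv(out_dir / "coefficients.tsv", sep="\t")
    inputs = {k: cfg[k] for k in ("network", "gmt", "targets", "organoid_expr", "ic50")}
    counts = {
        "network_nodes": net.n_nodes,
        "network_edges": net.n_edges,
        "pathways_filtered": len(coll),
        "proximal_pathways": len(proximal),
        "features_trained": len(usable),
        "organoids": len(response.samples),
    }
    manifest = _write_manifest(out_dir, "discovery", cfg, inputs, counts)
    return records, ranking, manifest


def load_ranking(path: str | Path) -> CoefficientRanking:
    df = pd.read_csv(path, sep="\t", index_col=0)
    alpha = df["alpha"].iloc[0]
    return CoefficientRanking(
        model_kind="ridge",
        alpha=None if pd.isna(alpha) else float(alpha),
        intercept=0.0,
        coefficients=df["beta"].to_dict(),
        ranks={f: int(r) for f, r in df["rank"].items()},
    )


def run_validation(config: dict) -> dict:
    """Validation: score patients, split per cohort, test survival
    separation in treated vs untreated patients, and run the optional
    isogenic, mutation-concordance and bootstrap checks.

    Required config keys: gmt, network, coefficients, patient_expr,
    clinical, out_dir; optional isogenic_expr/isogenic_labels,
    marker_gene, organoid_expr+ic50 (for bootstrap).
    """
    cfg = {**VALIDATION_DEFAULTS, **config}
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    coeff_path = Path(cfg["coefficients"])
    if not coeff_path.exists():
        raise FileNotFoundError(
            f"discovery output {coeff_path} missing; run discovery first"
        )
    ranking = load_ranking(coeff_path)
    net = core_io.largest_connected_component(
        core_io.read_edge_list(cfg["network"], min_score=cfg.get("min_score", 700))
    )
    coll = core_io.filter_to_network(core_io.read_gmt(cfg["gmt"]), net)
    clinical = core_io.read_clinical(cfg["clinical"])

    activity = _pathway_activity(cfg["patient_expr"], coll, cfg["log2p1"])
    scored = score_patients(activity, ranking, n_top=int(cfg["n_top"]))

    treated_ids = clinical.subset(treated=True).patients
    untreated_ids = clinical.subset(treated=False).patients
    from .patients import PatientScoreTable
    treated_scores = PatientScoreTable(
        scored.df.loc[[p for p in treated_ids if p in scored.df.index]].copy(),
        scored.n_pathways_used)
    untreated_scores = PatientScoreTable(
        scored.df.loc[[p for p in untreated_ids if p in scored.df.index]].copy(),
        scored.n_pathways_used)
    treated_split = median_split(treated_scores)
    untreated_split = median_split(untreated_scores)
    report_km = validate_biomarker(clinical, treated_split, untreated_split)

    report: dict = {
        "n_pathways_used": scored.n_pathways_used,
        "treated": {"logrank_chi2": report_km.treated.statistic,
                    "p": report_km.treated.p,
                    "n_responder": report_km.treated_counts[0],
                    "n_nonresponder": report_km.treated_counts[1]},
        "untreated": {"logrank_chi2": report_km.untreated.statistic,
                      "p": report_km.untreated.p,
                      "n_responder": report_km.untreated_counts[0],
                      "n_nonresponder": report_km.untreated_counts[1]},
    }

    iso_activity = iso_labels = None
    if cfg.get("isogenic_expr"):
        iso_expr = core_io.read_expression(cfg["isogenic_expr"])
        if cfg["log2p1"]:
            iso_expr = log2_plus_one(iso_expr)
        iso_activity = ssgsea_scores(iso_expr, coll)
        iso_labels = pd.read_csv(cfg["isogenic_labels"], sep="\t", index_col=0
                                 ).iloc[:, 0].astype(str)
        top = ranking.top_features(1)[0]
        t, p, direction = isogenic_contrast(iso_activity, iso_labels, top)
        report["isogenic"] = {"pathway": top, "t": t, "p": p,
                              "higher_mean_in": direction}

    if cfg.get("marker_gene"):
        split_all = median_split(scored)
        status = clinical.mutation_status(cfg["marker_gene"]).reindex(
            split_all.df.index)
        u, p = mutation_concordance(split_all, status,
                                    alternative=cfg["marker_alternative"])
        report["mutation_concordance"] = {"gene": cfg["marker_gene"],
                                          "U": u, "p": p}

    n_boot = int(cfg["bootstrap_iterations"])
    if n_boot > 0:
        if iso_activity is None:
            raise ValueError("bootstrap requires isogenic_expr/isogenic_labels")
        organoid_activity = _pathway_activity(cfg["organoid_expr"], coll,
                                              cfg["log2p1"])
        response = core_io.read_ic50(cfg["ic50"])
        observed = best_predictive_rank(
            ranking, activity, clinical, iso_activity, iso_labels,
            alpha_sig=cfg["alpha_sig"],
        )
        k = len(ranking.ranks)
        summary = bootstrap_empirical_p(
            coll, k, observed, organoid_activity, response, activity,
            clinical, iso_activity, iso_labels, n_iter=n_boot,
            alpha_sig=cfg["alpha_sig"], seed=_derive_seed(seed, "bootstrap"),
        )
        report["bootstrap"] = {
            "observed_rank": summary.observed_rank,
            "empirical_p": summary.empirical_p,
            "formatted_p": summary.formatted_p(),
            "n_absent": summary.n_absent,
            "n_iter": summary.n_iter,
        }

    scored_out = median_split(scored).df
    scored_out.to_csv(out_dir / "scores.tsv", sep="\t", index_label="patient_id")
    rows = [
        {"cohort": "treated", "n_responder": report["treated"]["n_responder"],
         "n_nonresponder": report["treated"]["n_nonresponder"],
         "logrank_chi2": report["treated"]["logrank_chi2"],
         "p": report["treated"]["p"]},
        {"cohort": "untreated", "n_responder": report["untreated"]["n_responder"],
         "n_nonresponder": report["untreated"]["n_nonresponder"],
         "logrank_chi2": report["untreated"]["logrank_chi2"],
         "p": report["untreated"]["p"]},
    ]
    pd.DataFrame(rows).to_csv(out_dir / "validation_report.tsv", sep="\t",
                              index=False)
    (out_dir / "validation_report.json").write_text(
        json.dumps(report, indent=2, default=float) + "\n")
    inputs = {k: cfg[k] for k in ("gmt", "network", "coefficients",
                                  "patient_expr", "clinical")}
    counts = {"patients_scored": len(scored.df),
              "treated": len(treated_ids), "untreated": len(untreated_ids)}
    _write_manifest(out_dir, "validation", cfg, inputs, counts)
    return report
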