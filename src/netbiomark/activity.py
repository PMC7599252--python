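"""Per-sample pathway activity via single-sample GSEA (ssGSEA) and
feature standardization.

For each sample, genes are ranked by expression (descending); the
enrichment score (ES) of a gene set is the area between the weighted
in-set cumulative distribution (gene rank magnitudes raised to a weight
exponent, normalized to sum 1 over in-set genes) and the uniform
out-of-set cumulative distribution, accumulated down the ranked list.
The normalized enrichment score (NES) divides every ES by the range
(max - min) of all ES values across every pathway x sample pair of the
call, the convention of the common ssGSEA implementations. Because the
statistic is rank-based it is invariant to any strictly monotone
transform of a sample's expression values.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("netbiomark")


@dataclass
class PathwayActivityMatrix(ExpressionMatrix):
    """Pathways x samples activity matrix with provenance."""

    collection_name: str = ""
    weight: float = 0.25
    normalization: str = "global"


def log2_plus_one(m: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(x + 1); expression must be non-negative."""
    if (m.df.values < 0).any():
        raise ValueError("negative expression value; log2(x+1) undefined scale")
    return ExpressionMatrix(np.log2(m.df + 1.0), value_scale="log2p1")


def _sample_order(values: pd.Series) -> np.ndarray:
    """Positions of genes sorted by expression descending; ties broken
    by descending row label, so the ordering is deterministic."""
    tmp = pd.DataFrame({"v": values.values, "g": values.index.astype(str)})
    order = tmp.sort_values(["v", "g"], ascending=[False, False], kind="mergesort")
    return order.index.to_numpy()


def single_sample_es(
    values: pd.Series, gene_sets: dict[str, np.ndarray], weight: float
) -> dict[str, float]:
    """Enrichment scores of one sample for pre-indexed gene sets.

    ``gene_sets`` maps pathway name -> boolean membership vector aligned
    to ``values``' index.
    """
    n = len(values)
    order = _sample_order(values)
    # rank magnitude: top gene gets n, bottom gets 1
    rank_mag = np.arange(n, 0, -1, dtype=float)
    out: dict[str, float] = {}
    for name, member in gene_sets.items():
        in_set = member[order]
        n_in = int(in_set.sum())
        n_out = n - n_in
        if n_in == 0 or n_out == 0:
            raise ValueError(f"gene set {name!r} degenerate within the matrix")
        w = np.where(in_set, rank_mag ** weight, 0.0)
        cum_in = np.cumsum(w) / w.sum()
        cum_out = np.cumsum(~in_set) / n_out
        out[name] = float(np.sum(cum_in - cum_out))
    return out


def ssgsea_scores(
    m: ExpressionMatrix,
    coll: GeneSetCollection,
    weight: float = 0.25,
    normalization: str = "global",
) -> PathwayActivityMatrix:
    """ssGSEA activity (NES) per pathway x sample.

    ``normalization='global'`` (default) divides all ES by the single
    range max(ES) - min(ES) over the whole call; ``'per_sample'``
    normalizes each sample's column by its own ES range. Pathways with
    no gene among the matrix rows are dropped with a warning.
    """
    if normalization not in ("global", "per_sample"):
        raise ValueError(f"unknown normalization {normalization!r}")
    genes = m.df.index.astype(str)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for ssGSEA")
    const_zero = (m.df == 0).all(axis=0)
    if const_zero.any():
        bad = list(m.df.columns[const_zero])
        raise ValueError(f"constant-zero samples: {bad}")

    indexed: dict[str, np.ndarray] = {}
    for name in sorted(coll.names()):
        member = genes.isin(coll[name])
        if member.sum() == 0:
            logger.warning("pathway %r has no genes in the matrix; dropped", name)
            continue
        if member.sum() == len(genes):
            logger.warning("pathway %r covers every gene; dropped", name)
            continue
        indexed[name] = np.asarray(member)
    if not indexed:
        raise ValueError("no pathway overlaps the expression matrix")

    es = pd.DataFrame(
        {
            sample: single_sample_es(m.df[sample], indexed, weight)
            for sample in m.df.columns
        }
    )
    if normalization == "global":
        spread = float(es.values.max() - es.values.min())
        nes = es / spread if spread > 0 else es * 0.0
    else:
        spread = es.max(axis=0) - es.min(axis=0)
        nes = es.divide(spread.where(spread > 0, 1.0), axis=1)
    return PathwayActivityMatrix(
        nes, value_scale="nes", weight=weight, normalization=normalization
    )


def standardize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-feature z-score across samples: subtract the row mean, divide
    by the population (1/n) standard deviation. Constant rows are
    dropped with a warning; a single-column matrix is an error.
    Idempotent within floating tolerance."""
    if m.df.shape[1] < 2:
        raise ValueError("standardize needs >= 2 samples")
    sd = m.df.std(axis=1, ddof=0)
    constant = sd == 0
    if constant.any():
        logger.warning("dropping %d constant feature rows", int(constant.sum()))
    kept = m.df.loc[~constant]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[~constant], axis=0)
    if isinstance(m, PathwayActivityMatrix):
        return PathwayActivityMatrix(
            z, value_scale="zscore", collection_name=m.collection_name,
            weight=m.weight, normalization=m.normalization,
        )
    return ExpressionMatrix(z, value_scale="zscore")
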