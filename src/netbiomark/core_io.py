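"""Domain types and readers/writers for networks, gene sets, expression
matrices, drug targets, dose-response and clinical tables.

All on-disk formats are plain text: STRING-style edge lists (TSV with an
integer confidence score per edge), GMT gene-set collections, expression
TSVs (first column = feature label, header = sample labels), and flat
clinical TSVs. Gene identifiers are opaque strings; identifier mapping
(e.g. to UniProt) is the caller's job.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger("netbiomark")

VALUE_SCALES = ("raw", "log2p1", "nes", "zscore")


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class InteractionNetwork:
    """Undirected protein-protein interaction graph.

    Backed by a :class:`networkx.Graph`; no self-loops, no duplicate
    edges. Edge confidence scores (0-1000) are kept as the ``score``
    edge attribute but are only ever used to threshold edges, never as
    distances.
    """

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self.graph

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene)


@dataclass
class GeneSetCollection:
    """Named pathways mapped to gene sets. Names unique, sets nonempty."""

    sets: dict[str, set[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class DrugTargetMap:
    """Drug name -> nonempty set of target genes."""

    targets: dict[str, set[str]]

    def __getitem__(self, drug: str) -> set[str]:
        return self.targets[drug]

    def __contains__(self, drug: str) -> bool:
        return drug in self.targets


@dataclass
class ExpressionMatrix:
    """Features (genes or pathways) x samples matrix of real values.

    ``value_scale`` tracks the semantics of the values: ``raw`` counts /
    intensities, ``log2p1`` = log2(x+1), ``nes`` = ssGSEA normalized
    enrichment scores, ``zscore`` = per-feature standardized.
    """

    df: pd.DataFrame
    value_scale: str = "raw"

    def __post_init__(self) -> None:
        if self.value_scale not in VALUE_SCALES:
            raise ValueError(f"unknown value_scale {self.value_scale!r}")
        if self.df.index.has_duplicates:
            raise ValueError("duplicate feature labels")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate sample labels")
        n_na = int(self.df.isna().any(axis=1).sum())
        if n_na:
            logger.info("dropping %d feature rows with missing values", n_na)
            self.df = self.df.dropna(axis=0)

    @property
    def features(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[str]:
        return list(self.df.columns)


@dataclass
class DoseResponseTable:
    """Sample -> IC50 (positive, drug-concentration units)."""

    ic50: pd.Series

    def __post_init__(self) -> None:
        if (self.ic50 <= 0).any():
            bad = self.ic50.index[self.ic50 <= 0].tolist()
            raise ValueError(f"non-positive IC50 for samples {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.ic50.index)

    def check_paired(self, expr: ExpressionMatrix) -> None:
        missing = set(self.samples) - set(expr.samples)
        if missing:
            raise ValueError(
                f"IC50 samples not in expression matrix: {sorted(missing)}"
            )


@dataclass
class ClinicalTable:
    """Per-patient survival time (days), event flag, treatment flag and
    optional per-gene mutation status columns (``mutation_<gene>``)."""

    df: pd.DataFrame

    REQUIRED = ("time_days", "event", "treated")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValueError(f"clinical table missing column {col!r}")
        if (self.df["time_days"] < 0).any():
            raise ValueError("negative survival time")
        if not self.df["event"].isin([0, 1]).all():
            raise ValueError("event must be 0 (censored) or 1 (death)")

    @property
    def patients(self) -> list[str]:
        return list(self.df.index)

    def subset(self, treated: bool) -> "ClinicalTable":
        return ClinicalTable(self.df[self.df["treated"].astype(bool) == treated].copy())

    def mutation_status(self, gene: str) -> pd.Series:
        col = f"mutation_{gene}"
        if col not in self.df.columns:
            raise KeyError(f"no mutation column for gene {gene!r}")
        return self.df[col].astype(bool)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, min_score: int = 700) -> InteractionNetwork:
    """Read a STRING-style TSV edge list, keeping edges with score
    strictly greater than ``min_score``.

    Self-loops are discarded and symmetric duplicates collapsed. A
    malformed line raises :class:`FormatError` naming its line number;
    an empty resulting network is an error.
    """
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    g = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 columns, got {len(parts)}")
            a, b, raw = parts[0].strip(), parts[1].strip(), parts[2].strip()
            try:
                score = int(float(raw))
            except ValueError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise FormatError(f"{path}:{lineno}: non-numeric score {raw!r}") from None
            if not a or not b:
                raise FormatError(f"{path}:{lineno}: empty gene identifier")
            if a == b:
                continue
            if score > min_score:
                g.add_edge(a, b, score=score)
    if g.number_of_edges() == 0:
        raise FormatError(f"{path}: no edges pass min_score={min_score}")
    logger.info("read %d nodes / %d edges (score > %d) from %s",
                g.number_of_nodes(), g.number_of_edges(), min_score, path)
    return InteractionNetwork(g)


def largest_connected_component(net: InteractionNetwork) -> InteractionNetwork:
    """Induced subgraph on the largest connected component.

    Size ties are broken by the lexicographically smallest member node so
    the result is deterministic.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    comps = nx.connected_components(net.graph)
    best = sorted(comps, key=lambda c: (-len(c), min(c)))[0]
    return InteractionNetwork(net.graph.subgraph(best).copy())


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, genes...; tab-separated).

    The description column is ignored; duplicate genes within a set are
    collapsed; a repeated pathway name is an error.
    """
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 fields")
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
            genes = {g for g in parts[2:] if g}
            if not genes:
                raise FormatError(f"{path}:{lineno}: pathway {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets)


def filter_to_network(
    coll: GeneSetCollection, net: InteractionNetwork
) -> GeneSetCollection:
    """Intersect every pathway with the network's nodes, dropping
    pathways left empty. Idempotent."""
    nodes = net.nodes
    kept: dict[str, set[str]] = {}
    dropped = 0
    for name, genes in coll.sets.items():
        inside = genes & nodes
        if inside:
            kept[name] = inside
        else:
            dropped += 1
    logger.info("network filter: %d pathways retained, %d dropped", len(kept), dropped)
    return GeneSetCollection(kept)


def read_drug_targets(path: str | Path) -> DrugTargetMap:
    """Read a long-form TSV of drug, target-gene pairs (optional header)."""
    targets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected drug<TAB>gene")
            drug, gene = parts[0].strip(), parts[1].strip()
            if lineno == 1 and drug.lower() in ("drug", "drug_name"):
                continue
            targets.setdefault(drug, set()).add(gene)
    if not targets:
        raise FormatError(f"{path}: no drug-target pairs")
    return DrugTargetMap(targets)


def filter_targets_to_network(
    dmap: DrugTargetMap, net: InteractionNetwork
) -> DrugTargetMap:
    """Intersect targets with network nodes; drugs with no in-network
    target are dropped with a warning."""
    nodes = net.nodes
    kept: dict[str, set[str]] = {}
    for drug, genes in dmap.targets.items():
        inside = genes & nodes
        if inside:
            kept[drug] = inside
        else:
            logger.warning("drug %r has no targets in the network; dropped", drug)
    return DrugTargetMap(kept)


def read_expression(path: str | Path, value_scale: str = "raw") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), value_scale=value_scale)


def read_ic50(path: str | Path) -> DoseResponseTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: expected sample<TAB>ic50")
    s = df.iloc[:, 0].astype(float)
    s.index = s.index.astype(str)
    s.name = "ic50"
    return DoseResponseTable(s)


def read_clinical(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ClinicalTable(df)


# ---------------------------------------------------------------------------
# Writers (round-trip partners of the readers above)
# ---------------------------------------------------------------------------

def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("geneA\tgeneB\tcombined_score\n")
        for a, b, data in sorted(net.graph.edges(data=True)):
            fh.write(f"{a}\t{b}\t{data.get('score', 999)}\n")


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(coll.sets):
            genes = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    m.df.to_csv(path, sep="\t", index_label="feature")


def write_ic50(t: DoseResponseTable, path: str | Path) -> None:
    t.ic50.to_frame().to_csv(path, sep="\t", index_label="sample")


def write_clinical(t: ClinicalTable, path: str | Path) -> None:
    t.df.to_csv(path, sep="\t", index_label="patient_id")


def write_drug_targets(dmap: DrugTargetMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("drug\ttarget\n")
        for drug in sorted(dmap.targets):
            for gene in sorted(dmap.targets[drug]):
                fh.write(f"{drug}\t{gene}\n")
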