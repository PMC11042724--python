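"""Readers and writers for the plain-text formats the pipeline consumes.

Matrices are TSV/CSV with molecule ids in the first column and one header
row of sample ids; gene sets come in GMT; labels are a two-column TSV
(sample, class); interaction networks are three-column edge lists
(``geneA<TAB>geneB<TAB>weight``, weight optional); retained patient
similarity networks are exported as GraphML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import OmicsMatrix, validate_binary

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayRecord:
    """A named gene set: the unit over which similarity networks are built."""

    id: str
    name: str
    source: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"pathway {self.id!r} has no members")


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def read_omics_table(path: str | Path, ome_kind: str = "expression") -> OmicsMatrix:
    """Read a molecule x sample matrix from delimited text.

    ``ome_kind="mutation"`` additionally validates that every entry is 0/1.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate molecule ids in {path.name}: {dups}")
    if df.columns.has_duplicates:
        dups = sorted(df.columns[df.columns.duplicated()].unique())
        raise ValueError(f"duplicate sample ids in {path.name}: {dups}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric cell in {path.name}: molecule {bad[0]!r}, "
                f"sample {col!r}")
    matrix = OmicsMatrix(df.astype(float), ome_kind)
    if ome_kind == "mutation":
        validate_binary(matrix)
    return matrix


def write_omics_table(matrix: OmicsMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> list[PathwayRecord]:
    """Read a GMT gene-set file: name, description, then members."""
    path = Path(path)
    records: list[PathwayRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line needs >= 3 tab-separated "
                    f"fields, found {len(fields)}")
            name, desc, *members = fields
            members = [m for m in members if m]
            if name in seen:
                raise ValueError(f"{path.name}:{lineno}: duplicate set id {name!r}")
            seen.add(name)
            records.append(PathwayRecord(id=name, name=name, source=desc,
                                         members=frozenset(members)))
    if not records:
        logger.warning("read_gmt: %s contains no gene sets", path)
    return records


def write_gmt(records: Iterable[PathwayRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write("\t".join([rec.id, rec.source, *sorted(rec.members)]) + "\n")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV (sample id, class label) into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "label"],
                     dtype=str, comment="#")
    if df["sample"].duplicated().any():
        dups = sorted(df.loc[df["sample"].duplicated(), "sample"].unique())
        raise ValueError(f"duplicate sample ids in labels: {dups}")
    labels = pd.Series(df["label"].values, index=df["sample"].values, name="label")
    classes = sorted(labels.unique())
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, found {classes}")
    return labels


def write_labels(labels: pd.Series, path: str | Path) -> None:
    labels.to_csv(path, sep="\t", header=False)


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an undirected weighted edge list (weight optional, default 1)."""
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"edge list line {lineno}: needs >= 2 fields")
            a, b = fields[0], fields[1]
            w = float(fields[2]) if len(fields) > 2 else 1.0
            graph.add_edge(a, b, weight=w)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b, data in graph.edges(data=True):
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0)}\n")


def write_psn_graphml(network, path: str | Path) -> None:
    """Export a similarity network (with labels, centrality, separability
    metadata when present) as GraphML.  Re-reading reproduces the weights
    to 1e-9."""
    from .psn import SimilarityNetwork  # local import avoids a cycle

    if not isinstance(network, SimilarityNetwork):
        raise TypeError("write_psn_graphml expects a SimilarityNetwork")
    w = network.weights
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("weight matrix is not symmetric")
    g = nx.Graph()
    g.graph["pathway_id"] = network.pathway_id
    g.graph["direction"] = network.direction
    if network.separability is not None:
        g.graph["power"] = int(network.separability.power)
        g.graph["cohesive_class"] = str(network.separability.cohesive_class)
    for idx, pid in enumerate(network.patient_ids):
        attrs = {"label": str(network.labels[pid])}
        if network.centrality is not None:
            attrs["centrality"] = float(network.centrality.loc[pid, "scaled"])
        g.add_node(pid, **attrs)
    n = len(network.patient_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                g.add_edge(network.patient_ids[i], network.patient_ids[j],
                           weight=float(w[i, j]))
    nx.write_graphml(g, path)


def read_psn_graphml(path: str | Path):
    """Re-read a GraphML export into a SimilarityNetwork."""
    from .psn import SimilarityNetwork, SeparabilityResult

    g = nx.read_graphml(path)
    patient_ids = list(g.nodes)
    labels = {p: g.nodes[p]["label"] for p in patient_ids}
    n = len(patient_ids)
    w = np.zeros((n, n))
    index = {p: i for i, p in enumerate(patient_ids)}
    for a, b, data in g.edges(data=True):
        w[index[a], index[b]] = w[index[b], index[a]] = float(data["weight"])
    network = SimilarityNetwork(
        pathway_id=g.graph.get("pathway_id", "unknown"),
        patient_ids=patient_ids,
        weights=w,
        direction=g.graph.get("direction", "activated"),
        labels=labels)
    return network
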