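"""Readers and writers: expression tables, GMT gene sets, label tables,
and cluster-network serialization (JSON canonical, GraphML, DOT)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .datamodel import ClusterAssignment, GeneSetCollection, TimeGrid, TimeSeriesMatrix
from .network import ClusterNetwork

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_labels",
    "write_labels",
    "write_network",
    "read_network",
]

NETWORK_FORMATS = ("json", "graphml", "dot")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path,
    times: Sequence[float],
    n_replicates: int = 1,
    interpolation_step: float = 1.0,
    *,
    missing_values: tuple[str, ...] = ("", "NA", "NaN", "nan"),
) -> TimeSeriesMatrix:
    """Read a delimited genes x (time x replicate) table.

    The first column holds gene ids; the remaining ``N_t * N_r`` columns
    are laid out time-major (all replicates of t1, then t2, ...). The
    layout is declared, never inferred from headers; TSV/CSV is chosen by
    file extension.
    """
    path = Path(path)
    grid = TimeGrid(times, interpolation_step)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, na_values=list(missing_values))
    expected = grid.n_timepoints * n_replicates
    if df.shape[1] != expected:
        raise ValueError(
            f"{path.name}: {df.shape[1]} value columns but grid declares "
            f"{grid.n_timepoints} time points x {n_replicates} replicates = {expected}"
        )
    ids = [str(g) for g in df.index]
    dupes = sorted({g for g in ids if ids.count(g) > 1})
    if dupes:
        raise ValueError(f"{path.name}: duplicate gene ids: {dupes}")
    for col in df.columns:
        bad = df[col][~df[col].apply(lambda v: isinstance(v, (int, float)) or pd.isna(v))]
        if len(bad):
            raise ValueError(
                f"{path.name}: non-numeric value {bad.iloc[0]!r} in column "
                f"{col!r}, row {bad.index[0]!r}"
            )
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path.name}: non-numeric cell: {exc}") from exc
    tensor = values.reshape(len(ids), grid.n_timepoints, n_replicates)
    return TimeSeriesMatrix(ids, tensor, grid)


def write_expression(m: TimeSeriesMatrix, path: str | Path) -> None:
    """Write a matrix in the time-major layout read_expression expects."""
    path = Path(path)
    cols = [
        f"t{ti}_r{q}" if m.n_replicates > 1 else f"t{ti}"
        for ti in range(m.n_timepoints)
        for q in range(m.n_replicates)
    ]
    flat = m.values.reshape(m.n_genes, -1)
    df = pd.DataFrame(flat, index=m.gene_ids, columns=cols)
    df.index.name = "gene"
    df.to_csv(path, sep=_sep_for(path))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read tab-separated gene sets: id, description, gene, gene, ..."""
    path = Path(path)
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line needs id, description "
                    f"and at least one gene ({len(fields)} field(s) found)"
                )
            pid, name, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path.name}:{lineno}: gene set {pid!r} is empty")
            sets[pid] = (name, frozenset(genes))
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pid in sets.ids():
            genes = "\t".join(sorted(sets.genes(pid)))
            fh.write(f"{pid}\t{sets.name(pid)}\t{genes}\n")


def read_labels(path: str | Path) -> dict[str, int]:
    """Read a two-column gene -> cluster TSV (with or without header)."""
    path = Path(path)
    labels: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path.name}:{lineno}: expected 2 columns")
            gene, cluster = parts
            if lineno == 1 and not cluster.lstrip("-").isdigit():
                continue  # header
            labels[gene] = int(cluster)
    if not labels:
        raise ValueError(f"{path.name}: no labels found")
    return labels


def write_labels(labels: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tcluster\n")
        for gene, cluster in labels.items():
            fh.write(f"{gene}\t{cluster}\n")


def write_network(network: ClusterNetwork, path: str | Path, format: str = "json") -> None:
    """Serialize a cluster network; JSON round-trips losslessly."""
    network.validate()
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(network.to_dict(), fh, indent=1)
            fh.write("\n")
    elif format == "graphml":
        g = _to_nx(network)
        for _, data in g.nodes(data=True):
            for key in ("genes", "grid", "mean", "sd"):
                data[key] = json.dumps(data[key])
        for _, _, data in g.edges(data=True):
            data["annotations"] = json.dumps(data["annotations"])
        nx.write_graphml(g, path)
    elif format == "dot":
        lines = ["digraph cluster_network {"]
        for node in network.nodes:
            lines.append(
                f'  c{node.cluster} [label="cluster {node.cluster} '
                f'({len(node.genes)} genes)"];'
            )
        for e in network.edges:
            label = ", ".join(a.pathway_id for a in e.annotations)
            attr = f' [label="{label}"]' if label else ""
            lines.append(f"  c{e.source} -> c{e.target}{attr};")
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown network format {format!r}; use {NETWORK_FORMATS}")


def _to_nx(network: ClusterNetwork) -> nx.DiGraph:
    g = nx.DiGraph(order=json.dumps(network.order))
    for node in network.nodes:
        g.add_node(
            node.cluster,
            genes=list(node.genes),
            grid=list(node.grid),
            mean=list(node.mean),
            sd=list(node.sd),
        )
    for e in network.edges:
        g.add_edge(
            e.source,
            e.target,
            annotations=[
                {
                    "pathway_id": a.pathway_id,
                    "name": a.name,
                    "p_union": a.p_union,
                    "p_source": a.p_source,
                    "p_target": a.p_target,
                }
                for a in e.annotations
            ],
        )
    return g


def read_network(path: str | Path) -> ClusterNetwork:
    """Read a JSON cluster network written by :func:`write_network`."""
    with open(path) as fh:
        return ClusterNetwork.from_dict(json.load(fh))
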