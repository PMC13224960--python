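"""Readers and writers: abundance tables, GraphML, Pajek, edge-list TSV.

GraphML goes through networkx with a canonicalization pass (nodes, edges
and attribute keys written in sorted order) so that write -> read -> write
is byte-identical.  Pajek covers the documented lossy subset only: node
id, label, (x, y) coordinates and edge weight.  All writers emit UTF-8
with LF line endings.
"""

from __future__ import annotations

import shlex
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .model import MetaNetwork, OmicsTable, net_from_edgelist

__all__ = ["read_abundance_table", "read_graph", "write_graph"]

GRAPH_FORMATS = ("graphml", "pajek", "edgelist_tsv")
MISSING_POLICIES = ("error", "zero", "drop_feature")


def read_abundance_table(path, layer: str = "", missing_policy: str = "error") -> OmicsTable:
    """Read a feature x sample TSV (header = sample ids, first column = feature ids).

    ``missing_policy`` controls empty cells: ``error`` rejects them,
    ``zero`` fills 0, ``drop_feature`` removes rows containing any gap.
    Non-numeric cells and duplicate feature ids are always errors.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty table: {path}")
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()].astype(str)))
        raise ValueError(f"duplicate feature IDs in {path}: {', '.join(dups)}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at feature {df.index[r]!r}, sample {df.columns[c]!r}: "
            f"{df.iat[r, c]!r}"
        )
    missing = numeric.isna()
    if missing.to_numpy().any():
        if missing_policy == "error":
            r, c = np.argwhere(missing.to_numpy())[0]
            raise ValueError(
                f"missing cell at feature {numeric.index[r]!r}, sample {numeric.columns[c]!r}"
            )
        if missing_policy == "zero":
            numeric = numeric.fillna(0.0)
        else:  # drop_feature
            numeric = numeric.loc[~missing.any(axis=1)]
            if numeric.shape[0] == 0:
                raise ValueError("drop_feature removed every feature")
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return OmicsTable(values=numeric.astype(float), layer=layer)


# --------------------------------------------------------------------------
# graph formats

def _canonical_copy(net: nx.Graph) -> MetaNetwork:
    """Sorted nodes/edges and lexicographic attribute order, for stable output."""
    out = MetaNetwork()
    out.graph.update(dict(sorted(net.graph.items(), key=lambda kv: str(kv[0]))))
    for n in sorted(net.nodes, key=str):
        out.add_node(n, **dict(sorted(net.nodes[n].items())))
    for u, v in sorted((tuple(sorted((u, v), key=str)) for u, v in net.edges()),
                       key=lambda e: (str(e[0]), str(e[1]))):
        out.add_edge(u, v, **dict(sorted(net[u][v].items())))
    return out


def write_graph(net: nx.Graph, path, format: str = "graphml") -> None:
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_canonical_copy(net), path, encoding="utf-8")
    elif format == "pajek":
        _write_pajek(net, path)
    elif format == "edgelist_tsv":
        rows = []
        for u, v in sorted((tuple(sorted((u, v), key=str)) for u, v in net.edges()),
                           key=lambda e: (str(e[0]), str(e[1]))):
            d = net[u][v]
            rows.append({
                "source": u,
                "target": v,
                "r": d.get("r", np.nan),
                "sign": d.get("sign", 1),
                "p_adj": d.get("p_adj", np.nan),
            })
        pd.DataFrame(rows, columns=["source", "target", "r", "sign", "p_adj"]).to_csv(
            path, sep="\t", index=False, lineterminator="\n")
    else:
        raise ValueError(f"unknown format {format!r}; choose from {GRAPH_FORMATS}")


def read_graph(path, format: str = "graphml") -> MetaNetwork:
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        net = MetaNetwork()
        net.graph.update(g.graph)
        net.add_nodes_from(g.nodes(data=True))
        net.add_edges_from(g.edges(data=True))
        return net
    if format == "pajek":
        return _read_pajek(path)
    if format == "edgelist_tsv":
        df = pd.read_csv(path, sep="\t")
        for col in ("source", "target", "r", "p_adj"):
            if col not in df.columns:
                raise ValueError(f"edgelist TSV {path} lacks column {col!r}")
        return net_from_edgelist(
            df[["source", "target", "r", "p_adj"]].itertuples(index=False, name=None))
    raise ValueError(f"unknown format {format!r}; choose from {GRAPH_FORMATS}")


def _write_pajek(net: nx.Graph, path: Path) -> None:
    nodes = sorted(net.nodes, key=str)
    index = {n: i + 1 for i, n in enumerate(nodes)}
    lines = ["% omicnet pajek subset: id, label, x, y, weight",
             f"*Vertices {len(nodes)}"]
    for n in nodes:
        d = net.nodes[n]
        x = float(d.get("x", 0.0))
        y = float(d.get("y", 0.0))
        lines.append(f'{index[n]} "{n}" {x!r} {y!r}')
    lines.append("*Edges")
    for u, v in sorted((tuple(sorted((u, v), key=str)) for u, v in net.edges()),
                       key=lambda e: (str(e[0]), str(e[1]))):
        w = float(net[u][v].get("weight", 1.0))
        lines.append(f"{index[u]} {index[v]} {w!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def _read_pajek(path: Path) -> MetaNetwork:
    net = MetaNetwork()
    labels: dict[int, str] = {}
    section = None
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("%"):
            continue
        low = line.lower()
        if low.startswith("*vertices"):
            section = "vertices"
            continue
        if low.startswith(("*edges", "*arcs")):
            section = "edges"
            continue
        try:
            parts = shlex.split(line)
            if section == "vertices":
                idx = int(parts[0])
                label = parts[1]
                labels[idx] = label
                attrs = {}
                if len(parts) >= 4:
                    attrs = {"x": float(parts[2]), "y": float(parts[3])}
                net.add_node(label, **attrs)
            elif section == "edges":
                u, v = labels[int(parts[0])], labels[int(parts[1])]
                w = float(parts[2]) if len(parts) >= 3 else 1.0
                net.add_edge(u, v, weight=w)
            else:
                raise ValueError("data before *Vertices section")
        except (ValueError, KeyError, IndexError) as exc:
            raise ValueError(f"malformed pajek file {path} at line {lineno}: {raw!r}") from exc
    return net
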