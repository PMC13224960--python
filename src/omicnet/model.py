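"""Core data model: omics tables, attributed networks, layout coordinates.

The network container is a thin :class:`networkx.Graph` subclass so that
the full networkx toolbox stays available, while construction helpers
enforce the package invariants: undirected, no self-loops, no duplicate
edges, and a consistent ``sign``/``weight`` derivation from the edge
correlation coefficient ``r``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "OmicsTable",
    "MetaNetwork",
    "Coors",
    "NetComparison",
    "net_from_edgelist",
    "annotate_nodes",
    "compare_nets",
]


@dataclass
class OmicsTable:
    """A feature x sample numeric matrix with metadata.

    Parameters
    ----------
    values : pandas.DataFrame
        Features on rows, samples on columns, finite numeric body.
    layer : str
        Omics layer tag, e.g. ``"micro"``, ``"gene"``, ``"chem"``.
    feature_meta : pandas.DataFrame, optional
        Per-feature annotations indexed by feature id.
    norm_history : list of str
        Ordered names of transforms already applied.
    """

    values: pd.DataFrame
    layer: str = ""
    feature_meta: pd.DataFrame | None = None
    norm_history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if not isinstance(v, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame")
        if v.shape[1] == 0:
            raise ValueError("empty table: no samples")
        if v.index.duplicated().any():
            dups = sorted(set(v.index[v.index.duplicated()].astype(str)))
            raise ValueError(f"duplicate feature IDs: {', '.join(dups)}")
        if v.columns.duplicated().any():
            dups = sorted(set(v.columns[v.columns.duplicated()].astype(str)))
            raise ValueError(f"duplicate sample IDs: {', '.join(dups)}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("values must be finite (apply a missing policy at read)")

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: pd.DataFrame, transform: str | None = None) -> "OmicsTable":
        hist = list(self.norm_history) + ([transform] if transform else [])
        meta = None if self.feature_meta is None else self.feature_meta.copy()
        if meta is not None:
            meta = meta.loc[meta.index.intersection(values.index)]
        return OmicsTable(values=values, layer=self.layer, feature_meta=meta, norm_history=hist)


class MetaNetwork(nx.Graph):
    """Attributed undirected network.

    Node attributes: ``layer``, ``label``, ``size``, ``module``, ``role``,
    ``Zi``, ``Pi`` (all optional).  Edge attributes: ``r``, ``sign`` in
    {+1, -1}, ``weight`` = \\|r\\|, ``p_adj``, ``intra_module``.
    Construction parameters live in ``self.graph``.
    """

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        for u, v in self.edges():
            if u == v:
                raise ValueError(f"self-loop at node {u!r}")
            d = self[u][v]
            r = d.get("r")
            if r is not None:
                sign = d.get("sign")
                if sign is not None and sign != (1 if r > 0 else -1):
                    raise ValueError(f"edge ({u},{v}): sign {sign} inconsistent with r={r}")
                w = d.get("weight")
                if w is not None and abs(w - abs(r)) > 1e-12:
                    raise ValueError(f"edge ({u},{v}): weight {w} != |r|={abs(r)}")

    def negative_edge_fraction(self) -> float:
        m = self.number_of_edges()
        if m == 0:
            return 0.0
        neg = sum(1 for _, _, d in self.edges(data=True) if d.get("sign", 1) == -1)
        return neg / m


@dataclass
class Coors:
    """Node coordinates from a layout, plus optional group placement info.

    ``table`` has columns ``node``, ``x``, ``y`` and optionally ``group``.
    ``group_meta`` maps group label -> dict with keys such as ``anchor``
    (x, y) and ``scale``.
    """

    table: pd.DataFrame
    group_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"node", "x", "y"}
        if not required.issubset(self.table.columns):
            raise ValueError("Coors table needs columns node, x, y")
        xy = self.table[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValueError("non-finite coordinate")
        if self.table["node"].duplicated().any():
            raise ValueError("duplicate node in Coors")

    @property
    def nodes(self) -> list:
        return list(self.table["node"])

    def as_dict(self) -> dict:
        return {
            row.node: (row.x, row.y)
            for row in self.table.itertuples(index=False)
        }

    def covers(self, nodes: Iterable) -> bool:
        return set(self.table["node"]) == set(nodes)


@dataclass
class NetComparison:
    """Set-based comparison of two networks (edge identity is unordered)."""

    node_intersection: int
    node_union: int
    node_only_a: int
    node_only_b: int
    edge_intersection: int
    edge_union: int
    edge_only_a: int
    edge_only_b: int


def _edge_key(u, v) -> tuple:
    return (u, v) if str(u) <= str(v) else (v, u)


def net_from_edgelist(
    edges: Iterable[Sequence],
    node_attrs: Mapping[str, Mapping] | None = None,
) -> MetaNetwork:
    """Build a network from rows ``(u, v, r, p_adj)``.

    Duplicate unordered pairs are collapsed keeping the smaller ``p_adj``
    (ties broken by larger \\|r\\|).  ``sign`` and ``weight`` are derived
    from ``r``.  Self-loops and non-numeric ``r`` are rejected.
    """
    best: dict[tuple, tuple[float, float]] = {}
    for row in edges:
        u, v, r, p_adj = row[0], row[1], row[2], row[3]
        if u == v:
            raise ValueError(f"self-loop: ({u!r}, {v!r})")
        try:
            r = float(r)
            p_adj = float(p_adj)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric r or p_adj in edge ({u!r}, {v!r})") from exc
        if not math.isfinite(r):
            raise ValueError(f"non-numeric r in edge ({u!r}, {v!r})")
        key = _edge_key(u, v)
        if key not in best:
            best[key] = (r, p_adj)
        else:
            r0, p0 = best[key]
            if (p_adj, -abs(r)) < (p0, -abs(r0)):
                best[key] = (r, p_adj)
    net = MetaNetwork()
    for (u, v), (r, p_adj) in sorted(best.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))):
        net.add_edge(u, v, r=r, sign=1 if r > 0 else -1, weight=abs(r), p_adj=p_adj)
    if node_attrs:
        for node, attrs in node_attrs.items():
            if node in net:
                net.nodes[node].update(attrs)
    return net


def annotate_nodes(net: MetaNetwork, table: pd.DataFrame, key: str | None = None) -> dict:
    """Attach table columns as node attributes, matching on ``key``.

    ``key=None`` matches on the table index.  The network is modified in
    place; the return value reports ``matched``, ``unmatched_nodes`` and
    ``unmatched_rows``.
    """
    if key is not None:
        if key not in table.columns:
            raise KeyError(f"key column {key!r} absent from table")
        table = table.set_index(key)
    ids = set(table.index)
    node_set = set(net.nodes)
    matched = 0
    for node in net.nodes:
        if node in ids:
            row = table.loc[node]
            if isinstance(row, pd.DataFrame):  # duplicated id: first wins
                row = row.iloc[0]
            net.nodes[node].update(row.to_dict())
            matched += 1
    return {
        "matched": matched,
        "unmatched_nodes": sorted(str(n) for n in node_set - ids),
        "unmatched_rows": sorted(str(i) for i in ids - node_set),
    }


def compare_nets(net_a: nx.Graph, net_b: nx.Graph) -> NetComparison:
    """Set comparison of node and edge sets; edge identity ignores orientation."""
    na, nb = set(net_a.nodes), set(net_b.nodes)
    ea = {_edge_key(u, v) for u, v in net_a.edges()}
    eb = {_edge_key(u, v) for u, v in net_b.edges()}
    return NetComparison(
        node_intersection=len(na & nb),
        node_union=len(na | nb),
        node_only_a=len(na - nb),
        node_only_b=len(nb - na),
        edge_intersection=len(ea & eb),
        edge_union=len(ea | eb),
        edge_only_a=len(ea - eb),
        edge_only_b=len(eb - ea),
    )
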