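"""Network construction, module detection, Zi-Pi roles, subnetworks,
multi-omics assembly.

Edges are retained when |r| exceeds the correlation threshold *strictly*
and the adjusted p falls *strictly* below the significance threshold.
Modules come from Clauset-Newman-Moore greedy modularity agglomeration on
|r| weights; node roles follow the within-module degree z-score (Zi) and
participation coefficient (Pi) with the Guimera-Amaral cutoffs
(Zi >= 2.5, Pi >= 0.62).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms import community as nx_community

from . import config
from .correlate import CorrelationResult
from .model import MetaNetwork

__all__ = [
    "ModuleAssignment",
    "NodeRole",
    "c_net_build",
    "detect_modules",
    "zipi",
    "sample_subnetwork",
    "assemble_multiomics",
]


@dataclass
class ModuleAssignment:
    """node -> 1-based module id (ids ordered by descending module size)
    and the weighted modularity Q of the partition."""

    membership: dict
    modularity: float

    @property
    def n_modules(self) -> int:
        return len(set(self.membership.values()))

    def members(self, module_id: int) -> list:
        return sorted((n for n, m in self.membership.items() if m == module_id), key=str)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node": list(self.membership), "module": list(self.membership.values())}
        )


@dataclass
class NodeRole:
    """Per-node Zi / Pi values and the four-way role classification."""

    table: pd.DataFrame  # columns: node, Zi, Pi, role

    def counts(self) -> dict:
        return self.table["role"].value_counts().to_dict()


def c_net_build(
    corr: CorrelationResult,
    r_threshold: float = 0.6,
    p_threshold: float | None = 0.05,
    keep_isolated: bool = False,
) -> MetaNetwork:
    """Threshold a correlation result into a network.

    An edge is kept iff ``|r| > r_threshold`` and (when ``p_threshold``
    is set) ``p_adj < p_threshold``, both strict.  Isolated nodes are
    dropped unless ``keep_isolated``.
    """
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must be in (0, 1)")
    if p_threshold is not None:
        if not 0 < p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if corr.adjust == "none":
            raise ValueError(
                "correlation result has no adjusted p-values; "
                "recompute with adjust != 'none' or set p_threshold=None")

    net = MetaNetwork()
    net.graph.update({
        "method": corr.method, "r_threshold": r_threshold,
        "p_threshold": p_threshold if p_threshold is not None else "none",
        "adjust": corr.adjust, "n_samples": corr.n,
    })
    rv = corr.r.to_numpy()
    av = corr.p_adj.to_numpy()
    rows, cols = list(corr.r.index), list(corr.r.columns)
    intra = corr.mode == "intra"
    for i in range(rv.shape[0]):
        j0 = i + 1 if intra else 0
        for j in range(j0, rv.shape[1]):
            r = rv[i, j]
            if np.isnan(r) or abs(r) <= r_threshold:
                continue
            if p_threshold is not None and not av[i, j] < p_threshold:
                continue
            net.add_edge(rows[i], cols[j], r=float(r),
                         sign=1 if r > 0 else -1, weight=float(abs(r)),
                         p_adj=float(av[i, j]))
    if keep_isolated:
        if intra:
            net.add_nodes_from(rows)
        else:
            net.add_nodes_from(rows)
            net.add_nodes_from(cols)
    if corr.row_layer:
        for n in rows:
            if n in net:
                net.nodes[n]["layer"] = corr.row_layer
    if not intra and corr.col_layer:
        for n in cols:
            if n in net:
                net.nodes[n]["layer"] = corr.col_layer
    if net.number_of_edges() == 0:
        warnings.warn("no edge passed the thresholds: empty network", stacklevel=2)
    net.graph["n_nodes"] = net.number_of_nodes()
    net.graph["n_edges"] = net.number_of_edges()
    return net


def detect_modules(net: nx.Graph, mark_edges: bool = True) -> ModuleAssignment:
    """Greedy (CNM) modularity maximization with |r| edge weights.

    Module ids are 1-based in descending size order.  When ``mark_edges``
    the boolean edge attribute ``intra_module`` and node attribute
    ``module`` are written back onto the graph.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    for u, v, d in net.edges(data=True):
        d.setdefault("weight", abs(d.get("r", 1.0)))
    if net.number_of_edges() == 0:
        comms = [{n} for n in net.nodes]
    else:
        comms = [set(c) for c in nx_community.greedy_modularity_communities(
            net, weight="weight")]
    comms.sort(key=lambda c: (-len(c), min(str(n) for n in c)))
    membership = {n: i + 1 for i, c in enumerate(comms) for n in c}
    q = (nx_community.modularity(net, comms, weight="weight")
         if net.number_of_edges() else 0.0)
    if mark_edges:
        for n, m in membership.items():
            net.nodes[n]["module"] = m
        for u, v, d in net.edges(data=True):
            d["intra_module"] = membership[u] == membership[v]
    return ModuleAssignment(membership=membership, modularity=float(q))


def zipi(net: nx.Graph, modules: ModuleAssignment | dict) -> NodeRole:
    """Zi-Pi topological role classification.

    Zi is the z-score of a node's (unweighted) link count into its own
    module, standardized over that module's members; Pi = 1 - sum_m
    (k_im / k_i)^2 over modules m.  Isolated nodes get Pi = NaN and role
    ``peripheral``.  Roles: module_hub (high Zi only), connector (high Pi
    only), network_hub (both), peripheral (neither).
    """
    membership = modules.membership if isinstance(modules, ModuleAssignment) else dict(modules)
    missing = [n for n in net.nodes if n not in membership]
    if missing:
        raise ValueError(f"module assignment misses nodes: {missing[:5]}")

    # per-node link counts into each module
    k_into: dict = {n: {} for n in net.nodes}
    for u, v in net.edges():
        k_into[u][membership[v]] = k_into[u].get(membership[v], 0) + 1
        k_into[v][membership[u]] = k_into[v].get(membership[u], 0) + 1

    by_module: dict = {}
    for n in net.nodes:
        by_module.setdefault(membership[n], []).append(n)

    zi = {}
    for mod, members in by_module.items():
        internal = np.array([k_into[n].get(mod, 0) for n in members], dtype=float)
        mu, sd = internal.mean(), internal.std()
        for n, k in zip(members, internal):
            zi[n] = 0.0 if sd == 0 else (k - mu) / sd

    rows = []
    for n in sorted(net.nodes, key=str):
        k_i = net.degree(n)
        if k_i == 0:
            rows.append((n, zi[n], np.nan, "peripheral"))
            continue
        pi = 1.0 - sum((k / k_i) ** 2 for k in k_into[n].values())
        hub = zi[n] >= config.ZI_THRESHOLD
        conn = pi >= config.PI_THRESHOLD
        role = ("network_hub" if hub and conn else
                "module_hub" if hub else
                "connector" if conn else "peripheral")
        rows.append((n, zi[n], pi, role))
    table = pd.DataFrame(rows, columns=["node", "Zi", "Pi", "role"])
    for row in table.itertuples(index=False):
        net.nodes[row.node].update(Zi=float(row.Zi),
                                   Pi=float(row.Pi) if np.isfinite(row.Pi) else float("nan"),
                                   role=row.role)
    return NodeRole(table=table)


def sample_subnetwork(net: MetaNetwork, present_nodes) -> MetaNetwork:
    """Induced subgraph on the nodes present in a sample; attributes are
    inherited.  Nodes absent from the network are ignored with a warning."""
    present = set(present_nodes)
    extra = present - set(net.nodes)
    if extra:
        warnings.warn(f"{len(extra)} requested nodes absent from the network",
                      stacklevel=2)
    keep = present & set(net.nodes)
    if not keep:
        warnings.warn("no requested node present: empty subnetwork", stacklevel=2)
    sub = MetaNetwork()
    sub.graph.update(net.graph)
    sub.add_nodes_from((n, dict(net.nodes[n])) for n in keep)
    sub.add_edges_from((u, v, dict(d)) for u, v, d in net.edges(data=True)
                       if u in keep and v in keep)
    return sub


def assemble_multiomics(corr_blocks, thresholds) -> tuple[MetaNetwork, pd.DataFrame]:
    """Union network over inter-omics correlation blocks.

    ``corr_blocks`` is a list of inter-mode :class:`CorrelationResult`;
    ``thresholds`` a matching list of ``(r_threshold, p_threshold)``
    applied per block.  Feature ids must be unique across layers (a
    collision raises, listing the ids).  Returns the network and a
    per-block edge-sign tally (block, layers, positive, negative).
    """
    if len(corr_blocks) != len(thresholds):
        raise ValueError("one (r_threshold, p_threshold) pair per block required")
    id_layers: dict = {}
    for blk in corr_blocks:
        if blk.mode != "inter":
            raise ValueError("assemble_multiomics expects inter-mode blocks")
        for ids, layer in ((blk.row_ids, blk.row_layer), (blk.col_ids, blk.col_layer)):
            for fid in ids:
                if fid in id_layers and id_layers[fid] != layer:
                    clash = sorted(f for f in ids if f in id_layers and id_layers[f] != layer)
                    raise ValueError(f"feature ids collide across layers: {clash[:10]}")
                id_layers[fid] = layer

    net = MetaNetwork()
    tally_rows = []
    for b, (blk, (rt, pt)) in enumerate(zip(corr_blocks, thresholds)):
        sub = c_net_build(blk, r_threshold=rt, p_threshold=pt)
        pos = sum(1 for _, _, d in sub.edges(data=True) if d["sign"] == 1)
        neg = sub.number_of_edges() - pos
        tally_rows.append({
            "block": b,
            "layers": f"{blk.row_layer}-{blk.col_layer}",
            "positive": pos,
            "negative": neg,
        })
        net.add_nodes_from((n, dict(sub.nodes[n])) for n in sub.nodes)
        net.add_edges_from((u, v, dict(d)) for u, v, d in sub.edges(data=True))
    for n in net.nodes:
        net.nodes[n].setdefault("layer", id_layers.get(n, ""))
    return net, pd.DataFrame(tally_rows)
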