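"""Topology report, natural connectivity, power-law degree fit,
randomized-network comparison, and robustness curves.

All topological metrics are computed on the unweighted simple graph
(edge presence), the standard convention for co-occurrence networks.
Path-based metrics (average path length, diameter) are computed on the
largest connected component when the graph is disconnected, with an
explicit flag; global efficiency uses the 1/inf = 0 convention so it
stays defined globally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, special

from . import config
from .construct import detect_modules

__all__ = [
    "TopologyReport",
    "RobustnessCurve",
    "PowerLawFit",
    "topology_report",
    "natural_connectivity",
    "fit_powerlaw_degree",
    "compare_random",
    "robustness",
]


@dataclass
class TopologyReport:
    """The versioned 17-metric registry plus per-node centralities."""

    global_metrics: dict
    node_table: pd.DataFrame
    flags: list[str] = field(default_factory=list)
    version: str = config.TOPOLOGY_METRICS_VERSION


@dataclass
class RobustnessCurve:
    strategy: str
    table: pd.DataFrame  # fraction + mean/sd columns per metric
    replicates: int
    seed: int | None


@dataclass
class PowerLawFit:
    alpha: float
    xmin: int
    ks_distance: float
    n_tail: int
    degenerate: bool = False


def natural_connectivity(net: nx.Graph) -> float:
    """ln((1/N) sum_i exp(lambda_i)) over adjacency eigenvalues of the
    simple unweighted graph; computed through logsumexp for stability."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    a = nx.to_numpy_array(net, weight=None)
    lam = np.linalg.eigvalsh(a)
    return float(special.logsumexp(lam) - np.log(n))


def _largest_component(net: nx.Graph) -> nx.Graph:
    comp = max(nx.connected_components(net), key=len)
    return net.subgraph(comp)


def topology_report(net: nx.Graph) -> TopologyReport:
    """Compute the headline global metrics and per-node centralities."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    m = net.number_of_edges()
    flags: list[str] = []
    simple = nx.Graph(net)  # strip weights/multi-ness for topology

    n_comp = nx.number_connected_components(simple)
    lcc = _largest_component(simple)
    if n_comp > 1:
        flags.append("disconnected: path metrics computed on largest component")
    if lcc.number_of_nodes() > 1:
        apl = nx.average_shortest_path_length(lcc)
        diam = nx.diameter(lcc)
    else:
        apl, diam = 0.0, 0
        flags.append("largest component is a single node")

    neg = sum(1 for _, _, d in net.edges(data=True) if d.get("sign", 1) == -1)
    try:
        q = detect_modules(nx.Graph(net), mark_edges=False).modularity if m else 0.0
    except ValueError:
        q = 0.0

    degrees = dict(simple.degree())
    betw = nx.betweenness_centrality(simple)
    close = nx.closeness_centrality(simple)
    try:
        eig = nx.eigenvector_centrality_numpy(simple)
    except (nx.NetworkXException, TypeError):
        eig = {v: np.nan for v in simple}
        flags.append("eigenvector centrality failed to converge")

    g = {
        "n_nodes": n,
        "n_edges": m,
        "edge_density": nx.density(simple),
        "proportion_negative_edges": neg / m if m else 0.0,
        "average_degree": 2.0 * m / n,
        "average_path_length": apl,
        "diameter": diam,
        "average_clustering": nx.average_clustering(simple) if n else 0.0,
        "transitivity": nx.transitivity(simple),
        "global_efficiency": nx.global_efficiency(simple),
        "modularity": q,
        "natural_connectivity": natural_connectivity(simple),
        "n_components": n_comp,
        "largest_component_fraction": lcc.number_of_nodes() / n,
        "mean_betweenness": float(np.mean(list(betw.values()))),
        "mean_closeness": float(np.mean(list(close.values()))),
        "mean_eigenvector": float(np.mean(list(eig.values()))),
    }
    assert tuple(g) == config.TOPOLOGY_METRICS

    node_table = pd.DataFrame({
        "node": list(simple.nodes),
        "degree": [degrees[v] for v in simple.nodes],
        "betweenness": [betw[v] for v in simple.nodes],
        "closeness": [close[v] for v in simple.nodes],
        "eigenvector": [eig[v] for v in simple.nodes],
    })
    return TopologyReport(global_metrics=g, node_table=node_table, flags=flags)


# --------------------------------------------------------------------------
# power-law degree fit (Clauset-style discrete MLE)

def _discrete_alpha_mle(x: np.ndarray, xmin: int) -> float:
    """Maximize the discrete power-law likelihood via the Hurwitz zeta."""
    logsum = np.log(x).sum()
    n = x.size

    def nll(alpha):
        return n * np.log(special.zeta(alpha, xmin)) + alpha * logsum

    res = optimize.minimize_scalar(nll, bounds=(1.01, 6.0), method="bounded")
    return float(res.x)


def _discrete_cdf(alpha: float, xmin: int, xs: np.ndarray) -> np.ndarray:
    z = special.zeta(alpha, xmin)
    pmf = np.arange(xmin, xs.max() + 1, dtype=float) ** -alpha / z
    cdf = np.cumsum(pmf)
    return cdf[xs - xmin]


def fit_powerlaw_degree(net_or_degrees, min_tail: int = 50) -> PowerLawFit:
    """Discrete maximum-likelihood power-law fit to the degree sequence.

    ``xmin`` is chosen by minimal Kolmogorov-Smirnov distance over
    candidate values (Clauset-style).  The result is a report, never a
    verdict on scale-freeness.  Requires at least 50 nodes of degree >= 1.
    """
    if isinstance(net_or_degrees, nx.Graph):
        deg = np.array([d for _, d in net_or_degrees.degree()])
    else:
        deg = np.asarray(net_or_degrees, dtype=int)
    x = deg[deg >= 1]
    if x.size < 50:
        raise ValueError(f"need >= 50 positive degrees, got {x.size}")
    if np.ptp(x) == 0:
        return PowerLawFit(alpha=np.nan, xmin=int(x[0]), ks_distance=np.nan,
                           n_tail=x.size, degenerate=True)

    best = None
    for xmin in np.unique(x)[:-1]:
        tail = np.sort(x[x >= xmin])
        if tail.size < min_tail:
            break
        alpha = _discrete_alpha_mle(tail, int(xmin))
        model = _discrete_cdf(alpha, int(xmin), tail)
        emp_hi = np.arange(1, tail.size + 1) / tail.size
        emp_lo = np.arange(0, tail.size) / tail.size
        ks = float(np.max(np.maximum(np.abs(emp_hi - model), np.abs(emp_lo - model))))
        if best is None or ks < best.ks_distance:
            best = PowerLawFit(alpha=alpha, xmin=int(xmin), ks_distance=ks,
                               n_tail=tail.size)
    return best


# --------------------------------------------------------------------------
# randomized-network comparison

_NULL_METRICS = ("average_clustering", "transitivity", "global_efficiency",
                 "average_path_length", "natural_connectivity", "modularity")


def _null_metric_values(g: nx.Graph) -> dict:
    lcc = _largest_component(g)
    return {
        "average_clustering": nx.average_clustering(g),
        "transitivity": nx.transitivity(g),
        "global_efficiency": nx.global_efficiency(g),
        "average_path_length": (nx.average_shortest_path_length(lcc)
                                if lcc.number_of_nodes() > 1 else 0.0),
        "natural_connectivity": natural_connectivity(g),
        "modularity": (detect_modules(nx.Graph(g), mark_edges=False).modularity
                       if g.number_of_edges() else 0.0),
    }


def compare_random(net: nx.Graph, model: str = "er_gnm", n_rand: int = 100,
                   seed: int | None = None) -> pd.DataFrame:
    """z-scores of observed metrics against a randomized-network null.

    ``er_gnm`` draws G(n, m) with the observed node and edge counts;
    ``degree_preserving`` rewires with 10*m double-edge swaps, conserving
    every degree.  z = (obs - mean_null) / sd_null, NaN when sd_null = 0.
    """
    if model not in ("er_gnm", "degree_preserving"):
        raise ValueError("model must be 'er_gnm' or 'degree_preserving'")
    if n_rand < 10:
        raise ValueError("n_rand must be >= 10")
    simple = nx.Graph(net)
    n, m = simple.number_of_nodes(), simple.number_of_edges()
    if model == "degree_preserving" and m < 2:
        raise ValueError("degree_preserving rewiring needs at least 2 edges")
    rng = np.random.default_rng(seed)
    observed = _null_metric_values(simple)
    draws: dict = {k: [] for k in _NULL_METRICS}
    for _ in range(n_rand):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        if model == "er_gnm":
            g = nx.gnm_random_graph(n, m, seed=rep_seed)
        else:
            g = nx.Graph(simple)
            nx.double_edge_swap(g, nswap=10 * m, max_tries=1000 * m + 100,
                                seed=rep_seed)
        vals = _null_metric_values(g)
        for k in _NULL_METRICS:
            draws[k].append(vals[k])
    rows = []
    for k in _NULL_METRICS:
        arr = np.array(draws[k])
        sd = arr.std(ddof=1)
        rows.append({
            "metric": k, "observed": observed[k],
            "null_mean": arr.mean(), "null_sd": sd,
            "z": (observed[k] - arr.mean()) / sd if sd > 0 else np.nan,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# robustness to node removal

def _attack_metrics(g: nx.Graph, n_intact: int) -> tuple[float, float, float]:
    if g.number_of_nodes() == 0:
        return 0.0, 0.0, 0.0
    lcc_frac = len(max(nx.connected_components(g), key=len)) / n_intact
    return lcc_frac, natural_connectivity(g), nx.global_efficiency(g)


def robustness(net: nx.Graph, strategy: str = "random",
               fractions=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
               reps: int = 20, seed: int | None = None) -> RobustnessCurve:
    """Attack curves under cumulative node removal.

    ``random`` removes nodes in ``reps`` independently seeded random
    orders; the targeted strategies remove in descending intact-network
    degree or betweenness (static ranking, ties broken by node id).  The
    largest-component fraction is relative to the intact node count, so
    the fraction-0 row reproduces the intact metrics and fraction 1 gives 0.
    """
    if strategy not in ("random", "degree_targeted", "betweenness_targeted"):
        raise ValueError("unknown strategy")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    fr = np.asarray(fractions, dtype=float)
    if (np.diff(fr) <= 0).any() or fr.min() < 0 or fr.max() > 1:
        raise ValueError("fractions must be ascending within [0, 1]")
    simple = nx.Graph(net)
    n = simple.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")

    if strategy == "random":
        rng = np.random.default_rng(seed)
        orders = [list(rng.permutation(sorted(simple.nodes, key=str)))
                  for _ in range(reps)]
    else:
        if strategy == "degree_targeted":
            score = dict(simple.degree())
        else:
            score = nx.betweenness_centrality(simple)
        order = sorted(simple.nodes, key=lambda v: (-score[v], str(v)))
        orders = [order]

    per_metric: dict = {k: [] for k in ("lcc_fraction", "natural_connectivity",
                                        "global_efficiency")}
    for order in orders:
        traj = {k: [] for k in per_metric}
        g = nx.Graph(simple)
        removed = 0
        for f in fr:
            target = int(round(f * n))
            while removed < target:
                g.remove_node(order[removed])
                removed += 1
            lcc_f, nc, eff = _attack_metrics(g, n)
            traj["lcc_fraction"].append(lcc_f)
            traj["natural_connectivity"].append(nc)
            traj["global_efficiency"].append(eff)
        for k in per_metric:
            per_metric[k].append(traj[k])

    data = {"fraction": fr}
    for k, runs in per_metric.items():
        arr = np.array(runs)
        data[f"{k}_mean"] = arr.mean(axis=0)
        data[f"{k}_sd"] = arr.std(axis=0, ddof=1) if arr.shape[0] > 1 else np.zeros(fr.size)
    return RobustnessCurve(strategy=strategy, table=pd.DataFrame(data),
                           replicates=len(orders), seed=seed)
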