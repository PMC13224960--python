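"""Seeded synthetic data and toy networks.

Everything here is a pure function of its arguments (including the
seed), so every test input can be regenerated on the fly and no data
files ship with the package.

``planted_block_data`` uses a latent-factor construction: features in a
block share a common factor plus independent Gaussian noise, which keeps
memory at O(features x samples) and makes the target within-block
correlation analytically controllable — with factor variance v and noise
variance s^2 the expected pairwise correlation is v / (v + s^2).
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd

from .model import MetaNetwork, OmicsTable

__all__ = ["planted_block_data", "planted_module_network", "toy_networks"]


def planted_block_data(
    n_features: int = 100,
    n_samples: int = 50,
    n_blocks: int = 5,
    within_r: float = 0.7,
    noise_sd: float = 1.0,
    seed: int = 0,
    between_r: float = 0.0,
) -> OmicsTable:
    """Correlated-block feature table for correlation/threshold tests.

    Each block shares a latent factor scaled so the expected within-block
    correlation is ``within_r``; ``between_r > 0`` adds a global factor
    shared by every feature, planting that much correlation between
    blocks.  Block membership is recorded in ``feature_meta['block']``.
    """
    if not 0 < within_r < 1:
        raise ValueError("within_r must be in (0, 1)")
    if not 0 <= between_r < within_r:
        raise ValueError("need 0 <= between_r < within_r")
    if n_features % n_blocks != 0:
        raise ValueError("n_features must be divisible by n_blocks")
    rng = np.random.default_rng(seed)
    per_block = n_features // n_blocks
    s2 = noise_sd**2
    # loadings: total variance v_g + v_b + s2 with v_g/(tot) = between_r
    # and (v_g + v_b)/(tot) = within_r
    tot = s2 / (1.0 - within_r)
    v_g = between_r * tot
    v_b = (within_r - between_r) * tot
    def _unit(v):
        # realized (not just expected) unit variance keeps the planted
        # correlation close to its target for every seed
        return (v - v.mean()) / v.std()

    g = _unit(rng.standard_normal(n_samples))
    values = np.empty((n_features, n_samples))
    blocks = np.repeat(np.arange(n_blocks), per_block)
    for b in range(n_blocks):
        f = _unit(rng.standard_normal(n_samples))
        noise = rng.standard_normal((per_block, n_samples)) * noise_sd
        values[blocks == b] = (np.sqrt(v_g) * g + np.sqrt(v_b) * f)[None, :] + noise
    feature_ids = [f"f{i:04d}" for i in range(n_features)]
    sample_ids = [f"s{j:03d}" for j in range(n_samples)]
    meta = pd.DataFrame({"block": blocks}, index=feature_ids)
    return OmicsTable(
        values=pd.DataFrame(values, index=feature_ids, columns=sample_ids),
        layer="synthetic",
        feature_meta=meta,
    )


def planted_module_network(
    module_sizes=(25, 25, 25, 25),
    p_in: float = 0.5,
    p_out: float = 0.02,
    seed: int = 0,
) -> tuple[MetaNetwork, dict]:
    """Stochastic block model graph with the planted partition attached.

    Returns the network and a node -> module-index dict.  ``p_in <=
    p_out`` is allowed but warns, since recovery is then not guaranteed.
    """
    if p_in <= p_out:
        import warnings

        warnings.warn("p_in <= p_out: module recovery is not guaranteed", stacklevel=2)
    g = nx.stochastic_block_model(list(module_sizes), _block_probs(module_sizes, p_in, p_out),
                                  seed=seed)
    net = MetaNetwork()
    labels = {}
    offset = 0
    for b, size in enumerate(module_sizes):
        for i in range(offset, offset + size):
            name = f"n{i:04d}"
            labels[i] = name
            net.add_node(name, planted_module=b)
        offset += size
    for u, v in g.edges():
        net.add_edge(labels[u], labels[v], weight=1.0)
    partition = {labels[i]: g.nodes[i]["block"] for i in g.nodes}
    return net, partition


def _block_probs(sizes, p_in, p_out):
    k = len(sizes)
    return [[p_in if i == j else p_out for j in range(k)] for i in range(k)]


def toy_networks(name: str) -> MetaNetwork:
    """Canonical hand-checkable graphs: k2, k3, k4, p3, two_triangles,
    star10, two_k4_bridge."""
    edges = {
        "k2": [("a", "b")],
        "k3": [("a", "b"), ("b", "c"), ("a", "c")],
        "k4": list(itertools.combinations("abcd", 2)),
        "p3": [("a", "b"), ("b", "c")],
        "two_triangles": [("a", "b"), ("b", "c"), ("a", "c"),
                          ("d", "e"), ("e", "f"), ("d", "f")],
        "star10": [("hub", f"leaf{i}") for i in range(1, 10)],
        "two_k4_bridge": (list(itertools.combinations("abcd", 2))
                          + list(itertools.combinations("efgh", 2))
                          + [("d", "e")]),
    }
    if name not in edges:
        raise ValueError(f"unknown toy network {name!r}; choose from {sorted(edges)}")
    net = MetaNetwork()
    net.add_edges_from(edges[name])
    return net
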