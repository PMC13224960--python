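"""Geometric contracts of the layout family."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

import omicnet as on

STAR_RING = [(0, 3), (0.8, 1), (2.8, 1), (1.2, -0.3), (1.8, -2.4),
             (0, -1), (-1.8, -2.4), (-1.2, -0.3), (-2.8, 1), (-0.8, 1)]


def k_nodes(k):
    g = nx.Graph()
    g.add_nodes_from(f"n{i}" for i in range(k))
    return g


class TestBasicLayouts:
    def test_circle_convention(self):
        c = on.c_net_layout(k_nodes(4), "circle")
        xy = c.table[["x", "y"]].to_numpy()
        np.testing.assert_allclose(xy, [(0, 1), (-1, 0), (0, -1), (1, 0)], atol=1e-12)

    def test_grid_row_major(self):
        c = on.c_net_layout(k_nodes(9), "grid")
        xy = c.table[["x", "y"]].to_numpy()
        expect = [(i % 3, i // 3) for i in range(9)]
        np.testing.assert_allclose(xy, expect)

    def test_seeded_force_directed_reproducible(self):
        g = nx.karate_club_graph()
        a = on.c_net_layout(g, "force_directed", seed=11)
        b = on.c_net_layout(g, "force_directed", seed=11)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_unknown_algorithm_lists_registry(self):
        with pytest.raises(ValueError, match="circle"):
            on.c_net_layout(k_nodes(3), "no_such_layout")

    def test_every_layout_covers_nodes_finitely(self):
        g = nx.path_graph(7)
        from omicnet.layouts import LAYOUT_REGISTRY
        for name in LAYOUT_REGISTRY:
            c = on.c_net_layout(g, name, seed=1)
            assert c.covers(g.nodes)
            assert np.isfinite(c.table[["x", "y"]].to_numpy()).all()


class TestPolygonFamily:
    def groups(self, g, k):
        return {n: f"g{i % k}" for i, n in enumerate(sorted(g.nodes))}

    def test_single_nodes_at_side_midpoints(self):
        g = k_nodes(3)
        groups = {n: n for n in g.nodes}
        c = on.as_polygon(g, groups, 3)
        verts = np.array([(math.cos(math.radians(90 + 120 * i)),
                           math.sin(math.radians(90 + 120 * i))) for i in range(4)])
        mids = [(verts[i] + verts[(i + 1) % 3]) / 2 for i in range(3)]
        xy = c.table.sort_values("node")[["x", "y"]].to_numpy()
        np.testing.assert_allclose(xy, mids[:3], atol=1e-12)

    def test_three_nodes_quarter_positions(self):
        g = k_nodes(3)
        c = on.as_polygon(g, {n: "only" for n in g.nodes}, 4)
        a = np.array([0.0, 1.0])
        b = np.array([-1.0, 0.0])
        expect = [a + f * (b - a) for f in (0.25, 0.5, 0.75)]
        xy = c.table.sort_values("node")[["x", "y"]].to_numpy()
        np.testing.assert_allclose(xy, expect, atol=1e-12)

    def test_collinearity_with_side(self):
        g = k_nodes(12)
        c = on.as_polygon(g, self.groups(g, 4), 5)
        for _, row in c.table.iterrows():
            a, b = map(np.asarray, c.group_meta[row["group"]]["endpoints"])
            d, q = b - a, np.array([row.x, row.y]) - a
            cross = abs(d[0] * q[1] - d[1] * q[0])
            assert cross < 1e-9

    def test_more_groups_than_sides(self):
        g = k_nodes(4)
        with pytest.raises(ValueError, match="exceed"):
            on.as_polygon(g, {n: n for n in g.nodes}, 3)

    def test_polycircle_centers_and_radius(self):
        g = k_nodes(9)
        groups = self.groups(g, 3)
        c = on.as_polycircle(g, groups, 3)
        for label, meta in c.group_meta.items():
            anchor = np.asarray(meta["anchor"])
            assert np.hypot(*anchor) == pytest.approx(1.0, abs=1e-12)
            members = c.table[c.table.group == label]
            d = np.hypot(members.x - anchor[0], members.y - anchor[1])
            assert (d <= 0.3 + 1e-9).all()

    def test_polycircle_single_group_at_top_vertex(self):
        g = k_nodes(3)
        c = on.as_polycircle(g, {n: "g" for n in g.nodes}, 1)
        assert c.group_meta["g"]["anchor"] == pytest.approx((0.0, 1.0), abs=1e-12)


class TestSpatstat:
    def test_uniform_inside_square(self):
        g = k_nodes(1000)
        c = on.spatstat_layout(g, [(0, 0), (1, 0), (1, 1), (0, 1)],
                               "uniform_inside", seed=5)
        poly = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)]).buffer(1e-9)
        assert all(poly.contains(Point(x, y)) for x, y in
                   zip(c.table.x, c.table.y))
        assert c.table.x.mean() == pytest.approx(0.5, abs=0.05)
        assert c.table.y.mean() == pytest.approx(0.5, abs=0.05)

    def test_concave_star_containment(self):
        g = k_nodes(500)
        c = on.spatstat_layout(g, STAR_RING, "uniform_inside", seed=6)
        poly = Polygon(STAR_RING).buffer(1e-9)
        assert all(poly.contains(Point(x, y)) for x, y in zip(c.table.x, c.table.y))

    def test_matches_rejection_sampler_distribution(self):
        """Triangulation sampling agrees with a naive rejection oracle."""
        rng = np.random.default_rng(8)
        poly = Polygon(STAR_RING)
        minx, miny, maxx, maxy = poly.bounds
        ref = []
        while len(ref) < 2000:
            x = rng.uniform(minx, maxx)
            y = rng.uniform(miny, maxy)
            if poly.contains(Point(x, y)):
                ref.append((x, y))
        ref = np.array(ref)
        c = on.spatstat_layout(k_nodes(2000), STAR_RING, "uniform_inside", seed=9)
        got = c.table[["x", "y"]].to_numpy()
        np.testing.assert_allclose(got.mean(0), ref.mean(0), atol=0.1)
        np.testing.assert_allclose(got.std(0), ref.std(0), atol=0.1)

    def test_on_edges_square(self):
        c = on.spatstat_layout(k_nodes(4), [(0, 0), (1, 0), (1, 1), (0, 1)],
                               "on_edges")
        xy = {tuple(r) for r in c.table[["x", "y"]].to_numpy()}
        assert xy == {(0, 0), (1, 0), (1, 1), (0, 1)}

    def test_self_intersecting_rejected(self):
        bow = [(0, 0), (1, 1), (1, 0), (0, 1)]
        with pytest.raises(ValueError, match="self-intersect"):
            on.spatstat_layout(k_nodes(5), bow, "uniform_inside", seed=1)

    def test_seeded_reproducible(self):
        a = on.spatstat_layout(k_nodes(50), STAR_RING, "uniform_inside", seed=3)
        b = on.spatstat_layout(k_nodes(50), STAR_RING, "uniform_inside", seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestGroupedLayouts:
    def two_group_net(self):
        g = nx.Graph()
        g.add_nodes_from(f"a{i}" for i in range(4))
        g.add_nodes_from(f"b{i}" for i in range(4))
        groups = {n: n[0] for n in g.nodes}
        return g, groups

    def test_centroids_on_anchors(self):
        g, groups = self.two_group_net()
        c = on.g_layout(g, groups, {"a": {"anchor": (-2, 0), "scale": 1},
                                    "b": {"anchor": (2, 0), "scale": 1}})
        means = c.table.groupby("group")[["x", "y"]].mean()
        np.testing.assert_allclose(means.loc["a"], (-2, 0), atol=1e-9)
        np.testing.assert_allclose(means.loc["b"], (2, 0), atol=1e-9)

    def test_scale_halves_pairwise_distances(self):
        g, groups = self.two_group_net()
        c1 = on.g_layout(g, groups, {"a": {"scale": 1.0}, "b": {"scale": 1.0}})
        c2 = on.g_layout(g, groups, {"a": {"scale": 0.5}, "b": {"scale": 1.0}})
        sub1 = c1.table[c1.table.group == "a"][["x", "y"]].to_numpy()
        sub2 = c2.table[c2.table.group == "a"][["x", "y"]].to_numpy()
        d1 = np.linalg.norm(sub1[0] - sub1[1])
        d2 = np.linalg.norm(sub2[0] - sub2[1])
        assert d2 == pytest.approx(d1 / 2, abs=1e-12)

    def test_mixed_inner_algorithms(self):
        g, groups = self.two_group_net()
        c = on.g_layout(g, groups, {
            "a": {"anchor": (0, 0), "algorithm": "grid"},
            "b": {"anchor": (5, 5), "algorithm": "circle"}})
        b = c.table[c.table.group == "b"]
        d = np.hypot(b.x - 5, b.y - 5)
        np.testing.assert_allclose(d, d.iloc[0])  # all on a circle around anchor

    def test_missing_group_rejected(self):
        g, groups = self.two_group_net()
        del groups["a0"]
        with pytest.raises(ValueError, match="without group"):
            on.g_layout(g, groups, {})

    def test_circlepack_radius_rule_and_nonoverlap(self):
        g = nx.Graph()
        g.add_nodes_from(range(10))
        modules = {i: (1 if i < 9 else 2) for i in range(10)}
        c = on.g_layout_circlepack(g, modules)
        r1 = c.group_meta[1]["radius"]
        r2 = c.group_meta[2]["radius"]
        assert r1 / r2 == pytest.approx(3.0)
        a1 = np.asarray(c.group_meta[1]["anchor"])
        a2 = np.asarray(c.group_meta[2]["anchor"])
        assert np.linalg.norm(a1 - a2) >= r1 + r2 - 1e-9

    def test_circlepack_single_module_at_origin(self):
        g = nx.Graph()
        g.add_node("x")
        c = on.g_layout_circlepack(g, {"x": 1})
        assert c.group_meta[1]["anchor"] == (0.0, 0.0)

    def test_circlepack_pairwise_nonoverlap_many(self):
        rng = np.random.default_rng(4)
        g = nx.Graph()
        g.add_nodes_from(range(60))
        modules = {i: int(rng.integers(1, 9)) for i in range(60)}
        c = on.g_layout_circlepack(g, modules)
        metas = list(c.group_meta.values())
        for i in range(len(metas)):
            for j in range(i + 1, len(metas)):
                d = np.linalg.norm(np.asarray(metas[i]["anchor"])
                                   - np.asarray(metas[j]["anchor"]))
                assert d >= metas[i]["radius"] + metas[j]["radius"] - 1e-9

    def test_multilayer_offset_and_shear(self):
        g = nx.Graph()
        g.add_nodes_from(["a0", "a1", "b0", "b1"])
        layers = {n: n[0] for n in g.nodes}
        c = on.g_layout_multi_layer(g, layers, dz=1.0, alpha_deg=90.0)
        t = c.table.set_index("node")
        # alpha=90: no shear, identical inner layouts -> pure dz offset
        assert t.loc["b0", "y"] - t.loc["a0", "y"] == pytest.approx(1.0, abs=1e-12)
        assert t.loc["b0", "x"] == pytest.approx(t.loc["a0", "x"], abs=1e-12)

    def test_multilayer_invertible(self):
        g = nx.Graph()
        g.add_nodes_from(["a0", "a1", "b0"])
        layers = {n: n[0] for n in g.nodes}
        dz, alpha = 2.0, 60.0
        c = on.g_layout_multi_layer(g, layers, dz=dz, alpha_deg=alpha)
        ca, sa = math.cos(math.radians(alpha)), math.sin(math.radians(alpha))
        t = c.table.set_index("node")
        idx = {n: c.group_meta[layers[n]]["index"] for n in g.nodes}
        for n in g.nodes:
            y0 = (t.loc[n, "y"] - idx[n] * dz) / sa
            x0 = t.loc[n, "x"] - y0 * ca
            assert np.isfinite(x0) and np.isfinite(y0)


class TestTransforms:
    def square(self):
        return on.Coors(table=pd.DataFrame(
            {"node": list("abcd"), "x": [1.0, 0.0, -1.0, 0.0],
             "y": [0.0, 1.0, 0.0, -1.0]}))

    def test_rotate_about_origin(self):
        out = on.transform_coors(self.square(), "rotate",
                                 {"degrees": 90, "origin": (0, 0)})
        t = out.table.set_index("node")
        np.testing.assert_allclose(t.loc["a", ["x", "y"]], (0, 1), atol=1e-12)

    def test_mirror_definitions(self):
        t = on.transform_coors(self.square(), "mirror_x",
                               {"origin": (0, 0)}).table.set_index("node")
        np.testing.assert_allclose(t.loc["b", ["x", "y"]], (0, -1), atol=1e-12)
        t = on.transform_coors(self.square(), "mirror_y",
                               {"origin": (0, 0)}).table.set_index("node")
        np.testing.assert_allclose(t.loc["a", ["x", "y"]], (-1, 0), atol=1e-12)

    def test_full_rotation_identity(self):
        base = self.square()
        out = on.transform_coors(base, "rotate", {"degrees": 360})
        np.testing.assert_allclose(out.table[["x", "y"]], base.table[["x", "y"]],
                                   atol=1e-12)

    def test_scale_zero_rejected(self):
        with pytest.raises(ValueError):
            on.transform_coors(self.square(), "scale", {"factor": 0})

    def test_rotate_then_unrotate_identity(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        base = self.square()

        @given(st.floats(min_value=-360, max_value=360))
        @settings(deadline=None, derandomize=True, max_examples=100)
        def check(angle):
            fwd = on.transform_coors(base, "rotate", {"degrees": angle})
            back = on.transform_coors(fwd, "rotate", {"degrees": -angle})
            np.testing.assert_allclose(back.table[["x", "y"]],
                                       base.table[["x", "y"]], atol=1e-9)

        check()

    def test_default_center_is_centroid(self):
        coors = on.Coors(table=pd.DataFrame(
            {"node": ["a", "b"], "x": [1.0, 3.0], "y": [1.0, 1.0]}))
        out = on.transform_coors(coors, "scale", {"factor": 2.0})
        t = out.table.set_index("node")
        np.testing.assert_allclose(t.loc["a", ["x", "y"]], (0.0, 1.0))
        np.testing.assert_allclose(t.loc["b", ["x", "y"]], (4.0, 1.0))
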