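"""Per-compartment metrics, profiles, normalization, correlations and FΔ
curves, checked against exhaustive per-metric oracles."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cytomorph import quantify as q
from cytomorph.treeio import ChannelStats, MultiSignalTree, NeuronTree

from conftest import make_node, random_binary_tree


def nx_digraph(tree):
    """Independent graph view of a tree, for oracle computations."""
    g = nx.DiGraph()
    for n in tree.nodes:
        g.add_node(n.id, pos=n.position)
        if n.parent_id != -1:
            g.add_edge(n.parent_id, n.id,
                       length=math.dist(
                           next(m for m in tree.nodes
                                if m.id == n.parent_id).position, n.position))
    return g


def annotate_uniform(tree, F=1.0, asi_mt=100.0, asi_fa=50.0):
    ms = MultiSignalTree(tree=tree)
    ms.add_channel("mt", {n.id: ChannelStats(F, asi_mt, 0.0) for n in tree.nodes})
    ms.add_channel("fa", {n.id: ChannelStats(F, asi_fa, 0.0) for n in tree.nodes})
    return ms


class TestFormulas:
    @pytest.mark.parametrize("F,ASI,W,expect", [
        (0.0, 123.0, 4.0, 0.0),
        (0.5, 100.0, 2.0, 100.0),
        (1.0, 255.0, 1.0, 255.0),
    ])
    def test_cytoskeletal_quantity(self, F, ASI, W, expect):
        assert q.cytoskeletal_quantity(F, ASI, W) == expect

    def test_cq_rejects_out_of_range_fraction(self):
        with pytest.raises(ValueError):
            q.cytoskeletal_quantity(1.5, 100, 1)

    @pytest.mark.parametrize("cur,par,expect", [
        (10.0, 10.0, 0.0),
        (15.0, 10.0, 0.5),
        (5.0, 10.0, -0.5),
    ])
    def test_relative_change(self, cur, par, expect):
        assert q.relative_change(cur, par) == pytest.approx(expect)

    def test_relative_change_undefined_at_zero_parent(self):
        assert math.isnan(q.relative_change(5.0, 0.0))


class TestArborLength:
    def test_tips_are_zero_and_soma_is_total(self, y_tree):
        arbor = q.arbor_length(y_tree)
        total = sum(q.compartment_lengths(y_tree).values())
        assert arbor[4] == 0.0 and arbor[5] == 0.0
        assert arbor[1] == pytest.approx(total)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_subtree_sum(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_binary_tree(rng, 30)
        arbor = q.arbor_length(tree)
        g = nx_digraph(tree)
        for n in tree.nodes:
            want = sum(g.edges[e]["length"]
                       for d in nx.descendants(g, n.id)
                       for e in g.in_edges(d))
            assert arbor[n.id] == pytest.approx(want)

    def test_local_conservation_at_bifurcations(self, y_tree):
        arbor = q.arbor_length(y_tree)
        lengths = q.compartment_lengths(y_tree)
        # node 3 bifurcates into 4 and 5
        assert arbor[3] == pytest.approx(
            arbor[4] + lengths[4] + arbor[5] + lengths[5])


class TestEventsAndStrahler:
    def test_leaf_chain_and_bifurcation_classes(self, y_tree):
        ev = q.classify_events(y_tree)
        assert ev[1] == "root"
        assert ev[2] == "elongation"
        assert ev[3] == "bifurcation"
        assert ev[4] == ev[5] == "termination"

    @pytest.mark.parametrize("depth", [2, 3, 4])
    def test_full_binary_tree_census(self, depth):
        """A full binary tree with L leaves has L terminations and L−1
        bifurcations (root excluded from events)."""
        nodes = [make_node(1, -1, tag=1)]
        frontier = [1]
        nid = 2
        for level in range(depth):
            nxt = []
            for p in frontier:
                for _ in range(2):
                    nodes.append(make_node(nid, p, x=float(nid)))
                    nxt.append(nid)
                    nid += 1
            frontier = nxt
        t = NeuronTree(nodes=nodes)
        ev = q.classify_events(t)
        L = 2 ** depth
        counts = pd.Series(list(ev.values())).value_counts()
        assert counts["termination"] == L
        # root has 2 children but is excluded; internal bifurcations = L-2
        assert counts.get("bifurcation", 0) == L - 2
        strahler = q.strahler_order(t)
        assert strahler[1] == depth + 1  # root order of a balanced tree
        assert all(strahler[n] == 1 for n, e in ev.items()
                   if e == "termination")

    def test_multifurcation_raises(self):
        t = NeuronTree(nodes=[make_node(1, -1, tag=1)] +
                       [make_node(i, 1, x=i) for i in (2, 3, 4)])
        with pytest.raises(ValueError, match="children"):
            q.classify_events(t)

    def test_single_branch_all_order_one(self):
        t = NeuronTree(nodes=[make_node(i, i - 1 if i > 1 else -1, x=i)
                              for i in range(1, 6)])
        assert set(q.strahler_order(t).values()) == {1}

    def test_two_leaves_meeting_make_order_two(self, y_tree):
        s = q.strahler_order(y_tree)
        assert s[4] == s[5] == 1
        assert s[3] == 2 and s[1] == 2

    @pytest.mark.parametrize("seed", range(4))
    def test_strahler_matches_recursive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tree = random_binary_tree(rng, 40)
        kids = tree.children_map()

        def oracle(nid):
            ks = kids[nid]
            if not ks:
                return 1
            orders = sorted(oracle(k) for k in ks)
            if len(orders) == 1:
                return orders[0]
            return orders[1] + 1 if orders[0] == orders[1] else orders[1]

        got = q.strahler_order(tree)
        root = tree.roots()[0].id
        assert got[root] == oracle(root)
        assert got[root] == max(got.values())


class TestMetricsTable:
    def test_twenty_columns_in_order(self, y_tree):
        m = q.metrics_table(annotate_uniform(y_tree))
        assert list(m.columns) == q.METRIC_COLUMNS
        assert m.shape == (5, 20)

    def test_root_row_conventions(self, y_tree):
        m = q.metrics_table(annotate_uniform(y_tree))
        root = m.loc[1]
        assert root["path_distance"] == 0
        assert root["topological_distance"] == 0
        assert root["branch_order"] == 0
        assert math.isnan(root["rel_change_fa_quantity"])

    def test_hand_built_fixture_against_per_metric_oracles(self, y_tree):
        """Every metric on the 5-node Y-tree, verified by hand arithmetic:
        stem 0→4→8, bifurcation at 8, two tips at (11,±3)."""
        ms = annotate_uniform(y_tree, F=0.5, asi_mt=100.0, asi_fa=60.0)
        m = q.metrics_table(ms)
        tip_len = math.dist((8, 0, 0), (11, 3, 0))  # sqrt(18)
        # quantities: CQ = F*ASI*W, W = 2r (r=2 at root, 1 elsewhere)
        assert m.loc[1, "microtubule_quantity"] == pytest.approx(0.5 * 100 * 4)
        assert m.loc[2, "microtubule_quantity"] == pytest.approx(0.5 * 100 * 2)
        assert m.loc[2, "factin_intensity"] == pytest.approx(0.5 * 60)
        # topology
        assert list(m["topological_distance"]) == [0, 1, 2, 3, 3]
        assert list(m["branch_order"]) == [0, 0, 0, 1, 1]
        assert list(m["strahler_order"]) == [2, 2, 2, 1, 1]
        assert list(m["topo_event"]) == [
            "root", "elongation", "bifurcation", "termination", "termination"]
        assert m.loc[4, "path_distance"] == pytest.approx(8 + tip_len)
        assert m.loc[4, "compartment_length"] == pytest.approx(tip_len)
        assert m.loc[1, "arbor_length"] == pytest.approx(8 + 2 * tip_len)
        assert m.loc[4, "arbor_length"] == 0.0
        # uniform CQ along same-radius chain → relative change 0
        assert m.loc[3, "rel_change_mt_quantity"] == pytest.approx(0.0)
        # root→node2 halves the diameter → quantity halves
        assert m.loc[2, "rel_change_mt_quantity"] == pytest.approx(-0.5)
        # intensity (thickness-normalized) is uniform → change 0
        assert m.loc[2, "rel_change_mt_intensity"] == pytest.approx(0.0)
        assert list(m["parent_id"]) == [-1, 1, 2, 3, 3]
        assert list(m["compartment_type"]) == [
            "soma", "dendrite", "dendrite", "dendrite", "dendrite"]
        # integral = downstream sum of CQ*length incl. self
        cq2 = 0.5 * 100 * 2
        want_int4 = cq2 * tip_len
        assert m.loc[4, "integral_microtubule"] == pytest.approx(want_int4)
        want_int3 = cq2 * 4 + 2 * want_int4
        assert m.loc[3, "integral_microtubule"] == pytest.approx(want_int3)

    def test_total_compartment_length_equals_soma_arbor_length(self):
        rng = np.random.default_rng(11)
        tree = random_binary_tree(rng, 30)
        m = q.metrics_table(annotate_uniform(tree))
        assert m["compartment_length"].sum() == pytest.approx(
            m.loc[tree.roots()[0].id, "arbor_length"])

    def test_missing_channel_rejected(self, y_tree):
        ms = MultiSignalTree(tree=y_tree)
        ms.add_channel("mt", {n.id: ChannelStats(1, 1, 0) for n in y_tree.nodes})
        with pytest.raises(KeyError):
            q.metrics_table(ms)


class TestDistributionProfile:
    def test_length_conservation_both_axes(self):
        rng = np.random.default_rng(5)
        tree = random_binary_tree(rng, 40)
        m = q.metrics_table(annotate_uniform(tree))
        total = m["compartment_length"].sum()
        for axis in ("strahler", "path_distance"):
            p = q.distribution_profile(m, axis=axis, bin_width=10.0)
            assert p.total_length == pytest.approx(total)

    def test_single_branch_hand_binned(self):
        """10 μm chain of 2 μm compartments, 5 μm path bins: compartments
        end at path 2,4 (bin 1) and 6,8,10 (bin 2)."""
        t = NeuronTree(nodes=[make_node(i, i - 1 if i > 1 else -1,
                                        x=2.0 * (i - 1), tag=1 if i == 1 else 3)
                              for i in range(1, 7)])
        m = q.metrics_table(annotate_uniform(t))
        p = q.distribution_profile(m, axis="path_distance", bin_width=5.0)
        assert p.length_per_bin.tolist() == pytest.approx([4.0, 6.0])

    def test_chain_strahler_profile_all_order_one(self):
        t = NeuronTree(nodes=[make_node(i, i - 1 if i > 1 else -1, x=float(i))
                              for i in range(1, 8)])
        m = q.metrics_table(annotate_uniform(t))
        p = q.distribution_profile(m, axis="strahler")
        assert p.bins.tolist() == [1]
        assert p.total_length == pytest.approx(6.0)

    def test_non_positive_bin_width_rejected(self, y_tree):
        m = q.metrics_table(annotate_uniform(y_tree))
        with pytest.raises(ValueError):
            q.distribution_profile(m, axis="path_distance", bin_width=0)


class TestNormalization:
    def _profiles(self, seeds, scale=1.0):
        out = []
        for s in seeds:
            rng = np.random.default_rng(s)
            tree = random_binary_tree(rng, 25)
            ms = annotate_uniform(tree, asi_mt=100.0 * scale, asi_fa=50.0 * scale)
            out.append(q.distribution_profile(q.metrics_table(ms)))
        return out

    def test_reference_group_normalizes_to_unit_mean_total(self):
        profiles = self._profiles(range(4))
        ref = q.compute_reference(profiles)
        normed = q.normalize_profiles(profiles, ref)
        assert np.mean([p.total_mt for p in normed]) == pytest.approx(1.0)
        assert np.mean([p.total_fa for p in normed]) == pytest.approx(1.0)

    def test_doubled_group_normalizes_to_two(self):
        ref_profiles = self._profiles(range(4))
        ref = q.compute_reference(ref_profiles)
        doubled = self._profiles(range(4), scale=2.0)
        normed = q.normalize_profiles(doubled, ref)
        assert np.mean([p.total_mt for p in normed]) == pytest.approx(2.0)

    def test_binwise_ratios_preserved(self):
        a = self._profiles([1])[0]
        b = self._profiles([1], scale=3.0)[0]
        ref = q.compute_reference([a])
        na, nb = q.normalize_profiles([a, b], ref)
        mask = na.mt_per_bin > 0
        assert np.allclose(nb.mt_per_bin[mask] / na.mt_per_bin[mask], 3.0)

    def test_zero_reference_total_rejected(self):
        with pytest.raises(ValueError):
            q.NormalizationReference(0.0, 1.0)


class TestCorrelations:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(3)
        tree = random_binary_tree(rng, 30)
        m = q.metrics_table(annotate_uniform(tree))
        m2 = m.copy()
        m2["microtubule_quantity"] = m2["arbor_length"]
        r = q.arborlength_correlations(m2)
        assert r["microtubule_quantity"] == pytest.approx(1.0)

    def test_exact_linear_dependence(self):
        rng = np.random.default_rng(4)
        tree = random_binary_tree(rng, 30)
        m = q.metrics_table(annotate_uniform(tree))
        m2 = m.copy()
        m2["microtubule_quantity"] = 3.0 * m2["arbor_length"] + 5.0
        assert q.arborlength_correlations(m2)["microtubule_quantity"] == \
            pytest.approx(1.0)

    def test_zero_variance_predictor_is_nan(self):
        rng = np.random.default_rng(5)
        tree = random_binary_tree(rng, 20)
        m = q.metrics_table(annotate_uniform(tree))  # uniform radius? no
        m2 = m.copy()
        m2["diameter"] = 1.0
        assert math.isnan(q.arborlength_correlations(m2)["diameter"])

    def test_mt_built_as_dominant_predictor_wins(self):
        """When MT is constructed as the strongest linear correlate of
        arbor length, r(MT) exceeds the other four coefficients."""
        rng = np.random.default_rng(6)
        frames = []
        for s in range(5):
            tree = random_binary_tree(np.random.default_rng(s), 40)
            m = q.metrics_table(annotate_uniform(tree))
            m["microtubule_quantity"] = (
                m["arbor_length"] + rng.normal(0, 0.05 * m["arbor_length"].std(),
                                               len(m)))
            m["factin_quantity"] = rng.uniform(0, 100, len(m))
            m["diameter"] = rng.uniform(0.5, 4, len(m))
            frames.append(m)
        pooled = pd.concat(frames)
        r = q.arborlength_correlations(pooled)
        assert all(r["microtubule_quantity"] > abs(v)
                   for k, v in r.items() if k != "microtubule_quantity")


class TestFdeltaCurves:
    def test_ecdf_reaches_one_and_is_monotone(self):
        rng = np.random.default_rng(8)
        tree = random_binary_tree(rng, 40)
        ms = MultiSignalTree(tree=tree)
        ms.add_channel("mt", {n.id: ChannelStats(1.0, float(rng.uniform(50, 200)), 0)
                              for n in tree.nodes})
        ms.add_channel("fa", {n.id: ChannelStats(1.0, float(rng.uniform(50, 200)), 0)
                              for n in tree.nodes})
        m = q.metrics_table(ms)
        curves = q.fdelta_cumulative_curves(m)
        for ev, (vals, cum) in curves.items():
            if len(vals):
                assert cum[-1] == pytest.approx(1.0)
                assert (np.diff(vals) >= 0).all()
                assert (np.diff(cum) > 0).all()
                assert ((cum >= 0) & (cum <= 1)).all()

    def test_known_three_value_class(self):
        df = pd.DataFrame({
            "topo_event": ["bifurcation"] * 3,
            "rel_change_fa_quantity": [-0.5, 0.0, 0.5],
        })
        with pytest.warns(UserWarning):  # elongation/termination empty
            curves = q.fdelta_cumulative_curves(df)
        vals, cum = curves["bifurcation"]
        assert vals.tolist() == [-0.5, 0.0, 0.5]
        assert cum.tolist() == pytest.approx([1 / 3, 2 / 3, 1.0])
        assert len(curves["elongation"][0]) == 0


class TestPlotting:
    def test_profile_and_comparison_plots_render(self):
        import matplotlib
        matplotlib.use("Agg")
        from cytomorph import simulate as sim

        rng = np.random.default_rng(9)
        tree = random_binary_tree(rng, 30)
        m = q.metrics_table(annotate_uniform(tree))
        p = q.distribution_profile(m)
        ax = q.plot_profiles({"groupA": [p]}, quantity="mt")
        assert ax.get_legend() is not None
        res = sim.compare_distributions([p], [p])
        ax2 = sim.plot_comparison(res, quantity="length")
        assert len(ax2.get_lines()) == 2
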