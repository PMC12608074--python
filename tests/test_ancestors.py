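"""Ancestor-location queries: means, variance decomposition, tracks."""
import numpy as np
import pytest

import argbm
from argbm import ARG, AncestorQuery, BrownianDispersal
from argbm.ancestors import locate, resolve_query, track_frame
from argbm.paths import enumerate_minimal_paths, shared_times

from conftest import small_sim_arg


def all_upward_paths(arg, start):
    """Every node path from ``start`` to a root (exhaustive oracle)."""
    done, stack = [], [[start]]
    while stack:
        cur = stack.pop()
        ps = arg.parents(cur[-1])
        if not ps:
            done.append(tuple(cur))
        for p in ps:
            stack.append(cur + [p])
    return done


class TestResolveQuery:
    def test_sample_at_own_time_matches_sp_row(self, loop_arg):
        basis = enumerate_minimal_paths(loop_arg)
        sp = shared_times(loop_arg, basis)
        point = resolve_query(
            loop_arg, AncestorQuery(sample_id=0, position=0.5, time=0.0), basis
        )
        assert point.node == 0
        # the canonical path of sample 0 is basis path 0
        assert np.allclose(point.sa, sp[0])
        assert point.ta == pytest.approx(sp[0, 0])

    def test_root_time_query(self, loop_arg):
        basis = enumerate_minimal_paths(loop_arg)
        point = resolve_query(
            loop_arg, AncestorQuery(sample_id=1, position=0.5, time=4.0), basis
        )
        assert point.node == 5 and point.ta == 0.0

    def test_mid_edge_shared_times_oracle(self, two_tree):
        # ancestor of C at position 0.2, time 2.5: half way up edge F->E;
        # root path shares 0.5 with C's tree-1 path (rest of F->E), plus
        # E->Q wait E->G->Q above; overlaps computed by hand from the toy
        basis = enumerate_minimal_paths(two_tree)
        q = AncestorQuery(sample_id=2, position=0.2, time=2.5)
        point = resolve_query(two_tree, q, basis)
        assert point.edge == (4, 6)
        expected = {}
        for i, path in enumerate(basis.paths):
            edges = set(zip(path[:-1], path[1:]))
            t = 0.0
            if (4, 6) in edges:
                t += 3.0 - 2.5  # remainder of F->E above the point
            if (6, 7) in edges:
                t += 1.0  # E->G
            if (7, 8) in edges:
                t += 1.0  # G->Q
            expected[i] = t
        assert np.allclose(point.sa, [expected[i] for i in range(len(basis))])
        assert point.ta == pytest.approx(5.0 - 2.5)

    def test_out_of_range_errors(self, two_tree):
        basis = enumerate_minimal_paths(two_tree)
        with pytest.raises(ValueError):
            resolve_query(two_tree, AncestorQuery(0, 5.0, 1.0), basis)
        with pytest.raises(ValueError):
            resolve_query(two_tree, AncestorQuery(0, 0.5, -1.0), basis)
        with pytest.raises(ValueError, match="older than the local root"):
            resolve_query(two_tree, AncestorQuery(0, 0.5, 99.0), basis)


class TestLocate:
    def test_sample_location_is_exact(self, two_tree, two_tree_locations):
        model = BrownianDispersal().fit(two_tree, two_tree_locations)
        est = model.locate(2, 0.5, 0.0)
        assert est.mean[0] == pytest.approx(0.5)
        assert est.V == pytest.approx(0.0, abs=1e-9)
        assert est.V_bm >= 0 and est.V_root >= 0

    def test_single_sample_variance_grows_from_sample(self):
        # one sample, one root: the root MLE is the sample location and the
        # total V at time tau is exactly tau (BM forward from the only
        # observation), splitting into a sample-root bridge term plus root
        # uncertainty (t - ta)^2 / t
        t = 8.0
        arg = ARG.from_structure([0, t], [0], [(0, 1, 0, 1)], 1)
        model = BrownianDispersal().fit(arg, np.array([3.0]))
        assert model.root_locations_[0, 0] == pytest.approx(3.0)
        for tau in [0.0, 2.0, 5.0, 8.0]:
            est = model.locate(0, 0.5, tau, dispersal=1.0)
            ta = t - tau
            assert est.mean[0] == pytest.approx(3.0)
            assert est.V == pytest.approx(tau, abs=1e-9)
            assert est.V_bm == pytest.approx(ta * (t - ta) / t, abs=1e-9)
            assert est.V_root == pytest.approx((t - ta) ** 2 / t, abs=1e-9)

    def test_invariant_to_arbitrary_root_path(self, loop_arg, two_tree,
                                              two_tree_locations):
        cases = [
            (loop_arg, np.array([0.0, 1.0]), AncestorQuery(0, 0.5, 1.5)),
            (two_tree, two_tree_locations, AncestorQuery(2, 0.2, 1.0)),
        ]
        for arg, loc, q in cases:
            model = BrownianDispersal().fit(arg, loc)
            basis = model.basis_
            ref = locate(arg, loc, model, q)
            node, edge = ref.point.node, ref.point.edge
            start = node if node is not None else edge[1]
            for path in all_upward_paths(arg, start):
                est = locate(arg, loc, model, q, root_path=path)
                assert est.mean[0] == pytest.approx(ref.mean[0], abs=1e-9)
                assert est.V == pytest.approx(ref.V, abs=1e-9)

    def test_deepening_loop_node_pulls_ancestor_towards_its_subtree(
        self, two_tree_locations
    ):
        # moving the loop-closing node G into the past gives C's lineage
        # more time to wander, moving the MLE of H towards A and B
        means = []
        for t_g in [3.2, 3.8, 4.4]:
            arg = argbm.examples.two_tree_arg(t_g=t_g)
            model = BrownianDispersal().fit(arg, two_tree_locations)
            means.append(model.locate(0, 0.5, 2.0).mean[0])
        assert np.all(np.diff(means) < 0)  # towards A (-0.5) and B (0.0)

    def test_arg_variance_below_tree_variance(self):
        arg = small_sim_arg(seed=17, n_samples=10, L=5e4)
        cut = float(np.quantile(arg.node_times[arg.node_times > 0], 0.7)) + 0.5
        chopped = arg.chop(cut)
        rng = np.random.default_rng(1)
        loc = rng.normal(size=chopped.num_samples)
        whole = BrownianDispersal().fit(chopped, loc)
        iv = chopped.tree_intervals()
        pos = (iv[len(iv) // 2][0] + iv[len(iv) // 2][1]) / 2
        tree = BrownianDispersal().fit(chopped.window(pos, 0), loc)
        sample = int(chopped.samples[0])
        for tau in np.linspace(cut * 0.1, cut * 0.9, 5):
            v_arg = whole.locate(sample, pos, float(tau), dispersal=1.0).V
            v_tree = tree.locate(sample, pos, float(tau), dispersal=1.0).V
            assert v_arg <= v_tree + 1e-9

    def test_2d_confidence_ellipse(self, chopped_sim_arg):
        rng = np.random.default_rng(8)
        loc = rng.normal(size=(chopped_sim_arg.num_samples, 2))
        model = BrownianDispersal().fit(chopped_sim_arg, loc)
        est = model.locate(int(chopped_sim_arg.samples[0]), 10.0, 50.0)
        assert est.mean.shape == (2,)
        assert est.ellipse is not None
        assert np.all(est.ellipse["half_axes"] >= 0)


class TestTracks:
    def test_degenerate_grid_is_zero_variance_point(self, two_tree,
                                                    two_tree_locations):
        model = BrownianDispersal().fit(two_tree, two_tree_locations)
        track = model.locate_track(0, 0.5, [0.0])
        assert len(track) == 1
        assert track[0].V == pytest.approx(0.0, abs=1e-9)
        assert track[0].mean[0] == pytest.approx(-0.5)

    def test_y_pattern_across_recombination_breakpoint(self, two_tree,
                                                       two_tree_locations):
        # positions flanking the breakpoint share their lineage below the
        # recombination node (t=1) and diverge above it
        model = BrownianDispersal().fit(two_tree, two_tree_locations)
        left = model.locate_track(2, 0.5, [0.5, 2.5])
        right = model.locate_track(2, 1.5, [0.5, 2.5])
        assert left[0].mean[0] == pytest.approx(right[0].mean[0], abs=1e-12)
        assert left[1].mean[0] != pytest.approx(right[1].mean[0], abs=1e-6)

    def test_track_frame_and_monotone_grid(self, two_tree, two_tree_locations):
        model = BrownianDispersal().fit(two_tree, two_tree_locations)
        track = model.locate_track(0, 0.5, [0.0, 1.0, 2.0], level=0.9)
        df = track_frame(track)
        assert list(df.columns[:3]) == ["sample_id", "position", "time"]
        assert np.all(df.lo <= df.x) and np.all(df.x <= df.hi)
        with pytest.raises(ValueError):
            model.locate_track(0, 0.5, [2.0, 1.0])
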