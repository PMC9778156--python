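import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hicspring as hs
from hicspring.layout_engine import (
    LayoutParams,
    LayoutState,
    avoidance_forces,
    compute_forces,
    initial_state,
    load_params,
    node_repulsion,
    run_layout,
    segment_min_distance,
    segment_min_distances,
    spring_energy,
    spring_force,
    step,
)
from oracles import grid_segment_distance

coord = st.floats(-5, 5, allow_nan=False, width=32)
point = st.tuples(coord, coord, coord)


class TestSegmentMinDistance:
    @pytest.mark.parametrize(
        "p1,p2,q1,q2,expected",
        [
            ((0, 0, 0), (1, 0, 0), (0, 0, 1), (0, 1, 1), 1.0),  # skew offset
            ((0, 0, 0), (0, 0, 0), (3, 4, 0), (3, 4, 0), 5.0),  # two points
            ((0, 0, 0), (2, 0, 0), (1, 1, 0), (3, 1, 0), 1.0),  # parallel offset
            ((0, 0, 0), (2, 0, 0), (1, 0, 0), (1, 2, 0), 0.0),  # touching
        ],
    )
    def test_hand_cases(self, p1, p2, q1, q2, expected):
        d, s, t = segment_min_distance(p1, p2, q1, q2)
        assert d == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= s <= 1.0 and 0.0 <= t <= 1.0

    def test_matches_grid_oracle_on_random_pairs(self):
        rng = np.random.default_rng(11)
        segs = rng.uniform(-1, 1, size=(200, 4, 3))
        d, _, _ = segment_min_distances(segs[:, 0], segs[:, 1], segs[:, 2], segs[:, 3])
        for k in range(len(segs)):
            assert d[k] == pytest.approx(grid_segment_distance(*segs[k]), abs=1e-6)

    @given(p1=point, p2=point, q1=point, q2=point)
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_symmetric_in_segment_order(self, p1, p2, q1, q2):
        d1, _, _ = segment_min_distance(p1, p2, q1, q2)
        d2, _, _ = segment_min_distance(q1, q2, p1, p2)
        assert d1 == pytest.approx(d2, abs=1e-9)

    @given(p1=point, p2=point, q1=point, q2=point)
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_closest_points_realize_reported_distance(self, p1, p2, q1, q2):
        d, s, t = segment_min_distance(p1, p2, q1, q2)
        p1, p2, q1, q2 = (np.asarray(x, float) for x in (p1, p2, q1, q2))
        cp = p1 + s * (p2 - p1)
        cq = q1 + t * (q2 - q1)
        assert np.linalg.norm(cp - cq) == pytest.approx(d, abs=1e-9)


class TestSpringForce:
    def test_zero_at_rest_length(self):
        assert np.allclose(spring_force((0, 0, 0), (1, 0, 0), k=3, L0=1.0), 0)

    def test_stretched_hooke_value(self):
        f = spring_force((0, 0, 0), (3, 0, 0), k=2, L0=1.0)
        assert np.allclose(f, (4.0, 0.0, 0.0))

    def test_compressed_pushes_apart(self):
        f = spring_force((0, 0, 0), (0.5, 0, 0), k=2, L0=1.0)
        assert np.allclose(f, (-1.0, 0.0, 0.0))

    def test_coincident_points_give_zero(self):
        assert np.allclose(spring_force((1, 1, 1), (1, 1, 1), k=5, L0=1.0), 0)

    def test_newtons_third_law(self):
        a, b = (0.3, -1.0, 2.0), (1.5, 0.4, -0.7)
        assert np.allclose(
            spring_force(a, b, 2.5, 0.8), -spring_force(b, a, 2.5, 0.8)
        )


class TestNodeRepulsion:
    def test_beyond_cutoff_is_zero(self):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        assert np.allclose(node_repulsion(pos, c_rep=1.0, r_cut=2.0), 0)

    def test_inverse_square_magnitude_and_antisymmetry(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        F = node_repulsion(pos, c_rep=1.0, r_cut=2.0)
        assert np.allclose(F[0], (-1, 0, 0)) and np.allclose(F[1], (1, 0, 0))

    def test_collinear_middle_node_balanced(self):
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        F = node_repulsion(pos, c_rep=1.0, r_cut=10.0)
        assert np.allclose(F[1], 0, atol=1e-12)

    def test_forces_sum_to_zero_random_cloud(self):
        rng = np.random.default_rng(2)
        pos = rng.normal(size=(100, 3))
        F = node_repulsion(pos, c_rep=0.7, r_cut=1.5)
        assert np.linalg.norm(F.sum(axis=0)) < 1e-10


class TestAvoidance:
    @staticmethod
    def _chain(positions):
        bins = hs.make_bins({"a": (len(positions) - 1) * 10_000}, 10_000)
        return hs.build_multigraph(bins)

    def test_far_segments_no_force(self):
        pos = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 5], [0, 0, 5.0]])
        mg = self._chain(pos)
        params = LayoutParams()
        F = avoidance_forces(pos, mg, params)
        # middle edge connects the two; only non-adjacent pair is (e0, e2), far apart
        assert np.allclose(F, 0)

    def test_adjacent_edges_excluded(self):
        # sharp hairpin: consecutive edges nearly coincide but share a node
        pos = np.array([[0, 0, 0], [1, 0, 0], [0.01, 0.01, 0.0]])
        mg = self._chain(pos)
        F = avoidance_forces(pos, mg, LayoutParams())
        assert np.allclose(F, 0)

    def test_close_nonadjacent_pair_antisymmetric(self):
        # 4-edge chain folded so edge 0 and edge 3 cross at d_min/2
        d = 0.15
        pos = np.array(
            [[0, 0, 0], [2, 0, 0], [2, 2, 0], [1, 1.5, d], [1, -1.5, d]], dtype=float
        )
        mg = self._chain(pos)
        params = LayoutParams(d_min=0.3, c_avoid=5.0)
        F = avoidance_forces(pos, mg, params)
        assert not np.allclose(F, 0)
        # forces on the two participating segments cancel pairwise
        f_seg1 = F[0] + F[1]
        f_seg2 = F[3] + F[4]
        assert np.allclose(f_seg1 + f_seg2, 0, atol=1e-12)
        assert np.linalg.norm(F.sum(axis=0)) < 1e-12

    def test_contact_edges_never_participate(self):
        import pandas as pd

        bins = hs.make_bins({"a": 30_000, "b": 30_000}, 10_000)
        table = hs.ContactTable(
            bins, pd.DataFrame({"bin_i": [0], "bin_j": [3], "count": [1]})
        )
        mg = hs.build_multigraph(bins, table)
        # place the contact edge crossing a genomic edge; genomic edges far apart
        pos = np.zeros((mg.n_nodes, 3))
        pos[:4] = [[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]]  # chrA straight
        pos[4:] = [[0, 0, 10], [1, 0, 10], [2, 0, 10], [3, 0, 10]]  # chrB far
        F = avoidance_forces(pos, mg, LayoutParams())
        assert np.allclose(F, 0)


class TestStepAndRun:
    def test_fixed_point_when_forces_vanish(self):
        bins = hs.make_bins({"a": 10_000}, 10_000)
        mg = hs.build_multigraph(bins)
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        params = LayoutParams(c_rep=0.0, R=10.0)
        state = LayoutState(pos.copy(), np.zeros_like(pos))
        step(state, mg, params)
        assert np.allclose(state.positions, pos)

    def test_confinement_pulls_outlier_inward(self):
        bins = hs.make_bins({"a": 10_000}, 10_000)
        mg = hs.build_multigraph(bins)
        R = 2.0
        params = LayoutParams(R=R, c_rep=0.0, k1=1e-9)
        pos = np.array([[2 * R, 0, 0], [2 * R, 0, 1e-9]])
        state = LayoutState(pos.copy(), np.zeros_like(pos))
        step(state, mg, params)
        assert state.positions[0, 0] < 2 * R

    def test_determinism_same_seed_bit_identical(self):
        bins = hs.make_bins({"a": 60_000, "b": 40_000}, 10_000)
        mg = hs.build_multigraph(bins)
        params = LayoutParams(seed=123, max_iter=120)
        a = run_layout(mg, params)
        b = run_layout(mg, params)
        assert np.array_equal(a.positions, b.positions)
        assert a.iteration == b.iteration

    def test_relaxed_chain_recovers_rest_lengths(self):
        bins = hs.make_bins({"a": 120_000}, 10_000)
        mg = hs.build_multigraph(bins)
        worst = 0.0
        for seed in range(3):
            params = LayoutParams(c_rep=0.0, R=100.0, seed=seed, max_iter=6000, tol=1e-6)
            st_ = run_layout(mg, params)
            d = np.linalg.norm(
                st_.positions[mg.genomic_edges[:, 1]] - st_.positions[mg.genomic_edges[:, 0]],
                axis=1,
            )
            worst = max(worst, float(np.abs(d - 1.0).max()))
        assert worst < 0.05

    def test_contacted_pair_closer_than_uncontacted(self):
        import pandas as pd

        bins = hs.make_bins({"a": 200_000}, 10_000)
        # contact between bins 2 and 12; compare with uncontacted pair (5, 15)
        table = hs.ContactTable(bins, pd.DataFrame({"bin_i": [2], "bin_j": [12], "count": [5]}))
        mg = hs.build_multigraph(bins, table)
        params = LayoutParams(seed=4, R=50.0, c_rep=0.0, max_iter=4000)
        st_ = run_layout(mg, params)
        n = mg.start_node
        d_contact = np.linalg.norm(st_.positions[n(2)] - st_.positions[n(12)])
        d_free = np.linalg.norm(st_.positions[n(5)] - st_.positions[n(15)])
        assert d_contact < d_free

    def test_energy_non_increasing_after_transient(self):
        bins = hs.make_bins({"a": 150_000}, 10_000)
        mg = hs.build_multigraph(bins)
        params = LayoutParams(c_rep=0.0, c_avoid=0.0, R=100.0, seed=9)
        state = initial_state(mg, params, np.random.default_rng(9))
        energies = []
        for _ in range(600):
            step(state, mg, params)
            energies.append(spring_energy(state.positions, mg))
        tail = np.array(energies[100:])
        assert np.all(np.diff(tail) <= 1e-9)

    def test_soft_confinement_bound_after_convergence(self):
        bins = hs.make_bins({"a": 100_000, "b": 100_000}, 10_000)
        mg = hs.build_multigraph(bins)
        params = LayoutParams(R=2.0, seed=1, max_iter=3000)
        st_ = run_layout(mg, params)
        assert np.linalg.norm(st_.positions, axis=1).max() <= 2.0 * 1.05

    def test_empty_multigraph_rejected(self):
        bins = hs.make_bins({"a": 10_000}, 10_000)
        mg = hs.build_multigraph(bins)
        mg.node_chrom = np.empty(0, dtype=np.int32)
        with pytest.raises(ValueError):
            run_layout(mg, LayoutParams())


class TestParams:
    def test_validation_rejects_bad_combinations(self):
        with pytest.raises(ValueError):
            LayoutParams(dt=-0.1).validate()
        with pytest.raises(ValueError):
            LayoutParams(gamma=100.0, dt=0.02).validate()
        with pytest.raises(ValueError):
            LayoutParams(L1=1.0, L2=2.0).validate()

    def test_config_file_round_trip(self, tmp_path):
        p = tmp_path / "layout.cfg"
        p.write_text("k2 = 30\nseed = 7\nR = auto\ndt = 0.01\ngamma = 5\n")
        params = load_params(p)
        assert params.k2 == 30 and params.seed == 7 and params.R is None and params.dt == 0.01

    def test_config_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "layout.cfg"
        p.write_text("bogus = 1\n")
        with pytest.raises(ValueError, match="bogus"):
            load_params(p)

    def test_auto_radius_scales_with_genome(self):
        small = hs.build_multigraph(hs.make_bins({"a": 100_000}, 10_000))
        big = hs.build_multigraph(hs.make_bins({"a": 1_000_000}, 10_000))
        p = LayoutParams()
        assert p.resolve_radius(big) > p.resolve_radius(small)


class TestSnapshots:
    def test_callback_invoked_every_n_iterations(self):
        bins = hs.make_bins({"a": 50_000}, 10_000)
        mg = hs.build_multigraph(bins)
        seen = []
        run_layout(
            mg,
            LayoutParams(seed=0, max_iter=50, tol=0.0),
            snapshot_every=10,
            snapshot_callback=lambda st: seen.append(st.iteration),
        )
        assert seen == [10, 20, 30, 40, 50]
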