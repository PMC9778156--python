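import json

import numpy as np
import pandas as pd
import pytest

import hicspring as hs
from hicspring.layout_engine import LayoutState
from hicspring.structure_analysis import (
    export_structure,
    is_territorial,
    load_structure_json,
    overlay_annotation,
    plot_territory_matrix,
    telomere_clustering,
    territory_matrix,
)
from oracles import brute_territory_matrix


def state_of(pos):
    pos = np.asarray(pos, float)
    return LayoutState(pos, np.zeros_like(pos))


class TestTerritoryMatrix:
    def test_two_cluster_hand_example(self, two_cluster_layout):
        state, mg = two_cluster_layout
        tm = territory_matrix(state, mg)
        assert tm.matrix.loc["chrA", "chrA"] == pytest.approx(4 / 3)
        assert tm.matrix.loc["chrB", "chrB"] == pytest.approx(4 / 3)
        assert tm.matrix.loc["chrA", "chrB"] == pytest.approx(10.0)
        ok, verdicts = is_territorial(tm)
        assert ok and verdicts == {"chrA": True, "chrB": True}

    def test_all_coincident_zero_matrix(self):
        bins = hs.make_bins({"a": 20_000, "b": 20_000}, 10_000)
        mg = hs.build_multigraph(bins)
        tm = territory_matrix(state_of(np.zeros((6, 3))), mg)
        assert np.allclose(tm.matrix.to_numpy(), 0.0)

    def test_single_chromosome_mean_pairwise(self):
        bins = hs.make_bins({"a": 20_000}, 10_000)
        mg = hs.build_multigraph(bins)
        pos = [[0, 0, 0], [1, 0, 0], [3, 0, 0]]
        tm = territory_matrix(state_of(pos), mg)
        assert tm.matrix.iloc[0, 0] == pytest.approx((1 + 3 + 2) / 3)

    def test_agrees_with_brute_force_random(self):
        rng = np.random.default_rng(5)
        bins = hs.make_bins({"a": 70_000, "b": 50_000, "c": 30_000}, 10_000)
        mg = hs.build_multigraph(bins)
        pos = rng.normal(size=(mg.n_nodes, 3))
        tm = territory_matrix(state_of(pos), mg)
        M = brute_territory_matrix(pos, mg.node_chrom)
        assert np.allclose(tm.matrix.to_numpy(), M)


class TestIsTerritorial:
    def test_off_diagonal_minimum_fails(self):
        tm = hs.TerritoryMatrix(pd.DataFrame([[5.0, 1.0], [1.0, 5.0]], index=["a", "b"], columns=["a", "b"]))
        ok, verdicts = is_territorial(tm)
        assert not ok and verdicts == {"a": False, "b": False}

    def test_single_chromosome_vacuously_true(self):
        tm = hs.TerritoryMatrix(pd.DataFrame([[2.0]], index=["a"], columns=["a"]))
        assert is_territorial(tm)[0]

    def test_tie_counts_as_failure(self):
        tm = hs.TerritoryMatrix(pd.DataFrame([[2.0, 2.0], [2.0, 1.0]], index=["a", "b"], columns=["a", "b"]))
        ok, verdicts = is_territorial(tm)
        assert not ok and verdicts["a"] is False and verdicts["b"] is True

    def test_undefined_diagonal_indeterminate(self):
        bins = hs.make_bins({"a": 10_000, "b": 30_000}, 10_000)  # chrA: 1 bin -> 2 nodes? no: 2 nodes
        # chromosome with a single NODE cannot occur via build_multigraph, so craft matrix directly
        m = pd.DataFrame([[np.nan, 3.0], [3.0, 1.0]], index=["a", "b"], columns=["a", "b"])
        tm = hs.TerritoryMatrix(m, undefined=("a",))
        ok, verdicts = is_territorial(tm)
        assert not ok and verdicts["a"] == "indeterminate"

    def test_invariant_under_rigid_motion(self, two_cluster_layout):
        state, mg = two_cluster_layout
        theta = 0.7
        Rz = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        moved = state_of(state.positions @ Rz.T + np.array([5.0, -2.0, 1.0]))
        a = is_territorial(territory_matrix(state, mg))
        b = is_territorial(territory_matrix(moved, mg))
        assert a == b


class TestTelomereClustering:
    def _mg(self, n_chrom=3, bins_per_chrom=20):
        bins = hs.make_bins({f"c{i}": bins_per_chrom * 10_000 for i in range(n_chrom)}, 10_000)
        return hs.build_multigraph(bins)

    def test_random_labels_score_near_one(self):
        mg = self._mg()
        rng = np.random.default_rng(0)
        scores = [
            telomere_clustering(state_of(rng.normal(size=(mg.n_nodes, 3))), mg)
            for _ in range(20)
        ]
        assert abs(np.mean(scores) - 1.0) < 0.1

    def test_rabl_ground_truth_scores_below_one(self):
        pos, bins = hs.make_rabl(3, 50, 17.0)
        mg = hs.build_multigraph(bins)
        assert telomere_clustering(state_of(pos), mg) < 1.0

    def test_degenerate_coincident_returns_one(self):
        mg = self._mg()
        assert telomere_clustering(state_of(np.zeros((mg.n_nodes, 3))), mg) == 1.0

    def test_scale_invariance(self):
        mg = self._mg()
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(mg.n_nodes, 3))
        s1 = telomere_clustering(state_of(pos), mg)
        s2 = telomere_clustering(state_of(pos * 37.5), mg)
        assert s1 == pytest.approx(s2)

    def test_end_fraction_bounds(self):
        mg = self._mg()
        with pytest.raises(ValueError):
            telomere_clustering(state_of(np.zeros((mg.n_nodes, 3))), mg, end_fraction=0.6)


class TestOverlay:
    def test_partial_annotation_leaves_sentinel(self, two_chrom_bins):
        mg = hs.build_multigraph(two_chrom_bins)
        vals = overlay_annotation(mg, {0: 2.5})
        assert vals[mg.start_node(0)] == 2.5
        assert np.isnan(np.delete(vals, mg.start_node(0))).all()

    def test_full_annotation_no_sentinel_on_start_nodes(self, two_chrom_bins):
        mg = hs.build_multigraph(two_chrom_bins)
        vals = overlay_annotation(mg, {b: float(b) for b in range(5)})
        starts = mg.start_node(np.arange(5))
        assert not np.isnan(vals[starts]).any()

    def test_chrom_start_keys_and_duplicates_warn_last_wins(self, two_chrom_bins):
        mg = hs.build_multigraph(two_chrom_bins)
        table = pd.DataFrame(
            {"chrom": ["chrA", "chrA"], "start": [0, 0], "value": [1.0, 9.0]}
        )
        with pytest.warns(UserWarning, match="duplicate"):
            vals = overlay_annotation(mg, table)
        assert vals[mg.start_node(0)] == 9.0

    def test_unknown_bin_skipped_with_warning(self, two_chrom_bins):
        mg = hs.build_multigraph(two_chrom_bins)
        with pytest.warns(UserWarning, match="skipped"):
            vals = overlay_annotation(mg, {99: 1.0})
        assert np.isnan(vals).all()


class TestExportStructure:
    @pytest.fixture
    def single_chrom(self):
        bins = hs.make_bins({"a": 40_000}, 10_000)
        mg = hs.build_multigraph(bins)
        rng = np.random.default_rng(1)
        return mg, state_of(rng.normal(size=(mg.n_nodes, 3)))

    def test_xyz_line_count(self, single_chrom, tmp_path):
        mg, state = single_chrom
        p = tmp_path / "s.xyz"
        export_structure(state, mg, p, "xyz")
        assert len(p.read_text().strip().splitlines()) == mg.n_nodes + 1

    def test_pdb_atoms_chain_conect(self, single_chrom, tmp_path):
        mg, state = single_chrom
        p = tmp_path / "s.pdb"
        export_structure(state, mg, p, "pdb")
        lines = p.read_text().splitlines()
        atoms = [l for l in lines if l.startswith("ATOM")]
        conect = [l for l in lines if l.startswith("CONECT")]
        assert len(atoms) == 5 and len(conect) == 4
        assert len({l[21] for l in atoms}) == 1  # single chain id

    def test_pdb_too_many_chromosomes_suggests_json(self, tmp_path):
        bins = hs.make_bins({f"c{i}": 10_000 for i in range(70)}, 10_000)
        mg = hs.build_multigraph(bins)
        state = state_of(np.zeros((mg.n_nodes, 3)))
        with pytest.raises(ValueError, match="json"):
            export_structure(state, mg, tmp_path / "x.pdb", "pdb")

    def test_json_round_trip_exact_positions(self, single_chrom, tmp_path):
        mg, state = single_chrom
        p = tmp_path / "s.json"
        export_structure(state, mg, p, "json")
        doc = load_structure_json(p)
        back = np.array([[n["x"], n["y"], n["z"]] for n in doc["nodes"]])
        assert np.array_equal(back, state.positions)
        assert len(doc["genomic_edges"]) == mg.n_genomic_edges

    def test_plot_helper_returns_axes(self, two_cluster_layout):
        import matplotlib

        matplotlib.use("Agg")
        state, mg = two_cluster_layout
        ax = plot_territory_matrix(territory_matrix(state, mg))
        assert ax is not None
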