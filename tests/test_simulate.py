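import numpy as np
import pytest

import spotdecon as sd
from spotdecon.simulate import (CellCoordinates, add_neighbor_noise,
                                blur_bins, hex_bin_cells,
                                predict_cell_coordinates, rebalance_bins,
                                simulate_regular, simulate_spatial,
                                _axial_to_xy)


class TestSimulateRegular:
    def test_spot_laws_over_many_spots(self, small_scrna):
        sim = simulate_regular(small_scrna, 300, seed=1)
        m = len(small_scrna.type_names)
        for i in range(sim.n_spots):
            n_cells = len(sim.cell_assignment[i])
            assert 5 <= n_cells <= 15
            n_types = (sim.proportions.iloc[i] > 0).sum()
            assert 2 <= n_types <= min(6, m)
        np.testing.assert_allclose(
            sim.proportions.to_numpy().sum(axis=1), 1.0, atol=1e-9)

    def test_counts_equal_member_cell_sums(self, small_scrna):
        sim = simulate_regular(small_scrna, 40, seed=2)
        id_to_row = {c: i for i, c in enumerate(small_scrna.cell_ids)}
        for i in range(sim.n_spots):
            rows = [id_to_row[c] for c in sim.cell_assignment[i]]
            np.testing.assert_allclose(
                sim.counts[i], small_scrna.counts[rows].sum(axis=0))

    def test_mass_conservation(self, small_scrna):
        sim = simulate_regular(small_scrna, 25, seed=3)
        id_to_row = {c: i for i, c in enumerate(small_scrna.cell_ids)}
        total = sum(small_scrna.counts[id_to_row[c]].sum()
                    for spot in sim.cell_assignment for c in spot)
        assert sim.counts.sum() == pytest.approx(total)

    def test_row_major_coordinates_wrap_at_40(self, small_scrna):
        sim = simulate_regular(small_scrna, 85, seed=4)
        np.testing.assert_array_equal(sim.coordinates[0], [1, 1])
        np.testing.assert_array_equal(sim.coordinates[39], [1, 40])
        np.testing.assert_array_equal(sim.coordinates[40], [2, 1])
        np.testing.assert_array_equal(sim.coordinates[84], [3, 5])
        assert sim.coordinates[:, 1].max() <= 40

    def test_seeded_determinism_and_diversity(self, small_scrna):
        s1 = simulate_regular(small_scrna, 30, seed=5)
        s2 = simulate_regular(small_scrna, 30, seed=5)
        s3 = simulate_regular(small_scrna, 30, seed=6)
        np.testing.assert_array_equal(s1.counts, s2.counts)
        assert (s1.counts != s3.counts).any(axis=1).sum() >= 1

    def test_bad_n_spots(self, small_scrna):
        with pytest.raises(ValueError):
            simulate_regular(small_scrna, 0, seed=1)


class TestPredictCellCoordinates:
    def test_midpoint_of_two_spots(self):
        # 2-spot reference: every cell must land on the single midpoint
        rng = np.random.default_rng(0)
        counts = rng.poisson(5, size=(10, 30)).astype(float) + 1
        sc = sd.SingleCellDataset(counts, ["A"] * 5 + ["B"] * 5,
                                  [f"g{i}" for i in range(30)],
                                  [f"c{i}" for i in range(10)])
        ref = sd.SpatialDataset(rng.poisson(20, size=(2, 30)).astype(float),
                                [f"g{i}" for i in range(30)],
                                ["s0", "s1"],
                                np.array([[0.0, 0.0], [2.0, 0.0]]))
        cc = predict_cell_coordinates(sc, ref, k=2, seed=1,
                                      config=sd.RunConfig(vae_epochs=20,
                                                          vae_hidden_dim=32))
        np.testing.assert_allclose(cc.coords,
                                   np.tile([1.0, 0.0], (10, 1)))

    def test_k1_snaps_to_existing_spots(self, small_scrna,
                                        small_reference):
        ref, _, _ = small_reference
        cc = predict_cell_coordinates(
            small_scrna, ref, k=1, seed=2,
            config=sd.RunConfig(vae_epochs=30, vae_hidden_dim=64))
        ref_set = {tuple(c) for c in ref.coordinates}
        assert all(tuple(c) in ref_set for c in cc.coords)

    def test_no_coordinates_raises(self, small_scrna):
        ref = sd.SpatialDataset(np.ones((3, small_scrna.n_genes)),
                                small_scrna.gene_names,
                                ["s0", "s1", "s2"])
        with pytest.raises(ValueError, match="coordinates"):
            predict_cell_coordinates(small_scrna, ref)


class TestHexBinning:
    def test_cell_at_center_assigned_to_that_hexagon(self):
        size = 1.0
        centers = [_axial_to_xy(q, r, size) for q, r in
                   [(0, 0), (1, 0), (0, 1), (2, 1)]]
        coords = np.asarray(centers)
        asg = hex_bin_cells(coords, size)
        # cells exactly at distinct centers land in distinct hexes
        assert len({tuple(a) for a in asg.axial}) == 4

    def test_huge_hexagon_contains_everything(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 3, size=(20, 2))
        asg = hex_bin_cells(coords, hex_size=100.0)
        assert len({tuple(a) for a in asg.axial}) == 1

    def test_assignment_matches_nearest_center_oracle(self):
        # for a hexagonal tessellation, point-in-hexagon is equivalent
        # to nearest-center assignment
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 8, size=(200, 2))
        size = 1.3
        asg = hex_bin_cells(coords, size)
        origin = coords.min(axis=0)
        qs = np.arange(-2, 12)
        candidates = [(q, r) for q in qs for r in qs]
        centers = {c: origin + _axial_to_xy(*c, size) for c in candidates}
        for i, xy in enumerate(coords):
            d = {c: np.linalg.norm(xy - p) for c, p in centers.items()}
            best = min(d.values())
            nearest = {c for c, v in d.items() if v <= best + 1e-9}
            assert tuple(asg.axial[i]) in nearest

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            hex_bin_cells(np.zeros((3, 2)), hex_size=0)
        with pytest.raises(ValueError):
            hex_bin_cells(np.array([[np.nan, 0.0]]), hex_size=1.0)


class TestRebalanceBins:
    def test_overfull_bin_sheds_extras_to_neighbors(self):
        from spotdecon.simulate import HexAssignment

        axial = np.tile([(0, 0)], (20, 1))
        asg = HexAssignment(axial, np.ones(20, bool), 1.0,
                            np.zeros(2))
        out = rebalance_bins(asg, seed=0)
        bins = {}
        for a in out.axial:
            bins[tuple(a)] = bins.get(tuple(a), 0) + 1
        assert bins[(0, 0)] == 15
        moved = {b: n for b, n in bins.items() if b != (0, 0)}
        assert sum(moved.values()) == 5
        hex_dirs = {(1, 0), (1, -1), (0, -1), (-1, 0), (-1, 1), (0, 1)}
        assert set(moved) <= hex_dirs
        # bins below 4 cells are dropped from the kept mask
        for b, n in moved.items():
            expected_kept = n >= 4
            idx = [i for i in range(20) if tuple(out.axial[i]) == b]
            assert all(out.kept[i] == expected_kept for i in idx)

    def test_compliant_bin_untouched(self):
        from spotdecon.simulate import HexAssignment

        axial = np.tile([(2, 3)], (10, 1))
        asg = HexAssignment(axial, np.ones(10, bool), 1.0, np.zeros(2))
        out = rebalance_bins(asg, seed=1)
        np.testing.assert_array_equal(out.axial, axial)
        assert out.kept.all()

    def test_tiny_bin_dropped(self):
        from spotdecon.simulate import HexAssignment

        axial = np.vstack([np.tile([(0, 0)], (2, 1)),
                           np.tile([(5, 5)], (6, 1))])
        asg = HexAssignment(axial, np.ones(8, bool), 1.0, np.zeros(2))
        out = rebalance_bins(asg, seed=2)
        assert not out.kept[:2].any()
        assert out.kept[2:].all()
        assert out.dropped_bins == 1


@pytest.fixture(scope="module")
def spatial_sim(small_scrna, small_reference):
    ref, _, _ = small_reference
    cfg = sd.RunConfig(vae_epochs=60, vae_hidden_dim=128)
    return simulate_spatial(small_scrna, ref, hex_size=1.0, seed=3,
                            config=cfg)


class TestSimulateSpatial:
    def test_spot_sizes_and_proportions(self, spatial_sim):
        for i in range(spatial_sim.n_spots):
            assert 4 <= len(spatial_sim.cell_assignment[i]) <= 15
        np.testing.assert_allclose(
            spatial_sim.proportions.to_numpy().sum(axis=1), 1.0)

    def test_proportions_match_assignment(self, spatial_sim, small_scrna):
        id_to_type = dict(zip(small_scrna.cell_ids,
                              small_scrna.cell_types))
        for i in range(spatial_sim.n_spots):
            labels = [id_to_type[c]
                      for c in spatial_sim.cell_assignment[i]]
            for t in spatial_sim.proportions.columns:
                expected = labels.count(t) / len(labels)
                assert spatial_sim.proportions.iloc[i][t] == \
                    pytest.approx(expected)

    def test_reproducible_under_seed(self, small_scrna, small_reference):
        ref, _, _ = small_reference
        cfg = sd.RunConfig(vae_epochs=25, vae_hidden_dim=64)
        s1 = simulate_spatial(small_scrna, ref, 1.0, seed=4, config=cfg)
        s2 = simulate_spatial(small_scrna, ref, 1.0, seed=4, config=cfg)
        np.testing.assert_array_equal(s1.counts, s2.counts)
        np.testing.assert_array_equal(s1.coordinates, s2.coordinates)

    def test_single_type_input(self, small_scrna, small_reference):
        ref, _, _ = small_reference
        mask = small_scrna.cell_types == small_scrna.type_names[0]
        sc1 = small_scrna.subset_cells(mask)
        cfg = sd.RunConfig(vae_epochs=25, vae_hidden_dim=64)
        sim = simulate_spatial(sc1, ref, 2.0, seed=5, config=cfg)
        np.testing.assert_allclose(sim.proportions.to_numpy(), 1.0)

    def test_sum_mode_conserves_mass(self, small_scrna, small_reference):
        ref, _, _ = small_reference
        cfg = sd.RunConfig(vae_epochs=25, vae_hidden_dim=64)
        sim = simulate_spatial(small_scrna, ref, 1.0, seed=6,
                               aggregation="sum", config=cfg)
        id_to_row = {c: i for i, c in enumerate(small_scrna.cell_ids)}
        total = sum(small_scrna.counts[id_to_row[c]].sum()
                    for spot in sim.cell_assignment for c in spot)
        assert sim.counts.sum() == pytest.approx(total)


class TestAddNeighborNoise:
    def test_alpha_zero_is_identity(self, small_regular_sim):
        out = add_neighbor_noise(small_regular_sim, 0.5, 0.0, seed=1)
        np.testing.assert_array_equal(out.counts,
                                      small_regular_sim.counts)

    def test_alpha_one_gives_neighbor_mean(self, small_regular_sim):
        from spotdecon.simulate import _neighbor_sets

        out = add_neighbor_noise(small_regular_sim, 1.0, 1.0, seed=2)
        neighbors = _neighbor_sets(small_regular_sim)
        for i in range(small_regular_sim.n_spots):
            if neighbors[i]:
                np.testing.assert_allclose(
                    out.counts[i],
                    small_regular_sim.counts[neighbors[i]].mean(axis=0))

    def test_exact_selection_count_and_untouched_rows(
            self, small_regular_sim):
        out = add_neighbor_noise(small_regular_sim, 0.25, 0.2, seed=3)
        n = small_regular_sim.n_spots
        selected = set(out.provenance["noise_selected"])
        assert len(selected) == round(0.25 * n)
        for i in range(n):
            if i not in selected:
                np.testing.assert_array_equal(
                    out.counts[i], small_regular_sim.counts[i])

    def test_hand_arithmetic(self):
        # E_i = 10, neighbors {4, 8}, alpha 0.2 -> 9.2
        import pandas as pd

        counts = np.array([[10.0], [4.0], [8.0]])
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        props = pd.DataFrame(np.ones((3, 1)), columns=["A"])
        sim = sd.SimulatedSpatialDataset(
            counts, coords, props, ["g0"], ["s0", "s1", "s2"],
            [["c0"], ["c1"], ["c2"]], provenance={})
        out = add_neighbor_noise(sim, fraction=1 / 3, alpha=0.2, seed=10)
        sel = out.provenance["noise_selected"]
        if 0 in sel:
            assert out.counts[0, 0] == pytest.approx(0.8 * 10 + 0.2 * 6)

    def test_proportions_metadata_unchanged(self, small_regular_sim):
        out = add_neighbor_noise(small_regular_sim, 0.5, 0.3, seed=4)
        np.testing.assert_array_equal(
            out.proportions.to_numpy(),
            small_regular_sim.proportions.to_numpy())


class TestBlurBins:
    def _single_cell_slide(self):
        counts = np.array([[4.0, 0.0], [0.0, 2.0],
                           [1.0, 1.0], [3.0, 3.0]])
        coords = np.array([[0.5, 0.5], [1.5, 0.5],
                           [0.5, 1.5], [1.5, 1.5]])
        st = sd.SpatialDataset(counts, ["g0", "g1"],
                               [f"c{i}" for i in range(4)], coords)
        labels = np.array(["A", "B", "A", "B"])
        return st, labels

    def test_one_bin_pools_everything(self):
        st, labels = self._single_cell_slide()
        sim = blur_bins(st, 10.0, 10.0, labels=labels)
        assert sim.n_spots == 1
        np.testing.assert_allclose(sim.counts[0], st.counts.sum(axis=0))
        np.testing.assert_allclose(
            sim.proportions.iloc[0].to_numpy(), [0.5, 0.5])

    def test_grid_of_singletons(self):
        st, labels = self._single_cell_slide()
        sim = blur_bins(st, 1.0, 1.0, labels=labels)
        assert sim.n_spots == 4
        onehot = sim.proportions.to_numpy()
        assert ((onehot == 0) | (onehot == 1)).all()

    def test_without_labels_returns_plain_spatial(self):
        st, _ = self._single_cell_slide()
        out = blur_bins(st, 2.0, 2.0)
        assert isinstance(out, sd.SpatialDataset)
        assert out.n_spots == 1

    def test_mass_conservation(self, small_reference):
        ref, _, _ = small_reference
        out = blur_bins(ref, 3.3, 3.3)
        assert out.counts.sum() == pytest.approx(ref.counts.sum())
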