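"""Territory maps, U-matrix, heatmap binning, purity, and special zones."""

import numpy as np
import pytest

from genosig.blsom import BLSOMConfig, BLSOMModel, init_lattice, train
from genosig.diagnostics import (
    compute_umatrix,
    flag_special_zone_candidates,
    heatmap_bins,
    map_purity,
    node_table,
    territory_map,
)
from genosig.ingest import tile_windows
from genosig.kmer import build_dege_index, composition_matrix
from genosig.simulate import generate_genome, make_species_model


def toy_model(I=2, J=2, dim=3, weights=None, assignments=None):
    w = weights if weights is not None else np.zeros((I, J, dim))
    return BLSOMModel(
        I=I, J=J, weights=np.asarray(w, float),
        sigma1=1.0, sigma2=1.0, mean=np.zeros(w.shape[-1]),
        trained=True,
        assignments=None if assignments is None else np.asarray(assignments),
    )


class TestTerritoryMap:
    def test_single_multiple_vacant_categories(self):
        # 7 fragments of X on node (0,0); X and Y mixed on (1,1); (0,1),(1,0) empty
        assignments = [[0, 0]] * 7 + [[1, 1], [1, 1]]
        labels = ["X"] * 7 + ["X", "Y"]
        grid = territory_map(toy_model(assignments=assignments), labels)
        assert grid[0, 0] == "single:X"
        assert grid[1, 1] == "multiple"
        assert grid[0, 1] == grid[1, 0] == "vacant"

    def test_categories_partition_all_nodes(self, community_model, community_matrix):
        grid = territory_map(community_model, community_matrix.labels("species"))
        n_single = sum(str(c).startswith("single:") for c in grid.ravel())
        n_multi = int((grid == "multiple").sum())
        n_vacant = int((grid == "vacant").sum())
        assert n_single + n_multi + n_vacant == community_model.n_nodes

    def test_unlabeled_fragment_rejected(self):
        model = toy_model(assignments=[[0, 0], [0, 1]])
        with pytest.raises(ValueError):
            territory_map(model, ["X", None])


class TestUMatrix:
    def test_identical_weights_give_all_zero(self):
        u = compute_umatrix(toy_model(I=3, J=3, weights=np.ones((3, 3, 4))))
        assert not u.any()

    def test_two_block_lattice_maxima_on_boundary_columns(self):
        w = np.zeros((4, 2, 3))
        w[2:] = 5.0  # left half weight a, right half weight b
        u = compute_umatrix(toy_model(I=4, J=2, weights=w))
        assert u[1].max() == u[2].max() == 1.0
        assert u[0].max() == u[3].max() == 0.0

    def test_normalized_range(self, community_model):
        u = compute_umatrix(community_model)
        assert u.min() == 0.0 and u.max() == 1.0

    def test_invariant_under_constant_weight_shift(self, community_model):
        u1 = compute_umatrix(community_model)
        shifted = toy_model(
            I=community_model.I, J=community_model.J,
            weights=community_model.weights + 7.5,
        )
        np.testing.assert_allclose(compute_umatrix(shifted), u1, atol=1e-12)

    def test_single_node_lattice_rejected(self):
        with pytest.raises(ValueError):
            compute_umatrix(toy_model(I=1, J=1, weights=np.zeros((1, 1, 3))))


class TestHeatmapBins:
    def _model(self):
        w = np.zeros((3, 2, 10))
        w[:, :, 3] = [[0.0, 2.5], [5.0, 7.5], [9.0, 10.0]]  # class "AT" frequencies
        return toy_model(I=3, J=2, weights=w)

    def test_extremes_and_midpoint(self):
        idx = build_dege_index(2)
        bins = heatmap_bins(self._model(), idx, "AT")
        assert bins[0, 0] == 0  # node at the minimum frequency
        assert bins[2, 1] == 20  # node at the maximum frequency
        assert bins[1, 0] == 10  # exact midpoint -> floor(21/2)

    def test_constant_frequency_gives_neutral_bin(self):
        idx = build_dege_index(2)
        w = np.ones((2, 2, 10))
        assert (heatmap_bins(toy_model(I=2, J=2, weights=w), idx, "CG") == 10).all()

    def test_bins_monotone_in_frequency(self):
        idx = build_dege_index(2)
        model = self._model()
        bins = heatmap_bins(model, idx, "AT")
        f = model.weights[:, :, 3].ravel()
        b = bins.ravel()
        order = np.argsort(f)
        assert (np.diff(b[order]) >= 0).all()

    def test_unknown_class_rejected(self):
        with pytest.raises(KeyError):
            heatmap_bins(self._model(), build_dege_index(2), "QQ")


class TestMapPurity:
    def test_all_pure_nodes(self):
        model = toy_model(assignments=[[0, 0], [0, 1], [1, 0]])
        assert map_purity(model, ["X", "Y", "X"]) == 1.0

    def test_single_mixed_node(self):
        model = toy_model(assignments=[[0, 0]] * 4)
        assert map_purity(model, ["X", "X", "Y", "Y"]) == 0.0

    def test_mixed_toy_assignment(self):
        # 8 of 10 fragments on pure nodes
        assignments = [[0, 0]] * 4 + [[0, 1]] * 4 + [[1, 0], [1, 0]]
        labels = ["X"] * 4 + ["Y"] * 4 + ["X", "Y"]
        assert map_purity(toy_model(assignments=assignments), labels) == pytest.approx(0.8)


@pytest.fixture(scope="module")
def satellite_scenario():
    """Species A emits 10% of fragments from a distinct composition."""
    main = make_species_model("A", 40.0, seed=11)
    variant = make_species_model("A", 52.0, seed=12)
    other = make_species_model("B", 33.0, seed=13)
    frags = []
    for r in generate_genome(main, [1_800_000] * 3):
        frags += tile_windows(r, 100_000)
    n_main = len(frags)
    for r in generate_genome(variant, [600_000]):
        frags += tile_windows(r, 100_000)
    n_variant = len(frags) - n_main
    for r in generate_genome(other, [1_500_000] * 2):
        frags += tile_windows(r, 100_000)
    matrix = composition_matrix(frags, build_dege_index(3))
    cfg = BLSOMConfig(seqs_per_node=3)
    model = train(matrix, init_lattice(matrix, cfg), cfg)
    variant_idx = np.arange(n_main, n_main + n_variant)
    return model, matrix, variant_idx


class TestSpecialZones:
    def test_homogeneous_map_has_no_zones(self):
        w = np.random.default_rng(0).normal(size=(4, 4, 3)) * 1e-9
        model = toy_model(I=4, J=4, weights=w,
                          assignments=[[i, j] for i in range(4) for j in range(4)])
        labels = ["X"] * 16
        assert flag_special_zone_candidates(model, labels) == []
    def test_variant_fragments_flagged_as_satellite(self, satellite_scenario):
        model, matrix, variant_idx = satellite_scenario
        zones = flag_special_zone_candidates(model, matrix.labels("species"))
        assert zones, "expected a satellite special-zone candidate"
        assert {z.label for z in zones} == {"A"}
        flagged_nodes = {n for z in zones for n in z.nodes}
        variant_nodes = {tuple(map(int, model.assignments[i])) for i in variant_idx}
        assert variant_nodes <= flagged_nodes

    def test_extreme_quantile_flags_at_most_highest_boundary(self, satellite_scenario):
        model, matrix, _ = satellite_scenario
        labels = matrix.labels("species")
        lax = flag_special_zone_candidates(model, labels, quantile=0.0)
        strict = flag_special_zone_candidates(model, labels, quantile=1.0)
        assert len(strict) <= 1
        assert len(strict) <= len(lax)


def test_node_table_shape_and_occupancy(community_model, community_matrix):
    labels = community_matrix.labels("species")
    tab = node_table(community_model, labels)
    assert len(tab) == community_model.n_nodes
    assert tab["n_fragments"].sum() == community_matrix.n_fragments
    vacant = tab[tab["category"] == "vacant"]
    assert (vacant["n_fragments"] == 0).all()
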