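"""BLSOM initialization, batch training, and best-matching-node assignment."""

import numpy as np
import pandas as pd
import pytest

from genosig.blsom import (
    BLSOMConfig,
    assign,
    init_lattice,
    load_model,
    neighborhood_radius,
    save_model,
    train,
)
from genosig.kmer import CompositionMatrix, build_dege_index


def make_matrix(values: np.ndarray, species=None) -> CompositionMatrix:
    n = len(values)
    species = species if species is not None else ["sp"] * n
    prov = pd.DataFrame(
        {
            "species": species,
            "source": ["chr1"] * n,
            "start": np.arange(n) * 10,
            "end": np.arange(1, n + 1) * 10,
            "valid_fraction": 1.0,
        }
    )
    idx = build_dege_index(2)
    return CompositionMatrix(prov, idx, np.asarray(values, float), np.full(n, 10))


def known_sd_matrix():
    """1000 rows in 2D with per-axis SDs exactly (4, 1) about the mean."""
    pattern = np.array([[4.0, 1.0], [4.0, -1.0], [-4.0, 1.0], [-4.0, -1.0]])
    values = np.tile(pattern, (250, 1)) + 50.0
    return make_matrix(values)


def two_cluster_matrix(n_per=100, sep=30.0, noise=0.3, seed=5):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, noise, size=(n_per, 6)) + 10.0
    b = rng.normal(0, noise, size=(n_per, 6)) + 10.0
    b[:, 0] += sep
    values = np.vstack([a, b])
    labels = ["A"] * n_per + ["B"] * n_per
    return make_matrix(values, species=labels)


class TestInitLattice:
    def test_node_count_targets_ten_sequences_per_node(self):
        m = known_sd_matrix()
        model = init_lattice(m, BLSOMConfig(seqs_per_node=10))
        assert abs(model.I * model.J - 100) <= model.I + model.J  # within rounding

    def test_aspect_ratio_rounding_rule(self):
        # sigma1/sigma2 = 4 and n* = 100 -> J = sqrt(100/4) = 5, I = 20
        model = init_lattice(known_sd_matrix(), BLSOMConfig(seqs_per_node=10))
        assert (model.I, model.J) == (20, 5)
        assert model.sigma1 == pytest.approx(4.0)
        assert model.sigma2 == pytest.approx(1.0)

    def test_corner_weight_is_lattice_span_endpoint(self):
        m = known_sd_matrix()
        model = init_lattice(m, BLSOMConfig(seqs_per_node=10))
        x = np.asarray(m.values, float)
        mean = x.mean(axis=0)
        # principal axes of this matrix are the coordinate axes
        expected = mean.copy()
        expected[0] -= 2.5 * model.sigma1
        expected[1] -= 2.5 * model.sigma2
        np.testing.assert_allclose(model.weights[0, 0], expected, atol=1e-9)

    def test_degenerate_matrix_rejected(self):
        m = make_matrix(np.full((50, 3), 7.0))
        with pytest.raises(ValueError, match="degenerate"):
            init_lattice(m, BLSOMConfig(seqs_per_node=5))

    def test_zero_sigma2_clamps_j_with_warning(self):
        values = np.zeros((40, 3))
        values[:, 0] = np.linspace(0, 10, 40)
        m = make_matrix(values)
        with pytest.warns(UserWarning):
            model = init_lattice(m, BLSOMConfig(seqs_per_node=5))
        assert model.J == 2

    def test_too_few_rows_rejected(self):
        m = make_matrix(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValueError):
            init_lattice(m, BLSOMConfig(seqs_per_node=10))


class TestTrain:
    def test_row_shuffle_gives_bit_identical_weights(self):
        m = two_cluster_matrix()
        rng = np.random.default_rng(9)
        perm = rng.permutation(m.n_fragments)
        m_shuf = make_matrix(m.values[perm], species=list(np.array(m.fragments["species"])[perm]))
        cfg = BLSOMConfig(epochs=40)
        t1 = train(m, init_lattice(m, cfg), cfg)
        t2 = train(m_shuf, init_lattice(m_shuf, cfg), cfg)
        assert np.array_equal(t1.weights, t2.weights)
        assert np.array_equal(t1.assignments[perm], t2.assignments)

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            BLSOMConfig(epochs=0)

    def test_single_epoch_zero_radius_yields_node_means(self):
        m = two_cluster_matrix()
        cfg = BLSOMConfig(
            epochs=1, neighborhood_initial_radius=0.0, neighborhood_final_radius=0.0
        )
        model0 = init_lattice(m, cfg)
        bmu0 = assign(m, model0)
        trained = train(m, model0, cfg)
        x = np.asarray(m.values, float)
        lin0 = bmu0[:, 0] * model0.J + bmu0[:, 1]
        for node in np.unique(lin0):
            members = x[lin0 == node]
            i, j = divmod(int(node), model0.J)
            np.testing.assert_allclose(trained.weights[i, j], members.mean(axis=0), atol=1e-9)

    def test_well_separated_clusters_never_share_a_node(self):
        m = two_cluster_matrix()
        cfg = BLSOMConfig(epochs=60)
        trained = train(m, init_lattice(m, cfg), cfg)
        species = np.asarray(m.fragments["species"])
        lin = trained.assignments[:, 0] * trained.J + trained.assignments[:, 1]
        for node in np.unique(lin):
            assert len(set(species[lin == node])) == 1

    def test_dimension_mismatch_rejected(self):
        m = two_cluster_matrix()
        model = init_lattice(m, BLSOMConfig())
        other = make_matrix(np.random.default_rng(0).normal(size=(40, 3)))
        with pytest.raises(ValueError):
            train(other, model, BLSOMConfig())

    def test_radius_schedule_is_monotone_and_ends_at_final(self):
        epochs, r0, r1 = 37, 8.0, 1.0
        radii = [neighborhood_radius(t, epochs, r0, r1) for t in range(1, epochs + 1)]
        assert radii[0] == r0 and radii[-1] == r1
        assert all(a >= b for a, b in zip(radii, radii[1:]))


class TestAssign:
    def test_fragment_equal_to_weight_maps_to_that_node(self):
        m = two_cluster_matrix()
        cfg = BLSOMConfig(epochs=20)
        trained = train(m, init_lattice(m, cfg), cfg)
        i, j = trained.I // 2, trained.J // 2
        probe = make_matrix(trained.weights[i, j][None, :])
        assert tuple(assign(probe, trained)[0]) == (i, j)

    def test_bmu_matches_exhaustive_scan(self):
        m = two_cluster_matrix()
        cfg = BLSOMConfig(epochs=20)
        trained = train(m, init_lattice(m, cfg), cfg)
        rng = np.random.default_rng(2)
        probes = rng.uniform(5, 45, size=(100, 6))
        got = assign(make_matrix(probes), trained)
        flat = trained.flat_weights()
        for p, (gi, gj) in zip(probes, got):
            d = ((flat - p) ** 2).sum(axis=1)
            best = int(np.argmin(d))
            assert (gi, gj) == divmod(best, trained.J)

    def test_tie_breaks_to_smallest_linear_index(self):
        m = two_cluster_matrix()
        trained = train(m, init_lattice(m, BLSOMConfig(epochs=5)), BLSOMConfig(epochs=5))
        w = trained.flat_weights().copy()
        w[3] = w[10]  # force an exact tie between linear indices 3 and 10
        trained.weights = w.reshape(trained.I, trained.J, trained.dim)
        probe = make_matrix(w[10][None, :])
        i, j = assign(probe, trained)[0]
        assert i * trained.J + j == 3


def test_model_save_load_round_trip(tmp_path):
    m = two_cluster_matrix()
    cfg = BLSOMConfig(epochs=10)
    trained = train(m, init_lattice(m, cfg), cfg)
    save_model(trained, tmp_path / "model", fragments=m.fragments)
    back = load_model(tmp_path / "model")
    assert (back.I, back.J) == (trained.I, trained.J)
    np.testing.assert_allclose(back.weights, trained.weights)
    assert np.array_equal(back.assignments, trained.assignments)
    assert back.trained
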