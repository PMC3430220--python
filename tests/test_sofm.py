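"""Self-organizing map: competitive rule, schedule, training, partitions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sofmrbf import CANONICAL_DESCRIPTORS, Partition, SOFMConfig, SOFMModel
from sofmrbf.sofm import assign_and_partition, decay, init_sofm, train_sofm, update_weights, winner


def test_init_is_deterministic_and_bounded():
    cfg = SOFMConfig(seed=5)
    a = init_sofm(cfg, input_dim=7)
    b = init_sofm(cfg, input_dim=7)
    np.testing.assert_array_equal(a.weights, b.weights)
    assert a.weights.shape == (24, 7)
    assert np.all(np.abs(a.weights) <= 0.1)
    assert np.all(a.biases == 0)


def test_init_rejects_bad_dimensions():
    with pytest.raises(ValueError):
        init_sofm(SOFMConfig(), input_dim=0)
    with pytest.raises(ValueError):
        SOFMConfig(grid_rows=0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_winner_matches_brute_force_nearest_row(seed):
    """The competitive winner is exactly the nearest weight row."""
    rng = np.random.default_rng(seed)
    model = init_sofm(SOFMConfig(seed=seed), input_dim=5)
    model = SOFMModel(
        weights=rng.normal(size=(24, 5)),
        biases=model.biases,
        grid_coords=model.grid_coords,
        config=model.config,
    )
    sample = rng.normal(size=5)
    k = winner(model, sample)
    assert k == int(np.argmin(np.linalg.norm(model.weights - sample, axis=1)))


def test_winner_tie_goes_to_lowest_index():
    model = init_sofm(SOFMConfig(seed=0), input_dim=2)
    weights = np.zeros((24, 2))
    weights[3] = (1.0, 0.0)
    weights[7] = (-1.0, 0.0)
    model = SOFMModel(weights=weights, biases=model.biases, grid_coords=model.grid_coords, config=model.config)
    assert winner(model, np.array([0.0, 5.0])) == 0  # all-zero rows tie first
    weights2 = np.full((24, 2), 10.0)
    weights2[3] = (1.0, 0.0)
    weights2[7] = (-1.0, 0.0)
    model2 = SOFMModel(weights=weights2, biases=model.biases, grid_coords=model.grid_coords, config=model.config)
    assert winner(model2, np.array([0.0, 0.0])) == 3


def test_winner_on_weight_row_returns_that_row():
    rng = np.random.default_rng(3)
    model = init_sofm(SOFMConfig(seed=3), input_dim=4)
    model = SOFMModel(
        weights=rng.normal(size=(24, 4)), biases=model.biases, grid_coords=model.grid_coords, config=model.config
    )
    assert winner(model, model.weights[11]) == 11


@pytest.mark.parametrize(
    "eta0, nc0, step, max_steps, expected",
    [
        (0.5, 4, 5, 10, (0.25, 2)),
        (0.9, 3, 10, 10, (0.0, 0)),
        (0.9, 3, 1, 10, (0.81, 3)),  # ceil(2.7) = 3
        (0.9, 3, 0, 10, (0.9, 3)),
    ],
)
def test_linear_decay_schedule(eta0, nc0, step, max_steps, expected):
    eta, nc = decay(eta0, nc0, step, max_steps)
    assert eta == pytest.approx(expected[0])
    assert nc == expected[1]


def test_decay_rejects_step_beyond_budget():
    with pytest.raises(ValueError):
        decay(0.9, 3, 11, 10)


def test_update_moves_neighborhood_and_only_it():
    rng = np.random.default_rng(0)
    model = init_sofm(SOFMConfig(seed=0), input_dim=3)
    sample = rng.normal(size=3)

    # eta=1 with a grid-covering radius puts every row on the sample
    full = update_weights(model, sample, k=5, nc=10, eta=1.0)
    np.testing.assert_allclose(full.weights, np.tile(sample, (24, 1)))

    # eta=0 changes nothing
    frozen = update_weights(model, sample, k=5, nc=2, eta=0.0)
    np.testing.assert_array_equal(frozen.weights, model.weights)

    # eta=0.5, nc=0: only the winner moves, exactly halfway
    half = update_weights(model, sample, k=5, nc=0, eta=0.5)
    np.testing.assert_allclose(half.weights[5], model.weights[5] + 0.5 * (sample - model.weights[5]))
    untouched = [i for i in range(24) if i != 5]
    np.testing.assert_array_equal(half.weights[untouched], model.weights[untouched])


def test_update_radius_uses_chebyshev_grid_distance():
    model = init_sofm(SOFMConfig(seed=1), input_dim=2)
    sample = np.array([5.0, 5.0])
    out = update_weights(model, sample, k=0, nc=1, eta=1.0)
    moved = {i for i in range(24) if not np.array_equal(out.weights[i], model.weights[i])}
    coords = model.grid_coords
    expected = {i for i in range(24) if np.max(np.abs(coords[i] - coords[0])) <= 1}
    assert moved == expected


def test_training_is_deterministic_and_stays_in_hull():
    """Same seed gives identical maps; rows stay in the bounding box of
    initial weights and samples (each update is a convex combination)."""
    rng = np.random.default_rng(42)
    samples = rng.normal(size=(12, 6))
    cfg = SOFMConfig(seed=9, max_steps=200)
    m1 = train_sofm(samples, cfg)
    m2 = train_sofm(samples, cfg)
    np.testing.assert_array_equal(m1.weights, m2.weights)
    assert m1.steps_trained == 200

    init = init_sofm(cfg, 6)
    lo = np.minimum(init.weights.min(axis=0), samples.min(axis=0)) - 1e-12
    hi = np.maximum(init.weights.max(axis=0), samples.max(axis=0)) + 1e-12
    assert np.all(m1.weights >= lo) and np.all(m1.weights <= hi)


def test_separated_clouds_get_disjoint_winner_sets():
    """Two well-separated 2-D clouds never share a winning neuron."""
    rng = np.random.default_rng(0)
    cloud_a = rng.normal(loc=(0.0, 0.0), scale=0.1, size=(10, 2))
    cloud_b = rng.normal(loc=(5.0, 5.0), scale=0.1, size=(10, 2))
    samples = np.vstack([cloud_a, cloud_b])
    model = train_sofm(samples, SOFMConfig(seed=0, max_steps=500))
    winners_a = {winner(model, s) for s in cloud_a}
    winners_b = {winner(model, s) for s in cloud_b}
    assert winners_a.isdisjoint(winners_b)


def test_model_json_round_trip():
    rng = np.random.default_rng(5)
    model = train_sofm(rng.normal(size=(8, 3)), SOFMConfig(seed=2, max_steps=50))
    back = SOFMModel.from_json(model.to_json())
    np.testing.assert_array_equal(back.weights, model.weights)
    assert back.config == model.config


class TestPartition:
    def test_equality_ignores_neuron_labels(self):
        names = ["a", "b", "c", "d"]
        p1 = Partition.from_labels([4, 4, 9, 2], names)
        p2 = Partition.from_labels([17, 17, 1, 23], names)
        assert p1 == p2 and hash(p1) == hash(p2)
        assert p1 != Partition.from_labels([1, 2, 2, 3], names)

    def test_rejects_overlapping_groups(self):
        with pytest.raises(ValueError):
            Partition([{"a", "b"}, {"b", "c"}])

    def test_published_label_vector_groups(self, table2_records):
        """The 500-step label rows induce the published 8- and 9-group
        partitions of the twelve descriptors."""
        by_key = {(r.basis, r.training_steps): r for r in table2_records}
        p631 = Partition.from_labels(by_key[("6-31G(d)", 500)].label_vector(), list(CANONICAL_DESCRIPTORS))
        assert len(p631) == 8
        assert p631 == Partition(
            [
                {"dH_homo"},
                {"Q_Y"},
                {"Q_N", "dE"},
                {"Q_O", "E_HOMO-1", "E_HOMO"},
                {"N_X"},
                {"mu"},
                {"alpha"},
                {"E_LUMO", "E_LUMO+1"},
            ]
        )
        psto = Partition.from_labels(by_key[("STO-3G", 500)].label_vector(), list(CANONICAL_DESCRIPTORS))
        assert len(psto) == 9

    def test_identical_samples_form_single_group(self):
        samples = np.tile(np.arange(4.0), (5, 1))
        model = train_sofm(samples, SOFMConfig(seed=1, max_steps=100))
        part = assign_and_partition(model, samples, list("abcde"))
        assert len(part) == 1
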