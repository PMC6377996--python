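import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from blurbench import (
    ConfigError,
    L4Network,
    feedforward_drive,
    l4_represent,
    steady_state,
    train_l4,
)
from blurbench.l4_model import load_network, save_network


def random_network(rng, n_units=20, n_inputs=20, lam=0.1):
    aff = rng.standard_normal((n_units, n_inputs))
    aff /= np.linalg.norm(aff, axis=1, keepdims=True)
    lat = rng.uniform(-0.3, 0.3, size=(n_units, n_units))
    lat = np.clip((lat + lat.T) / 2, -1, 1)
    np.fill_diagonal(lat, 0.0)
    rho = np.abs(np.linalg.eigvalsh(lat)).max()
    return L4Network(afferent=aff, lateral=lat, theta=0.5, lam=min(lam, 0.5 / rho))


def damped_fixed_point_oracle(network, g, damping=0.3, iters=20000, tol=1e-12):
    """Independent solver: damped iteration of F -> [g + lam U F]+."""
    f = np.zeros_like(g)
    for _ in range(iters):
        target = np.maximum(0.0, g + network.lam * network.lateral @ f)
        f_new = (1 - damping) * f + damping * target
        if np.abs(f_new - f).max() < tol:
            return f_new
        f = f_new
    return f


class TestFeedforwardDrive:
    def test_perfect_prototype_match_recovers_scale(self, rng):
        net = random_network(rng)
        for c in (0.5, 1.0, 3.7):
            g = feedforward_drive(net, c * net.afferent[4])
            assert g[4] == pytest.approx(c, rel=1e-9)

    def test_cosine_at_threshold_gives_zero_drive(self, rng):
        net = random_network(rng, n_units=2, n_inputs=3)
        w = net.afferent[0]
        # build x with cosine exactly theta to w
        perp = np.array([w[1], -w[0], 0.0])
        perp -= w * (w @ perp)
        perp /= np.linalg.norm(perp)
        theta = net.theta
        x = theta * w + np.sqrt(1 - theta**2) * perp
        assert feedforward_drive(net, x)[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_input_gives_zero_drive(self, rng):
        net = random_network(rng)
        assert np.allclose(feedforward_drive(net, np.zeros(20)), 0.0)

    def test_positive_homogeneity(self, rng):
        net = random_network(rng)
        x = rng.standard_normal(20)
        assert np.allclose(
            feedforward_drive(net, 3.0 * x), 3.0 * feedforward_drive(net, x)
        )

    def test_dimension_mismatch_raises(self, rng):
        net = random_network(rng)
        with pytest.raises(ConfigError):
            feedforward_drive(net, np.zeros(7))


class TestSteadyState:
    def test_lambda_zero_matches_closed_form(self, rng):
        net = random_network(rng, lam=0.0)
        x = rng.standard_normal(20)
        state = steady_state(net, x, tol=1e-9)
        expected = np.maximum(0.0, feedforward_drive(net, x))
        assert state.converged
        assert np.abs(state.activities - expected).max() < 1e-7

    def test_zero_input_fixed_point_is_origin(self, rng):
        net = random_network(rng, lam=0.1)
        state = steady_state(net, np.zeros(20))
        assert np.allclose(state.activities, 0.0, atol=1e-6)

    def test_matches_independent_damped_oracle(self, rng):
        for _ in range(5):
            net = random_network(rng, lam=0.2)
            x = rng.standard_normal(20)
            state = steady_state(net, x, tol=1e-10, max_steps=50_000)
            oracle = damped_fixed_point_oracle(net, feedforward_drive(net, x))
            assert state.converged
            assert np.abs(state.activities - oracle).max() < 1e-8

    def test_fixed_point_residual_is_small(self, rng):
        net = random_network(rng, lam=0.2)
        x = rng.standard_normal(20)
        f = steady_state(net, x, tol=1e-10, max_steps=50_000).activities
        target = np.maximum(
            0.0, feedforward_drive(net, x) + net.lam * net.lateral @ f
        )
        assert np.abs(f - target).max() < 1e-7

    def test_nonconvergence_is_flagged_not_raised(self, rng):
        net = random_network(rng, lam=0.2)
        x = 5.0 * net.afferent[0]  # strong drive: convergence needs many steps
        state = steady_state(net, x, max_steps=2)
        assert not state.converged
        assert state.iterations == 2

    def test_dt_must_be_below_tau(self, rng):
        net = random_network(rng)
        with pytest.raises(ConfigError):
            steady_state(net, np.zeros(20), dt=10.0)


class TestRepresent:
    def test_zero_vector_maps_to_zero_row(self, rng):
        net = random_network(rng, lam=0.1)
        out = l4_represent(net, np.zeros((1, 20)))
        assert np.allclose(out, 0.0, atol=1e-6)

    def test_batch_equals_per_sample_integration(self, rng):
        net = random_network(rng, lam=0.15)
        data = rng.standard_normal((4, 20))
        batch = l4_represent(net, data, tol=1e-10, max_steps=50_000)
        for i, x in enumerate(data):
            single = steady_state(net, x, tol=1e-10, max_steps=50_000).activities
            assert np.allclose(batch[i], single, atol=1e-6)

    def test_homogeneity_without_lateral_coupling(self, rng):
        net = random_network(rng, lam=0.0)
        x = rng.standard_normal((1, 20))
        one = l4_represent(net, x, tol=1e-10)
        two = l4_represent(net, 2 * x, tol=1e-10)
        assert np.allclose(two, 2 * one, atol=1e-6)


class TestTraining:
    def test_planted_prototype_recovery(self, rng):
        """Tight noise clouds around 182 planted unit vectors are recovered
        with cosine >= 0.99 after optimal matching."""
        n_units, dim = 182, 182
        planted = rng.uniform(0, 1, size=(n_units, dim))
        planted /= np.linalg.norm(planted, axis=1, keepdims=True)
        vectors = np.repeat(planted, 5, axis=0) + 0.002 * rng.standard_normal(
            (n_units * 5, dim)
        )
        vectors = np.abs(vectors)
        net = train_l4(vectors, n_units=n_units, theta=0.9, lam=0.0, seed=0)
        cos = net.afferent @ planted.T
        row, col = linear_sum_assignment(-cos)
        assert cos[row, col].min() >= 0.99

    def test_lateral_matrix_properties(self, rng):
        vectors = np.abs(rng.standard_normal((300, 40))) + 0.1
        net = train_l4(vectors, n_units=30, theta=0.8, lam=0.05, seed=1)
        lat = net.lateral
        assert np.allclose(lat, lat.T)
        assert np.allclose(np.diag(lat), 0.0)
        assert np.abs(lat).max() <= 1.0 + 1e-12

    def test_afferent_rows_are_unit_norm_data_vectors(self, rng):
        vectors = np.abs(rng.standard_normal((200, 40))) + 0.1
        net = train_l4(vectors, n_units=20, theta=0.8, lam=0.0, seed=2)
        assert np.allclose(np.linalg.norm(net.afferent, axis=1), 1.0)
        unit = vectors / np.linalg.norm(vectors, axis=1, keepdims=True)
        # medoid prototypes are actual (normalised) training vectors
        cos = net.afferent @ unit.T
        assert np.allclose(cos.max(axis=1), 1.0, atol=1e-12)

    def test_stability_guard_shrinks_lambda(self, rng):
        base = np.abs(rng.standard_normal(40)) + 0.5
        vectors = base[None, :] * rng.uniform(0.5, 1.5, size=(300, 1))
        vectors += 0.01 * np.abs(rng.standard_normal((300, 40)))
        net = train_l4(vectors, n_units=30, theta=0.5, lam=0.9, seed=3)
        assert net.lam * net.spectral_radius < 1.0

    def test_zero_vectors_filtered_with_warning(self, rng):
        vectors = np.abs(rng.standard_normal((60, 10))) + 0.1
        vectors[5] = 0.0
        with pytest.warns(UserWarning):
            net = train_l4(vectors, n_units=8, theta=0.8, lam=0.0, seed=4)
        assert net.n_units == 8

    def test_too_few_vectors_raise(self, rng):
        with pytest.raises(ConfigError):
            train_l4(np.abs(rng.standard_normal((5, 10))), n_units=8)


class TestNetworkValidation:
    def test_rejects_non_unit_afferent_rows(self):
        with pytest.raises(ConfigError):
            L4Network(
                afferent=np.ones((3, 3)), lateral=np.zeros((3, 3)),
                theta=0.5, lam=0.0,
            )

    def test_rejects_unstable_lateral_gain(self):
        aff = np.eye(3)
        lat = np.ones((3, 3)) - np.eye(3)
        with pytest.raises(ConfigError):
            L4Network(afferent=aff, lateral=lat, theta=0.5, lam=0.9)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        net = random_network(rng)
        path = tmp_path / "net.npz"
        save_network(net, path, note="test")
        back = load_network(path)
        assert np.array_equal(back.afferent, net.afferent)
        assert np.array_equal(back.lateral, net.lateral)
        assert back.theta == net.theta and back.lam == net.lam
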