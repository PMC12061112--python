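"""Network contracts: block equivalence, loss arithmetic, topology."""

import numpy as np
import pytest

from wbcseg import model as M
from wbcseg.nn.tensor import Tensor
from wbcseg.ode import SolverConfig


@pytest.fixture
def dynamics(rng):
    dyn = M.ConvDynamics(8, rng)
    # randomize the zero-initialized closing conv so the field is non-trivial
    dyn.conv2.weight.data = rng.normal(0, 0.05, dyn.conv2.weight.data.shape)
    return dyn


class TestBlockEquivalence:
    def test_single_unit_euler_step_equals_residual_block(self, dynamics, rng):
        """A residual block is the one-step Euler discretization, bitwise."""
        res = M.ResidualBlock(dynamics)
        ode = M.OdeBlock(dynamics, SolverConfig(method="euler", step=1.0))
        x = Tensor(rng.normal(size=(2, 8, 16, 16)))
        assert np.array_equal(res(x).data, ode(x).data)

    def test_zero_dynamics_is_identity(self, rng):
        dyn = M.ConvDynamics(8, rng)  # closing conv zero-initialized
        ode = M.OdeBlock(dyn, SolverConfig(method="rk4", step=0.25))
        x = Tensor(rng.normal(size=(1, 8, 16, 16)))
        np.testing.assert_array_equal(ode(x).data, x.data)

    def test_residual_block_preserves_shape_finite(self, dynamics, rng):
        x = Tensor(rng.normal(size=(3, 8, 16, 16)))
        out = M.ResidualBlock(dynamics)(x)
        assert out.shape == x.shape
        assert np.all(np.isfinite(out.data))

    def test_step_refinement_converges(self, dynamics, rng):
        """Halving the step changes the output less than doubling it."""
        x = Tensor(rng.normal(size=(1, 8, 8, 8)))
        outs = {}
        for step in (1.0, 0.5, 0.25):
            ode = M.OdeBlock(dynamics, SolverConfig(method="euler", step=step))
            outs[step] = ode(x).data
        coarse = np.abs(outs[1.0] - outs[0.5]).max()
        fine = np.abs(outs[0.5] - outs[0.25]).max()
        assert fine < coarse

    def test_channel_mismatch_raises(self, dynamics, rng):
        x = Tensor(rng.normal(size=(1, 4, 8, 8)))
        with pytest.raises(ValueError):
            M.ResidualBlock(dynamics)(x)


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert M.sigmoid(0.0) == 0.5

    def test_saturation_without_overflow(self):
        assert M.sigmoid(50.0) == pytest.approx(1.0)
        assert M.sigmoid(-745.0) >= 0.0

    def test_symmetry(self, rng):
        u = rng.normal(scale=5.0, size=64)
        np.testing.assert_allclose(M.sigmoid(u) + M.sigmoid(-u), 1.0)


class TestBceLoss:
    def test_perfect_prediction_near_zero(self):
        mask = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert M.bce_loss(mask, mask) <= 1e-5

    def test_uninformative_prediction_is_ln2(self, rng):
        mask = (rng.random((8, 8)) > 0.5).astype(float)
        p = np.full((8, 8), 0.5)
        assert M.bce_loss(p, mask) == pytest.approx(np.log(2), rel=1e-9)

    def test_hand_computed_single_pixel(self):
        assert M.bce_loss(np.array([[0.9]]), np.array([[1.0]])) == \
            pytest.approx(0.10536, abs=1e-5)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            M.bce_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_gradient_pushes_probability_toward_label(self):
        p = Tensor(np.array([[0.3]]), requires_grad=True)
        M.bce_loss(p, np.array([[1.0]])).backward()
        assert p.grad[0, 0] < 0  # loss decreases as p increases toward 1

    def test_tensor_and_numpy_paths_agree(self, rng):
        p = rng.random((6, 6))
        mask = (rng.random((6, 6)) > 0.7).astype(float)
        assert M.bce_loss(Tensor(p), mask).item() == \
            pytest.approx(M.bce_loss(p, mask), rel=1e-12)


class TestBuildModel:
    def test_depth4_has_three_heads(self):
        net = M.build_model(M.ModelConfig(depth=4, base_channels=4))
        assert len(net.heads) == 3

    def test_smallest_legal_model_forward_shape(self, rng):
        net = M.build_model(M.ModelConfig(depth=2, base_channels=4))
        img = rng.integers(0, 255, size=(64, 64, 3), dtype=np.uint8)
        assert M.predict(net, img).shape == (64, 64)

    def test_parameter_count_increases_with_depth(self):
        counts = [M.build_model(M.ModelConfig(depth=d, base_channels=4)
                                ).n_parameters() for d in (2, 3, 4)]
        assert counts[0] < counts[1] < counts[2]

    @pytest.mark.parametrize("kwargs", [
        dict(depth=1), dict(base_channels=2), dict(ode_blocks_per_level=0)])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            M.ModelConfig(**kwargs)


class TestPredict:
    def test_deterministic(self, rng):
        net = M.build_model(M.ModelConfig(depth=2, base_channels=4, seed=3))
        img = rng.integers(0, 255, size=(64, 64, 3), dtype=np.uint8)
        np.testing.assert_array_equal(M.predict(net, img), M.predict(net, img))

    def test_output_in_unit_interval(self, rng):
        net = M.build_model(M.ModelConfig(depth=2, base_channels=4))
        img = rng.integers(0, 255, size=(64, 64, 3), dtype=np.uint8)
        p = M.predict(net, img)
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_fresh_model_predicts_half_everywhere(self, rng):
        """Zero-initialized heads put every logit at exactly zero."""
        net = M.build_model(M.ModelConfig(depth=3, base_channels=4))
        img = rng.integers(0, 255, size=(64, 64, 3), dtype=np.uint8)
        np.testing.assert_array_equal(M.predict(net, img), 0.5)

    def test_bad_spatial_size_raises(self, rng):
        net = M.build_model(M.ModelConfig(depth=4, base_channels=4))
        img = rng.integers(0, 255, size=(30, 30, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            M.predict(net, img)


def test_full_forward_backward_finite_gradients(rng):
    """Depth-2 model on a 64x64 batch: every parameter gets a finite grad."""
    net = M.build_model(M.ModelConfig(depth=2, base_channels=4, seed=1))
    x = Tensor(rng.normal(size=(2, 3, 64, 64)).astype(np.float64))
    y = (rng.random((2, 1, 64, 64)) > 0.9).astype(float)
    heads = net(x)
    loss = M.bce_loss(heads[0], y)
    for h in heads[1:]:
        loss = loss + M.bce_loss(h, y)
    loss.backward()
    for name, p in net.named_parameters():
        assert p.grad is not None, name
        assert np.all(np.isfinite(p.grad)), name


def test_checkpoint_round_trip(tmp_path, rng):
    net = M.build_model(M.ModelConfig(depth=2, base_channels=4, seed=9))
    img = rng.integers(0, 255, size=(64, 64, 3), dtype=np.uint8)
    before = M.predict(net, img)
    path = tmp_path / "ckpt.npz"
    M.save_checkpoint(net, path)
    restored = M.load_checkpoint(path)
    np.testing.assert_array_equal(M.predict(restored, img), before)
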