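"""Network assembly: stage-width conformance, output contract, determinism,
checkpointing, and trainability."""

import numpy as np
import pytest

from dafdnet.network import (DAFDNet, NetworkConfig, build_dafdnet, load_checkpoint,
                             mse_loss, save_checkpoint)
from dafdnet.training import Adam


def forward_probes(cfg, seed=0, batch=1):
    net = build_dafdnet(cfg, seed=seed)
    rng = np.random.default_rng(5)
    x = rng.random((batch, 1, cfg.input_size, cfg.input_size), dtype=np.float32)
    probes = {}
    out = net.forward(x, probes=probes)
    return net, x, out, probes


@pytest.fixture(scope="module")
def default_probes():
    cfg = NetworkConfig(input_size=128)
    return cfg, forward_probes(cfg)[3]


class TestConformance:
    """Stage widths of the full-width architecture (desk-size input; channel
    counts are independent of spatial size)."""

    @pytest.mark.parametrize("name,channels,scale", [
        ("Gab1", 32, 1), ("Gab2", 32, 2), ("Gab3", 32, 4),
        ("GhoM1", 32, 1), ("GhoM2", 64, 2), ("GhoM3", 128, 4),
        ("GG1", 64, 1), ("GG2", 96, 2), ("GG3", 160, 4),
        ("PF1", 32, 1), ("PF2", 64, 2), ("PF3", 128, 4),
        ("A1", 64, 1), ("A2", 128, 2), ("A3", 256, 4),
        ("Output", 1, 1),
    ])
    def test_stage_widths(self, default_probes, name, channels, scale):
        cfg, probes = default_probes
        side = cfg.input_size // scale
        assert probes[name].shape[1:] == (channels, side, side)

    def test_channel_counts_invariant_to_input_size(self, tiny_cfg):
        import dataclasses
        small = forward_probes(tiny_cfg)[3]
        large = forward_probes(dataclasses.replace(tiny_cfg, input_size=64))[3]
        for name in small:
            assert small[name].shape[1] == large[name].shape[1]


def test_output_is_probability_map(tiny_net, tiny_cfg, rng):
    x = rng.random((2, 1, 32, 32), dtype=np.float32)
    out = tiny_net.forward(x).data
    assert out.shape == (2, 1, 32, 32)
    assert out.min() >= 0.0 and out.max() <= 1.0


def test_forward_is_deterministic(tiny_net, rng):
    x = rng.random((1, 1, 32, 32), dtype=np.float32)
    tiny_net.eval()
    a = tiny_net.forward(x).data
    b = tiny_net.forward(x).data
    tiny_net.train()
    np.testing.assert_array_equal(a, b)


def test_wrong_input_shape_raises(tiny_net):
    with pytest.raises(ValueError):
        tiny_net.forward(np.zeros((1, 1, 16, 16), np.float32))


def test_indivisible_input_size_rejected():
    with pytest.raises(ValueError):
        NetworkConfig(input_size=100)


def test_predict_resamples_to_any_shape(tiny_net, rng):
    prob = tiny_net.predict(rng.random((50, 50)).astype(np.float32))
    assert prob.shape == (50, 50)
    assert prob.min() >= 0.0 and prob.max() <= 1.0


class TestMSELoss:
    def test_equal_inputs_give_zero(self, rng):
        m = rng.random((8, 8))
        assert mse_loss(m, m) == 0.0

    def test_saturated_disagreement_gives_one(self):
        assert mse_loss(np.ones((4, 4)), np.zeros((4, 4))) == pytest.approx(1.0)

    def test_half_level_against_empty(self):
        assert mse_loss(np.full((4, 4), 0.5), np.zeros((4, 4))) == pytest.approx(0.25)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros((2, 2)), np.zeros((3, 3)))


def test_one_adam_step_decreases_loss(tiny_cfg, rng):
    net = build_dafdnet(tiny_cfg, seed=3)
    x = rng.random((2, 1, 32, 32), dtype=np.float32)
    target = (rng.random((2, 1, 32, 32)) < 0.1).astype(np.float32)
    opt = Adam(net.parameters(), lr=1e-4)
    before = None
    for _ in range(2):
        opt.zero_grad()
        loss = mse_loss(net.forward(x), target)
        if before is None:
            before = loss.item()
        loss.backward()
        opt.step()
    after = mse_loss(net.forward(x).data, target)
    assert after < before


def test_checkpoint_roundtrip(tmp_path, tiny_cfg, rng):
    net = build_dafdnet(tiny_cfg, seed=9)
    x = rng.random((1, 1, 32, 32), dtype=np.float32)
    net.eval()
    before = net.forward(x).data
    path = tmp_path / "model.npz"
    save_checkpoint(net, path)
    loaded = load_checkpoint(path)
    assert loaded.cfg == tiny_cfg
    np.testing.assert_array_equal(loaded.eval().forward(x).data, before)
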