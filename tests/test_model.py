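"""MDU-Net graph: structure, output contracts, dense connectivity, pretrained load."""

import numpy as np
import pytest

from mdunet.codec import decode_probability
from mdunet.model import (
    DENSE201_BLOCKS,
    ConfigurationError,
    IncompatibleBackboneError,
    ModelConfig,
    build_model,
    desk_config,
    load_pretrained_backbone,
)

TINY = desk_config(input_size=32)


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(TINY, seed=0)


def test_structure_counts(tiny_model):
    d = tiny_model.describe()
    assert d["encoder_stages"] == 5
    assert d["decoder_stages"] == 4
    assert d["separation_branches"] == 4


def test_dense_connectivity_widths(tiny_model):
    cfg = tiny_model.config
    for blk, length in zip(tiny_model.blocks, cfg.block_lengths):
        assert blk.out_channels == blk.entry_channels + length * cfg.growth_rate


def test_forward_shapes_and_normalization(tiny_model, rng):
    x = rng.random((2, 1, 32, 32)).astype(np.float32)
    outs = tiny_model.predict_probs(x)
    assert len(outs) == 4
    for o in outs:
        assert o.shape == (2, 2, 32, 32)
        assert np.abs(o.sum(axis=1) - 1.0).max() < 1e-5


def test_outputs_decode_to_valid_masks(tiny_model, rng):
    x = rng.random((1, 1, 32, 32)).astype(np.float32)
    for o in tiny_model.predict_probs(x):
        mask = decode_probability(o[0].astype(np.float64) /
                                  o[0].astype(np.float64).sum(axis=0, keepdims=True))
        assert set(np.unique(mask)) <= {0, 1}


def test_duplicated_inputs_give_identical_outputs(tiny_model, rng):
    img = rng.random((1, 32, 32)).astype(np.float32)
    batch = np.stack([img, img])
    for o in tiny_model.predict_probs(batch):
        np.testing.assert_array_equal(o[0], o[1])


def test_single_task_config_has_one_head(rng):
    model = build_model(desk_config(input_size=32, n_tasks=1), seed=0)
    outs = model.predict_probs(rng.random((1, 1, 32, 32)).astype(np.float32))
    assert len(outs) == 1


def test_wrong_spatial_size_error_names_expected(tiny_model):
    with pytest.raises(ValueError, match="32x32"):
        tiny_model.forward(np.zeros((1, 1, 16, 16), dtype=np.float32))


def test_out_of_range_intensities_rejected(tiny_model):
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        tiny_model.forward(np.full((1, 1, 32, 32), 2.0, dtype=np.float32))


@pytest.mark.parametrize("bad", [
    dict(n_encoders=4),                       # n_encoders != n_decoders + 1
    dict(block_lengths=(2, 2)),               # wrong number of dense blocks
    dict(input_size=40),                      # not divisible by 2^4
    dict(fa_channels=(8, 8)),                 # wrong FA list length
    dict(growth_rate=0),
])
def test_invalid_configs_raise(bad):
    base = dict(input_size=64, initial_channels=8, growth_rate=8,
                block_lengths=(2, 2, 2, 2), branch_channels=8)
    base.update(bad)
    with pytest.raises(ConfigurationError):
        ModelConfig(**base).validate()


def test_build_model_validates_config():
    with pytest.raises(ConfigurationError):
        build_model(ModelConfig(input_size=100))


def test_backbone_weight_touches_every_task(rng):
    model = build_model(TINY, seed=3)
    x = rng.random((1, 1, 32, 32)).astype(np.float32)
    before = [o.copy() for o in model.predict_probs(x)]
    model.stem_conv.weight.data += 0.5
    after = model.predict_probs(x)
    for b, a in zip(before, after):
        assert not np.array_equal(b, a)


def test_branch_weight_touches_only_its_task(rng):
    model = build_model(TINY, seed=3)
    x = rng.random((1, 1, 32, 32)).astype(np.float32)
    before = [o.copy() for o in model.predict_probs(x)]
    model.branches[0].conv1.weight.data += 0.5
    after = model.predict_probs(x)
    assert not np.array_equal(before[0], after[0])
    for b, a in zip(before[1:], after[1:]):
        np.testing.assert_array_equal(b, a)


def test_state_dict_roundtrip(tiny_model, rng):
    state = tiny_model.state_dict()
    other = build_model(TINY, seed=99)
    other.load_state_dict(state)
    x = rng.random((1, 1, 32, 32)).astype(np.float32)
    for a, b in zip(tiny_model.predict_probs(x), other.predict_probs(x)):
        np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# Pretrained backbone loading
# ---------------------------------------------------------------------------

def _dense201_small():
    """Dense-201 encoder layout with small decoder/branch widths and input."""
    return ModelConfig(input_size=16, initial_channels=64, growth_rate=32,
                       block_lengths=DENSE201_BLOCKS, fa_channels=(8, 8, 8, 8),
                       branch_channels=4, n_tasks=1)


def test_mismatched_layout_is_rejected():
    model = build_model(TINY, seed=0)
    with pytest.raises(IncompatibleBackboneError, match="dense-201"):
        load_pretrained_backbone(model, "anything.npz")


def test_synthetic_weight_archive_loads_and_is_idempotent(tmp_path):
    # a synthetic stand-in archive in the dense-201 layout (not real
    # pretrained weights): donor-model encoder tensors saved to disk
    donor = build_model(_dense201_small(), seed=42)
    archive = {name: donor.named_parameters()[name].data
               for name in donor.encoder_parameter_names()}
    path = tmp_path / "synthetic_dense201_backbone.npz"
    np.savez(path, **archive)

    model = build_model(_dense201_small(), seed=7)
    fresh_stem = model.stem_conv.weight.data.copy()
    n = load_pretrained_backbone(model, path)
    assert n == len(model.encoder_parameter_names()) > 0
    assert not np.array_equal(model.stem_conv.weight.data, fresh_stem)
    snapshot = {k: v.copy() for k, v in model.state_dict().items()}
    assert load_pretrained_backbone(model, path) == n  # second load: no change
    for k, v in model.state_dict().items():
        np.testing.assert_array_equal(v, snapshot[k])


def test_incomplete_archive_loads_nothing(tmp_path):
    donor = build_model(_dense201_small(), seed=42)
    names = donor.encoder_parameter_names()
    archive = {name: donor.named_parameters()[name].data for name in names[:-1]}
    path = tmp_path / "incomplete.npz"
    np.savez(path, **archive)
    model = build_model(_dense201_small(), seed=7)
    before = model.stem_conv.weight.data.copy()
    with pytest.raises(IncompatibleBackboneError, match="missing"):
        load_pretrained_backbone(model, path)
    np.testing.assert_array_equal(model.stem_conv.weight.data, before)
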