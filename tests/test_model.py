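"""Model construction, forward records, parameter counting, checkpoints."""

import numpy as np
import pytest

from mvld.config import ConfigurationError, DimensionError, EncoderConfig
from mvld.masking import PatchMask, random_patch_mask
from mvld.model import (build_model, count_parameters, load_checkpoint,
                        load_checkpoint_into, parameter_breakdown, patchify,
                        save_checkpoint, unpatchify, weight_hash)
from mvld.tensor import no_grad

TOY = dict(image_layers=2, text_layers=2, fusion_layers=1, hidden_dim=32,
           num_heads=2, patch_size=8, image_size=32, image_channels=1,
           vocab_size=64, max_text_len=16, decoder_layers=2, decoder_dim=16)


def oracle_param_count(cfg: EncoderConfig):
    """Independent enumeration of every weight array's element count."""
    d, m = cfg.hidden_dim, round(cfg.hidden_dim * cfg.mlp_ratio)
    N, P, V, T = cfg.num_patches, cfg.patch_dim, cfg.vocab_size, cfg.max_text_len

    def block(dd, mm):
        return 4 * (dd * dd + dd) + 2 * 2 * dd + (dd * mm + mm + mm * dd + dd)

    image = (P * d + d) + d + (N + 1) * d + cfg.image_layers * block(d, m) + 2 * d
    text = V * d + T * d + 2 * d + cfg.text_layers * block(d, m) + 2 * d
    per_stream = 8 * (d * d + d) + (d * m + m + m * d + d) + 3 * 2 * d
    fusion = cfg.fusion_layers * 2 * per_stream
    dd, dm = cfg.decoder_dim, round(cfg.decoder_dim * cfg.mlp_ratio)
    heads = ((d * d + d) + 2 * d + V) + ((d * d + d) + (2 * d + 2)) + \
        ((d * dd + dd) + dd + (N + 1) * dd + cfg.decoder_layers * block(dd, dm)
         + 2 * dd + (dd * P + P))
    return image, text, fusion, heads


class TestBuild:
    def test_toy_forward_shape_contract(self, toy_student, toy_batch):
        images, ids = toy_batch
        rec = toy_student.forward_with_records(images[:1], ids[:1])
        assert len(rec.image_attn) == 2
        N = toy_student.config.num_patches
        assert rec.image_attn[0].shape == (1, 2, N + 1, N + 1)
        assert rec.mlm_logits.shape == (1, 16, 64)
        assert rec.pooled_joint.shape == (1, 32)

    def test_invalid_width_head_combination(self):
        with pytest.raises(ConfigurationError, match="divisible"):
            EncoderConfig(**{**TOY, "hidden_dim": 30, "num_heads": 4})

    def test_invalid_patch_geometry(self):
        with pytest.raises(ConfigurationError):
            EncoderConfig(**{**TOY, "image_size": 30})

    def test_layer_counts_at_least_one(self):
        with pytest.raises(ConfigurationError):
            EncoderConfig(**{**TOY, "fusion_layers": 0})

    def test_hidden_record_lengths_match_config(self, toy_student, toy_batch):
        images, ids = toy_batch
        rec = toy_student.forward_with_records(images[:2], ids[:2])
        cfg = toy_student.config
        assert len(rec.image_hidden) == cfg.image_layers
        assert len(rec.text_hidden) == cfg.text_layers
        assert len(rec.fusion_hidden) == cfg.fusion_layers


class TestForward:
    def test_attention_rows_stochastic(self, toy_student, toy_batch):
        images, ids = toy_batch
        rec = toy_student.forward_with_records(images, ids)
        for attn in rec.all_attention():
            rows = attn.numpy().sum(axis=-1)
            assert np.abs(rows - 1.0).max() < 1e-5

    def test_masked_forward_sequence_length(self, toy_student, toy_batch):
        images, ids = toy_batch
        rng = np.random.default_rng(3)
        masks = [random_patch_mask(16, 0.75, rng) for _ in range(4)]
        rec = toy_student.forward_with_records(images, ids, patch_mask=masks)
        assert rec.image_hidden[0].shape[1] == 4 + 1  # 16 - 12 visible + summary

    def test_nothing_masked_equals_unmasked_bitwise(self, toy_student, toy_batch):
        images, ids = toy_batch
        empty = PatchMask(np.zeros(16, dtype=np.int8), 0)
        with no_grad():
            a = toy_student.forward_with_records(images, ids)
            b = toy_student.forward_with_records(images, ids,
                                                 patch_mask=[empty] * 4)
        assert np.array_equal(a.pooled_joint.numpy(), b.pooled_joint.numpy())
        assert np.array_equal(a.mim_pred.numpy(), b.mim_pred.numpy())

    def test_same_inputs_same_records(self, toy_student, toy_batch):
        images, ids = toy_batch
        with no_grad():
            a = toy_student.forward_with_records(images, ids)
            b = toy_student.forward_with_records(images, ids)
        assert np.array_equal(a.mlm_logits.numpy(), b.mlm_logits.numpy())
        assert np.array_equal(a.image_attn[0].numpy(), b.image_attn[0].numpy())

    def test_wrong_mask_length_rejected(self, toy_student, toy_batch):
        images, ids = toy_batch
        bad = PatchMask(np.ones(9, dtype=np.int8), 9)
        with pytest.raises(DimensionError):
            toy_student.forward_with_records(images, ids, patch_mask=[bad] * 4)

    def test_wrong_image_size_rejected(self, toy_student):
        with pytest.raises(DimensionError):
            toy_student.forward_with_records(np.zeros((1, 48, 48, 1)),
                                             np.zeros((1, 16), dtype=int))

    def test_visible_patch_permutation_leaves_pooled_unchanged(self, toy_student,
                                                               toy_batch):
        images, ids = toy_batch
        m = toy_student
        patches = patchify(images[:1].astype(np.float32), 8)
        order = np.arange(16)[None]
        perm = np.random.default_rng(5).permutation(16)[None]

        def pooled(visible):
            # the encoder gathers patches and position indices together, so a
            # permuted ``visible`` feeds the same set in a different order
            with no_grad():
                img_x, _, _ = m.image_encoder(patches, visible)
                txt_x, _, _ = m.text_encoder(ids[:1])
                img_s, txt_s = img_x, txt_x
                for blk in m.fusion_blocks:
                    img_s, txt_s, _ = blk(img_s, txt_s)
                return m.itm_head.pool(img_s[:, 0], txt_s[:, 0]).numpy()

        base = pooled(order)
        shuffled = pooled(perm)
        assert np.abs(base - shuffled).max() < 1e-4


class TestParamCount:
    def test_toy_counts_match_enumeration_oracle(self):
        cfg = EncoderConfig(**TOY)
        model = build_model(cfg, seed=0)
        image, text, fusion, heads = oracle_param_count(cfg)
        got = parameter_breakdown(model)
        assert got == {"image": image, "text": text, "fusion": fusion,
                       "heads": heads}
        assert count_parameters(model) == image + text + fusion + heads == 101010

    def test_breakdown_sums_to_total(self, toy_teacher):
        parts = parameter_breakdown(toy_teacher)
        assert sum(parts.values()) == count_parameters(toy_teacher)

    def test_count_ignores_trainability(self, toy_teacher):
        before = count_parameters(toy_teacher)
        toy_teacher.set_trainable(False)
        try:
            assert count_parameters(toy_teacher) == before
        finally:
            toy_teacher.set_trainable(True)


class TestPatchify:
    def test_roundtrip(self, rng):
        imgs = rng.random((2, 32, 32, 1))
        back = unpatchify(patchify(imgs, 8), 8, 32, 1)
        assert np.array_equal(imgs, back)


class TestCheckpoint:
    def test_roundtrip_preserves_weights(self, tmp_path):
        model = build_model("toy-student", seed=3)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        assert weight_hash(loaded) == weight_hash(model)
        assert loaded.config == model.config

    def test_load_refuses_config_mismatch(self, tmp_path):
        model = build_model("toy-student", seed=3)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        other = build_model("toy-teacher", seed=3)
        with pytest.raises(ConfigurationError, match="hash"):
            load_checkpoint_into(other, path)
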