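"""Dual-stream vision-language encoder with a co-attention fusion module.

The model follows the masked-autoencoder family: a ViT-style image encoder
over non-overlapping patches (with an optional visible-subset forward for
masked image modeling), a text encoder over toy-tokenized captions, and a
fusion module in which an image stream and a text stream exchange
information through cross-attention.  Every forward pass records per-layer
hidden states and post-softmax attention probabilities so that distillation
and attention-guided masking can consume them.

Three task heads sit on top: a masked-language-modeling head tied to the
token embedding, a binary image-text matching head on the pooled joint
representation, and a lightweight transformer decoder that reconstructs
patch pixels for masked image modeling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .config import ConfigurationError, DimensionError, EncoderConfig, get_preset
from .nn import (CoAttentionBlock, Embedding, LayerNorm, Linear, Module,
                 Parameter, TransformerBlock, trunc_normal)
from .tensor import Tensor, concat, embedding, gelu, no_grad, row_scatter


@dataclass
class ForwardRecord:
    """Per-layer activations captured during one forward pass.

    Attention entries are post-softmax probabilities of shape
    (batch, heads, queries, keys); hidden entries are (batch, tokens, dim).
    ``fusion_hidden`` concatenates the image and text streams along the token
    axis; fusion attention is stored per stream (self-attention within each
    stream plus the two cross-attention directions).
    """
    image_hidden: List[Tensor] = field(default_factory=list)
    text_hidden: List[Tensor] = field(default_factory=list)
    fusion_hidden: List[Tensor] = field(default_factory=list)
    image_attn: List[Tensor] = field(default_factory=list)
    text_attn: List[Tensor] = field(default_factory=list)
    fusion_image_attn: List[Tensor] = field(default_factory=list)
    fusion_text_attn: List[Tensor] = field(default_factory=list)
    fusion_cross_i2t: List[Tensor] = field(default_factory=list)
    fusion_cross_t2i: List[Tensor] = field(default_factory=list)
    pooled_joint: Optional[Tensor] = None
    mlm_logits: Optional[Tensor] = None
    itm_logits: Optional[Tensor] = None
    mim_pred: Optional[Tensor] = None
    visible_indices: Optional[np.ndarray] = None

    @property
    def fusion_attn(self):
        """Per-layer (image-stream, text-stream) self-attention pairs."""
        return list(zip(self.fusion_image_attn, self.fusion_text_attn))

    def all_attention(self):
        for group in (self.image_attn, self.text_attn, self.fusion_image_attn,
                      self.fusion_text_attn, self.fusion_cross_i2t,
                      self.fusion_cross_t2i):
            yield from group


def patchify(images: np.ndarray, patch_size: int) -> np.ndarray:
    """(B, H, W, C) images -> (B, N, p*p*C) row-major patch vectors."""
    B, H, W, C = images.shape
    p = patch_size
    if H % p or W % p:
        raise DimensionError(f"image size {H}x{W} not divisible by patch {p}")
    g_h, g_w = H // p, W // p
    x = images.reshape(B, g_h, p, g_w, p, C)
    return x.transpose(0, 1, 3, 2, 4, 5).reshape(B, g_h * g_w, p * p * C)


def unpatchify(patches: np.ndarray, patch_size: int, image_size: int,
               channels: int) -> np.ndarray:
    B, N, _ = patches.shape
    g = image_size // patch_size
    x = patches.reshape(B, g, g, patch_size, patch_size, channels)
    return x.transpose(0, 1, 3, 2, 4, 5).reshape(B, image_size, image_size, channels)


class ImageEncoder(Module):
    def __init__(self, cfg: EncoderConfig, rng, dtype):
        d = cfg.hidden_dim
        self.patch_proj = Linear(cfg.patch_dim, d, rng, dtype)
        self.cls_token = Parameter(trunc_normal(rng, (1, 1, d), dtype=dtype))
        self.pos_embed = Parameter(trunc_normal(rng, (cfg.num_patches + 1, d), dtype=dtype))
        self.blocks = [TransformerBlock(d, cfg.num_heads, cfg.mlp_ratio, rng, dtype)
                       for _ in range(cfg.image_layers)]
        self.norm = LayerNorm(d, dtype)

    def __call__(self, patches: np.ndarray, visible: Optional[np.ndarray] = None):
        """``patches``: (B, N, P).  ``visible``: (B, V) patch indices to keep;
        the summary token is always prepended and is never masked."""
        B = patches.shape[0]
        if visible is not None:
            patches = patches[np.arange(B)[:, None], visible]
            pos = embedding(self.pos_embed, visible + 1)
        else:
            N = patches.shape[1]
            pos = embedding(self.pos_embed, np.broadcast_to(np.arange(1, N + 1), (B, N)))
        x = self.patch_proj(Tensor(patches)) + pos
        cls = self.cls_token + self.pos_embed[0:1].reshape(1, 1, -1)
        cls = concat([cls] * B, axis=0) if B > 1 else cls
        x = concat([cls, x], axis=1)
        hiddens, attns = [], []
        for blk in self.blocks:
            x, attn = blk(x)
            hiddens.append(x)
            attns.append(attn)
        return self.norm(x), hiddens, attns


class TextEncoder(Module):
    def __init__(self, cfg: EncoderConfig, rng, dtype):
        d = cfg.hidden_dim
        self.token_embed = Embedding(cfg.vocab_size, d, rng, dtype)
        self.pos_embed = Parameter(trunc_normal(rng, (cfg.max_text_len, d), dtype=dtype))
        self.embed_norm = LayerNorm(d, dtype)
        self.blocks = [TransformerBlock(d, cfg.num_heads, cfg.mlp_ratio, rng, dtype)
                       for _ in range(cfg.text_layers)]
        self.norm = LayerNorm(d, dtype)

    def __call__(self, token_ids: np.ndarray):
        B, T = token_ids.shape
        pos = embedding(self.pos_embed, np.broadcast_to(np.arange(T), (B, T)))
        x = self.embed_norm(self.token_embed(token_ids) + pos)
        hiddens, attns = [], []
        for blk in self.blocks:
            x, attn = blk(x)
            hiddens.append(x)
            attns.append(attn)
        return self.norm(x), hiddens, attns


class MLMHead(Module):
    """Transform + vocabulary projection tied to the token embedding."""

    def __init__(self, cfg: EncoderConfig, token_embed: Embedding, rng, dtype):
        d = cfg.hidden_dim
        self.dense = Linear(d, d, rng, dtype)
        self.norm = LayerNorm(d, dtype)
        self._tied = token_embed
        self.bias = Parameter(np.zeros(cfg.vocab_size, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        h = self.norm(gelu(self.dense(x)))
        return h @ self._tied.weight.transpose(1, 0) + self.bias


class ITMHead(Module):
    def __init__(self, cfg: EncoderConfig, rng, dtype):
        d = cfg.hidden_dim
        self.pooler = Linear(d, d, rng, dtype)
        self.classifier = Linear(d, 2, rng, dtype)

    def pool(self, img_cls: Tensor, txt_cls: Tensor) -> Tensor:
        return self.pooler((img_cls + txt_cls) * 0.5).tanh()

    def __call__(self, pooled: Tensor) -> Tensor:
        return self.classifier(pooled)


class MIMDecoder(Module):
    """Masked-autoencoder style decoder: visible fused image tokens are
    projected to the decoder width, mask tokens fill the masked slots, and a
    small transformer predicts raw pixel vectors for every patch."""

    def __init__(self, cfg: EncoderConfig, rng, dtype):
        dd = cfg.decoder_dim
        self.embed = Linear(cfg.hidden_dim, dd, rng, dtype)
        self.mask_token = Parameter(trunc_normal(rng, (1, 1, dd), dtype=dtype))
        self.pos_embed = Parameter(trunc_normal(rng, (cfg.num_patches + 1, dd), dtype=dtype))
        self.blocks = [TransformerBlock(dd, cfg.decoder_heads, cfg.mlp_ratio, rng, dtype)
                       for _ in range(cfg.decoder_layers)]
        self.norm = LayerNorm(dd, dtype)
        self.out = Linear(dd, cfg.patch_dim, rng, dtype)
        self._num_patches = cfg.num_patches

    def __call__(self, fused_img: Tensor, visible: Optional[np.ndarray]) -> Tensor:
        B = fused_img.shape[0]
        N = self._num_patches
        tokens = self.embed(fused_img)            # (B, V+1, dd)
        if visible is None:
            full = tokens
        else:
            base = concat([self.mask_token] * B, axis=0) if B > 1 else self.mask_token
            base = base * Tensor(np.ones((1, N + 1, 1), dtype=tokens.dtype))
            V = visible.shape[1]
            rows = np.concatenate([np.zeros((B, 1), dtype=np.int64), visible + 1], axis=1)
            batch_idx = np.repeat(np.arange(B)[:, None], V + 1, axis=1)
            flat_tokens = tokens.reshape(B * (V + 1), -1)
            full = row_scatter(base, batch_idx.reshape(-1),
                               rows.reshape(-1), flat_tokens)
        pos = embedding(self.pos_embed, np.broadcast_to(np.arange(N + 1), (B, N + 1)))
        x = full + pos
        for blk in self.blocks:
            x, _ = blk(x)
        pred = self.out(self.norm(x))
        return pred[:, 1:]                        # drop the summary-token slot


class VisionLanguageModel(Module):
    def __init__(self, config: EncoderConfig, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.config = config
        self.image_encoder = ImageEncoder(config, rng, dtype)
        self.text_encoder = TextEncoder(config, rng, dtype)
        self.fusion_blocks = [CoAttentionBlock(config.hidden_dim, config.num_heads,
                                               config.mlp_ratio, rng, dtype)
                              for _ in range(config.fusion_layers)]
        self.mlm_head = MLMHead(config, self.text_encoder.token_embed, rng, dtype)
        self.itm_head = ITMHead(config, rng, dtype)
        self.mim_decoder = MIMDecoder(config, rng, dtype)

    # named_parameters must not descend into the tied embedding twice
    def named_parameters(self, prefix: str = ""):
        seen = set()
        for name, p in super().named_parameters(prefix):
            if id(p) in seen:
                continue
            seen.add(id(p))
            yield name, p

    def forward_with_records(self, images: np.ndarray, token_ids: np.ndarray,
                             patch_mask: Optional[np.ndarray] = None,
                             token_plan=None) -> ForwardRecord:
        cfg = self.config
        images = np.asarray(images, dtype=np.float32)
        if images.ndim == 3:
            images = images[..., None]
        if images.shape[1] != cfg.image_size or images.shape[2] != cfg.image_size:
            raise DimensionError(
                f"expected {cfg.image_size}px images, got {images.shape[1:3]}")
        if images.shape[3] != cfg.image_channels:
            if images.shape[3] == 1:
                images = np.repeat(images, cfg.image_channels, axis=3)
            else:
                raise DimensionError("channel count mismatch")
        token_ids = np.asarray(token_ids, dtype=np.int64)
        if token_ids.shape[1] != cfg.max_text_len:
            raise DimensionError(
                f"expected text length {cfg.max_text_len}, got {token_ids.shape[1]}")

        if token_plan is not None:
            from .masking import apply_token_plans
            token_ids = apply_token_plans(token_ids, token_plan)

        patches = patchify(images, cfg.patch_size)
        visible = None
        if patch_mask is not None:
            mask_arr = _as_mask_array(patch_mask, len(images))
            if mask_arr.shape[1] != cfg.num_patches:
                raise DimensionError(
                    f"patch mask length {mask_arr.shape[1]} != N={cfg.num_patches}")
            counts = (~mask_arr).sum(axis=1)
            if not (counts == counts[0]).all():
                raise DimensionError("per-sample visible counts must match")
            visible = np.stack([np.flatnonzero(~m) for m in mask_arr])

        rec = ForwardRecord(visible_indices=visible)
        img_x, rec.image_hidden, rec.image_attn = self.image_encoder(patches, visible)
        txt_x, rec.text_hidden, rec.text_attn = self.text_encoder(token_ids)

        img_s, txt_s = img_x, txt_x
        for blk in self.fusion_blocks:
            img_s, txt_s, maps = blk(img_s, txt_s)
            rec.fusion_hidden.append(concat([img_s, txt_s], axis=1))
            rec.fusion_image_attn.append(maps["image_self"])
            rec.fusion_text_attn.append(maps["text_self"])
            rec.fusion_cross_i2t.append(maps["image_to_text"])
            rec.fusion_cross_t2i.append(maps["text_to_image"])

        rec.pooled_joint = self.itm_head.pool(img_s[:, 0], txt_s[:, 0])
        rec.mlm_logits = self.mlm_head(txt_s)
        rec.itm_logits = self.itm_head(rec.pooled_joint)
        rec.mim_pred = self.mim_decoder(img_s, visible)
        return rec


def _as_mask_array(patch_mask, batch_size: int) -> np.ndarray:
    """Accept a PatchMask, a list of PatchMask, or a (B, N) array."""
    from .masking import PatchMask
    if isinstance(patch_mask, PatchMask):
        arr = np.broadcast_to(patch_mask.mask.astype(bool), (batch_size, patch_mask.mask.size))
        return np.ascontiguousarray(arr)
    if isinstance(patch_mask, (list, tuple)):
        return np.stack([m.mask.astype(bool) if isinstance(m, PatchMask)
                         else np.asarray(m, dtype=bool) for m in patch_mask])
    return np.asarray(patch_mask, dtype=bool)


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def build_model(config, seed: int = 0, dtype=np.float32) -> VisionLanguageModel:
    """Instantiate a model from an :class:`EncoderConfig` or preset name."""
    if isinstance(config, str):
        config = get_preset(config)
    if not isinstance(config, EncoderConfig):
        raise ConfigurationError("config must be an EncoderConfig or preset name")
    return VisionLanguageModel(config, seed=seed, dtype=dtype)


def forward_with_records(model: VisionLanguageModel, images, token_ids,
                         patch_mask=None, token_plan=None,
                         trainable: bool = True) -> ForwardRecord:
    if trainable:
        return model.forward_with_records(images, token_ids, patch_mask, token_plan)
    with no_grad():
        return model.forward_with_records(images, token_ids, patch_mask, token_plan)


def count_parameters(model: VisionLanguageModel) -> int:
    return model.num_parameters()


def parameter_breakdown(model: VisionLanguageModel) -> dict:
    """Component-wise trainable parameter counts; values sum to the total."""
    groups = {"image": 0, "text": 0, "fusion": 0, "heads": 0}
    for name, p in model.named_parameters():
        if name.startswith("image_encoder"):
            groups["image"] += p.data.size
        elif name.startswith("text_encoder"):
            groups["text"] += p.data.size
        elif name.startswith("fusion_blocks"):
            groups["fusion"] += p.data.size
        else:
            groups["heads"] += p.data.size
    return groups


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: VisionLanguageModel, path, extra: Optional[dict] = None):
    """Single-file checkpoint: weights + embedded config JSON + config hash."""
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    meta = {"config": json.loads(model.config.to_json()),
            "config_hash": model.config.config_hash()}
    if extra:
        for k, v in extra.items():
            if isinstance(v, np.ndarray):
                arrays[f"extra/{k}"] = v
            else:
                meta.setdefault("extra", {})[k] = v
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def _read_checkpoint(path):
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    return meta, arrays


def load_checkpoint(path, dtype=np.float32) -> VisionLanguageModel:
    meta, arrays = _read_checkpoint(path)
    config = EncoderConfig(**meta["config"])
    model = build_model(config, seed=0, dtype=dtype)
    model.load_state_dict({k[len("param/"):]: v for k, v in arrays.items()
                           if k.startswith("param/")})
    return model


def load_checkpoint_into(model: VisionLanguageModel, path):
    """Load weights into an existing model; refuses a mismatched config hash."""
    meta, arrays = _read_checkpoint(path)
    if meta["config_hash"] != model.config.config_hash():
        raise ConfigurationError(
            f"checkpoint config hash {meta['config_hash']} does not match "
            f"model config hash {model.config.config_hash()}")
    model.load_state_dict({k[len("param/"):]: v for k, v in arrays.items()
                           if k.startswith("param/")})
    return meta


def weight_hash(model: VisionLanguageModel) -> str:
    h = hashlib.sha256()
    for name, p in sorted(model.named_parameters()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()
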