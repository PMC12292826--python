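"""Teacher-to-student distillation: layer mapping, hidden-state and
attention-map losses.

Each of the l student layers is aligned with teacher layer m(i) =
ceil(i * L / l) — the last teacher layer of the i-th of l equal-depth
intervals — which reproduces the published 2:1 / 3:1 / 6:1 mappings whenever
L / l is integral and degrades gracefully otherwise.  Hidden states are
compared with MSE summed over student layers; attention maps (post-softmax)
are compared head-by-head with MSE, summed over layers and heads and scaled
by 1/h.  The teacher side never receives gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

from .config import ConfigurationError, DimensionError
from .tensor import Tensor, mse


@dataclass(frozen=True)
class LayerMap:
    hidden_map: tuple       # teacher layer index (1-based) per student layer
    attn_map: tuple
    component: str = "image"

    def __post_init__(self):
        for seq in (self.hidden_map, self.attn_map):
            if any(b <= a for a, b in zip(seq, seq[1:])):
                raise ConfigurationError("layer map must be strictly increasing")


def build_layer_map(teacher_layers: int, student_layers: int,
                    component: str = "image") -> LayerMap:
    """Uniform interval mapping m(i) = ceil(i * L / l), so m(l) = L."""
    L, l = teacher_layers, student_layers
    if not 1 <= l <= L:
        raise ConfigurationError(
            f"student depth {l} must satisfy 1 <= l <= teacher depth {L}")
    mapping = tuple(math.ceil(i * L / l) for i in range(1, l + 1))
    return LayerMap(hidden_map=mapping, attn_map=mapping, component=component)


def _as_tensor_list(xs) -> List[Tensor]:
    return [x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))
            for x in xs]


def hidden_distillation_loss(student_hidden: Sequence, teacher_hidden: Sequence,
                             layer_map: LayerMap) -> Tensor:
    """Sum over student layers of MSE(H_i^S, H_m(i)^T)."""
    student_hidden = _as_tensor_list(student_hidden)
    teacher_hidden = _as_tensor_list(teacher_hidden)
    if len(student_hidden) != len(layer_map.hidden_map):
        raise DimensionError("student depth does not match the layer map")
    total = None
    for i, t_idx in enumerate(layer_map.hidden_map):
        s = student_hidden[i]
        t = teacher_hidden[t_idx - 1].detach()
        if s.shape != t.shape:
            raise DimensionError(
                f"hidden shape mismatch at student layer {i + 1}: "
                f"{s.shape} vs teacher layer {t_idx}: {t.shape}")
        term = mse(s, t)
        total = term if total is None else total + term
    return total


def attention_distillation_loss(student_attn: Sequence, teacher_attn: Sequence,
                                layer_map: LayerMap) -> Tensor:
    """(1/h) * sum over student layers and heads of MSE between student and
    mapped teacher attention maps (post-softmax probabilities)."""
    student_attn = _as_tensor_list(student_attn)
    teacher_attn = _as_tensor_list(teacher_attn)
    if len(student_attn) != len(layer_map.attn_map):
        raise DimensionError("student depth does not match the layer map")
    h = student_attn[0].shape[-3]
    total = None
    for j, t_idx in enumerate(layer_map.attn_map):
        s = student_attn[j]
        t = teacher_attn[t_idx - 1].detach()
        if s.shape[-3] != t.shape[-3]:
            raise ConfigurationError(
                f"head count mismatch: student {s.shape[-3]} vs teacher {t.shape[-3]}")
        if s.shape != t.shape:
            raise DimensionError(
                f"attention shape mismatch at student layer {j + 1}: "
                f"{s.shape} vs {t.shape}")
        for i in range(h):
            s_i = s[i] if s.ndim == 3 else s[:, i]
            t_i = t[i] if t.ndim == 3 else t[:, i]
            term = mse(s_i, t_i)
            total = term if total is None else total + term
    return total * (1.0 / h)


def distillation_losses(student_record, teacher_record, student_cfg, teacher_cfg):
    """Hidden and attention distillation across image, text and fusion
    components of two forward records; returns (L_hid, L_attn)."""
    comps = (
        ("image", student_record.image_hidden, teacher_record.image_hidden,
         student_record.image_attn, teacher_record.image_attn,
         student_cfg.image_layers, teacher_cfg.image_layers),
        ("text", student_record.text_hidden, teacher_record.text_hidden,
         student_record.text_attn, teacher_record.text_attn,
         student_cfg.text_layers, teacher_cfg.text_layers),
        ("fusion", student_record.fusion_hidden, teacher_record.fusion_hidden,
         student_record.fusion_image_attn, teacher_record.fusion_image_attn,
         student_cfg.fusion_layers, teacher_cfg.fusion_layers),
    )
    hid_total, attn_total = None, None
    for name, s_hid, t_hid, s_attn, t_attn, l, L in comps:
        lmap = build_layer_map(L, l, component=name)
        h_term = hidden_distillation_loss(s_hid, t_hid, lmap)
        a_term = attention_distillation_loss(s_attn, t_attn, lmap)
        if name == "fusion":
            # the text stream's self-attention is distilled as well
            lmap_t = build_layer_map(L, l, component="fusion")
            a_term = a_term + attention_distillation_loss(
                student_record.fusion_text_attn, teacher_record.fusion_text_attn,
                lmap_t)
        hid_total = h_term if hid_total is None else hid_total + h_term
        attn_total = a_term if attn_total is None else attn_total + a_term
    return hid_total, attn_total
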