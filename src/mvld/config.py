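"""Encoder architecture configuration and the preset registry.

Presets mirror the three published architectures (a 12/12/6-layer teacher and
two compact students at 7/6/2 and 5/4/1 layers, all at width 768 with 16 px
patches on 288 px images) plus two tiny "toy" configurations sized so the
whole pipeline runs in seconds on one CPU.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass


class ConfigurationError(ValueError):
    """An architecture or run configuration violates an invariant."""


class DimensionError(ValueError):
    """An input's shape is inconsistent with the configuration."""


@dataclass(frozen=True)
class EncoderConfig:
    image_layers: int
    text_layers: int
    fusion_layers: int
    hidden_dim: int
    num_heads: int
    mlp_ratio: float = 4.0
    patch_size: int = 16
    image_size: int = 288
    image_channels: int = 3
    vocab_size: int = 50265
    max_text_len: int = 64
    decoder_layers: int = 8
    decoder_dim: int = 512
    role: str = "student"

    def __post_init__(self):
        if self.hidden_dim % self.num_heads:
            raise ConfigurationError(
                f"hidden_dim ({self.hidden_dim}) must be divisible by "
                f"num_heads ({self.num_heads})")
        if self.image_size % self.patch_size:
            raise ConfigurationError(
                f"image_size ({self.image_size}) must be divisible by "
                f"patch_size ({self.patch_size})")
        for name in ("image_layers", "text_layers", "fusion_layers", "decoder_layers"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.max_text_len < 2:
            raise ConfigurationError("max_text_len must be >= 2 (special tokens)")
        if self.mlp_ratio <= 0:
            raise ConfigurationError("mlp_ratio must be positive")
        if self.role not in ("teacher", "student"):
            raise ConfigurationError("role must be 'teacher' or 'student'")
        if self.vocab_size < 5:
            raise ConfigurationError("vocab_size must cover the special tokens")

    @property
    def grid_size(self) -> int:
        return self.image_size // self.patch_size

    @property
    def num_patches(self) -> int:
        return self.grid_size ** 2

    @property
    def patch_dim(self) -> int:
        return self.patch_size * self.patch_size * self.image_channels

    @property
    def decoder_heads(self) -> int:
        h = 8
        while self.decoder_dim % h:
            h //= 2
        return h

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "EncoderConfig":
        return cls(**json.loads(s))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def _full_scale(**kw) -> EncoderConfig:
    base = dict(hidden_dim=768, num_heads=12, mlp_ratio=4.0, patch_size=16,
                image_size=288, image_channels=3, vocab_size=50265,
                max_text_len=64, decoder_layers=8, decoder_dim=512)
    base.update(kw)
    return EncoderConfig(**base)


def _toy_scale(**kw) -> EncoderConfig:
    base = dict(hidden_dim=32, num_heads=2, mlp_ratio=4.0, patch_size=8,
                image_size=32, image_channels=1, vocab_size=64,
                max_text_len=16, decoder_layers=2, decoder_dim=16)
    base.update(kw)
    return EncoderConfig(**base)


PRESETS: dict = {
    "teacher-m3ae": lambda: _full_scale(image_layers=12, text_layers=12,
                                         fusion_layers=6, role="teacher"),
    "student-base": lambda: _full_scale(image_layers=7, text_layers=6,
                                         fusion_layers=2, role="student"),
    "student-small": lambda: _full_scale(image_layers=5, text_layers=4,
                                          fusion_layers=1, role="student"),
    "toy-teacher": lambda: _toy_scale(image_layers=4, text_layers=4,
                                      fusion_layers=2, role="teacher"),
    "toy-student": lambda: _toy_scale(image_layers=2, text_layers=2,
                                      fusion_layers=1, role="student"),
}


def get_preset(name: str) -> EncoderConfig:
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
    return factory()
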