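"""Synthetic radiograph-like image-caption corpus with known salient regions.

Each sample is a low-contrast grayscale image (a smooth background built from
a few random low-frequency sinusoids) with one bright elliptical "lesion"
planted entirely inside a known quadrant, paired with a template caption
("a <size> <shape> <intensity> opacity in the <position> region") that
mentions exactly the descriptor words used to render the lesion.  Because the
patch indices covered by the lesion are recorded, attention-guided masking
and the cross-modal objectives can be tested against ground truth without
any external dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
from PIL import Image

from .tokenizer import SPECIAL_TOKENS, Vocabulary

SIZES = ("tiny", "small", "large")
SHAPES = ("round", "oval", "elongated")
INTENSITIES = ("faint", "bright", "dense")
POSITIONS = ("upper-left", "upper-right", "lower-left", "lower-right")
CAPTION_TEMPLATE = "a {size} {shape} {intensity} opacity in the {position} region"

# lesion geometry, as fractions of the image side
_SIZE_RADII = {"tiny": (0.06, 0.09), "small": (0.10, 0.13), "large": (0.16, 0.19)}
_SHAPE_RATIO = {"round": 1.0, "oval": 0.6, "elongated": 0.35}
_INTENSITY_DELTA = {"faint": 0.25, "bright": 0.45, "dense": 0.65}
# plausible range of the lesion's pixel-area fraction under the defaults
AREA_FRACTION_RANGE = (0.001, 0.15)

VOCAB_SIZE = 64


def default_vocab_tokens() -> List[str]:
    words = ["a", "opacity", "in", "the", "region"]
    words += list(SIZES) + list(SHAPES) + list(INTENSITIES) + list(POSITIONS)
    tokens = list(SPECIAL_TOKENS) + words
    i = 0
    while len(tokens) < VOCAB_SIZE:
        tokens.append(f"filler-{i:02d}")
        i += 1
    return tokens


def default_vocabulary() -> Vocabulary:
    return Vocabulary(default_vocab_tokens())


def random_caption(rng: np.random.Generator) -> str:
    """One caption drawn from the template grammar."""
    return CAPTION_TEMPLATE.format(
        size=SIZES[rng.integers(len(SIZES))],
        shape=SHAPES[rng.integers(len(SHAPES))],
        intensity=INTENSITIES[rng.integers(len(INTENSITIES))],
        position=POSITIONS[rng.integers(len(POSITIONS))])


def grammar_token_sequence(rng: np.random.Generator, vocab: Vocabulary,
                           total_len: int) -> np.ndarray:
    """A [CLS] ... [SEP] token sequence of exactly ``total_len`` built by
    concatenating grammar captions (truncated to fit)."""
    words: List[str] = []
    while len(words) < total_len - 2:
        words.extend(random_caption(rng).split())
    ids = [vocab.cls_id] + [vocab.token_to_id[w] for w in words[: total_len - 2]] \
        + [vocab.sep_id]
    return np.asarray(ids, dtype=np.int64)


@dataclass
class SyntheticSample:
    image: np.ndarray                  # (H, W) float in [0, 1]
    caption: str
    lesion_patches: np.ndarray         # sorted patch indices under the grid
    lesion_descriptor: Dict[str, str]  # position / shape / size / intensity words
    lesion_center: tuple = (0.0, 0.0)  # (row, col) in pixels
    lesion_area: int = 0               # lesion pixel count


def _background(rng: np.random.Generator, size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size] / size
    img = np.full((size, size), 0.35)
    for _ in range(3):
        fx, fy = rng.uniform(0.5, 2.0, size=2)
        phase = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0.02, 0.06)
        img += amp * np.sin(2 * np.pi * (fx * xx + fy * yy) + phase)
    return img


def _quadrant_of(row: float, col: float, size: int) -> str:
    vert = "upper" if row < size / 2 else "lower"
    horiz = "left" if col < size / 2 else "right"
    return f"{vert}-{horiz}"


def generate_sample(rng: np.random.Generator, image_size: int = 32,
                    patch_size: int = 8) -> SyntheticSample:
    size_word = SIZES[rng.integers(len(SIZES))]
    shape_word = SHAPES[rng.integers(len(SHAPES))]
    intensity_word = INTENSITIES[rng.integers(len(INTENSITIES))]
    position_word = POSITIONS[rng.integers(len(POSITIONS))]

    a = rng.uniform(*_SIZE_RADII[size_word]) * image_size
    b = max(a * _SHAPE_RATIO[shape_word], 1.0)
    theta = rng.uniform(0, np.pi)

    half = image_size / 2
    margin = a + 1.0
    lo, hi = margin, half - margin
    if hi <= lo:                      # lesion too large for the quadrant
        lo = hi = half / 2
    cy = rng.uniform(lo, hi)
    cx = rng.uniform(lo, hi)
    if position_word.startswith("lower"):
        cy += half
    if position_word.endswith("right"):
        cx += half

    img = _background(rng, image_size)
    yy, xx = np.mgrid[0:image_size, 0:image_size]
    dy, dx = yy + 0.5 - cy, xx + 0.5 - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not inside.any():              # guarantee at least one lesion pixel
        inside[int(np.clip(cy, 0, image_size - 1)), int(np.clip(cx, 0, image_size - 1))] = True
    img = np.clip(img + inside * _INTENSITY_DELTA[intensity_word], 0.0, 1.0)

    grid = image_size // patch_size
    rows, cols = np.nonzero(inside)
    patches = np.unique((rows // patch_size) * grid + (cols // patch_size))
    caption = CAPTION_TEMPLATE.format(size=size_word, shape=shape_word,
                                      intensity=intensity_word,
                                      position=position_word)
    descriptor = {"position": position_word, "shape": shape_word,
                  "size": size_word, "intensity": intensity_word}
    return SyntheticSample(image=img, caption=caption, lesion_patches=patches,
                           lesion_descriptor=descriptor, lesion_center=(cy, cx),
                           lesion_area=int(inside.sum()))


def generate_corpus(n: int, image_size: int = 32, patch_size: int = 8,
                    out_dir=None, seed: int = 0,
                    vocab_path: Optional[str] = None):
    """Generate ``n`` samples; if ``out_dir`` is given, write PNG images, a
    JSONL manifest and the vocabulary file.  Fully deterministic in ``seed``.

    Returns the list of :class:`SyntheticSample`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    samples = [generate_sample(rng, image_size, patch_size) for _ in range(n)]
    if out_dir is not None:
        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        vocab = default_vocabulary()
        vpath = Path(vocab_path) if vocab_path else out / "vocab.txt"
        vocab.save(vpath)
        with open(out / "manifest.jsonl", "w") as fh:
            for i, s in enumerate(samples):
                rel = f"images/img_{i:05d}.png"
                arr = np.round(s.image * 255).astype(np.uint8)
                Image.fromarray(arr, mode="L").save(out / rel)
                fh.write(json.dumps({
                    "image": rel,
                    "caption": s.caption,
                    "salient_patches": [int(p) for p in s.lesion_patches],
                    "descriptor": s.lesion_descriptor,
                    "lesion_center": [float(c) for c in s.lesion_center],
                }) + "\n")
        meta = {"n": n, "image_size": image_size, "patch_size": patch_size,
                "seed": seed, "vocab": vpath.name}
        (out / "corpus.json").write_text(json.dumps(meta, indent=2) + "\n")
    return samples


class Corpus:
    """An on-disk corpus (manifest + PNGs + vocabulary) loaded into memory."""

    def __init__(self, root):
        self.root = Path(root)
        meta = json.loads((self.root / "corpus.json").read_text())
        self.image_size = meta["image_size"]
        self.patch_size = meta["patch_size"]
        self.vocab = Vocabulary.load(self.root / meta["vocab"])
        self.samples: List[SyntheticSample] = []
        with open(self.root / "manifest.jsonl") as fh:
            for line in fh:
                rec = json.loads(line)
                arr = np.asarray(Image.open(self.root / rec["image"]),
                                 dtype=np.float64) / 255.0
                self.samples.append(SyntheticSample(
                    image=arr, caption=rec["caption"],
                    lesion_patches=np.asarray(rec["salient_patches"], dtype=np.int64),
                    lesion_descriptor=rec.get("descriptor", {}),
                    lesion_center=tuple(rec.get("lesion_center", (0.0, 0.0)))))

    def __len__(self):
        return len(self.samples)

    def batch(self, indices, max_text_len: int):
        """(images (B, H, W, 1) float32, token_ids (B, T)) for the indices."""
        imgs = np.stack([self.samples[i].image for i in indices])[..., None]
        ids = self.vocab.encode_batch([self.samples[i].caption for i in indices],
                                      max_text_len)
        return imgs.astype(np.float32), ids


def oracle_salience(sample: SyntheticSample, num_patches: int) -> np.ndarray:
    """Ground-truth salience: 1 on lesion patches, 0 elsewhere."""
    s = np.zeros(num_patches, dtype=np.float64)
    s[np.asarray(sample.lesion_patches, dtype=np.int64)] = 1.0
    return s
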