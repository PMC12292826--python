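"""Pre-training objectives: MLM, MIM, ITM, and their unweighted composition.

The total pre-training loss is the plain sum L_mlm + L_mim + L_itm; with
distillation it becomes L_total = L_pretrain + (L_hid + L_attn).  No
weighting coefficients are applied by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .tensor import Tensor, cross_entropy_with_logits


@dataclass
class LossReport:
    """All loss components and their exact sums."""
    mlm: float
    mim: float
    itm: float
    hid: float
    attn: float
    pretrain: float
    distill: float
    total: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("mlm", "mim", "itm", "hid", "attn", "pretrain", "distill", "total")}


def _scalar(x) -> float:
    return float(x.data) if isinstance(x, Tensor) else float(x)


def mlm_loss(logits, targets) -> Tensor:
    """Mean cross-entropy over masked positions.

    ``logits``: (M, V) scores at the M masked positions; ``targets``: (M,)
    original token ids.  An empty batch of masked positions is defined as
    loss 0 (with a warning), since a batch may contain no maskable tokens.
    """
    logits = Tensor.as_tensor(logits)
    targets = np.asarray(targets, dtype=np.int64)
    if targets.size == 0:
        warnings.warn("mlm_loss called with zero masked positions; returning 0",
                      stacklevel=2)
        return Tensor(np.asarray(0.0, dtype=logits.data.dtype))
    return cross_entropy_with_logits(logits, targets)


def mim_loss(predicted_patches, true_patches, mask) -> Tensor:
    """Mean squared error over the masked patches' pixel vectors only.

    ``predicted_patches``/``true_patches``: (B, N, P); ``mask``: PatchMask,
    list of PatchMask, or (B, N) binary array with 1 = masked.
    """
    from .masking import PatchMask
    if isinstance(mask, PatchMask):
        mask = mask.mask[None, :]
    elif isinstance(mask, (list, tuple)):
        mask = np.stack([m.mask if isinstance(m, PatchMask) else np.asarray(m)
                         for m in mask])
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("masked image modeling requires a nonempty patch mask")
    pred = Tensor.as_tensor(predicted_patches)
    true = np.asarray(true_patches)
    if mask.shape[0] == 1 and pred.shape[0] > 1:
        mask = np.broadcast_to(mask, pred.shape[:2])
    b_idx, p_idx = np.nonzero(mask)
    diff = pred[b_idx, p_idx] - Tensor(true[b_idx, p_idx])
    return (diff * diff).mean()


def make_itm_batch(images: np.ndarray, token_ids: np.ndarray,
                   negative_fraction: float = 0.5,
                   rng: Optional[np.random.Generator] = None
                   ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Build an image-text matching batch with in-batch negatives.

    Each pair is independently flipped to a negative with probability
    ``negative_fraction``; a negative replaces either its caption or its
    image (equal probability) with that of a different, uniformly chosen
    batch member.  Returns (images, token_ids, labels) with label 1 for
    matched pairs.
    """
    rng = np.random.default_rng() if rng is None else rng
    images = np.asarray(images)
    token_ids = np.asarray(token_ids)
    B = images.shape[0]
    if B < 2 and negative_fraction > 0:
        raise ValueError("a negative pair needs at least two batch members")
    out_img = images.copy()
    out_txt = token_ids.copy()
    labels = np.ones(B, dtype=np.int64)
    for i in range(B):
        if rng.random() < negative_fraction:
            labels[i] = 0
            partner = int(rng.integers(B - 1))
            if partner >= i:
                partner += 1
            if rng.random() < 0.5:
                out_txt[i] = token_ids[partner]
            else:
                out_img[i] = images[partner]
    return out_img, out_txt, labels


def itm_loss(logits, labels) -> Tensor:
    """Mean binary cross-entropy from 2-way logits (index 1 = matched)."""
    logits = Tensor.as_tensor(logits)
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("itm_loss requires at least one pair")
    return cross_entropy_with_logits(logits, labels)


def compose_losses(mlm, mim, itm, hid, attn) -> LossReport:
    """Exact unweighted sums: pretrain = mlm+mim+itm, distill = hid+attn,
    total = pretrain + distill."""
    vals = {}
    for name, v in (("mlm", mlm), ("mim", mim), ("itm", itm),
                    ("hid", hid), ("attn", attn)):
        f = _scalar(v)
        if not np.isfinite(f):
            raise ValueError(f"non-finite loss component: {name} = {f}")
        vals[name] = f
    pretrain = vals["mlm"] + vals["mim"] + vals["itm"]
    distill = vals["hid"] + vals["attn"]
    return LossReport(pretrain=pretrain, distill=distill,
                      total=pretrain + distill, **vals)
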