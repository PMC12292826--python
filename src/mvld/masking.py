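"""Token and patch masking, and attention-guided progressive mask generation.

Masked language modeling selects 15% of the maskable tokens and applies the
classic 80/10/10 replacement split.  Masked image modeling masks 75% of the
patches, either uniformly at random or guided by an aggregated teacher +
student attention field.  The guided strategy splits patches into a
high-attention group (size round((1-r)*N), with r decaying linearly from
0.95 to 0.3 over training) that is always masked, and fills the remaining
budget with uniform draws from the low-attention group, so the total budget
stays at round(0.75*N) at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .config import ConfigurationError, DimensionError
from .tensor import no_grad

MLM_RATE = 0.15
PATCH_MASK_RATIO = 0.75
ACTION_MASK = "replace_with_mask"
ACTION_RANDOM = "replace_with_random"
ACTION_KEEP = "keep"
_ACTION_PROBS = (0.8, 0.1, 0.1)


def round_half_up(x: float) -> int:
    """Deterministic round-half-up (avoids banker's rounding)."""
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Token masking (MLM)
# ---------------------------------------------------------------------------

@dataclass
class TokenMaskPlan:
    """Positions selected for MLM, their replacement actions and targets."""
    selected_positions: np.ndarray          # (M,) int
    actions: List[str]                      # one of the three actions per position
    target_ids: np.ndarray                  # original token ids at the positions
    replacement_ids: np.ndarray             # id to place at each position

    def __len__(self):
        return len(self.selected_positions)


def plan_token_masking(token_ids: Sequence[int], special_token_ids,
                       rate: float = MLM_RATE,
                       rng: Optional[np.random.Generator] = None,
                       vocab_size: Optional[int] = None,
                       mask_token_id: Optional[int] = None) -> TokenMaskPlan:
    """Select ``floor(rate * maskable)`` non-special positions uniformly and
    assign replacement actions with probabilities 0.8 / 0.1 / 0.1."""
    if not 0 < rate < 1:
        raise ValueError("rate must be in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    token_ids = np.asarray(token_ids, dtype=np.int64)
    special = set(int(s) for s in special_token_ids)
    maskable = np.array([i for i, t in enumerate(token_ids) if int(t) not in special],
                        dtype=np.int64)
    n_sel = int(np.floor(rate * maskable.size))
    if n_sel == 0:
        empty = np.empty(0, dtype=np.int64)
        return TokenMaskPlan(empty, [], empty.copy(), empty.copy())
    chosen = np.sort(rng.choice(maskable, size=n_sel, replace=False))
    draws = rng.random(n_sel)
    actions, repl = [], np.empty(n_sel, dtype=np.int64)
    if vocab_size is None:
        vocab_size = int(token_ids.max()) + 1
    pool = np.array([t for t in range(vocab_size) if t not in special], dtype=np.int64)
    for k, pos in enumerate(chosen):
        if draws[k] < _ACTION_PROBS[0]:
            actions.append(ACTION_MASK)
            if mask_token_id is None:
                raise ValueError("mask_token_id required when tokens are masked")
            repl[k] = mask_token_id
        elif draws[k] < _ACTION_PROBS[0] + _ACTION_PROBS[1]:
            actions.append(ACTION_RANDOM)
            repl[k] = rng.choice(pool)
        else:
            actions.append(ACTION_KEEP)
            repl[k] = token_ids[pos]
    return TokenMaskPlan(chosen, actions, token_ids[chosen].copy(), repl)


def apply_token_plans(token_ids: np.ndarray, plans) -> np.ndarray:
    """Apply one plan per row of a (B, T) id matrix; returns a modified copy."""
    out = np.asarray(token_ids, dtype=np.int64).copy()
    if isinstance(plans, TokenMaskPlan):
        plans = [plans] * out.shape[0]
    for row, plan in zip(out, plans):
        if len(plan):
            row[plan.selected_positions] = plan.replacement_ids
    return out


# ---------------------------------------------------------------------------
# Patch masks
# ---------------------------------------------------------------------------

@dataclass
class PatchMask:
    mask: np.ndarray                        # (N,) 0/1, 1 = masked
    budget: int
    salience: Optional[np.ndarray] = None   # scores that produced the mask, if any

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=np.int8)
        if int(self.mask.sum()) != self.budget:
            raise ValueError("popcount(mask) != budget")

    @property
    def masked_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)

    @property
    def visible_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask == 0)


def random_patch_mask(num_patches: int, ratio: float = PATCH_MASK_RATIO,
                      rng: Optional[np.random.Generator] = None) -> PatchMask:
    if num_patches <= 0:
        raise DimensionError("num_patches must be positive")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng() if rng is None else rng
    budget = round_half_up(ratio * num_patches)
    mask = np.zeros(num_patches, dtype=np.int8)
    mask[rng.choice(num_patches, size=budget, replace=False)] = 1
    return PatchMask(mask, budget)


# ---------------------------------------------------------------------------
# Attention aggregation and salience
# ---------------------------------------------------------------------------

@dataclass
class SalienceField:
    aggregate: np.ndarray                   # (N, N) in [0, 1]
    salience: np.ndarray                    # (N,) nonnegative
    provenance: tuple = ("student_uni", "teacher_uni", "student_mul", "teacher_mul")


def aggregate_attention(a_s_uni: np.ndarray, a_t_uni: np.ndarray,
                        a_s_mul: np.ndarray, a_t_mul: np.ndarray,
                        provenance: tuple = ("student_uni", "teacher_uni",
                                             "student_mul", "teacher_mul")
                        ) -> SalienceField:
    """Element-wise sum of the four attention maps, min-max normalised to
    [0, 1]; a constant sum yields the uniform 0.5 matrix."""
    maps = [np.asarray(a, dtype=np.float64) for a in
            (a_s_uni, a_t_uni, a_s_mul, a_t_mul)]
    shape = maps[0].shape
    if len(shape) != 2 or shape[0] != shape[1]:
        raise DimensionError("attention maps must be square N x N matrices")
    for m in maps[1:]:
        if m.shape != shape:
            raise DimensionError("attention maps must share the same shape")
    total = maps[0] + maps[1] + maps[2] + maps[3]
    if not np.isfinite(total).all() or (total < 0).any():
        raise ValueError("attention maps must be finite and nonnegative")
    lo, hi = total.min(), total.max()
    if hi - lo < 1e-12:
        agg = np.full(shape, 0.5)
    else:
        agg = (total - lo) / (hi - lo)
    field = SalienceField(aggregate=agg, salience=np.empty(0), provenance=provenance)
    field.salience = salience_from_attention(field)
    return field


def salience_from_attention(field: SalienceField) -> np.ndarray:
    """Per-patch salience: the column mean of the aggregate ("attention
    received" by each patch, averaged over querying patches)."""
    return field.aggregate.mean(axis=0)


# ---------------------------------------------------------------------------
# Progressive schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaskSchedule:
    r_start: float = 0.95
    r_end: float = 0.3
    max_steps: int = 1

    def __post_init__(self):
        if not 0 < self.r_end <= self.r_start < 1:
            raise ConfigurationError("require 0 < r_end <= r_start < 1")
        if self.max_steps < 1:
            raise ConfigurationError("max_steps must be >= 1")


def schedule_r(step: int, schedule: MaskSchedule) -> float:
    """Linear decay r = r_start - (r_start - r_end) * step / max_steps,
    clamped to r_end beyond max_steps."""
    if step < 0:
        raise ValueError("step must be nonnegative")
    frac = min(step / schedule.max_steps, 1.0)
    return schedule.r_start - (schedule.r_start - schedule.r_end) * frac


# ---------------------------------------------------------------------------
# Attention-guided mask generation
# ---------------------------------------------------------------------------

def attention_guided_mask(salience: np.ndarray, r: float,
                          total_ratio: float = PATCH_MASK_RATIO,
                          rng: Optional[np.random.Generator] = None) -> PatchMask:
    """Mask the high-attention group (the round((1-r)*N) most salient
    patches) plus uniform draws from the low group up to the fixed budget
    round(total_ratio*N).  Ties in salience break toward the lower index."""
    if not 0 < r < 1:
        raise ValueError("r must be in (0, 1)")
    if not 0 < total_ratio < 1:
        raise ValueError("total_ratio must be in (0, 1)")
    salience = np.asarray(salience, dtype=np.float64)
    n = salience.size
    if n < 1:
        raise DimensionError("salience must be non-empty")
    rng = np.random.default_rng() if rng is None else rng
    budget = round_half_up(total_ratio * n)
    if budget > n:
        raise ValueError("mask budget exceeds the number of patches")
    k_high = round_half_up((1.0 - r) * n)
    order = np.argsort(-salience, kind="stable")   # descending, ties -> lower index
    high = order[:min(k_high, budget)]
    low = np.sort(order[min(k_high, budget):])     # canonical index order for sampling
    remaining = budget - high.size
    extra = rng.choice(low, size=remaining, replace=False) if remaining > 0 else \
        np.empty(0, dtype=np.int64)
    mask = np.zeros(n, dtype=np.int8)
    mask[high] = 1
    mask[extra.astype(np.int64)] = 1
    return PatchMask(mask, budget)


def _square_map(attn: np.ndarray, drop_first: bool) -> np.ndarray:
    """Head-average an attention stack (B, h, S, S), optionally drop the
    summary-token row/column, and renormalise rows."""
    m = attn.mean(axis=1)
    if drop_first:
        m = m[:, 1:, 1:]
    denom = m.sum(axis=-1, keepdims=True)
    return m / np.where(denom == 0, 1.0, denom)


def extract_attention_maps(record) -> tuple:
    """(uni-modal, multi-modal) N x N maps per sample from a forward record.

    Uni-modal: last image-encoder layer self-attention.  Multi-modal: the
    image-stream self-attention of the last fusion layer (text influence
    reaches it through the preceding cross-attention sublayers).  Both are
    head-averaged with the summary token removed and rows renormalised.
    """
    uni = _square_map(record.image_attn[-1].numpy(), drop_first=True)
    mul = _square_map(record.fusion_image_attn[-1].numpy(), drop_first=True)
    return uni, mul


def compute_guided_mask_for_batch(teacher, student, images, token_ids,
                                  step: int, schedule: MaskSchedule,
                                  rng: Optional[np.random.Generator] = None,
                                  total_ratio: float = PATCH_MASK_RATIO
                                  ) -> List[PatchMask]:
    """One gradient-free forward of teacher and student on the unmasked pair,
    followed by aggregation, salience scoring and mask generation with
    r = schedule_r(step).  ``teacher`` may be None (student-only guidance:
    the student maps are used twice, which min-max normalisation makes
    equivalent to using them once)."""
    if teacher is not None and teacher.config.num_patches != student.config.num_patches:
        raise ConfigurationError("teacher and student patch grids differ")
    rng = np.random.default_rng() if rng is None else rng
    with no_grad():
        s_rec = student.forward_with_records(images, token_ids)
        t_rec = teacher.forward_with_records(images, token_ids) \
            if teacher is not None else s_rec
    s_uni, s_mul = extract_attention_maps(s_rec)
    t_uni, t_mul = extract_attention_maps(t_rec)
    r = schedule_r(step, schedule)
    masks = []
    for b in range(len(s_uni)):
        fld = aggregate_attention(s_uni[b], t_uni[b], s_mul[b], t_mul[b])
        m = attention_guided_mask(fld.salience, r, total_ratio, rng)
        m.salience = fld.salience
        masks.append(m)
    return masks
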