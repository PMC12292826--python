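"""Stage-1 pre-training loop, mask visualization, and the efficiency report.

Each optimizer step runs (1) a gradient-free teacher+student forward on the
unmasked pair to compute the attention-guided patch mask, (2) one forward
per pre-training task (MLM with masked text, MIM with masked image, ITM with
in-batch negatives), (3) hidden-state and attention distillation on the MLM
branch, and (4) one AdamW update on the total loss.  Every step appends a
JSONL metrics row; checkpoints embed optimizer and RNG state so a run can be
resumed bit-for-bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import masking, objectives
from .config import ConfigurationError, EncoderConfig, get_preset, PRESETS
from .distill import build_layer_map, distillation_losses
from .model import (VisionLanguageModel, build_model, count_parameters,
                    forward_with_records, load_checkpoint, parameter_breakdown,
                    patchify, save_checkpoint, weight_hash)
from .nn import AdamW, linear_warmup_decay
from .synthdata import Corpus
from .tensor import Tensor


@dataclass
class RunConfig:
    corpus: str = ""
    out_dir: str = "run"
    student: str = "toy-student"
    teacher: Optional[str] = None          # preset name, checkpoint path, or None
    learning_rate: float = 1e-3            # toy default; full scale uses 1e-5
    warmup_frac: float = 0.1
    weight_decay: float = 0.01
    batch_size: int = 8
    max_steps: int = 100
    seed: int = 0
    checkpoint_every: int = 0              # 0 = final checkpoint only
    mlm_rate: float = masking.MLM_RATE
    mask_ratio: float = masking.PATCH_MASK_RATIO
    r_start: float = 0.95
    r_end: float = 0.3
    itm_negative_fraction: float = 0.5
    use_distill: bool = True
    use_guided_mask: bool = True
    dump_masks: bool = False

    def __post_init__(self):
        if not 0 <= self.warmup_frac < 1:
            raise ConfigurationError("warmup_frac must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.max_steps < 1:
            raise ConfigurationError("max_steps must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class PretrainResult:
    checkpoint: str
    metrics: str
    initial_total: float
    final_total: float
    steps_run: int
    teacher_hash_before: Optional[str]
    teacher_hash_after: Optional[str]


def _resolve_teacher(source: Optional[str]) -> Optional[VisionLanguageModel]:
    if source is None:
        return None
    if source in PRESETS:
        return build_model(source, seed=0)
    return load_checkpoint(source)


def _layer_map_echo(student_cfg: EncoderConfig,
                    teacher_cfg: Optional[EncoderConfig]) -> dict:
    if teacher_cfg is None:
        return {}
    return {comp: list(build_layer_map(L, l, comp).hidden_map)
            for comp, L, l in (("image", teacher_cfg.image_layers, student_cfg.image_layers),
                               ("text", teacher_cfg.text_layers, student_cfg.text_layers),
                               ("fusion", teacher_cfg.fusion_layers, student_cfg.fusion_layers))}


def _gather_mlm(record, plans):
    """Collect (logits at masked positions, target ids) across the batch."""
    b_idx, p_idx, targets = [], [], []
    for b, plan in enumerate(plans):
        for pos, tgt in zip(plan.selected_positions, plan.target_ids):
            b_idx.append(b)
            p_idx.append(int(pos))
            targets.append(int(tgt))
    if not targets:
        return None, np.empty(0, dtype=np.int64)
    logits = record.mlm_logits[np.asarray(b_idx), np.asarray(p_idx)]
    return logits, np.asarray(targets, dtype=np.int64)


def pretrain(config: RunConfig, resume_from: Optional[str] = None) -> PretrainResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    corpus = Corpus(config.corpus)
    student_cfg = get_preset(config.student) if isinstance(config.student, str) \
        else config.student

    ss = np.random.SeedSequence(config.seed)
    init_seed, *rng_seeds = ss.spawn(5)
    rngs = {name: np.random.default_rng(s) for name, s in
            zip(("data", "mask", "mlm", "itm"), rng_seeds)}

    student = build_model(student_cfg, seed=int(init_seed.generate_state(1)[0] % (2**31)))
    teacher = _resolve_teacher(config.teacher)
    start_step = 0
    opt = AdamW(student.parameters(), lr=config.learning_rate,
                weight_decay=config.weight_decay)
    if resume_from is not None:
        meta, arrays = _load_resume(student, opt, resume_from)
        start_step = meta["extra"]["step"] + 1
        for name, state in json.loads(meta["extra"]["rng_states"]).items():
            rngs[name].bit_generator.state = state
    if teacher is not None:
        teacher.set_trainable(False)
        if teacher.config.hidden_dim != student.config.hidden_dim and config.use_distill:
            raise ConfigurationError("teacher and student widths differ")
    teacher_hash_before = weight_hash(teacher) if teacher is not None else None

    schedule = masking.MaskSchedule(config.r_start, config.r_end, config.max_steps)
    cfg = student.config
    vocab = corpus.vocab
    echo = {"run_config": asdict(config),
            "layer_maps": _layer_map_echo(cfg, teacher.config if teacher else None)}
    (out / "run_config.json").write_text(json.dumps(echo, indent=2) + "\n")

    metrics_path = out / "metrics.jsonl"
    mode = "a" if resume_from is not None else "w"
    initial_total = final_total = float("nan")
    with open(metrics_path, mode) as mfh:
        for step in range(start_step, config.max_steps):
            opt.lr = linear_warmup_decay(step, config.max_steps,
                                         config.learning_rate, config.warmup_frac)
            n = len(corpus)
            idx = rngs["data"].choice(n, size=config.batch_size,
                                      replace=n < config.batch_size)
            images, token_ids = corpus.batch(idx, cfg.max_text_len)

            # (1) patch masks for the MIM branch
            if config.use_guided_mask:
                masks = masking.compute_guided_mask_for_batch(
                    teacher, student, images, token_ids, step, schedule,
                    rngs["mask"], config.mask_ratio)
            else:
                masks = [masking.random_patch_mask(cfg.num_patches,
                                                   config.mask_ratio, rngs["mask"])
                         for _ in range(config.batch_size)]
            if config.dump_masks:
                _dump_masks(out, step, masks)

            # (2) MLM branch: masked text + full image
            plans = [masking.plan_token_masking(
                row, vocab.special_ids, config.mlm_rate, rngs["mlm"],
                vocab_size=len(vocab), mask_token_id=vocab.mask_id)
                for row in token_ids]
            rec_mlm = student.forward_with_records(images, token_ids,
                                                   token_plan=plans)
            mlm_logits, mlm_targets = _gather_mlm(rec_mlm, plans)
            l_mlm = objectives.mlm_loss(mlm_logits, mlm_targets) \
                if mlm_targets.size else Tensor(np.float32(0.0))

            # (3) distillation on the MLM branch
            if config.use_distill and teacher is not None:
                t_rec = forward_with_records(teacher, images, token_ids,
                                             token_plan=plans, trainable=False)
                l_hid, l_attn = distillation_losses(rec_mlm, t_rec,
                                                    cfg, teacher.config)
            else:
                l_hid = Tensor(np.float32(0.0))
                l_attn = Tensor(np.float32(0.0))

            # MIM branch: masked image + full text
            rec_mim = student.forward_with_records(images, token_ids,
                                                   patch_mask=masks)
            true_patches = patchify(images.astype(np.float32), cfg.patch_size)
            l_mim = objectives.mim_loss(rec_mim.mim_pred, true_patches, masks)

            # ITM branch: full image + full text with in-batch negatives
            itm_img, itm_txt, labels = objectives.make_itm_batch(
                images, token_ids, config.itm_negative_fraction, rngs["itm"])
            rec_itm = student.forward_with_records(itm_img, itm_txt)
            l_itm = objectives.itm_loss(rec_itm.itm_logits, labels)

            report = objectives.compose_losses(l_mlm, l_mim, l_itm, l_hid, l_attn)
            total = l_mlm + l_mim + l_itm + l_hid + l_attn

            opt.zero_grad()
            total.backward()
            opt.step()

            if step == start_step and resume_from is None:
                initial_total = report.total
            final_total = report.total
            row = {"step": step, "r": schedule_value(step, schedule),
                   "lr": opt.lr, **report.as_dict()}
            mfh.write(json.dumps(row) + "\n")

            if config.checkpoint_every and (step + 1) % config.checkpoint_every == 0 \
                    and step + 1 < config.max_steps:
                _save_run_checkpoint(student, opt, rngs, step,
                                     out / f"checkpoint_{step + 1:06d}.npz")

    ckpt = out / "checkpoint_final.npz"
    _save_run_checkpoint(student, opt, rngs, config.max_steps - 1, ckpt)
    teacher_hash_after = weight_hash(teacher) if teacher is not None else None
    return PretrainResult(checkpoint=str(ckpt), metrics=str(metrics_path),
                          initial_total=initial_total, final_total=final_total,
                          steps_run=config.max_steps - start_step,
                          teacher_hash_before=teacher_hash_before,
                          teacher_hash_after=teacher_hash_after)


def schedule_value(step: int, schedule: masking.MaskSchedule) -> float:
    return masking.schedule_r(step, schedule)


def _dump_masks(out: Path, step: int, masks):
    d = out / "masks"
    d.mkdir(exist_ok=True)
    arrays = {f"mask_{i}": m.mask for i, m in enumerate(masks)}
    for i, m in enumerate(masks):
        if m.salience is not None:
            arrays[f"salience_{i}"] = m.salience
    np.savez(d / f"step_{step:06d}.npz", **arrays)


def _save_run_checkpoint(student, opt, rngs, step, path):
    rng_states = {name: rng.bit_generator.state for name, rng in rngs.items()}
    extra = {f"opt/{k}": v for k, v in opt.state_dict().items()}
    extra["step"] = step
    extra["rng_states"] = json.dumps(rng_states)
    save_checkpoint(student, path, extra=extra)


def _load_resume(student, opt, path):
    from .model import _read_checkpoint
    meta, arrays = _read_checkpoint(path)
    if meta["config_hash"] != student.config.config_hash():
        raise ConfigurationError("resume checkpoint does not match the student config")
    student.load_state_dict({k[len("param/"):]: v for k, v in arrays.items()
                             if k.startswith("param/")})
    opt.load_state_dict({k[len("extra/opt/"):]: v for k, v in arrays.items()
                         if k.startswith("extra/opt/")})
    return meta, arrays


# ---------------------------------------------------------------------------
# Visualization
# ---------------------------------------------------------------------------

def visualize_masks(checkpoint: str, corpus_dir: str, step: int, out_dir: str,
                    max_steps: int = 1000, seed: int = 0,
                    teacher_checkpoint: Optional[str] = None) -> list:
    """Write one PNG panel per corpus sample: original image, random mask,
    attention-guided mask, and the salience heat map at the given step."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not 0 <= step <= max_steps:
        raise ValueError(f"step must lie in [0, {max_steps}]")
    student = load_checkpoint(checkpoint)
    teacher = load_checkpoint(teacher_checkpoint) if teacher_checkpoint else None
    corpus = Corpus(corpus_dir)
    cfg = student.config
    schedule = masking.MaskSchedule(max_steps=max_steps)
    rng = np.random.default_rng(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for i in range(len(corpus)):
        images, token_ids = corpus.batch([i], cfg.max_text_len)
        guided = masking.compute_guided_mask_for_batch(
            teacher, student, images, token_ids, step, schedule, rng)[0]
        rand = masking.random_patch_mask(cfg.num_patches, rng=rng)
        img = images[0, :, :, 0]
        fig, axes = plt.subplots(1, 4, figsize=(10, 3))
        axes[0].imshow(img, cmap="gray", vmin=0, vmax=1)
        axes[0].set_title("image")
        for ax, m, title in ((axes[1], rand, "random mask"),
                             (axes[2], guided, "guided mask")):
            ax.imshow(_overlay(img, m.mask, cfg.patch_size), vmin=0, vmax=1)
            ax.set_title(title)
        sal = guided.salience.reshape(cfg.grid_size, cfg.grid_size)
        axes[3].imshow(sal, cmap="magma")
        axes[3].set_title(f"salience (r={schedule_value(step, schedule):.2f})")
        for ax in axes:
            ax.axis("off")
        path = out / f"panel_{i:05d}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(str(path))
    return written


def _overlay(img: np.ndarray, mask: np.ndarray, patch_size: int) -> np.ndarray:
    g = int(np.sqrt(mask.size))
    grid = mask.reshape(g, g).astype(float)
    up = np.kron(grid, np.ones((patch_size, patch_size)))
    rgb = np.stack([img] * 3, axis=-1)
    rgb[..., 0] = np.where(up > 0, 0.7 * rgb[..., 0] + 0.3, rgb[..., 0])
    rgb[..., 1] = np.where(up > 0, 0.4 * rgb[..., 1], rgb[..., 1])
    rgb[..., 2] = np.where(up > 0, 0.4 * rgb[..., 2], rgb[..., 2])
    return np.clip(rgb, 0, 1)


# ---------------------------------------------------------------------------
# Efficiency report
# ---------------------------------------------------------------------------

def report_efficiency(preset_names, measure_time: bool = False,
                      seed: int = 0) -> list:
    """Parameter totals (and optional measured step times, which are
    hardware-dependent and informational only) for the given presets."""
    rows = []
    base_params = None
    for name in preset_names:
        model = build_model(name, seed=seed)
        total = count_parameters(model)
        row = {"preset": name, "total_params": total,
               "breakdown": parameter_breakdown(model)}
        if base_params is None:
            base_params = total
        row["param_ratio_vs_first"] = base_params / total
        if measure_time:
            cfg = model.config
            images = np.zeros((1, cfg.image_size, cfg.image_size,
                               cfg.image_channels), dtype=np.float32)
            ids = np.zeros((1, cfg.max_text_len), dtype=np.int64)
            t0 = time.perf_counter()
            forward_with_records(model, images, ids, trainable=False)
            row["forward_seconds"] = time.perf_counter() - t0
            row["timing_note"] = "hardware-dependent, informational"
        rows.append(row)
        del model
    return rows
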