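"""Training orchestration: single-run multitask optimization, per-task
best-checkpoint saving, fold evaluation, cross-validation and prediction.

The network is trained **once** for all four tasks: every optimization step
minimizes the unweighted sum of the four per-task cross entropies.  After
each epoch the per-task validation mean DSC is computed (forward, argmax
decode, score against truth) and, under the ``per_task_best`` policy, a
task's checkpoint is overwritten whenever its validation DSC strictly
improves — so all per-task checkpoints originate from the same optimization
trajectory and share one history id.  The ``single_best_total`` policy keeps
instead the single model with the lowest epoch training loss.

Checkpoints are ``.npz`` archives bundling every weight and batch-norm
statistic with the full model configuration and best-metric metadata, so
evaluation and prediction need no side information.
"""

from __future__ import annotations

import glob
import json
import logging
import os
from dataclasses import dataclass, field, replace, asdict

import imageio.v3 as iio
import numpy as np

from .autodiff import Adam
from .codec import TASK_NAMES, decode_probability, to_multitask_targets, union_mask
from .data import AugmentConfig, CaseRecord, FoldSplit, epoch_stream, load_case, resize_case
from .model import MDUNet, ModelConfig, build_model, desk_config
from .objectives import MetricsTable, aggregate, score_pair, task_loss, total_loss
from .phantom import derive_case_seed

__all__ = [
    "TrainConfig", "RunArtifacts", "train", "evaluate", "cross_validate",
    "predict", "save_checkpoint", "load_checkpoint", "list_case_ids",
]

logger = logging.getLogger("mdunet")

CHECKPOINT_POLICIES = ("per_task_best", "single_best_total")


@dataclass(frozen=True)
class TrainConfig:
    model: ModelConfig = field(default_factory=desk_config)
    aug: AugmentConfig = field(default_factory=AugmentConfig)
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer_name: str = "adam"
    seed: int = 0
    checkpoint_policy: str = "per_task_best"

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.optimizer_name != "adam":
            raise ValueError(f"unknown optimizer '{self.optimizer_name}' (only 'adam' is built in)")
        if self.checkpoint_policy not in CHECKPOINT_POLICIES:
            raise ValueError(f"checkpoint_policy must be one of {CHECKPOINT_POLICIES}")


@dataclass
class RunArtifacts:
    checkpoints: dict
    history: list
    history_id: str
    out_dir: str
    log_path: str


def _setup_run_logging(out_dir):
    os.makedirs(out_dir, exist_ok=True)
    log_path = os.path.join(out_dir, "train.log")
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler)
               and not isinstance(h, logging.FileHandler) for h in logger.handlers):
        stream = logging.StreamHandler()
        stream.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(stream)
    logger.setLevel(logging.INFO)
    return log_path, handler


def _case_target_arrays(rec) -> dict:
    """Encoded (2, H, W) float targets per task for one (possibly augmented) case."""
    t = to_multitask_targets(rec.clavicle_mask, rec.anterior_mask, rec.posterior_mask)
    return {name: enc.astype(np.float32)
            for name, enc in zip(TASK_NAMES, t.as_list())}


def _task_truth(rec, task):
    if task == "all_bones":
        return union_mask(rec.clavicle_mask, rec.anterior_mask, rec.posterior_mask)
    return getattr(rec, f"{task}_mask")


def _load_fold_cases(data_dir, ids, size):
    return [resize_case(load_case(data_dir, cid), size) for cid in ids]


def _validation_dsc(model: MDUNet, val_cases, batch_size) -> dict:
    task_names = model.task_names
    sums = {t: 0.0 for t in task_names}
    for start in range(0, len(val_cases), batch_size):
        chunk = val_cases[start : start + batch_size]
        images = np.stack([c.image for c in chunk])[:, None, :, :]
        probs = model.predict_probs(images)
        for t_idx, task in enumerate(task_names):
            for b_idx, rec in enumerate(chunk):
                pred = decode_probability(probs[t_idx][b_idx])
                sums[task] += score_pair(pred, _task_truth(rec, task)).dsc
    return {t: sums[t] / len(val_cases) for t in task_names}


def save_checkpoint(path, model: MDUNet, meta: dict):
    payload = {f"param::{k}": v for k, v in model.state_dict().items()}
    meta = dict(meta)
    meta["model_config"] = asdict(model.config)
    payload["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path, seed: int = 0):
    archive = np.load(path)
    meta = json.loads(bytes(archive["meta_json"]).decode())
    cfg_dict = dict(meta["model_config"])
    cfg_dict["block_lengths"] = tuple(cfg_dict["block_lengths"])
    if cfg_dict.get("fa_channels") is not None:
        cfg_dict["fa_channels"] = tuple(cfg_dict["fa_channels"])
    config = ModelConfig(**cfg_dict)
    model = build_model(config, seed=seed)
    state = {k[len("param::"):]: archive[k] for k in archive.files if k.startswith("param::")}
    model.load_state_dict(state)
    return model, meta


def train(data_dir, fold: FoldSplit, cfg: TrainConfig, out_dir) -> RunArtifacts:
    """One multitask optimization run over a fold's training cases."""
    log_path, handler = _setup_run_logging(out_dir)
    try:
        return _train_impl(data_dir, fold, cfg, out_dir, log_path)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _train_impl(data_dir, fold, cfg, out_dir, log_path):
    size = cfg.model.input_size
    missing = [cid for cid in (*fold.train_ids, *fold.val_ids)
               if not os.path.exists(os.path.join(data_dir, f"{cid}_image.png"))]
    if missing:
        raise FileNotFoundError(f"cases not found in {data_dir}: {missing[:5]}")
    train_cases = _load_fold_cases(data_dir, fold.train_ids, size)
    val_cases = _load_fold_cases(data_dir, fold.val_ids, size)

    model = build_model(cfg.model, seed=cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.learning_rate)
    aug = replace(cfg.aug, seed=derive_case_seed(cfg.seed, 1_000_003))
    task_names = model.task_names
    history_id = f"{cfg.seed:08x}-fold{fold.fold_index}"
    logger.info("training run %s: %d train / %d val cases, %d epochs, batch %d",
                history_id, len(train_cases), len(val_cases), cfg.epochs, cfg.batch_size)

    best_dsc = {t: -1.0 for t in task_names}
    best_total = np.inf
    checkpoints: dict = {}
    history = []

    for epoch in range(1, cfg.epochs + 1):
        samples = list(epoch_stream(train_cases, aug, epoch))
        order = np.random.default_rng(
            np.random.PCG64(derive_case_seed(cfg.seed, 2_000_003 + epoch))).permutation(len(samples))
        samples = [samples[i] for i in order]

        batch_totals, task_sums = [], {t: 0.0 for t in task_names}
        n_batches = 0
        for start in range(0, len(samples), cfg.batch_size):
            chunk = samples[start : start + cfg.batch_size]
            images = np.stack([s.image for s in chunk])[:, None, :, :]
            targets = [np.stack([_case_target_arrays(s)[t] for s in chunk])
                       for t in task_names]
            preds = model.forward(images, training=True)
            losses = [task_loss(p, y) for p, y in zip(preds, targets)]
            loss = total_loss(losses) if len(losses) == len(TASK_NAMES) \
                else _sum_tensors(losses)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite total loss {loss.data!r} at epoch {epoch}, "
                    f"batch {n_batches}; aborting")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            batch_totals.append(float(loss.data))
            for t, l in zip(task_names, losses):
                task_sums[t] += float(l.data)
            n_batches += 1

        epoch_total = float(np.mean(batch_totals))
        epoch_tasks = {t: task_sums[t] / n_batches for t in task_names}
        val_dsc = _validation_dsc(model, val_cases, cfg.batch_size)
        history.append({"epoch": epoch, "total_loss": epoch_total,
                        "task_losses": epoch_tasks, "val_dsc": val_dsc})
        logger.info("epoch %d/%d total_loss=%.4f val_dsc=%s", epoch, cfg.epochs, epoch_total,
                    {t: round(v, 4) for t, v in val_dsc.items()})

        if cfg.checkpoint_policy == "per_task_best":
            for t in task_names:
                if val_dsc[t] > best_dsc[t]:
                    best_dsc[t] = val_dsc[t]
                    path = os.path.join(out_dir, f"ckpt_{t}.npz")
                    save_checkpoint(path, model, {
                        "task": t, "epoch": epoch, "best_val_dsc": val_dsc[t],
                        "history_id": history_id})
                    checkpoints[t] = path
        else:
            if epoch_total < best_total:
                best_total = epoch_total
                path = os.path.join(out_dir, "ckpt_best_total.npz")
                save_checkpoint(path, model, {
                    "task": None, "epoch": epoch, "best_total_loss": epoch_total,
                    "history_id": history_id})
                checkpoints["best_total"] = path

    with open(os.path.join(out_dir, "history.json"), "w") as fh:
        json.dump({"history_id": history_id, "epochs": history}, fh, indent=1)
    return RunArtifacts(checkpoints=checkpoints, history=history,
                        history_id=history_id, out_dir=out_dir, log_path=log_path)


def _sum_tensors(losses):
    from .autodiff import add
    acc = losses[0]
    for l in losses[1:]:
        acc = add(acc, l)
    return acc


def _resolve_checkpoints(checkpoints):
    """Accept RunArtifacts, a dict, a directory, or a single checkpoint path."""
    if isinstance(checkpoints, RunArtifacts):
        return dict(checkpoints.checkpoints)
    if isinstance(checkpoints, dict):
        return dict(checkpoints)
    path = str(checkpoints)
    if os.path.isdir(path):
        found = {}
        for t in TASK_NAMES:
            p = os.path.join(path, f"ckpt_{t}.npz")
            if os.path.exists(p):
                found[t] = p
        single = os.path.join(path, "ckpt_best_total.npz")
        if os.path.exists(single):
            found["best_total"] = single
        if not found:
            raise FileNotFoundError(f"no checkpoints found in {path}")
        return found
    return {"best_total": path}


def evaluate(checkpoints, fold: FoldSplit, data_dir, out_csv=None, batch_size=8) -> MetricsTable:
    """Score checkpoints on a fold's test cases, one row per (case, task).

    Per-task checkpoints evaluate their own task; a single checkpoint
    evaluates all tasks.
    """
    ckpts = _resolve_checkpoints(checkpoints)
    rows = []
    per_task = {t: p for t, p in ckpts.items() if t in TASK_NAMES}
    if per_task:
        plan = [(load_checkpoint(p)[0], [t]) for t, p in per_task.items()]
    else:
        model, _ = load_checkpoint(ckpts["best_total"])
        plan = [(model, list(model.task_names))]
    test_cases = None
    for model, tasks in plan:
        size = model.config.input_size
        if test_cases is None or test_cases[0].image.shape != (size, size):
            test_cases = _load_fold_cases(data_dir, fold.test_ids, size)
        for start in range(0, len(test_cases), batch_size):
            chunk = test_cases[start : start + batch_size]
            images = np.stack([c.image for c in chunk])[:, None, :, :]
            probs = model.predict_probs(images)
            for task in tasks:
                t_idx = model.task_names.index(task)
                for b_idx, rec in enumerate(chunk):
                    pred = decode_probability(probs[t_idx][b_idx])
                    rows.append((rec.id, task, score_pair(pred, _task_truth(rec, task))))
    table = aggregate(rows)
    if out_csv:
        table.to_csv(out_csv)
    return table


def list_case_ids(data_dir):
    ids = sorted(os.path.basename(p)[: -len("_image.png")]
                 for p in glob.glob(os.path.join(data_dir, "*_image.png")))
    if not ids:
        raise FileNotFoundError(f"no cases found in {data_dir}")
    return ids


def cross_validate(data_dir, cfg: TrainConfig, seed: int, out_dir):
    """Fourfold cross-validation: train + evaluate per fold, pool all test rows.

    Returns ``(fold_tables, pooled_table, folds)``; the pooled table covers
    every case exactly once per task (the four test sets partition the ids).
    """
    from .data import fourfold_split, write_fold_manifests

    ids = list_case_ids(data_dir)
    folds = fourfold_split(ids, seed)
    os.makedirs(out_dir, exist_ok=True)
    write_fold_manifests(folds, out_dir)
    tables = []
    pooled_rows = []
    for fold in folds:
        fold_dir = os.path.join(out_dir, f"fold_{fold.fold_index}")
        run_cfg = replace(cfg, seed=derive_case_seed(seed, fold.fold_index) % (2 ** 31))
        artifacts = train(data_dir, fold, run_cfg, fold_dir)
        table = evaluate(artifacts, fold, data_dir,
                         out_csv=os.path.join(fold_dir, "metrics.csv"))
        tables.append(table)
        for _, row in table.rows.iterrows():
            pooled_rows.append((row["case"], row["task"], _row_scores(row)))
    pooled = aggregate(pooled_rows)
    pooled.to_csv(os.path.join(out_dir, "pooled_metrics.csv"))
    return tables, pooled, folds


def _row_scores(row):
    from .objectives import SegScores
    return SegScores(tp=0, fp=0, fn=0, dsc=row["dsc"], precision=row["precision"],
                     recall=row["recall"], jaccard=row["jaccard"])


def predict(checkpoint, image_file, out_dir, save_probabilities=False) -> dict:
    """Segment one image file with a checkpoint; write one mask PNG per task.

    Also reports how many pixels disagree between the predicted all-bones
    mask and the OR of the three structure predictions — the heads are
    independent, so the two need not coincide.
    """
    model, meta = load_checkpoint(checkpoint)
    try:
        raw = np.asarray(iio.imread(image_file), dtype=np.float32)
    except Exception as exc:
        raise IOError(f"cannot read image {image_file}: {exc}") from exc
    if raw.ndim == 3:
        raw = raw.mean(axis=2)
    image = raw / 255.0 if raw.max() > 1.0 else raw
    size = model.config.input_size
    if image.shape != (size, size):
        from skimage.transform import resize as _resize
        image = _resize(image, (size, size), order=1, anti_aliasing=True,
                        preserve_range=True).astype(np.float32)
    probs = model.predict_probs(image[None, None, :, :])
    os.makedirs(out_dir, exist_ok=True)
    stem = os.path.splitext(os.path.basename(str(image_file)))[0]
    masks, paths = {}, {}
    for t_idx, task in enumerate(model.task_names):
        mask = decode_probability(probs[t_idx][0])
        masks[task] = mask
        p = os.path.join(out_dir, f"{stem}_{task}_pred.png")
        iio.imwrite(p, (mask * 255).astype(np.uint8))
        paths[task] = p
    result = {"mask_paths": paths}
    if set(TASK_NAMES) <= set(masks):
        union = union_mask(masks["clavicle"], masks["anterior"], masks["posterior"])
        result["all_bones_vs_union_disagreement"] = int(
            np.count_nonzero(masks["all_bones"] != union))
    if save_probabilities:
        prob_path = os.path.join(out_dir, f"{stem}_probabilities.npz")
        np.savez(prob_path, **{t: probs[i] for i, t in enumerate(model.task_names)})
        result["probabilities_path"] = prob_path
    return result
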