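"""End-to-end orchestration: training, evaluation, prediction, ablation.

Checkpoints are self-describing ``.npz`` files embedding the full model and
preprocessing configuration, so evaluation never needs the original config
file. All randomness flows from a single seed.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .arch import ModelConfig, UNet, build_model
from .loss import DiceLossSpec, dice_loss_tensor
from .metrics import MetricsReport, evaluate_model
from .nn import Adam, SGD, Tensor
from .phantom import PhantomPair, PhantomSpec, generate_dataset
from .preprocess import AugmentationSpec, WindowSpec, apply_window, augment_pair
from .stats import compare_reports

__all__ = ["TrainConfig", "TrainResult", "run_training", "run_evaluation",
           "run_ablation", "save_checkpoint", "load_checkpoint", "prepare_inputs"]


@dataclass
class TrainConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: DiceLossSpec = field(default_factory=DiceLossSpec)
    window: WindowSpec = field(default_factory=WindowSpec)
    augmentation: AugmentationSpec | None = field(default_factory=AugmentationSpec)
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 50
    early_stopping_patience: int = 10
    seed: int = 0
    # data: either a phantom recipe (n_phantoms + base spec + jitter) ...
    n_phantoms: int = 200
    phantom_base: PhantomSpec = field(default_factory=PhantomSpec)
    phantom_jitter: dict = field(default_factory=dict)
    # ... or a directory of paired images/masks
    data_dir: str | None = None

    def validate(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.data_dir is None and self.n_phantoms < 3:
            raise ValueError("n_phantoms must be >= 3")


@dataclass
class TrainResult:
    model: UNet
    history: list[dict]
    checkpoint_path: Path | None
    best_val_dice: float


def prepare_inputs(pairs: list[PhantomPair], window: WindowSpec) -> tuple[np.ndarray, np.ndarray]:
    """Window-normalize HU images and stack into (N, 1, H, W) float32 arrays."""
    imgs = np.stack([apply_window(p.image, window) for p in pairs]).astype(np.float32)
    masks = np.stack([p.mask for p in pairs]).astype(np.float32)
    return imgs[:, None], masks[:, None]


def _soft_dice_score(gt: np.ndarray, prob: np.ndarray) -> float:
    """Mean hard-threshold Dice over a batch (monitoring only)."""
    scores = []
    for g, p in zip(gt, prob):
        pb = (p >= 0.5)
        gb = g > 0.5
        denom = gb.sum() + pb.sum()
        scores.append(2.0 * np.logical_and(gb, pb).sum() / denom if denom else 1.0)
    return float(np.mean(scores))


def _load_dataset(cfg: TrainConfig) -> tuple[list[PhantomPair], list[str]]:
    if cfg.data_dir is not None:
        from .phantom import load_pair

        data_dir = Path(cfg.data_dir)
        stems = sorted(p.name[:-len("_spec.json")] for p in data_dir.glob("*_spec.json"))
        if not stems:
            raise FileNotFoundError(f"no phantom pairs found in {data_dir}")
        fmt = "png" if (data_dir / f"{stems[0]}_image.png").exists() else "nifti"
        pairs = [load_pair(data_dir, s, fmt=fmt) for s in stems]
        from .phantom import split_sizes

        n_train, n_val, n_test = split_sizes(len(pairs))
        rng = np.random.default_rng(cfg.seed)
        order = rng.permutation(len(pairs))
        labels = [""] * len(pairs)
        tags = ["train"] * n_train + ["val"] * n_val + ["test"] * n_test
        for pos, idx in enumerate(order):
            labels[idx] = tags[pos]
        return pairs, labels
    return generate_dataset(cfg.n_phantoms, cfg.phantom_base, cfg.phantom_jitter,
                            seed=cfg.seed)


def run_training(cfg: TrainConfig, out_dir: str | Path | None = None,
                 log_fn=None) -> TrainResult:
    """Train a model per config; returns history and (optionally) a checkpoint."""
    cfg.validate()
    log = log_fn or (lambda msg: None)
    rng = np.random.default_rng(cfg.seed)

    pairs, labels = _load_dataset(cfg)
    train_pairs = [p for p, l in zip(pairs, labels) if l == "train"]
    val_pairs = [p for p, l in zip(pairs, labels) if l == "val"]
    x_val, y_val = prepare_inputs(val_pairs, cfg.window)

    model = build_model(cfg.model, seed=cfg.seed)
    params = list(model.parameters())
    if cfg.optimizer == "adam":
        opt = Adam(params, lr=cfg.learning_rate)
    else:
        opt = SGD(params, lr=cfg.learning_rate)

    fill = 0.0  # images are window-normalized; 0 is the minimum window value
    history: list[dict] = []
    best_val = -np.inf
    best_state: list[np.ndarray] | None = None
    patience_left = cfg.early_stopping_patience

    n_train = len(train_pairs)
    for epoch in range(cfg.epochs):
        t0 = time.time()
        model.train()
        order = rng.permutation(n_train)
        epoch_losses = []
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch_imgs, batch_masks = [], []
            for i in idx:
                img = apply_window(train_pairs[i].image, cfg.window)
                mask = train_pairs[i].mask
                if cfg.augmentation is not None and not cfg.augmentation.is_identity:
                    img, mask = augment_pair(img, mask, cfg.augmentation,
                                             rng=rng, fill_value=fill)
                    img = np.clip(img, 0.0, 1.0)
                batch_imgs.append(img)
                batch_masks.append(mask)
            xb = np.stack(batch_imgs).astype(np.float32)[:, None]
            yb = np.stack(batch_masks).astype(np.float32)[:, None]

            model.zero_grad()
            probs = model(Tensor(xb))
            loss = dice_loss_tensor(yb, probs, cfg.loss)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.item()}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())

        model.eval()
        if len(val_pairs):
            val_prob = model(Tensor(x_val)).data[:, 0]
            val_dice = _soft_dice_score(y_val[:, 0], val_prob)
        else:
            val_dice = float("nan")
        record = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                  "val_dice": val_dice, "seconds": time.time() - t0}
        history.append(record)
        log(json.dumps(record))

        if len(val_pairs) and val_dice > best_val:
            best_val = val_dice
            best_state = [a.copy() for a in model.state_arrays()]
            patience_left = cfg.early_stopping_patience
        elif len(val_pairs):
            patience_left -= 1
            if patience_left <= 0:
                log(json.dumps({"early_stop": epoch}))
                break

    if best_state is not None:
        model.load_state_arrays(best_state)

    ckpt_path = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ckpt_path = out_dir / "checkpoint.npz"
        save_checkpoint(model, cfg, ckpt_path)
        with open(out_dir / "history.jsonl", "w") as fh:
            for rec in history:
                fh.write(json.dumps(rec) + "\n")
    return TrainResult(model=model, history=history, checkpoint_path=ckpt_path,
                       best_val_dice=float(best_val) if best_state is not None else float("nan"))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: UNet, cfg: TrainConfig, path: str | Path) -> None:
    arrays = {f"arr_{i}": a for i, a in enumerate(model.state_arrays())}
    meta = {
        "model": model.config.to_dict(),
        "window": dataclasses.asdict(cfg.window),
        "loss": dataclasses.asdict(cfg.loss),
        "seed": cfg.seed,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> tuple[UNet, WindowSpec, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = [data[f"arr_{i}"] for i in range(len(data.files) - 1)]
    model = build_model(ModelConfig.from_dict(meta["model"]), seed=meta.get("seed", 0))
    model.load_state_arrays(arrays)
    model.eval()
    window = WindowSpec(**meta["window"])
    return model, window, meta


# ---------------------------------------------------------------------------
# evaluation / ablation
# ---------------------------------------------------------------------------

def run_evaluation(model: UNet, pairs: list[PhantomPair], window: WindowSpec,
                   label: str = "model", threshold: float | None = None,
                   batch_size: int = 8) -> MetricsReport:
    """Predict on every pair with training-identical preprocessing and score."""
    if not pairs:
        raise ValueError("no pairs to evaluate")
    model.eval()
    preds = []
    imgs, _ = prepare_inputs(pairs, window)
    thr = threshold if threshold is not None else model.config.output_threshold
    for start in range(0, len(pairs), batch_size):
        chunk = imgs[start:start + batch_size]
        prob = model(Tensor(chunk)).data[:, 0]
        preds.extend((prob >= thr).astype(np.uint8))
    gt_pred = [(p.mask, pred) for p, pred in zip(pairs, preds)]
    return evaluate_model(gt_pred, label=label)


def run_ablation(base_cfg: TrainConfig,
                 versions=("V1", "V2"),
                 attentions=("sSE", "MSSA"),
                 n_msa_values=(1, 2, 3, 4),
                 out_dir: str | Path | None = None,
                 log_fn=None) -> tuple[dict, "object"]:
    """Train/evaluate a grid of configs on one shared seeded dataset.

    Returns (reports, stats_frame): one MetricsReport per grid cell (keyed
    ``{version}_{attention}_n{n}``) and an ANOVA/LSD comparison per metric.
    Cell failures are recorded and the grid continues.
    """
    log = log_fn or (lambda msg: None)
    pairs, labels = _load_dataset(base_cfg)
    test_pairs = [p for p, l in zip(pairs, labels) if l == "test"]

    reports: dict[str, MetricsReport] = {}
    failures: dict[str, str] = {}
    for version in versions:
        for attention in attentions:
            for n in n_msa_values:
                key = f"{version}_{attention}_n{n}"
                try:
                    mc = dataclasses.replace(base_cfg.model, version=version,
                                             attention=attention, n_msa_blocks=n)
                    cfg = dataclasses.replace(base_cfg, model=mc)
                    result = run_training(cfg, out_dir=None, log_fn=log_fn)
                    reports[key] = run_evaluation(result.model, test_pairs,
                                                  cfg.window, label=key)
                    log(json.dumps({"cell": key, "done": True}))
                except Exception as exc:  # noqa: BLE001 - grid must continue
                    failures[key] = str(exc)
                    log(json.dumps({"cell": key, "error": str(exc)}))
    stats_frame = None
    if len(reports) >= 2:
        stats_frame = compare_reports(list(reports.values()))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for rep in reports.values():
            rep.save(out_dir)
        if stats_frame is not None:
            stats_frame.to_csv(out_dir / "ablation_stats.csv", index=False)
        if failures:
            with open(out_dir / "failures.json", "w") as fh:
                json.dump(failures, fh, indent=2)
    return reports, stats_frame
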