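"""Training, prediction and evaluation harness.

Defaults follow the published training recipe for this architecture: Adam
with learning rate 1e-4 and weight decay 1e-5, batch size 18, inputs resized
to 256x256.  Runs are fully seeded (model initialization, shuffling,
phantoms), losses are logged per epoch as line-delimited JSON, and the best
checkpoint (by validation Dice) is kept as a single ``.npz`` file holding
the flat parameter state plus the architecture/training configs.

Variant switches mirror the ablation grid: ``full`` is the complete model
with GFI skips and the hybrid Dice+BCE+SSIM loss; ``backbone`` removes both
(Dice-only loss); ``w_gfi`` restores only GFI; ``w_hloss`` restores only the
hybrid loss; ``mit_only`` / ``rcnn_only`` keep a single encoder branch.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .decoder import RMTFNet, RMTFNetConfig
from .losses import LossWeights, SSIMParams, dice_loss, hybrid_loss
from .metrics import MetricReport, dice_iou, evaluate_dataset
from .nn import Adam
from .synthetic import load_pairs

__all__ = [
    "TrainConfig", "TrainResult", "train", "predict", "evaluate",
    "save_checkpoint", "load_checkpoint",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 1e-5
    batch_size: int = 18
    epochs: int = 30
    seed: int = 0
    variant: str = "full"
    mit_variant: str = "B"
    width_divisor: int = 1
    depths: tuple[int, ...] | None = None
    rcnn_channels: tuple[int, int, int, int] = (64, 128, 256, 512)
    decoder_channels: tuple[int, int, int, int] = (256, 128, 64, 32)
    loss_alpha: float = 1.0
    loss_beta: float = 1.0
    loss_gamma: float = 1.0
    ssim_window: int = 11
    ssim_sigma: float = 1.5
    max_steps: int | None = None
    val_fraction: float = 0.2
    target_size: int = 256

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    def net_config(self) -> RMTFNetConfig:
        return RMTFNetConfig(
            variant=self.variant, mit_variant=self.mit_variant,
            width_divisor=self.width_divisor, depths=self.depths,
            rcnn_channels=tuple(self.rcnn_channels),
            decoder_channels=tuple(self.decoder_channels))

    def loss_weights(self) -> LossWeights:
        if self.net_config().use_hybrid_loss:
            return LossWeights(self.loss_alpha, self.loss_beta, self.loss_gamma)
        return LossWeights(self.loss_alpha, 0.0, 0.0)   # Dice-only ablation

    def ssim_params(self) -> SSIMParams:
        return SSIMParams(self.ssim_window, self.ssim_sigma)

    @classmethod
    def tiny(cls, variant: str = "full", **overrides) -> "TrainConfig":
        base = dict(variant=variant, width_divisor=8, depths=(1, 1, 1, 1),
                    rcnn_channels=(8, 16, 32, 64),
                    decoder_channels=(32, 16, 8, 4),
                    batch_size=4, epochs=30, target_size=64,
                    learning_rate=1e-3)   # scaled-down problem, larger step
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainResult:
    model: RMTFNet
    log: list
    best_val_dice: float
    checkpoint_path: str | None = None

    @property
    def losses(self) -> list[float]:
        return [rec["mean_loss"] for rec in self.log]


# ------------------------------------------------------------- checkpoints
def save_checkpoint(path, model: RMTFNet, train_cfg: TrainConfig) -> None:
    meta = {"net": {**asdict(model.cfg)}, "train": asdict(train_cfg)}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **model.state_dict())


def load_checkpoint(path) -> tuple[RMTFNet, TrainConfig]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    net_meta = meta["net"]
    for key in ("depths", "rcnn_channels", "decoder_channels"):
        if net_meta.get(key) is not None:
            net_meta[key] = tuple(net_meta[key])
    net_cfg = RMTFNetConfig(**net_meta)
    tmeta = meta["train"]
    for key in ("depths", "rcnn_channels", "decoder_channels"):
        if tmeta.get(key) is not None:
            tmeta[key] = tuple(tmeta[key])
    train_cfg = TrainConfig(**tmeta)
    model = RMTFNet(net_cfg, rng=np.random.default_rng(0))
    model.load_state_dict(state)
    model.eval()
    return model, train_cfg


# ---------------------------------------------------------------- training
def _batch_loss(model: RMTFNet, images, masks, weights, ssim_params):
    logits = model(images)
    probs = logits.sigmoid()
    if weights.beta == 0 and weights.gamma == 0:
        return dice_loss(probs, masks) * weights.alpha
    return hybrid_loss(probs, masks, weights, ssim_params)


def train(cfg: TrainConfig, data_dir=None, images=None, masks=None,
          out_dir=None, log_every: int = 0) -> TrainResult:
    """Train a network; supply either ``data_dir`` (PNG pairs) or arrays.

    Raises on an empty dataset and aborts with a diagnostic if the loss goes
    non-finite.  Returns the model restored to its best-validation state.
    """
    if images is None:
        if data_dir is None:
            raise ValueError("provide data_dir or in-memory images/masks")
        images, masks, _ = load_pairs(data_dir, target_size=cfg.target_size)
    images = np.asarray(images, dtype=np.float64)
    masks = np.asarray(masks, dtype=np.float64)
    n = images.shape[0]
    if n == 0:
        raise ValueError("empty dataset")

    rng = np.random.default_rng(cfg.seed)
    model = RMTFNet(cfg.net_config(), rng=rng)
    opt = Adam(model.parameters(), lr=cfg.learning_rate,
               weight_decay=cfg.weight_decay)
    weights = cfg.loss_weights()
    ssim_params = cfg.ssim_params()

    n_val = int(round(cfg.val_fraction * n))
    order = rng.permutation(n)
    val_idx, train_idx = order[:n_val], order[n_val:]
    if train_idx.size == 0:
        train_idx, val_idx = order, order

    log: list[dict] = []
    best_dice = -1.0
    best_state = None
    step = 0
    stop = False
    for epoch in range(cfg.epochs):
        model.train()
        perm = rng.permutation(train_idx)
        epoch_losses = []
        for start in range(0, perm.size, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            loss = _batch_loss(model, images[idx], masks[idx],
                               weights, ssim_params)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at step {step} (epoch {epoch}): "
                    f"{loss.data!r}")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                stop = True
                break

        model.eval()
        val_dices = []
        for i in val_idx:
            pred = model.predict_mask(images[i:i + 1])[0, 0]
            d, _ = dice_iou(pred, masks[i, 0])
            val_dices.append(d)
        rec = {
            "epoch": epoch, "step": step,
            "mean_loss": float(np.mean(epoch_losses)) if epoch_losses else None,
            "val_dice": float(np.mean(val_dices)) if val_dices else None,
        }
        log.append(rec)
        if log_every and epoch % log_every == 0:
            print(json.dumps(rec))
        if rec["val_dice"] is not None and rec["val_dice"] > best_dice:
            best_dice = rec["val_dice"]
            best_state = model.state_dict()
        if stop:
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()

    ckpt_path = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        ckpt_path = str(out / "checkpoint.npz")
        save_checkpoint(ckpt_path, model, cfg)
        with open(out / "train_log.jsonl", "w") as fh:
            for rec in log:
                fh.write(json.dumps(rec) + "\n")
    return TrainResult(model=model, log=log, best_val_dice=best_dice,
                       checkpoint_path=ckpt_path)


# --------------------------------------------------------------- inference
def predict(model_or_ckpt, images) -> np.ndarray:
    """Binary masks (N,1,H,W uint8) for a batch of images."""
    if isinstance(model_or_ckpt, (str, Path)):
        model, _ = load_checkpoint(model_or_ckpt)
    else:
        model = model_or_ckpt
    images = np.asarray(images, dtype=np.float64)
    if images.ndim == 3:
        images = images[None]
    return model.predict_mask(images)


def evaluate(model_or_ckpt, data_dir=None, images=None, masks=None,
             target_size: int = 256, report_path=None) -> MetricReport:
    """Predict over a dataset and compute the five-metric report."""
    if isinstance(model_or_ckpt, (str, Path)):
        model, tcfg = load_checkpoint(model_or_ckpt)
        target_size = tcfg.target_size
    else:
        model = model_or_ckpt
    if images is None:
        if data_dir is None:
            raise ValueError("provide data_dir or in-memory images/masks")
        images, masks, _ = load_pairs(data_dir, target_size=target_size)
    images = np.asarray(images, dtype=np.float64)
    masks = np.asarray(masks, dtype=np.float64)
    probs = [model.predict_proba(images[i:i + 1])[0, 0]
             for i in range(images.shape[0])]
    gts = [masks[i, 0] for i in range(masks.shape[0])]
    report = evaluate_dataset(probs, gts)
    if report_path is not None:
        report.to_json(report_path)
    return report
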