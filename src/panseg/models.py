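"""Per-class binary segmentation models: training recipe and inference.

One binary UNet is trained per ductal tissue class (normal acinar, ADM,
dysplasia).  The training set for a class combines 80% of the tiles in which
that class appears ("relevant" tiles, the positives) with a small fraction
(default 7.5%, the middle of the 5-10% range) of tiles of other tissue as
negative controls; the remaining 20% of relevant tiles are held out for
per-epoch validation and model selection.  Tiles are augmented on the fly
with flips, 90-degree rotations and small shears.  The default recipe is
50 epochs, batch size 32, learning rate 7e-4, Adam, binary cross-entropy.

Whole images are predicted tile-by-tile on a 50%-overlap grid and stitched
back with unweighted overlap averaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .tiling import plan_grid, stitch_mean
from .unet import UNet, Adam, build_unet

BCE_EPS = 1e-7
AUGMENTATIONS = ("flip_h", "flip_v", "rotate", "shear")


@dataclass(frozen=True)
class TrainingConfig:
    """Training hyper-parameters; defaults are the published recipe.

    ``model_scale``/``depth``/``input_size`` control the UNet size: the
    full-scale preset is 64 base channels, depth 4, 512-px tiles; the
    desk-scale preset (8 channels, depth 2, 64-px tiles) runs the identical
    code paths in minutes on one CPU.
    """

    epochs: int = 50
    batch_size: int = 32
    learning_rate: float = 7e-4
    optimizer: str = "adam"
    loss: str = "bce"
    relevant_fraction: float = 0.8
    other_fraction: float = 0.075
    augmentations: tuple = AUGMENTATIONS
    seed: int = 0
    model_scale: int = 8
    depth: int = 2
    input_size: int = 64
    selection: str = "bce"  # "bce" (lowest held-out BCE) or "dice"
    shear_max_deg: float = 10.0

    def __post_init__(self):
        if not (0 < self.relevant_fraction <= 1):
            raise ValueError("relevant_fraction must lie in (0, 1]")
        if not (0 <= self.other_fraction <= 1):
            raise ValueError("other_fraction must lie in [0, 1]")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.loss != "bce":
            raise ValueError("only binary cross entropy loss is supported")
        unknown = set(self.augmentations) - set(AUGMENTATIONS)
        if unknown:
            raise ValueError(f"unknown augmentations: {unknown}")


def full_scale_config(**overrides) -> TrainingConfig:
    return TrainingConfig(model_scale=64, depth=4, input_size=512, **overrides)


def desk_scale_config(**overrides) -> TrainingConfig:
    return TrainingConfig(model_scale=8, depth=2, input_size=64, **overrides)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def bce_loss(targets, predictions, eps: float = BCE_EPS) -> float:
    """Mean binary cross entropy, predictions clamped to [eps, 1 - eps]."""
    y = np.asarray(targets, np.float64)
    p = np.asarray(predictions, np.float64)
    if y.shape != p.shape:
        raise ValueError("targets and predictions must share a shape")
    if y.size == 0:
        raise ValueError("empty batch")
    p = np.clip(p, eps, 1.0 - eps)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


# ---------------------------------------------------------------------------
# training-set composition and augmentation
# ---------------------------------------------------------------------------


def compose_training_set(relevant_tiles, other_tiles, config: TrainingConfig):
    """Split tiles into (train, heldout) per the published composition rule.

    ``floor(relevant_fraction * n_relevant)`` relevant tiles train (the rest
    are held out) plus ``floor(other_fraction * n_other)`` other-tissue
    tiles as negative controls.  The shuffle is seeded.
    """
    relevant = list(relevant_tiles)
    other = list(other_tiles)
    if not relevant:
        raise ValueError("relevant tile list is empty")
    rng = np.random.default_rng(config.seed)
    ridx = rng.permutation(len(relevant))
    n_train = int(np.floor(config.relevant_fraction * len(relevant)))
    train = [relevant[i] for i in ridx[:n_train]]
    heldout = [relevant[i] for i in ridx[n_train:]]
    n_other = int(np.floor(config.other_fraction * len(other)))
    if n_other:
        oidx = rng.permutation(len(other))[:n_other]
        train.extend(other[i] for i in oidx)
    return train, heldout


def augment_tile(tile, mask, ops, rng, shear_max_deg: float = 10.0):
    """Apply one random geometric transform batch to a (tile, mask) pair.

    Flips fire independently with probability 1/2; rotation draws a random
    multiple of 90 degrees; shear draws an angle uniform in
    +-shear_max (degrees) about each axis, bilinear for the tile and
    nearest-neighbour for the mask so it stays binary.
    """
    ops = set(ops)
    unknown = ops - set(AUGMENTATIONS) - {"shear_max"}
    if unknown:
        raise ValueError(f"unknown augmentations: {unknown}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    tile = np.asarray(tile)
    mask = np.asarray(mask)
    if tile.shape[:2] != mask.shape[:2]:
        raise ValueError("tile and mask must share spatial shape")
    if "flip_h" in ops and rng.random() < 0.5:
        tile, mask = tile[:, ::-1], mask[:, ::-1]
    if "flip_v" in ops and rng.random() < 0.5:
        tile, mask = tile[::-1], mask[::-1]
    if "rotate" in ops:
        k = int(rng.integers(0, 4))
        tile, mask = np.rot90(tile, k, axes=(0, 1)), np.rot90(mask, k, axes=(0, 1))
    if "shear" in ops:
        deg = rng.uniform(-shear_max_deg, shear_max_deg)
        s = np.tan(np.radians(deg))
        h, w = mask.shape[:2]
        # shear about the tile centre so content stays in frame
        mat = np.array([[1.0, s], [0.0, 1.0]])
        offset = np.array([h / 2, w / 2]) - mat @ np.array([h / 2, w / 2])
        if tile.ndim == 3:
            tile = np.stack(
                [
                    ndimage.affine_transform(
                        tile[..., c], mat, offset=offset, order=1, mode="reflect"
                    )
                    for c in range(tile.shape[2])
                ],
                axis=-1,
            )
        else:
            tile = ndimage.affine_transform(tile, mat, offset=offset, order=1, mode="reflect")
        mask = ndimage.affine_transform(
            mask.astype(np.uint8), mat, offset=offset, order=0, mode="reflect"
        ).astype(mask.dtype)
    return np.ascontiguousarray(tile), np.ascontiguousarray(mask)


# ---------------------------------------------------------------------------
# tile extraction
# ---------------------------------------------------------------------------


def extract_class_tiles(
    image01: np.ndarray,
    truth: np.ndarray,
    class_code: int,
    tile_size: int = 64,
    stride: int = 32,
    min_class_fraction: float = 0.02,
):
    """Cut (tile, binary-mask) pairs and sort them into relevant vs other.

    A tile is *relevant* when at least ``min_class_fraction`` of its pixels
    carry the class; tiles with any cellular tissue but (almost) none of the
    class are *other* tiles; pure-background tiles are dropped.
    """
    grid = plan_grid(*truth.shape, tile_size=tile_size, stride=stride)
    relevant, other = [], []
    for img_t, tru_t in zip(grid.cut(image01), grid.cut(truth)):
        m = tru_t == class_code
        frac = m.mean()
        if frac >= min_class_fraction:
            relevant.append((np.ascontiguousarray(img_t), m))
        elif (tru_t != 0).any():
            other.append((np.ascontiguousarray(img_t), m))
    return relevant, other


# ---------------------------------------------------------------------------
# trained model container + training loop
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    class_name: str
    net: UNet
    config: TrainingConfig
    input_size: int
    log: pd.DataFrame | None = None
    best_epoch: int | None = None

    def predict_tiles(self, tiles: np.ndarray) -> np.ndarray:
        return self.net.predict_proba(tiles)

    def save(self, path):
        """Weights as .npz plus a JSON config sidecar."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        weights = self.net.get_weights()
        np.savez(path, **{f"w{i}": w for i, w in enumerate(weights)})
        meta = {
            "class_name": self.class_name,
            "config": asdict(self.config),
            "input_size": self.input_size,
            "best_epoch": self.best_epoch,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        if self.log is not None:
            self.log.to_csv(path.with_suffix(".log.csv"), index=False)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg_d = meta["config"]
        cfg_d["augmentations"] = tuple(cfg_d["augmentations"])
        config = TrainingConfig(**cfg_d)
        net = build_unet(config.model_scale, config.input_size, config.depth, config.seed)
        data = np.load(path.with_suffix(".npz"))
        net.set_weights([data[f"w{i}"] for i in range(len(data.files))])
        return cls(
            class_name=meta["class_name"],
            net=net,
            config=config,
            input_size=meta["input_size"],
            best_epoch=meta["best_epoch"],
        )


def _dice_binary(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = int(a.sum()), int(b.sum())
    if sa + sb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (sa + sb)


def _eval_tiles(net: UNet, tiles, batch: int):
    """(mean BCE, mean Dice at 0.5) over a list of (tile, mask) pairs."""
    losses, dices = [], []
    for i in range(0, len(tiles), batch):
        chunk = tiles[i : i + batch]
        x = np.stack([t for t, _ in chunk]).astype(np.float32)
        y = np.stack([m for _, m in chunk]).astype(np.float64)
        p = net.predict_proba(x)
        losses.append(bce_loss(y, p) * len(chunk))
        for pj, yj in zip(p, y):
            dices.append(_dice_binary(pj >= 0.5, yj >= 0.5))
    return sum(losses) / len(tiles), float(np.mean(dices))


def train_model(samples, config: TrainingConfig, class_name: str = "") -> TrainedModel:
    """Train one binary UNet on (tile, mask) pairs.

    ``samples`` may be a (train, heldout) tuple from compose_training_set or
    a flat list (then split internally).  Per-epoch train/held-out BCE and
    held-out Dice are logged; the returned model carries the weights of the
    epoch with the lowest held-out BCE (or highest Dice when
    ``config.selection == "dice"``).
    """
    if isinstance(samples, tuple) and len(samples) == 2:
        train, heldout = list(samples[0]), list(samples[1])
    else:
        train = list(samples)
        n = max(1, int(np.floor(config.relevant_fraction * len(train))))
        heldout = train[n:]
        train = train[:n]
    if not train:
        raise ValueError("no training tiles")
    all_masks = np.concatenate([m.ravel() for _, m in train])
    if all_masks.all() or not all_masks.any():
        import warnings

        warnings.warn(
            "training masks are single-class overall; the model can only "
            "learn a constant map",
            stacklevel=2,
        )

    rng = np.random.default_rng(config.seed)
    net = build_unet(config.model_scale, config.input_size, config.depth, config.seed)
    opt = Adam(net.params(), lr=config.learning_rate)
    eval_set = heldout if heldout else train
    rows = []
    best_key, best_weights, best_epoch = None, None, 0
    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        epoch_losses = []
        for i in range(0, len(order), config.batch_size):
            chunk = [train[j] for j in order[i : i + config.batch_size]]
            xs, ys = [], []
            for t, m in chunk:
                if config.augmentations:
                    t, m = augment_tile(
                        t, m, config.augmentations, rng, config.shear_max_deg
                    )
                xs.append(t)
                ys.append(m)
            x = np.stack(xs).astype(np.float32)
            y = np.stack(ys).astype(np.float64)
            z = net.forward(x, train=True).astype(np.float64)
            p = 1.0 / (1.0 + np.exp(-z))
            # stable BCE-with-logits value for the log
            loss = float(np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - y * z))
            net.backward(((p - y) / z.size).astype(np.float32))
            opt.step()
            epoch_losses.append(loss)
        val_bce, val_dice = _eval_tiles(net, eval_set, config.batch_size)
        rows.append(
            {
                "epoch": epoch,
                "train_bce": float(np.mean(epoch_losses)),
                "val_bce": val_bce,
                "val_dice": val_dice,
            }
        )
        key = -val_dice if config.selection == "dice" else val_bce
        if best_key is None or key < best_key:
            best_key, best_weights, best_epoch = key, net.get_weights(), epoch
    net.set_weights(best_weights)
    return TrainedModel(
        class_name=class_name,
        net=net,
        config=config,
        input_size=config.input_size,
        log=pd.DataFrame(rows),
        best_epoch=best_epoch,
    )


# ---------------------------------------------------------------------------
# whole-image inference
# ---------------------------------------------------------------------------


def predict_image(
    model: TrainedModel,
    image: np.ndarray,
    tile_size: int | None = None,
    stride: int | None = None,
    batch_size: int = 32,
) -> np.ndarray:
    """Tile an image, predict each tile, stitch by overlap averaging.

    ``image`` is HxWx3, either uint8 in [0, 255] or float in [0, 1], already
    normalized the same way the training tiles were.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an HxWx3 RGB image")
    if image.dtype != np.float32 and image.dtype != np.float64:
        image01 = image.astype(np.float32) / 255.0
    else:
        image01 = image.astype(np.float32)
    tile_size = tile_size or model.input_size
    stride = stride or tile_size // 2
    grid = plan_grid(*image01.shape[:2], tile_size=tile_size, stride=stride)
    t0 = grid.tiles[0]
    if t0.height != model.input_size or t0.width != model.input_size:
        raise ValueError(
            f"tile extent {t0.height}x{t0.width} does not match the model "
            f"input size {model.input_size}"
        )
    tiles = grid.cut(image01)
    preds = []
    for i in range(0, len(tiles), batch_size):
        x = np.stack(tiles[i : i + batch_size])
        preds.extend(model.net.predict_proba(x))
    return stitch_mean(grid, preds)
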