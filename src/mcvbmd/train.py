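"""Dataset splitting, training protocol and volume-level inference.

Training minimises the Dice loss with Adam (default hyperparameters); the
2-D network consumes individual slices (batch size 4, learning rate 1e-5 at
full scale), the 3-D network whole volumes (batch size 1, learning rate
1e-4).  Non-pretrained configurations are repeated with perturbed seeds and
the best run is kept, selected on validation Dice.  The 70/20/10 split
leaves remainder cases unassigned by default, matching a 541-case cohort
splitting into 378/108/54 with one case left over.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .core import BinaryMask
from .errors import ConfigurationError, LeakageError, ShapeError
from .models import UNet2D, UNet3D, dice_loss, dsc_binary
from .preprocess import NormalizationStats

__all__ = [
    "TrainConfig", "SplitResult", "split_dataset", "train_model",
    "predict_volume", "binarize",
]


@dataclass(frozen=True)
class TrainConfig:
    architecture: str = "2d"  # {"2d", "3d"}
    learning_rate: float | None = None  # default 1e-5 (2D) / 1e-4 (3D)
    batch_size: int | None = None  # default 4 (2D) / 1 (3D)
    epochs: int = 100
    patience: int = 15  # early stopping on validation Dice
    seed: int = 0
    n_repeats: int = 1
    split_fractions: tuple[float, float, float] = (0.70, 0.20, 0.10)
    remainder_policy: str = "unassigned"

    def resolved_lr(self) -> float:
        if self.learning_rate is not None:
            return self.learning_rate
        return 1e-5 if self.architecture == "2d" else 1e-4

    def resolved_batch_size(self) -> int:
        if self.batch_size is not None:
            return self.batch_size
        return 4 if self.architecture == "2d" else 1

    def validate(self) -> None:
        if self.architecture not in ("2d", "3d"):
            raise ConfigurationError("architecture must be '2d' or '3d'")
        if any(f < 0 for f in self.split_fractions) or sum(self.split_fractions) > 1 + 1e-9:
            raise ConfigurationError("split fractions must be >= 0 and sum <= 1")
        if self.resolved_batch_size() < 1:
            raise ConfigurationError("batch size must be >= 1")


@dataclass(frozen=True)
class SplitResult:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    leftover_ids: tuple[str, ...] = field(default_factory=tuple)


def split_dataset(case_ids, fractions=(0.70, 0.20, 0.10), seed: int = 0,
                  remainder_policy: str = "unassigned") -> SplitResult:
    """Shuffle and split case ids into train/val/test.

    Per-split counts are ``floor(fraction * N)``; the remainder is left
    unassigned by default (policy ``"unassigned"``) or appended to the
    training split (``"to_train"``).
    """
    case_ids = list(case_ids)
    if len(case_ids) < 3:
        raise ConfigurationError("need at least 3 cases to split")
    if any(f < 0 for f in fractions) or sum(fractions) > 1 + 1e-9:
        raise ConfigurationError("fractions must be >= 0 and sum <= 1")
    if remainder_policy not in ("unassigned", "to_train"):
        raise ConfigurationError(f"unknown remainder policy {remainder_policy!r}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(case_ids))
    shuffled = [case_ids[i] for i in order]
    n = len(case_ids)
    counts = [int(np.floor(f * n)) for f in fractions]
    train = shuffled[: counts[0]]
    val = shuffled[counts[0]: counts[0] + counts[1]]
    test = shuffled[counts[0] + counts[1]: counts[0] + counts[1] + counts[2]]
    leftover = shuffled[counts[0] + counts[1] + counts[2]:]
    if remainder_policy == "to_train":
        train, leftover = train + leftover, []
    return SplitResult(tuple(train), tuple(val), tuple(test), tuple(leftover))


def _check_leakage(stats: NormalizationStats | None, split: SplitResult) -> None:
    if stats is None or not stats.case_ids:
        return
    forbidden = set(split.val_ids) | set(split.test_ids)
    leaked = forbidden & set(stats.case_ids)
    if leaked:
        raise LeakageError(
            f"normalization stats were computed on non-training cases: {sorted(leaked)}")


def _slice_batches(cases: dict[str, tuple[np.ndarray, np.ndarray]],
                   ids, batch_size: int, rng: np.random.Generator):
    """All (3-channel slice, mask slice) samples of the 2D training set, shuffled."""
    samples = []
    for cid in ids:
        vol, mask = cases[cid]
        for z in range(vol.shape[2]):
            samples.append((cid, z))
    order = rng.permutation(len(samples))
    for start in range(0, len(samples), batch_size):
        chunk = [samples[i] for i in order[start:start + batch_size]]
        xs = np.stack([np.repeat(cases[cid][0][None, :, :, z], 3, axis=0)
                       for cid, z in chunk])
        ys = np.stack([cases[cid][1][None, :, :, z] for cid, z in chunk])
        yield xs.astype(np.float32), ys.astype(np.float32)


def _volume_batches(cases, ids, rng):
    order = rng.permutation(len(ids))
    for i in order:
        vol, mask = cases[ids[i]]
        yield (vol.transpose(2, 0, 1)[None, None].astype(np.float32),
               mask.transpose(2, 0, 1)[None, None].astype(np.float32))


def _run_single_training(build_fn, cases, split, config, seed):
    rng = np.random.default_rng(seed)
    model = build_fn(seed)
    opt = nn.Adam(model.parameters(), lr=config.resolved_lr())
    batch_size = config.resolved_batch_size()
    history = {"epoch": [], "train_loss": [], "val_loss": [], "val_dice": []}
    best = {"dice": -1.0, "state": None, "epoch": -1}
    stall = 0
    for epoch in range(config.epochs):
        model.train()
        losses = []
        if config.architecture == "2d":
            batches = _slice_batches(cases, split.train_ids, batch_size, rng)
        else:
            batches = _volume_batches(cases, split.train_ids, rng)
        for xb, yb in batches:
            opt.zero_grad()
            pred = model(nn.Tensor(xb))
            loss = dice_loss(pred, yb)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    f"lr={config.resolved_lr()}, seed={seed}")
            loss.backward()
            opt.step()
            losses.append(value)
        model.eval()
        val_losses, val_dices = [], []
        for cid in split.val_ids:
            vol, mask = cases[cid]
            prob = predict_volume(model, vol)
            val_losses.append(dice_loss(prob, mask.astype(np.float32)))
            val_dices.append(dsc_binary(binarize(prob).values, mask))
        val_dice = float(np.mean(val_dices)) if val_dices else float("nan")
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(np.mean(val_losses)) if val_losses else float("nan"))
        history["val_dice"].append(val_dice)
        if val_dices and val_dice > best["dice"]:
            best = {"dice": val_dice, "state": model.state_dict(), "epoch": epoch}
            stall = 0
        else:
            stall += 1
        if split.val_ids and stall > config.patience:
            break
    if best["state"] is not None:
        model.load_state_dict(best["state"])
    history["best_epoch"] = best["epoch"]
    history["best_val_dice"] = best["dice"]
    return model, history


def train_model(build_fn, cases: dict[str, tuple[np.ndarray, np.ndarray]],
                split: SplitResult, config: TrainConfig,
                stats: NormalizationStats | None = None):
    """Train a segmentation network on preprocessed cases.

    ``build_fn(seed)`` constructs a fresh model (a :class:`UNet2D` or
    :class:`UNet3D`); ``cases`` maps case id to ``(normalized volume,
    binary mask)`` arrays at the network grid, indexed (row, col, slice).
    Each of ``config.n_repeats`` runs perturbs the seed by its repeat index
    and the best run by validation Dice is returned along with the list of
    per-run histories.
    """
    config.validate()
    if isinstance(build_fn, nn.Module):
        if config.n_repeats > 1:
            raise ConfigurationError(
                "repeated training needs a model factory, not a built model")
        prebuilt = build_fn
        build_fn = lambda seed: prebuilt  # noqa: E731
    if not split.train_ids:
        raise ConfigurationError("empty training split")
    missing = [cid for cid in split.train_ids + split.val_ids if cid not in cases]
    if missing:
        raise ConfigurationError(f"cases missing from the cohort: {missing}")
    _check_leakage(stats, split)
    best_model, histories, best_dice = None, [], -np.inf
    for repeat in range(config.n_repeats):
        model, history = _run_single_training(
            build_fn, cases, split, config, seed=config.seed + repeat)
        histories.append(history)
        score = history["best_val_dice"] if np.isfinite(history["best_val_dice"]) \
            else -history["train_loss"][-1]
        if best_model is None or score > best_dice:
            best_model, best_dice = model, score
    return best_model, histories


def predict_volume(model, volume: np.ndarray, chunk: int = 16) -> np.ndarray:
    """Probability grid for one preprocessed volume, same (r, c, s) shape.

    The 2-D path iterates over all slices (stacked in order); the 3-D path
    is a single forward pass.  The model is put in eval mode (dropout off,
    running batch-norm statistics).
    """
    model.eval()
    if isinstance(model, UNet2D):
        out = np.empty_like(volume, dtype=np.float32)
        for start in range(0, volume.shape[2], chunk):
            sl = volume[:, :, start:start + chunk]
            xb = np.repeat(sl.transpose(2, 0, 1)[:, None], 3, axis=1)
            prob = model(nn.Tensor(xb.astype(np.float32))).data
            out[:, :, start:start + chunk] = prob[:, 0].transpose(1, 2, 0)
        return out
    if isinstance(model, UNet3D):
        xb = volume.transpose(2, 0, 1)[None, None].astype(np.float32)
        prob = model(nn.Tensor(xb)).data
        return prob[0, 0].transpose(1, 2, 0)
    raise ShapeError(f"unsupported model type {type(model).__name__}")


def binarize(prob_grid: np.ndarray, threshold: float = 0.5,
             voxel_size_mm: float = 0.082,
             annotated_range: tuple[int, int] | None = None) -> BinaryMask:
    """Strictly-greater-than thresholding; exact ties go to background."""
    values = (np.asarray(prob_grid) > threshold).astype(np.uint8)
    return BinaryMask(values, voxel_size_mm, annotated_range)
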