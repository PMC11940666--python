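"""Training loop and whole-map enhancement.

Tile pairs come from cutting a low-depth and a high-depth map of the
same chromosome into aligned 40 x 40 blocks.  Optimization is Adam with
a stepped learning-rate schedule, ``lr(e) = lr0 * 0.5 ** (e // period)``
(defaults: lr0 = 2e-4 halved every 5 epochs), minimizing the composite
loss of :mod:`hicenhance.losses`.  The checkpoint kept is the epoch with
the highest mean validation SSIM.

:func:`enhance` applies a trained generator to a full contact map:
split into tiles, forward in inference mode (output clamped to [0, 1]),
merge, symmetrize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import ContactMap, merge_blocks, split_blocks
from .losses import LossConfig, total_loss
from .nn import Adam, Module, Tensor, no_grad

__all__ = [
    "TrainConfig",
    "TrainResult",
    "learning_rate",
    "scale_pair",
    "make_pairs",
    "train",
    "predict_tiles",
    "enhance",
]


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 16
    lr0: float = 2e-4
    lr_halving_period: int = 5
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch_size < 1 or self.lr_halving_period < 1:
            raise ValueError("epochs, batch_size and lr_halving_period must be >= 1")
        if not (self.lr0 > 0 and math.isfinite(self.lr0)):
            raise ValueError(f"lr0 must be positive and finite, got {self.lr0}")


def learning_rate(epoch: int, cfg: TrainConfig | None = None) -> float:
    """Stepped schedule ``lr0 * 0.5 ** (epoch // period)`` (0-based epoch)."""
    cfg = cfg or TrainConfig()
    if epoch < 0:
        raise ValueError(f"epoch must be >= 0, got {epoch}")
    return cfg.lr0 * 0.5 ** (epoch // cfg.lr_halving_period)


def scale_pair(low: ContactMap, high: ContactMap) -> tuple[ContactMap, ContactMap]:
    """Balance and jointly scale a (low-depth, high-depth) raw map pair.

    Both maps are KR-balanced independently, the high-depth map sets the
    clipping cap via :func:`normalize01`, and the low-depth map is
    divided by the *same* cap (then clipped to 1) so that corresponding
    entries live on a common scale.  Balancing equalizes row sums, so
    the depth difference appears as sparsity and noise rather than
    brightness; a per-map cap would still stretch the two value
    distributions inconsistently.
    """
    from .io_formats import kr_balance, normalize01

    if low.state == "raw_counts":
        low, _ = kr_balance(low)
    if high.state == "raw_counts":
        high, _ = kr_balance(high)
    high_s = normalize01(high)
    m = np.minimum(low.matrix / high_s.scale, 1.0)
    low_s = replace(low, matrix=m, state="scaled01", scale=high_s.scale)
    return low_s, high_s


def make_pairs(
    low: ContactMap,
    high: ContactMap,
    H: int = 40,
    stride: int | None = None,
    max_diag_bins: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (input, target) tile batches from a low/high-depth map pair.

    Both maps must cover the same chromosome at the same binning and be
    in ``scaled01`` state.  A ``stride`` smaller than ``H`` produces
    overlapping tiles (more training pairs from a short chromosome).
    Returns float32 arrays of shape (N, 1, H, H).
    """
    if low.n_bins != high.n_bins or low.chrom != high.chrom:
        raise ValueError(
            f"map mismatch: {low.chrom}/{low.n_bins} bins vs "
            f"{high.chrom}/{high.n_bins} bins"
        )
    for m, name in ((low, "low"), (high, "high")):
        if m.state != "scaled01":
            raise ValueError(f"{name} map must be scaled01, got {m.state!r}")
    gl = split_blocks(low, H=H, stride=stride, max_diag_bins=max_diag_bins)
    gh = split_blocks(high, H=H, stride=stride, max_diag_bins=max_diag_bins)
    if gl.index != gh.index:
        raise RuntimeError("tile grids disagree; identical maps must tile alike")
    x = np.asarray(gl.blocks, dtype=np.float32)[:, None]
    y = np.asarray(gh.blocks, dtype=np.float32)[:, None]
    return x, y


@dataclass
class TrainResult:
    """Epoch-level history plus the best checkpoint (by validation SSIM)."""

    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_ssim: float = -np.inf
    best_state: dict[str, np.ndarray] | None = None


def _check_batch(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=np.float32)
    if a.ndim != 4 or a.shape[1] != 1:
        raise ValueError(f"{name} must have shape (N, 1, H, W), got {a.shape}")
    return a


def predict_tiles(model: Module, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
    """Inference-mode forward over tile batches (output clamped to [0, 1])."""
    x = _check_batch(x, "x")
    outs = []
    with no_grad():
        for i in range(0, x.shape[0], batch_size):
            outs.append(model(Tensor(x[i : i + batch_size]), training=False).data)
    return np.concatenate(outs, axis=0)


def _validate(model: Module, x: np.ndarray, y: np.ndarray, batch_size: int) -> dict:
    from .evaluation import ssim

    pred = predict_tiles(model, x, batch_size)
    mse = float(np.mean((pred - y) ** 2))
    psnr = float("inf") if mse == 0 else float(10.0 * np.log10(1.0 / mse))
    ssims = [ssim(pred[i, 0], y[i, 0]) for i in range(pred.shape[0])]
    return {"val_mse": mse, "val_ssim": float(np.mean(ssims)), "val_psnr": psnr}


def train(
    model: Module,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
    cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
    log=None,
) -> TrainResult:
    """Optimize ``model`` on (low, high) tile pairs.

    Per epoch: set the scheduled learning rate, shuffle (seeded), run
    Adam over mini-batches of the composite loss, then score the
    validation tiles.  The model is left holding the weights of the
    best-validation-SSIM epoch (best training loss when no validation
    set is given).  A non-finite loss aborts with ``RuntimeError``.
    ``log``, if given, is called with each epoch's history record.
    """
    cfg = cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    x_train = _check_batch(x_train, "x_train")
    y_train = _check_batch(y_train, "y_train")
    if x_train.shape != y_train.shape:
        raise ValueError(f"train shapes differ: {x_train.shape} vs {y_train.shape}")
    has_val = x_val is not None and y_val is not None
    if has_val:
        x_val = _check_batch(x_val, "x_val")
        y_val = _check_batch(y_val, "y_val")
        if x_val.shape != y_val.shape:
            raise ValueError(f"val shapes differ: {x_val.shape} vs {y_val.shape}")

    n = x_train.shape[0]
    opt = Adam(model.parameters(), lr=cfg.lr0)
    rng = np.random.default_rng(cfg.seed)
    result = TrainResult()
    best_score = -np.inf

    for epoch in range(cfg.epochs):
        opt.lr = learning_rate(epoch, cfg)
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        losses = []
        for i in range(0, n, cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            pred = model(Tensor(x_train[idx]), training=True)
            loss, _ = total_loss(Tensor(y_train[idx]), pred, loss_cfg)
            lv = loss.item()
            if not math.isfinite(lv):
                raise RuntimeError(f"non-finite loss {lv} at epoch {epoch}")
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(lv)
        rec = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean(losses)),
        }
        if has_val:
            rec.update(_validate(model, x_val, y_val, cfg.batch_size))
            score = rec["val_ssim"]
        else:
            score = -rec["train_loss"]
        result.history.append(rec)
        if log is not None:
            log(rec)
        if score > best_score:
            best_score = score
            result.best_epoch = epoch
            result.best_val_ssim = rec.get("val_ssim", float("nan"))
            result.best_state = model.state_dict()

    if result.best_state is not None:
        model.load_state_dict(result.best_state)
    return result


def enhance(
    model: Module,
    cmap: ContactMap,
    H: int = 40,
    batch_size: int = 16,
    max_diag_bins: int | None = None,
) -> ContactMap:
    """Enhance a full scaled contact map with a trained generator.

    The map is tiled, each tile is reconstructed in inference mode,
    tiles are merged back (cropping any padding) and the result is
    symmetrized.  State and scale carry over, so
    ``enhanced.matrix * enhanced.scale`` recovers balanced-count units.
    """
    if cmap.state != "scaled01":
        raise ValueError(f"enhance expects a scaled01 map, got {cmap.state!r}")
    grid = split_blocks(cmap, H=H, max_diag_bins=max_diag_bins)
    tiles = np.asarray(grid.blocks, dtype=np.float32)[:, None]
    pred = predict_tiles(model, tiles, batch_size)[:, 0].astype(np.float64)
    out_grid = replace(grid, blocks=list(pred))
    return merge_blocks(out_grid, symmetrize=True)
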