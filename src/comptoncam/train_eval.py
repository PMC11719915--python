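"""Training loop and image-similarity metrics.

The networks are trained with ADAM (learning rate 0.001, batch size 1)
on the normalized mean square error

    NMSE = ||f* − f̂||² / ||f*||²,

which is also the headline evaluation metric alongside the peak
signal-to-noise ratio

    PSNR = 10 log10( ||f*||∞² / MSE ),   MSE = ||f* − f̂||² / (M N O),

and the structural similarity index

    SSIM = (2 μ̂ μ* + c1)(2 σ̂* + c2) /
           ((μ̂² + μ*² + c1)(σ̂² + σ*² + c2)),

computed by default with *global* volume statistics (c1 = (0.01 L)²,
c2 = (0.03 L)², L the label's data range); a sliding-window variant is
available.  Model selection keeps the epoch with the lowest validation
mean NMSE.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .dataset import SupervisedDataset
from .grids import ImageVolume
from .networks import FrameletUNet

__all__ = [
    "MetricConfig",
    "TrainConfig",
    "TrainResult",
    "nmse",
    "psnr",
    "ssim",
    "train",
    "evaluate",
]


def _arr(x) -> np.ndarray:
    return x.values if isinstance(x, ImageVolume) else np.asarray(x, float)


def nmse(est, ref) -> float:
    """Normalized mean square error ``||ref − est||² / ||ref||²``."""
    est, ref = _arr(est), _arr(ref)
    if est.shape != ref.shape:
        raise ValueError("shape mismatch")
    denom = float((ref**2).sum())
    if denom == 0:
        raise ValueError("reference is all-zero")
    return float(((ref - est) ** 2).sum() / denom)


def psnr(est, ref) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    est, ref = _arr(est), _arr(ref)
    if est.shape != ref.shape:
        raise ValueError("shape mismatch")
    mse = float(((ref - est) ** 2).mean())
    if mse == 0:
        return float("inf")
    peak = float(np.abs(ref).max())
    return float(10.0 * np.log10(peak**2 / mse))


@dataclass(frozen=True)
class MetricConfig:
    """SSIM stabilizers and scope.

    ``c1``/``c2`` default to ``(k L)²`` with k = 0.01 / 0.03 and L the
    reference data range; ``scope`` selects global volume statistics or
    a 7³ uniform sliding window averaged over the volume.
    """

    k1: float = 0.01
    k2: float = 0.03
    scope: str = "global"
    window: int = 7

    def __post_init__(self) -> None:
        if self.scope not in ("global", "windowed"):
            raise ValueError("scope must be 'global' or 'windowed'")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError("stabilizer factors must be positive")


def ssim(est, ref, cfg: MetricConfig = MetricConfig()) -> float:
    """Structural similarity index in [-1, 1] (1 for identical images)."""
    est, ref = _arr(est), _arr(ref)
    if est.shape != ref.shape:
        raise ValueError("shape mismatch")
    data_range = float(ref.max() - ref.min()) or 1.0
    c1 = (cfg.k1 * data_range) ** 2
    c2 = (cfg.k2 * data_range) ** 2
    if cfg.scope == "global":
        mu_e, mu_r = est.mean(), ref.mean()
        var_e, var_r = est.var(), ref.var()
        cov = ((est - mu_e) * (ref - mu_r)).mean()
        return float(
            (2 * mu_e * mu_r + c1)
            * (2 * cov + c2)
            / ((mu_e**2 + mu_r**2 + c1) * (var_e + var_r + c2))
        )
    w = cfg.window
    mean = lambda a: ndimage.uniform_filter(a, size=w, mode="reflect")
    mu_e, mu_r = mean(est), mean(ref)
    var_e = mean(est**2) - mu_e**2
    var_r = mean(ref**2) - mu_r**2
    cov = mean(est * ref) - mu_e * mu_r
    s = (
        (2 * mu_e * mu_r + c1)
        * (2 * cov + c2)
        / ((mu_e**2 + mu_r**2 + c1) * (var_e + var_r + c2))
    )
    return float(s.mean())


# --------------------------------------------------------------------------
# training


@dataclass(frozen=True)
class TrainConfig:
    """ADAM training hyperparameters (batch of one, NMSE loss)."""

    learning_rate: float = 0.001
    batch_size: int = 1
    max_epochs: int = 10
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size != 1:
            raise ValueError("only batch size 1 is supported")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class TrainResult:
    """Trained model plus the per-epoch history.

    ``model`` carries the best-epoch weights (lowest validation mean
    NMSE); ``history`` has one row per epoch with mean train/validation
    NMSE.
    """

    model: FrameletUNet
    history: pd.DataFrame
    best_epoch: int
    config: TrainConfig
    baseline_val_nmse: float = field(default=float("nan"))

    @property
    def best_val_nmse(self) -> float:
        return float(self.history["val_nmse"].iloc[self.best_epoch])

    def summary(self) -> str:
        lines = [
            f"Framelet U-Net training ({self.model.spec.variant})",
            "=" * 40,
            f"parameters:        {self.model.n_params()}",
            f"epochs:            {len(self.history)}",
            f"best epoch:        {self.best_epoch}",
            f"best val NMSE:     {self.best_val_nmse:.6f}",
            f"untrained val NMSE:{self.baseline_val_nmse:.6f}",
            f"learning rate:     {self.config.learning_rate}",
            f"seed:              {self.config.seed}",
        ]
        return "\n".join(lines)


def _mean_split_nmse(model: FrameletUNet, items) -> float:
    vals = []
    for x, y in items:
        pred = np.maximum(model.forward(x[None], training=False)[0], 0.0)
        vals.append(nmse(pred, y))
    return float(np.mean(vals))


def train(
    model: FrameletUNet, dataset: SupervisedDataset, cfg: TrainConfig = TrainConfig()
) -> TrainResult:
    """Train on the ``train`` split, select the best epoch on ``val``.

    The loss per sample is exactly ``nmse(model(input), label)``; its
    gradient ``2 (est − ref) / ||ref||²`` is backpropagated one sample
    at a time.  The best-epoch weights are restored before returning.
    """
    train_items = dataset.items["train"]
    val_items = dataset.items["val"]
    if not train_items or not val_items:
        raise ValueError("train and val splits must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    opt = model.make_optimizer(lr=cfg.learning_rate)
    baseline = _mean_split_nmse(model, val_items)
    rows = []
    best_val = np.inf
    best_epoch = -1
    best_params = None
    for epoch in range(cfg.max_epochs):
        order = (
            rng.permutation(len(train_items))
            if cfg.shuffle
            else np.arange(len(train_items))
        )
        losses = []
        for i in order:
            x, y = train_items[i]
            opt.zero_grad()
            out = model.forward(x[None], training=True)[0]
            denom = float((y**2).sum())
            losses.append(float(((y - out) ** 2).sum() / denom))
            model.backward(((out - y) * (2.0 / denom))[None])
            opt.step()
        val_nmse = _mean_split_nmse(model, val_items)
        rows.append((epoch, float(np.mean(losses)), val_nmse))
        if val_nmse < best_val:
            best_val = val_nmse
            best_epoch = epoch
            best_params = [p.copy() for p in model.params]
    if best_params is not None:
        for p, bp in zip(model.params, best_params):
            p[...] = bp
    history = pd.DataFrame(rows, columns=["epoch", "train_nmse", "val_nmse"])
    return TrainResult(
        model=model,
        history=history,
        best_epoch=best_epoch,
        config=cfg,
        baseline_val_nmse=baseline,
    )


def evaluate(
    model: FrameletUNet,
    dataset: SupervisedDataset,
    split: str = "test",
    metric_cfg: MetricConfig = MetricConfig(),
) -> pd.DataFrame:
    """Per-image NMSE/PSNR/SSIM on a split, with a trailing mean row."""
    items = dataset.items[split]
    rows = []
    for i, (x, y) in enumerate(items):
        pred = np.maximum(model.forward(x[None], training=False)[0], 0.0)
        rows.append((i, nmse(pred, y), psnr(pred, y), ssim(pred, y, metric_cfg)))
    df = pd.DataFrame(rows, columns=["image", "nmse", "psnr", "ssim"])
    mean = df[["nmse", "psnr", "ssim"]].mean()
    df.loc[len(df)] = ["mean", *mean.tolist()]
    return df


def copy_model(model: FrameletUNet) -> FrameletUNet:
    """Deep copy (weights, BN statistics) of a network."""
    return copy.deepcopy(model)
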