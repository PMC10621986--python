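"""Keypoint-regression network: architecture, losses, training, inference.

The network maps the three co-registered 141x141 camera views (three input
channels) to 72 numbers: per view, 12 keypoints (10 backbone points and 2
eye centroids) as (x, y) pixel coordinates bounded to [0, 141] by a scaled
sigmoid. The encoder is four bottleneck residual blocks (32, 64, 128, 256
output channels, stride-2 transitions); the decoder is three fully
connected layers of 288, 144 and 72 units, every conv/dense layer preceded
by batch normalization and followed by a leaky rectifier (slope 0.01).

The loss is the backbone RMSE plus ``lambda_eye`` times an eye loss that
is symmetric under swapping the two eye labels within each view: for each
camera the RMSE of the better of the two complete eye assignments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .render import IMAGE_SIZE
from .synthesis import TrainingExample

__all__ = [
    "NetworkSpec",
    "TrainingConfig",
    "PoseNet",
    "backbone_loss",
    "eye_loss",
    "total_loss",
    "train",
    "predict",
]


@dataclass
class NetworkSpec:
    channels: tuple[int, ...] = (32, 64, 128, 256)
    fc_sizes: tuple[int, ...] = (288, 144, 72)
    leak: float = 0.01
    output_scale: float = float(IMAGE_SIZE)
    in_channels: int = 3

    @property
    def n_outputs(self) -> int:
        return self.fc_sizes[-1]  # 72 = 3 views x 12 keypoints x 2 coords


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    batch_size: int = 300
    epochs: int = 120
    val_fraction: float = 0.1   # 9:1 train/validation split
    lambda_eye: float = 5.0
    seed: int = 0
    downscale: int = 1          # integer image block-mean factor
    # desk-scale profile: TrainingConfig(batch_size=64, epochs=15,
    # downscale=3) trains usefully on a few thousand examples on one CPU

    def __post_init__(self) -> None:
        if self.lambda_eye < 0:
            raise ValueError("lambda_eye must be non-negative")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")


def _bottleneck(cin: int, cout: int, stride: int, leak: float,
                rng: np.random.Generator) -> nn.Residual:
    mid = max(cout // 4, 4)
    branch = nn.Sequential(
        nn.BatchNorm2d(cin), nn.Conv2d(cin, mid, k=1, pad=0, rng=rng),
        nn.LeakyReLU(leak),
        nn.BatchNorm2d(mid), nn.Conv2d(mid, mid, k=3, stride=stride, pad=1,
                                       rng=rng),
        nn.LeakyReLU(leak),
        nn.BatchNorm2d(mid), nn.Conv2d(mid, cout, k=1, pad=0, rng=rng),
        nn.LeakyReLU(leak),
    )
    shortcut = nn.Conv2d(cin, cout, k=1, stride=stride, pad=0, rng=rng)
    return nn.Residual(branch, shortcut)


class PoseNet:
    """Encoder-decoder keypoint regressor (see module docstring)."""

    def __init__(self, spec: NetworkSpec | None = None, seed: int = 0):
        self.spec = spec or NetworkSpec()
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        cin = self.spec.in_channels
        for cout in self.spec.channels:
            layers.append(_bottleneck(cin, cout, stride=2, leak=self.spec.leak,
                                      rng=rng))
            cin = cout
        layers.append(nn.GlobalAvgPool())
        nin = cin
        for i, nout in enumerate(self.spec.fc_sizes):
            layers.append(nn.BatchNorm1d(nin))
            layers.append(nn.Dense(nin, nout, rng=rng))
            if i < len(self.spec.fc_sizes) - 1:
                layers.append(nn.LeakyReLU(self.spec.leak))
            nin = nout
        layers.append(nn.ScaledSigmoid(self.spec.output_scale))
        self.net = nn.Sequential(*layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """(N, 3, H, W) images -> (N, 72) raw keypoint vector."""
        return self.net.forward(x.astype(nn.F32), train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.net.backward(dy.astype(nn.F32))

    def params(self):
        return self.net.params()

    # -- persistence ------------------------------------------------------

    def state_arrays(self) -> list[np.ndarray]:
        arrs = [p for p, _ in self.params()]
        for layer in _walk(self.net):
            if isinstance(layer, nn._BatchNorm):
                arrs.extend([layer.run_mean, layer.run_var])
        return arrs

    def save(self, path: str) -> None:
        np.savez_compressed(path, *self.state_arrays())

    def load(self, path: str) -> None:
        data = np.load(path)
        for arr, key in zip(self.state_arrays(), data.files):
            arr[...] = data[key]


def _walk(layer: nn.Layer):
    yield layer
    for child in getattr(layer, "layers", []):
        yield from _walk(child)
    for name in ("branch", "shortcut"):
        if hasattr(layer, name):
            yield from _walk(getattr(layer, name))


# --------------------------------------------------------------------------
# losses (keypoints as (n_views, 12, 2) or batches thereof)
# --------------------------------------------------------------------------

def backbone_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """RMSE over the 10 backbone keypoints of all three views (60 values)."""
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    e = pred[..., :10, :] - truth[..., :10, :]
    return float(np.sqrt(np.mean(e**2)))


def eye_loss(pred: np.ndarray, truth: np.ndarray) -> float:
    """Per camera, the smaller RMSE over the two eye assignments, summed.

    Exactly symmetric under swapping the ground-truth eye indices in any
    view.
    """
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch")
    p = pred[..., 10:12, :]
    g = truth[..., 10:12, :]
    direct = np.sqrt(np.mean((p - g) ** 2, axis=(-2, -1)))
    swapped = np.sqrt(np.mean((p - g[..., ::-1, :]) ** 2, axis=(-2, -1)))
    return float(np.sum(np.minimum(direct, swapped), axis=-1).mean()
                 if pred.ndim > 3 else np.minimum(direct, swapped).sum())


def total_loss(pred: np.ndarray, truth: np.ndarray,
               lambda_eye: float = 5.0) -> float:
    """backbone_loss + lambda * eye_loss."""
    if lambda_eye < 0:
        raise ValueError("lambda_eye must be non-negative")
    return backbone_loss(pred, truth) + lambda_eye * eye_loss(pred, truth)


def _loss_and_grad(pred: np.ndarray, truth: np.ndarray, lambda_eye: float):
    """Batch-mean loss and gradient w.r.t. pred ((N, V, 12, 2) arrays)."""
    n = pred.shape[0]
    grad = np.zeros_like(pred)
    total = 0.0
    eps = 1e-12
    eb = pred[:, :, :10, :] - truth[:, :, :10, :]
    per_bb = np.sqrt(np.mean(eb.reshape(n, -1) ** 2, axis=1))
    m_bb = eb.reshape(n, -1).shape[1]
    grad[:, :, :10, :] = eb / (m_bb * (per_bb + eps)[:, None, None, None])
    total += per_bb.mean()
    p = pred[:, :, 10:12, :]
    g = truth[:, :, 10:12, :]
    d_direct = np.sqrt(np.mean((p - g) ** 2, axis=(2, 3)))
    d_swap = np.sqrt(np.mean((p - g[:, :, ::-1, :]) ** 2, axis=(2, 3)))
    use_swap = d_swap < d_direct
    best = np.where(use_swap, d_swap, d_direct)
    g_eff = np.where(use_swap[:, :, None, None], g[:, :, ::-1, :], g)
    grad[:, :, 10:12, :] = lambda_eye * (p - g_eff) \
        / (4.0 * (best + eps)[:, :, None, None])
    total += lambda_eye * best.sum(axis=1).mean()
    grad /= n  # batch mean
    return float(total), grad


# --------------------------------------------------------------------------
# training / inference
# --------------------------------------------------------------------------

def _prepare_images(examples: list[TrainingExample], downscale: int) -> np.ndarray:
    imgs = np.stack([e.images for e in examples]).astype(nn.F32) / 255.0
    if downscale > 1:
        n, c, h, w = imgs.shape
        h2, w2 = h - h % downscale, w - w % downscale
        imgs = imgs[:, :, :h2, :w2].reshape(
            n, c, h2 // downscale, downscale, w2 // downscale, downscale
        ).mean(axis=(3, 5))
    return imgs


def _prepare_targets(examples: list[TrainingExample]) -> np.ndarray:
    return np.stack([e.keypoints for e in examples]).astype(nn.F32)


def train(
    examples: list[TrainingExample],
    spec: NetworkSpec | None = None,
    config: TrainingConfig | None = None,
    model: PoseNet | None = None,
    verbose: bool = False,
) -> tuple[PoseNet, dict]:
    """Train the keypoint network on synthetic examples.

    Splits the dataset 9:1 into training and validation (shuffled with the
    config seed), optimizes with Adam, and returns the model plus a history
    dict with per-epoch train/validation losses. Aborts on NaN loss.
    """
    config = config or TrainingConfig()
    spec = spec or NetworkSpec()
    rng = np.random.default_rng(config.seed)
    model = model or PoseNet(spec, seed=config.seed)
    X = _prepare_images(examples, config.downscale)
    Y = _prepare_targets(examples)
    n = len(X)
    order = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    opt = nn.Adam(model.params(), lr=config.learning_rate)
    history = {"train": [], "val": []}
    n_views = Y.shape[1]
    for epoch in range(config.epochs):
        perm = rng.permutation(train_idx)
        losses = []
        for start in range(0, len(perm), config.batch_size):
            idx = perm[start:start + config.batch_size]
            if len(idx) < 2:
                continue  # batchnorm needs more than one sample
            out = model.forward(X[idx], train=True)
            pred = out.reshape(len(idx), n_views, 12, 2)
            loss, grad = _loss_and_grad(pred, Y[idx], config.lambda_eye)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch}; lower the learning rate")
            model.backward(grad.reshape(len(idx), -1))
            opt.step()
            losses.append(loss)
        val_pred = predict(model, X[val_idx], prepared=True)
        vloss = total_loss(val_pred, Y[val_idx], config.lambda_eye)
        history["train"].append(float(np.mean(losses)) if losses else np.nan)
        history["val"].append(float(vloss))
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}: "
                  f"train {history['train'][-1]:.3f} val {vloss:.3f}")
    return model, history


def predict(model: PoseNet, images: np.ndarray, downscale: int = 1,
            prepared: bool = False, batch_size: int = 256) -> np.ndarray:
    """Keypoints for a batch of view triplets.

    ``images`` is (N, 3, H, W) (uint8 or unit-scale float) or a single
    triplet (3, H, W); returns (N, 3, 12, 2) (or (3, 12, 2)) with every
    coordinate in [0, 141] by construction.
    """
    single = images.ndim == 3
    x = images[None] if single else images
    if not prepared:
        x = x.astype(nn.F32)
        if x.max() > 1.5:
            x = x / 255.0
        if downscale > 1:
            n, c, h, w = x.shape
            h2, w2 = h - h % downscale, w - w % downscale
            x = x[:, :, :h2, :w2].reshape(n, c, h2 // downscale, downscale,
                                          w2 // downscale, downscale).mean(axis=(3, 5))
    if x.shape[1] != model.spec.in_channels:
        raise ValueError("expected 3-channel view triplets")
    outs = []
    for start in range(0, len(x), batch_size):
        out = model.forward(x[start:start + batch_size], train=False)
        outs.append(out)
    out = np.concatenate(outs)
    kp = out.reshape(len(x), -1, 12, 2)
    return kp[0] if single else kp
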