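"""Lesion segmentation: windowed intensity normalization, a small 2D U-Net
trained slice-wise on DWI, mask cleanup/exclusion rules, and the DICE metric.

Preprocessing and cleanup follow the clinical pipeline conventions: images
are windowed to [0, 1] with a level/width pair; after inference, 2D slice
components under 20 pixels are deleted (too small to carry texture), and
subjects whose cleaned 3D lesion is under 50 voxels are flagged for
exclusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from ._nn import Adam, Conv2d, MaxPool2, ReLU, Upsample2, sigmoid
from .errors import DataError, ParameterError, ShapeError

MIN_SLICE_COMPONENT_PIXELS = 20  # 2D cleanup rule: strict <
MIN_LESION_VOXELS = 50           # 3D exclusion rule: strict <


@dataclass
class SegConfig:
    depth: int = 2
    base_channels: int = 8
    epochs: int = 100
    learning_rate: float = 5e-3
    batch_size: int = 8
    seed: int = 0
    window_level: float | None = None
    window_width: float | None = None
    threshold: float = 0.5

    def __post_init__(self):
        if self.depth < 1:
            raise ParameterError("depth must be >= 1")
        if self.window_width is not None and self.window_width <= 0:
            raise ParameterError("window_width must be > 0")


def normalize_intensity(volume: np.ndarray, level: float, width: float) -> np.ndarray:
    """Window an image to [0, 1]: v -> clip((v - (level - width/2)) / width, 0, 1)."""
    if width <= 0:
        raise ParameterError(f"window width must be > 0, got {width}")
    v = np.asarray(volume, dtype=float)
    return np.clip((v - (level - width / 2.0)) / width, 0.0, 1.0)


def robust_window(volume: np.ndarray, lo: float = 1.0, hi: float = 99.0) -> tuple[float, float]:
    """Level/width from robust percentiles, for data without scanner windowing."""
    p_lo, p_hi = np.percentile(volume, [lo, hi])
    width = max(float(p_hi - p_lo), np.finfo(float).eps)
    return float((p_lo + p_hi) / 2.0), width


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """DICE overlap 2|A∩B| / (|A| + |B|); two empty masks give 1.0."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ShapeError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


_STRUCT_8 = np.ones((3, 3), dtype=int)  # 8-connectivity in-plane


def postprocess_mask(mask: np.ndarray) -> tuple[np.ndarray, bool]:
    """Clean a binary mask and apply the exclusion rule.

    Per axial slice (axis 0), 8-connected components with fewer than 20 pixels
    are removed.  If the cleaned 3D mask has fewer than 50 voxels the subject
    is flagged excluded (strict inequalities at both boundaries).
    Returns ``(cleaned_mask, excluded)``.
    """
    m = np.asarray(mask).astype(bool)
    out = np.zeros_like(m)
    for z in range(m.shape[0]):
        lab, n = ndimage.label(m[z], structure=_STRUCT_8)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes[1:] >= MIN_SLICE_COMPONENT_PIXELS
        out[z] = keep[lab]
    excluded = int(out.sum()) < MIN_LESION_VOXELS
    return out.astype(np.uint8), excluded


# ---------------------------------------------------------------------------
# U-Net
# ---------------------------------------------------------------------------

class _UNet:
    """Small encoder-decoder with long skip connections (NumPy, manual grads)."""

    def __init__(self, depth: int, base_channels: int, rng: np.random.Generator):
        self.depth = depth
        c = base_channels
        self.enc: list[list] = []
        c_in = 1
        for d in range(depth):
            c_out = c * (2 ** d)
            self.enc.append([Conv2d(c_in, c_out, 3, rng), ReLU(),
                             Conv2d(c_out, c_out, 3, rng), ReLU()])
            c_in = c_out
        self.pools = [MaxPool2() for _ in range(depth - 1)]
        self.ups = [Upsample2() for _ in range(depth - 1)]
        self.dec: list[list] = []
        for d in range(depth - 2, -1, -1):
            c_skip = c * (2 ** d)
            c_deep = c * (2 ** (d + 1))
            self.dec.append([Conv2d(c_deep + c_skip, c_skip, 3, rng), ReLU(),
                             Conv2d(c_skip, c_skip, 3, rng), ReLU()])
        self.head = Conv2d(c, 1, 1, rng)

    def _blocks(self):
        for blk in self.enc + self.dec:
            yield from blk
        yield self.head

    @property
    def params(self):
        out = []
        for layer in self._blocks():
            out.extend(layer.params)
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        skips = []
        h = x
        for d in range(self.depth):
            for layer in self.enc[d]:
                h = layer.forward(h)
            if d < self.depth - 1:
                skips.append(h)
                h = self.pools[d].forward(h)
        self._skip_channels = []
        for j, d in enumerate(range(self.depth - 2, -1, -1)):
            h = self.ups[j].forward(h)
            skip = skips[d]
            self._skip_channels.append((h.shape[1], skip.shape[1]))
            h = np.concatenate([h, skip], axis=1)
            for layer in self.dec[j]:
                h = layer.forward(h)
        return self.head.forward(h)

    def backward(self, dy: np.ndarray) -> None:
        g = self.head.backward(dy)
        dskips: dict[int, np.ndarray] = {}
        for j in range(len(self.dec) - 1, -1, -1):
            d = self.depth - 2 - j
            for layer in reversed(self.dec[j]):
                g = layer.backward(g)
            c_deep, _ = self._skip_channels[j]
            dskips[d] = g[:, c_deep:]
            g = self.ups[j].backward(g[:, :c_deep])
        for d in range(self.depth - 1, -1, -1):
            if d < self.depth - 1:
                g = self.pools[d].backward(g)
                g = g + dskips[d]
            for layer in reversed(self.enc[d]):
                g = layer.backward(g)


@dataclass
class Segmenter:
    """Trained slice-wise lesion segmenter."""

    net: _UNet
    config: SegConfig
    history: dict = field(default_factory=dict)

    @property
    def _divisor(self) -> int:
        return 2 ** (self.config.depth - 1)

    def _pad(self, img: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
        h, w = img.shape
        dv = self._divisor
        ph, pw = (-h) % dv, (-w) % dv
        return np.pad(img, ((0, ph), (0, pw)), mode="edge"), (h, w)

    def predict_proba_slice(self, img: np.ndarray) -> np.ndarray:
        padded, (h, w) = self._pad(np.asarray(img, dtype=float))
        logits = self.net.forward(padded[None, None])
        return sigmoid(logits)[0, 0, :h, :w]

    def predict_proba(self, volume: np.ndarray) -> np.ndarray:
        return np.stack([self.predict_proba_slice(s) for s in volume])


def _seg_loss_grad(logits: np.ndarray, target: np.ndarray,
                   smooth: float = 1.0) -> tuple[float, np.ndarray]:
    """Binary cross-entropy + soft-DICE loss; returns (loss, dL/dlogits)."""
    p = sigmoid(logits)
    n_pix = logits.size
    eps = 1e-12
    bce = float(-np.mean(target * np.log(p + eps) + (1 - target) * np.log(1 - p + eps)))
    inter = float((p * target).sum())
    sums = float(p.sum() + target.sum())
    dice_loss = 1.0 - (2 * inter + smooth) / (sums + smooth)
    dbce = (p - target) / n_pix
    ddice_dp = -(2 * target * (sums + smooth) - (2 * inter + smooth)) / (sums + smooth) ** 2
    dlogits = dbce + ddice_dp * p * (1 - p)
    return bce + dice_loss, dlogits


def train_unet(slice_pairs: list[tuple[np.ndarray, np.ndarray]],
               config: SegConfig = SegConfig()) -> Segmenter:
    """Train the 2D U-Net on (normalized image slice, binary mask slice) pairs.

    Records per-epoch mean loss in ``segmenter.history['loss']``.
    """
    if len(slice_pairs) == 0:
        raise DataError("empty training set")
    if not any(m.any() for _, m in slice_pairs):
        raise DataError("need at least one slice containing lesion pixels")
    rng = np.random.default_rng(config.seed)
    net = _UNet(config.depth, config.base_channels, rng)
    seg = Segmenter(net=net, config=config)

    imgs, msks = [], []
    for img, msk in slice_pairs:
        padded, _ = seg._pad(np.asarray(img, dtype=float))
        pm, _ = seg._pad(np.asarray(msk, dtype=float))
        imgs.append(padded)
        msks.append(pm)
    X = np.stack(imgs)[:, None]
    Y = np.stack(msks)[:, None]

    opt = Adam(net.params, lr=config.learning_rate)
    losses = []
    n = X.shape[0]
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = net.forward(X[idx])
            loss, dlogits = _seg_loss_grad(logits, Y[idx])
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
    seg.history = {"loss": losses}
    return seg


def segment_volume(segmenter: Segmenter, volume: np.ndarray,
                   threshold: float | None = None) -> np.ndarray:
    """Slice-by-slice inference; probability >= threshold becomes lesion."""
    vol = np.asarray(volume, dtype=float)
    if vol.ndim != 3:
        raise ShapeError(f"expected a 3D volume, got shape {vol.shape}")
    thr = segmenter.config.threshold if threshold is None else threshold
    proba = segmenter.predict_proba(vol)
    return (proba >= thr).astype(np.uint8)


def save_segmenter(seg: Segmenter, path: str | Path) -> None:
    """Persist weights (npz) plus a JSON sidecar with config and history."""
    path = Path(path)
    arrays = {}
    for i, (p, _g) in enumerate(seg.net.params):
        arrays[f"p{i}"] = p
    np.savez(path.with_suffix(".npz"), **arrays)
    sidecar = {"config": asdict(seg.config), "history": seg.history}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_segmenter(path: str | Path) -> Segmenter:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = SegConfig(**sidecar["config"])
    net = _UNet(config.depth, config.base_channels, np.random.default_rng(0))
    data = np.load(path.with_suffix(".npz"))
    for i, (p, _g) in enumerate(net.params):
        p[...] = data[f"p{i}"]
    return Segmenter(net=net, config=config, history=sidecar.get("history", {}))
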