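"""Two-stage cascaded fully-convolutional segmenter with class-balanced loss.

Stage 1 segments the liver on axial slices; the liver ROI is then cropped,
resampled and fed to stage 2, which segments lesions inside it — the
cascade constrains lesions to the liver.  Because lesion pixels are rare
(about 1 % of liver pixels), the per-pixel cross-entropy is weighted by
inverse class frequency:

    L = -(1/N) sum_i  w_i [ t_i log p_i + (1 - t_i) log(1 - p_i) ]

with w_i the weight of pixel i's true class, normalized to mean 1 across
classes.

The networks are miniature U-Nets (3 resolution levels, 11 convolutions
with ReLU activations, max-pool downsampling, nearest-neighbour upsampling
and skip concatenations — about 19 layers counting activations and
resampling), implemented directly in numpy with im2col convolutions,
hand-derived backpropagation and an Adam optimizer.  Fully convolutional:
any input size divisible by 4 is accepted.  Runs are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from scipy import ndimage as ndi

from .core import Mask, Volume

_EPS = 1e-7


# ---------------------------------------------------------------------------
# class-balanced loss
# ---------------------------------------------------------------------------

@dataclass
class BalancedLossConfig:
    class_weights: dict[int, float] = field(default_factory=lambda: {0: 1.0, 1: 1.0})

    def __post_init__(self):
        if any(w <= 0 for w in self.class_weights.values()):
            raise ValueError("class weights must be positive")

    def pixel_weights(self, truth: np.ndarray) -> np.ndarray:
        t = np.asarray(truth)
        return np.where(t > 0, self.class_weights[1], self.class_weights[0])


def class_weights_from_frequency(truth) -> dict[int, float]:
    """Inverse-frequency class weights, normalized so the mean weight is 1.

    At 1 % lesion pixels the lesion/background weight ratio is 99.
    """
    t = np.asarray(truth.data if isinstance(truth, Mask) else truth) > 0
    n = t.size
    n1 = int(t.sum())
    if n1 == 0 or n1 == n:
        warnings.warn("single-class batch; using uniform class weights")
        return {0: 1.0, 1: 1.0}
    f0, f1 = (n - n1) / n, n1 / n
    w0, w1 = 1.0 / f0, 1.0 / f1
    m = (w0 + w1) / 2.0
    return {0: w0 / m, 1: w1 / m}


def balanced_cross_entropy(pred: np.ndarray, truth: np.ndarray,
                           cfg: BalancedLossConfig | None = None) -> float:
    """Class-weighted binary cross-entropy, mean over pixels.

    With all weights 1 this is exactly the unweighted binary cross-entropy.
    Predictions are clipped to [eps, 1-eps] with eps = 1e-7.
    """
    cfg = cfg or BalancedLossConfig()
    p = np.clip(np.asarray(pred, dtype=np.float64), _EPS, 1.0 - _EPS)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    w = cfg.pixel_weights(t)
    ll = t * np.log(p) + (1.0 - t) * np.log(1.0 - p)
    return float(-(w * ll).mean())


def balanced_cross_entropy_grad(pred: np.ndarray, truth: np.ndarray,
                                cfg: BalancedLossConfig | None = None) -> np.ndarray:
    """Analytic gradient of :func:`balanced_cross_entropy` w.r.t. ``pred``."""
    cfg = cfg or BalancedLossConfig()
    p = np.clip(np.asarray(pred, dtype=np.float64), _EPS, 1.0 - _EPS)
    t = np.asarray(truth, dtype=np.float64)
    w = cfg.pixel_weights(t)
    return -(w * (t / p - (1.0 - t) / (1.0 - p))) / p.size


# ---------------------------------------------------------------------------
# numpy conv-net primitives
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patches, stride 1, 'same' padding."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    cols = np.empty((n, c, k * k, h, w), dtype=x.dtype)
    for di in range(k):
        for dj in range(k):
            cols[:, :, di * k + dj] = xp[:, :, di:di + h, dj:dj + w]
    return cols.reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, shape, k: int, pad: int) -> np.ndarray:
    n, c, h, w = shape
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols = cols.reshape(n, c, k * k, h, w)
    for di in range(k):
        for dj in range(k):
            xp[:, :, di:di + h, dj:dj + w] += cols[:, :, di * k + dj]
    return xp[:, :, pad:pad + h, pad:pad + w]


class Conv2D:
    """k x k convolution, stride 1, same padding, optional fused ReLU."""

    def __init__(self, c_in: int, c_out: int, k: int, rng, relu: bool = True):
        scale = np.sqrt(2.0 / (c_in * k * k))   # He initialization
        self.W = (rng.standard_normal((c_out, c_in * k * k)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.k, self.pad, self.relu = k, k // 2, relu
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.k, self.pad)
        out = np.einsum("fk,nkp->nfp", self.W, cols) + self.b[None, :, None]
        out = out.reshape(n, -1, h, w)
        if self.relu:
            mask = out > 0
            out = out * mask
            self._cache = (cols, x.shape, mask)
        else:
            self._cache = (cols, x.shape, None)
        return out

    def backward(self, dout: np.ndarray):
        cols, xshape, mask = self._cache
        if mask is not None:
            dout = dout * mask
        n, f, h, w = dout.shape
        dflat = dout.reshape(n, f, h * w)
        self.dW = np.einsum("nfp,nkp->fk", dflat, cols) / 1.0
        self.db = dflat.sum(axis=(0, 2))
        dcols = np.einsum("fk,nfp->nkp", self.W, dflat)
        return _col2im(dcols, xshape, self.k, self.pad)

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


class MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = (xr == out[:, :, :, None, :, None])
        self._shape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._shape
        d = (self._mask * dout[:, :, :, None, :, None]).astype(dout.dtype)
        # split ties evenly so the gradient is exact
        counts = self._mask.sum(axis=(3, 5), keepdims=True)
        d = d / counts
        return d.reshape(n, c, h, w)


class Upsample2:
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout):
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class MiniUNet:
    """3-level fully-convolutional U-Net miniature (see module docstring)."""

    def __init__(self, in_channels: int = 1, base: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        b = base
        self.enc1 = [Conv2D(in_channels, b, 3, rng), Conv2D(b, b, 3, rng)]
        self.enc2 = [Conv2D(b, 2 * b, 3, rng), Conv2D(2 * b, 2 * b, 3, rng)]
        self.bott = [Conv2D(2 * b, 4 * b, 3, rng), Conv2D(4 * b, 4 * b, 3, rng)]
        self.dec2 = [Conv2D(6 * b, 2 * b, 3, rng), Conv2D(2 * b, 2 * b, 3, rng)]
        self.dec1 = [Conv2D(3 * b, b, 3, rng), Conv2D(b, b, 3, rng)]
        self.head = Conv2D(b, 1, 1, rng, relu=False)
        self.pool1, self.pool2 = MaxPool2(), MaxPool2()
        self.up2, self.up1 = Upsample2(), Upsample2()
        self.in_channels = in_channels

    def _convs(self):
        return self.enc1 + self.enc2 + self.bott + self.dec2 + self.dec1 + [self.head]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel logits for a batch (N, C, H, W); H, W divisible by 4."""
        x = np.asarray(x, dtype=np.float32)
        if x.shape[2] % 4 or x.shape[3] % 4:
            raise ValueError("input height/width must be divisible by 4")
        e1 = x
        for l in self.enc1:
            e1 = l.forward(e1)
        e2 = self.pool1.forward(e1)
        for l in self.enc2:
            e2 = l.forward(e2)
        bt = self.pool2.forward(e2)
        for l in self.bott:
            bt = l.forward(bt)
        d2 = np.concatenate([self.up2.forward(bt), e2], axis=1)
        self._split2 = self.up2
        for l in self.dec2:
            d2 = l.forward(d2)
        d1 = np.concatenate([self.up1.forward(d2), e1], axis=1)
        for l in self.dec1:
            d1 = l.forward(d1)
        return self.head.forward(d1)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[:, None].astype(np.float32))
        for l in reversed(self.dec1):
            d = l.backward(d)
        n_up = d.shape[1] - self.enc1[-1].W.shape[0]
        d_up1, d_e1 = d[:, :n_up], d[:, n_up:]
        d2 = self.up1.backward(d_up1)
        for l in reversed(self.dec2):
            d2 = l.backward(d2)
        n_up2 = d2.shape[1] - self.enc2[-1].W.shape[0]
        d_up2, d_e2 = d2[:, :n_up2], d2[:, n_up2:]
        dbt = self.up2.backward(d_up2)
        for l in reversed(self.bott):
            dbt = l.backward(dbt)
        de2 = self.pool2.backward(dbt) + d_e2
        for l in reversed(self.enc2):
            de2 = l.backward(de2)
        de1 = self.pool1.backward(de2) + d_e1
        for l in reversed(self.enc1):
            de1 = l.backward(de1)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        z = self.forward(x)
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


class Adam:
    def __init__(self, net: MiniUNet, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net, self.lr, self.b1, self.b2, self.eps = net, lr, beta1, beta2, eps
        self.t = 0
        self.state = {}

    def step(self):
        self.t += 1
        for li, layer in enumerate(self.net._convs()):
            for arr, gname in ((layer.W, "dW"), (layer.b, "db")):
                g = getattr(layer, gname)
                key = (li, gname)
                m, v = self.state.get(key, (np.zeros_like(arr), np.zeros_like(arr)))
                m = self.b1 * m + (1 - self.b1) * g
                v = self.b2 * v + (1 - self.b2) * g * g
                self.state[key] = (m, v)
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                arr -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(arr.dtype)


# ---------------------------------------------------------------------------
# slice plumbing
# ---------------------------------------------------------------------------

@dataclass
class SliceBatch:
    """2D axial slices with per-pixel binary truth labels."""

    slices: np.ndarray       # (N, H, W) intensities
    labels: np.ndarray       # (N, H, W) in {0, 1}
    spacing: tuple[float, float] = (1.0, 1.0)
    stack_adjacent: bool = False   # 2.5D: upper/lower neighbours as channels

    def inputs(self) -> np.ndarray:
        """Network input (N, C, H, W), normalized to [0, 1]."""
        x = np.asarray(self.slices, dtype=np.float32) / 255.0
        if not self.stack_adjacent:
            return x[:, None]
        lower = np.roll(x, 1, axis=0)
        upper = np.roll(x, -1, axis=0)
        lower[0] = x[0]
        upper[-1] = x[-1]
        return np.stack([lower, x, upper], axis=1)


def slices_from_volume(volume: Volume, labels: np.ndarray,
                       stack_adjacent: bool = False) -> SliceBatch:
    """Axial (z) slices of a volume + binary labels as a SliceBatch."""
    sl = np.moveaxis(volume.data, 2, 0)
    lb = np.moveaxis(np.asarray(labels).astype(np.uint8), 2, 0)
    return SliceBatch(sl, (lb > 0).astype(np.uint8),
                      spacing=volume.spacing[:2], stack_adjacent=stack_adjacent)


@dataclass
class CropInfo:
    bbox: tuple[int, int, int, int]    # x0, x1, y0, y1 (in-plane, exclusive)
    target_shape: tuple[int, int]
    orig_shape: tuple[int, int]

    def map_back(self, prob_slices: np.ndarray) -> np.ndarray:
        """Resample (N, h, w) stage-2 output back onto the original grid."""
        x0, x1, y0, y1 = self.bbox
        out = np.zeros((prob_slices.shape[0],) + self.orig_shape,
                       dtype=np.float64)
        for i, sl in enumerate(prob_slices):
            out[i, x0:x1, y0:y1] = _zoom_to(sl.astype(np.float64),
                                            (x1 - x0, y1 - y0), order=1)
        return out


def crop_resample_roi(batch: SliceBatch, liver_mask: np.ndarray, margin: int = 2,
                      target_shape: tuple[int, int] = (32, 32)
                      ) -> tuple[SliceBatch, CropInfo]:
    """Crop the in-plane liver bounding box (+margin) and resample slices.

    ``liver_mask`` is (N, H, W) aligned with the batch; the recorded
    :class:`CropInfo` maps stage-2 outputs back to the original grid.
    """
    liv = np.asarray(liver_mask).astype(bool)
    if not liv.any():
        raise ValueError("liver mask is empty; cannot crop ROI")
    xs, ys = np.nonzero(liv.any(axis=0))
    x0 = max(int(xs.min()) - margin, 0)
    x1 = min(int(xs.max()) + 1 + margin, liv.shape[1])
    y0 = max(int(ys.min()) - margin, 0)
    y1 = min(int(ys.max()) + 1 + margin, liv.shape[2])
    th, tw = target_shape
    zoom = (th / (x1 - x0), tw / (y1 - y0))
    n = batch.slices.shape[0]
    out_s = np.empty((n, th, tw), dtype=np.float32)
    out_l = np.empty((n, th, tw), dtype=np.uint8)
    for i in range(n):
        out_s[i] = _zoom_to(batch.slices[i, x0:x1, y0:y1].astype(np.float32),
                            target_shape, order=1)
        out_l[i] = _zoom_to(batch.labels[i, x0:x1, y0:y1].astype(np.float32),
                            target_shape, order=0).astype(np.uint8)
    info = CropInfo(bbox=(x0, x1, y0, y1), target_shape=target_shape,
                    orig_shape=liv.shape[1:])
    return SliceBatch(out_s, out_l, spacing=batch.spacing,
                      stack_adjacent=batch.stack_adjacent), info


def _zoom_to(arr: np.ndarray, shape, order: int) -> np.ndarray:
    zoom = (shape[0] / arr.shape[0], shape[1] / arr.shape[1])
    out = ndi.zoom(arr, zoom, order=order, grid_mode=True, mode="nearest")
    out = out[:shape[0], :shape[1]]
    if out.shape != tuple(shape):   # zoom rounding can undershoot by one
        pad = ((0, shape[0] - out.shape[0]), (0, shape[1] - out.shape[1]))
        out = np.pad(out, pad, mode="edge")
    return out


# ---------------------------------------------------------------------------
# training and prediction
# ---------------------------------------------------------------------------

def train_stage(net: MiniUNet, batch: SliceBatch,
                loss_cfg: BalancedLossConfig | None = None,
                epochs: int = 10, batch_size: int = 8, lr: float = 1e-3,
                seed: int = 0, augment_flips: bool = False) -> list[float]:
    """Optimize the balanced loss with Adam; returns the per-epoch loss curve.

    With ``augment_flips`` each mini-batch is randomly mirrored in-plane.
    Deterministic under a fixed seed (numpy only, single-threaded math).
    Raises on divergence (non-finite loss).
    """
    cfg = loss_cfg or BalancedLossConfig()
    x = batch.inputs()
    t = batch.labels.astype(np.float32)
    n = x.shape[0]
    if n == 0:
        raise ValueError("empty batch stream")
    rng = np.random.default_rng(seed)
    opt = Adam(net, lr=lr)
    curve = []
    for epoch in range(epochs):
        # step decay stabilizes the late FP-pruning phase of training
        opt.lr = lr * (0.5 ** (epoch // max(1, int(np.ceil(epochs * 0.4)))))
        order = rng.permutation(n)
        losses = []
        for i0 in range(0, n, batch_size):
            idx = order[i0:i0 + batch_size]
            xb, tb = x[idx], t[idx]
            if augment_flips:
                axis = int(rng.integers(0, 3))   # none / height / width
                if axis:
                    xb = np.flip(xb, axis=axis + 1).copy()
                    tb = np.flip(tb, axis=axis).copy()
            z = net.forward(xb)
            p = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
            w = cfg.pixel_weights(tb)
            pc = np.clip(p, _EPS, 1 - _EPS)
            loss = float(-(w * (tb * np.log(pc)
                                + (1 - tb) * np.log(1 - pc))).mean())
            if not np.isfinite(loss):
                raise FloatingPointError(f"training diverged (loss={loss})")
            dz = (w * (p - tb) / p.size).astype(np.float32)
            net.backward(dz)
            opt.step()
            losses.append(loss)
        curve.append(float(np.mean(losses)))
    return curve


@dataclass
class CascadeModel:
    stage1: MiniUNet
    stage2: MiniUNet
    roi_margin: int = 2
    roi_shape: tuple[int, int] = (48, 48)
    threshold: float = 0.5
    stack_adjacent: bool = False


@dataclass
class CascadePrediction:
    liver: Mask
    lesion: Mask
    liver_prob: np.ndarray
    lesion_prob: np.ndarray
    empty: bool = False


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndi.label(mask)
    if n <= 1:
        return mask
    sizes = ndi.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    return lab == (1 + int(np.argmax(sizes)))


def cascade_predict(model: CascadeModel, volume: Volume) -> CascadePrediction:
    """Run the full cascade: liver mask, ROI crop, lesion mask inside it."""
    batch = slices_from_volume(volume, np.zeros(volume.shape),
                               stack_adjacent=model.stack_adjacent)
    x1 = batch.inputs()
    p1 = model.stage1.predict_proba(x1)                     # (nz, H, W)
    liver_sl = p1 >= model.threshold
    if not liver_sl.any():
        empty = Mask(np.zeros(volume.shape, dtype=np.uint8), volume.spacing)
        return CascadePrediction(empty, empty,
                                 np.moveaxis(p1, 0, 2), np.zeros(volume.shape),
                                 empty=True)
    liver_vol = _largest_component(np.moveaxis(liver_sl, 0, 2))
    liver_sl = np.moveaxis(liver_vol, 2, 0)

    masked = batch.slices * liver_sl                        # stage-2 input
    roi_batch, info = crop_resample_roi(
        SliceBatch(masked, batch.labels, batch.spacing, model.stack_adjacent),
        liver_sl, margin=model.roi_margin, target_shape=model.roi_shape)
    p2_roi = model.stage2.predict_proba(roi_batch.inputs())
    p2 = info.map_back(p2_roi)
    lesion_sl = (p2 >= model.threshold) & liver_sl          # cascade constraint

    liver_mask = Mask(liver_vol.astype(np.uint8), volume.spacing)
    lesion_mask = Mask(np.moveaxis(lesion_sl, 0, 2).astype(np.uint8),
                       volume.spacing)
    return CascadePrediction(liver_mask, lesion_mask,
                             np.moveaxis(p1, 0, 2), np.moveaxis(p2, 0, 2))


def train_cascade(train_phantoms, seed: int = 0, epochs: int = 12,
                  lr: float = 2e-3, base_channels: int = 8,
                  roi_shape: tuple[int, int] = (48, 48),
                  stack_adjacent: bool = False) -> tuple[CascadeModel, dict]:
    """Train both cascade stages on phantom volumes with truth masks.

    Stage 1 learns liver-vs-background on raw slices; stage 2 learns
    lesion-vs-parenchyma on liver-masked, truth-cropped, resampled slices.
    Class weights follow the inverse pixel frequency of each stage's target.
    Returns the model plus the two loss curves.
    """
    from .core import LESION

    s1_slices, s1_labels = [], []
    s2_slices, s2_labels = [], []
    for ph in train_phantoms:
        liver = ph.truth.data > 0
        lesion = ph.truth.data == LESION
        b1 = slices_from_volume(ph.volume, liver, stack_adjacent=stack_adjacent)
        s1_slices.append(b1.slices)
        s1_labels.append(b1.labels)
        liver_sl = np.moveaxis(liver, 2, 0)
        masked = b1.slices * liver_sl
        b2_full = SliceBatch(masked, np.moveaxis(lesion, 2, 0).astype(np.uint8),
                             b1.spacing, stack_adjacent)
        b2, _ = crop_resample_roi(b2_full, liver_sl, target_shape=roi_shape)
        keep = liver_sl.any(axis=(1, 2))       # only slices containing liver
        s2_slices.append(b2.slices[keep])
        s2_labels.append(b2.labels[keep])

    batch1 = SliceBatch(np.concatenate(s1_slices), np.concatenate(s1_labels),
                        stack_adjacent=stack_adjacent)
    batch2 = SliceBatch(np.concatenate(s2_slices), np.concatenate(s2_labels),
                        stack_adjacent=stack_adjacent)

    in_ch = 3 if stack_adjacent else 1
    net1 = MiniUNet(in_channels=in_ch, base=base_channels, seed=seed)
    net2 = MiniUNet(in_channels=in_ch, base=base_channels, seed=seed + 1)
    cfg1 = BalancedLossConfig(class_weights_from_frequency(batch1.labels))
    cfg2 = BalancedLossConfig(class_weights_from_frequency(batch2.labels))
    curve1 = train_stage(net1, batch1, cfg1, epochs=epochs, lr=lr, seed=seed + 10)
    curve2 = train_stage(net2, batch2, cfg2, epochs=epochs, lr=lr, seed=seed + 11)
    model = CascadeModel(stage1=net1, stage2=net2, roi_shape=roi_shape,
                         stack_adjacent=stack_adjacent)
    return model, {"stage1_loss": curve1, "stage2_loss": curve2}
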