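"""Analytic convolutional front-end (filter-rectify-filter Gabor energy).

The visual stage emulates a cascade of simple and complex cells in early
visual cortex with two repeated-filtering layers.  Each layer applies, in
order: convolution with a quadrature pair of oriented Gabor filters
(4 orientations), an energy rectification combining the cosine and sine
phases, divisive normalization across orientations, and binomial spatial
pooling with factor-2 downsampling.  Layer 2 treats each of the 4 layer-1
channels as a fresh input, yielding 16 doubly filtered channels (VV, VH,
...).  A trained cross-channel feature-pooling layer (16 scalar weights,
fit by least squares against the normalized product of all channels)
collapses the stack to a single map per image that highlights the line
crossing and the target; the map is flattened row-major to form the
feature vector fed to the sensorimotor network.

All convolution kernels are fixed analytically; only the 16 pooling
weights are learned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.fft import next_fast_len, rfft2, irfft2
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GaborBank",
    "gabor_kernels",
    "gabor_energy",
    "divisive_normalize",
    "spatial_pool",
    "GaborFrontend",
]

_BINOMIAL = np.array([1.0, 2.0, 1.0]) / 4.0


@dataclass(frozen=True)
class GaborBank:
    """Quadrature Gabor filter bank (cosine and sine phase per orientation).

    ``orientations_deg`` label the image structure each filter prefers
    (0 = horizontal contours, 90 = vertical); the sinusoidal carrier runs
    perpendicular to that label, across the contour.  ``wavelength`` is in
    pixels; the default of 2 px (0.5 cycles per pixel, the Nyquist band)
    makes the filters band-pass on the binary raster so that filtering
    attenuates rather than amplifies smooth structure — a sub-pixel
    wavelength would alias the carrier to DC on an integer grid and turn
    the axis-aligned filters into pure low-pass Gaussians.
    """

    orientations_deg: tuple = (0.0, 45.0, 90.0, 135.0)
    size: int = 7
    sigma: float = 1.0
    wavelength: float = 2.0
    aspect: float = 2.0
    phase: float = 0.0

    @property
    def n_orientations(self) -> int:
        return len(self.orientations_deg)


def gabor_kernels(bank: GaborBank) -> tuple[np.ndarray, np.ndarray]:
    """Return (cos, sin) kernel stacks of shape (n_orient, size, size).

    x is the column offset (rightward), y the upward offset.  For a filter
    labelled theta, the carrier axis is x' = x cos(theta+90) +
    y sin(theta+90) (perpendicular to the preferred contour) and the
    envelope is compressed by the aspect ratio along y'; the cosine kernel
    is even-symmetric and the sine kernel odd-symmetric about the filter
    axis.
    """
    half = bank.size // 2
    x = np.arange(-half, half + 1, dtype=float)
    X, Y = np.meshgrid(x, -x, indexing="xy")  # row index grows downward
    cos_k, sin_k = [], []
    for deg in bank.orientations_deg:
        th = np.deg2rad(deg + 90.0)
        xr = X * np.cos(th) + Y * np.sin(th)
        yr = -X * np.sin(th) + Y * np.cos(th)
        env = np.exp(-(xr ** 2 + (bank.aspect * yr) ** 2)
                     / (2.0 * bank.sigma ** 2))
        arg = 2.0 * np.pi * xr / bank.wavelength + bank.phase
        cos_k.append(env * np.cos(arg))
        sin_k.append(env * np.sin(arg))
    return np.stack(cos_k), np.stack(sin_k)


class _LayerFFT:
    """Cached kernel rFFTs for batched zero-padded same-mode convolution.

    Works in float32: the subsequent processing is statistical (divisive
    normalization, pooling, least squares), so single precision is ample.
    """

    def __init__(self, bank: GaborBank, shape: tuple[int, int]):
        ck, sk = gabor_kernels(bank)
        h, w = shape
        kh, kw = ck.shape[-2:]
        self.pad = (next_fast_len(h + kh - 1), next_fast_len(w + kw - 1))
        self.off = ((kh - 1) // 2, (kw - 1) // 2)
        self.shape = shape
        self.cf = rfft2(ck.astype(np.float32), s=self.pad)
        self.sf = rfft2(sk.astype(np.float32), s=self.pad)

    def energy(self, imgs: np.ndarray) -> np.ndarray:
        """imgs (n, h, w) -> quadrature energy (n, n_orient, h, w)."""
        f = rfft2(np.asarray(imgs, dtype=np.float32), s=self.pad)
        c = irfft2(f[:, None] * self.cf[None], s=self.pad)
        s = irfft2(f[:, None] * self.sf[None], s=self.pad)
        e = np.sqrt(c * c + s * s)
        r0, c0 = self.off
        h, w = self.shape
        return np.ascontiguousarray(e[:, :, r0:r0 + h, c0:c0 + w])


def gabor_energy(images: np.ndarray, bank: GaborBank | None = None,
                 _fft: _LayerFFT | None = None) -> np.ndarray:
    """Complex-cell energy maps: sqrt(C_cos^2 + C_sin^2) per orientation.

    ``images`` may be (h, w) or (n, h, w); output gains an orientation
    axis: (n, n_orient, h, w).
    """
    bank = bank or GaborBank()
    imgs = np.asarray(images, dtype=np.float32)
    single = imgs.ndim == 2
    imgs = imgs[None] if single else imgs
    if imgs.ndim != 3:
        raise ValueError("images must be (h, w) or (n, h, w)")
    if _fft is None:
        _fft = _LayerFFT(bank, imgs.shape[-2:])
    e = _fft.energy(imgs)
    return e[0] if single else e


def divisive_normalize(energy: np.ndarray, eps: float = 1e-4,
                       axis: int = -3) -> np.ndarray:
    """Divide each orientation channel by the cross-orientation sum.

    Pixels whose summed energy falls below ``eps`` output zero, so empty
    image regions stay silent; elsewhere the channels form a partition of
    unity.
    """
    total = energy.sum(axis=axis, keepdims=True)
    return np.where(total > eps, energy / np.where(total > eps, total, 1.0),
                    0.0)


def spatial_pool(maps: np.ndarray) -> np.ndarray:
    """Binomial low-pass then stride-2 decimation along the last two axes.

    The 3-tap binomial kernel [1, 2, 1]/4 sums to one (constant maps are
    preserved; boundary handled by edge replication) and the decimation
    keeps even indices, so output dims are ceil(n/2).
    """
    out = ndimage.correlate1d(maps, _BINOMIAL, axis=-1, mode="nearest")
    out = ndimage.correlate1d(out, _BINOMIAL, axis=-2, mode="nearest")
    return np.ascontiguousarray(out[..., ::2, ::2])


class GaborFrontend(BaseEstimator, TransformerMixin):
    """Two-layer Gabor-energy front-end with trained feature pooling.

    ``fit`` learns the 16 cross-channel pooling weights by least squares:
    the regression target is the pixel-wise product of the 16 layer-2
    channels, normalized to a maximum of one per image (the product is
    large only where every oriented channel is active, i.e. at the line
    crossing and the target).  ``transform`` maps an (n, h, w) image stack
    to (n, d) flattened pooled feature maps with d = ceil(h/4)*ceil(w/4).

    A ``pool_variant="sigmoid"`` option replaces the single linear pooling
    with a two-stage sigmoid+linear pooling; the linear form is the
    default and the normative definition.
    """

    def __init__(self, bank: GaborBank | None = None, eps: float = 1e-4,
                 pool_variant: str = "linear", chunk_size: int = 256):
        self.bank = bank
        self.eps = eps
        self.pool_variant = pool_variant
        self.chunk_size = chunk_size

    # ---- internals -------------------------------------------------------

    def _get_bank(self) -> GaborBank:
        return self.bank or GaborBank()

    def _ffts(self, shape: tuple[int, int]):
        cache = getattr(self, "_fft_cache", None)
        if cache is None:
            cache = self._fft_cache = {}
        if shape not in cache:
            bank = self._get_bank()
            h2 = ((shape[0] + 1) // 2, (shape[1] + 1) // 2)
            cache[shape] = (_LayerFFT(bank, shape), _LayerFFT(bank, h2))
        return cache[shape]

    def layer_stacks(self, images: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray,
                                np.ndarray, np.ndarray]:
        """Per-layer maps: (E1, S1, E2, S2).

        E* are raw energy maps (pre-normalization), S* the normalized and
        pooled outputs; S2 has 16 channels = 4 orientations x 4 parents.
        """
        imgs = np.asarray(images, dtype=np.float32)
        if imgs.ndim != 3:
            raise ValueError("expected an (n, h, w) image stack")
        bank = self._get_bank()
        l1f, l2f = self._ffts(imgs.shape[-2:])
        e1 = gabor_energy(imgs, bank, _fft=l1f)           # (n, 4, h, w)
        s1 = spatial_pool(divisive_normalize(e1, self.eps))
        n, k, h2, w2 = s1.shape
        e2 = gabor_energy(s1.reshape(n * k, h2, w2), bank, _fft=l2f)
        e2 = e2.reshape(n, k, bank.n_orientations, h2, w2)
        s2 = spatial_pool(divisive_normalize(e2, self.eps, axis=-3))
        n, k, o, h4, w4 = s2.shape
        return e1, s1, e2.reshape(n, k * o, h2, w2), s2.reshape(n, k * o,
                                                                h4, w4)

    @staticmethod
    def _product_target(s2: np.ndarray) -> np.ndarray:
        """Normalized cross-channel product: the pooling training target."""
        logp = np.log(np.clip(s2, 1e-30, None)).sum(axis=1)
        prod = np.exp(logp) * np.all(s2 > 0.0, axis=1)
        mx = prod.max(axis=(-2, -1), keepdims=True)
        return np.where(mx > 0.0, prod / np.where(mx > 0.0, mx, 1.0), 0.0)

    # ---- sklearn surface -------------------------------------------------

    def fit(self, X: np.ndarray, y=None) -> "GaborFrontend":
        """Learn feature-pooling weights from a stack of training images."""
        X = np.asarray(X, dtype=np.float32)
        rows, targets = [], []
        for start in range(0, len(X), self.chunk_size):
            _, _, _, s2 = self.layer_stacks(X[start:start + self.chunk_size])
            tgt = self._product_target(s2)
            n, c = s2.shape[:2]
            rows.append(s2.transpose(0, 2, 3, 1).reshape(-1, c))
            targets.append(tgt.reshape(-1))
        A = np.concatenate(rows).astype(np.float64)
        b = np.concatenate(targets).astype(np.float64)
        w, res, *_ = np.linalg.lstsq(A, b, rcond=None)
        self.pooling_weights_ = w
        self.n_channels_ = A.shape[1]
        self.training_loss_ = float(np.mean((A @ w - b) ** 2))
        return self

    def pooled_map(self, images: np.ndarray) -> np.ndarray:
        """Feature-pooled map F = sum_i w_i S_i, shape (n, h/4, w/4)."""
        check_is_fitted(self, "pooling_weights_")
        _, _, _, s2 = self.layer_stacks(images)
        if self.pool_variant == "sigmoid":
            hidden = 1.0 / (1.0 + np.exp(-s2))
            return np.tensordot(hidden, self.pooling_weights_, axes=([1], [0]))
        return np.tensordot(s2, self.pooling_weights_, axes=([1], [0]))

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Row-major flattened pooled maps, chunked for memory."""
        X = np.asarray(X, dtype=np.float32)
        out = []
        for start in range(0, len(X), self.chunk_size):
            f = self.pooled_map(X[start:start + self.chunk_size])
            out.append(f.reshape(len(f), -1))
        return np.concatenate(out)

    def output_dim(self, n_pixels: int) -> int:
        h2 = (n_pixels + 1) // 2
        return ((h2 + 1) // 2) ** 2

    def layer_energy(self, images: np.ndarray) -> tuple[float, float]:
        """Mean rectified energy at layers 1 and 2 (decays layer to layer)."""
        e1, _, e2, _ = self.layer_stacks(images)
        return float(np.mean(e1)), float(np.mean(e2))
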