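"""Frozen convolutional feature bank for patch embeddings.

The MIL predictors operate on a low-dimensional embedding of each patch.
Following the regime in which convolutional layers are kept fixed and only
post-convolutional layers are trained, the feature extractor here is a small
four-layer convolutional filter bank whose weights are drawn once from a
seeded Gaussian and never updated.  Per-layer response statistics (mean
magnitude and standard deviation of every channel) plus first-order gray
statistics form the patch feature vector; the trainable embedding layer of
the MIL model sits on top of these frozen features.

Random convolutional filters are well suited to two-texture discrimination:
their response energy captures local gradient, scale and orientation
statistics, which is exactly what separates lesion from background textures.
A VGG-style pretrained extractor can be substituted behind the same
interface when pretrained weights are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .slide import NoisyPatchSet, SlideImage

__all__ = ["PatchFeatureExtractor", "standardize_features"]


def _conv2d(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Valid 3x3 convolution. x: (N,H,W,Cin), weights: (3,3,Cin,Cout)."""
    windows = sliding_window_view(x, (3, 3), axis=(1, 2))  # (N,H-2,W-2,Cin,3,3)
    return np.einsum("nijcxy,xyco->nijo", windows, weights, optimize=True)


def _avgpool2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    return x[:, : 2 * h2, : 2 * w2].reshape(n, h2, 2, w2, 2, c).mean(axis=(2, 4))


@dataclass
class PatchFeatureExtractor:
    """Fixed random four-conv-layer feature bank.

    Patches are converted to gray in [0, 1], resampled to ``input_size``
    square, and passed through four 3x3 convolutions (ReLU, average-pooling
    after the first two).  The feature vector concatenates the gray mean and
    standard deviation with the per-channel mean |response| and response
    standard deviation of every conv layer.
    """

    n_channels: int = 8
    input_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        rng = np.random.default_rng(np.random.SeedSequence((self.seed, 0xFEA7)))
        chans = [1] + [self.n_channels] * 4
        self.weights: list[np.ndarray] = [
            rng.normal(0.0, 1.0 / np.sqrt(9 * cin), size=(3, 3, cin, cout))
            for cin, cout in zip(chans[:-1], chans[1:])
        ]

    @property
    def n_features(self) -> int:
        return 2 + 2 * 4 * self.n_channels

    def _prepare(self, patches: np.ndarray) -> np.ndarray:
        """uint8 RGB patch stack (N,P,P,3) -> gray (N,s,s) in [0,1]."""
        gray = patches.astype(np.float64).mean(axis=-1) / 255.0
        n, p, _ = gray.shape
        s = self.input_size
        if p == s:
            return gray
        if p % s == 0:
            f = p // s
            return gray.reshape(n, s, f, s, f).mean(axis=(2, 4))
        return np.stack(
            [resize(g, (s, s), anti_aliasing=True, mode="reflect") for g in gray]
        )

    def transform_patches(self, patches: np.ndarray) -> np.ndarray:
        """Feature matrix (N, n_features) for a stack of RGB patches."""
        x = self._prepare(patches)[..., None]  # (N,s,s,1)
        feats = [x[..., 0].mean(axis=(1, 2)), x[..., 0].std(axis=(1, 2))]
        for layer, w in enumerate(self.weights):
            x = np.maximum(_conv2d(x, w), 0.0)
            feats.append(np.abs(x).mean(axis=(1, 2)))
            feats.append(x.std(axis=(1, 2)))
            if layer < 2:
                x = _avgpool2(x)
        return np.column_stack(
            [f if f.ndim == 2 else f[:, None] for f in feats]
        )

    def transform(self, slide: SlideImage, pset: NoisyPatchSet) -> np.ndarray:
        """Feature matrix for every patch of ``pset`` on ``slide``."""
        p = pset.patch_size
        stack = np.stack(
            [
                slide.pixels[r : r + p, c : c + p]
                for r, c in pset.coords
            ]
        )
        return self.transform_patches(stack)


def standardize_features(
    X: np.ndarray, stats: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Z-score features; returns (standardized X, (mean, std)).

    When ``stats`` is given (held-out inference) those moments are applied
    instead of refitting.  Constant features get unit scale.
    """
    if stats is None:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        stats = (mean, std)
    mean, std = stats
    return (X - mean) / std, stats
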