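"""Synthetic coarse annotations: controlled corruption of ground truth.

Two corruption procedures emulate how an approximate annotation differs from
the true lesion outline:

* **uniform flip** — flip an exact fraction rho1 of the truly-positive
  patches and rho0 of the truly-negative patches, chosen uniformly without
  replacement.  This gives direct control over false-positive and
  false-negative rates.
* **omit small lesions** — a geometric corruption: keep only the largest
  lesion, dilate it and take its convex hull, so small lesions are missed
  entirely and the kept boundary is coarse and convex.  A mask with a single
  lesion is instead cut in half (one half kept), so the corruption always
  introduces false negatives.

``noise_rates`` measures the realized (rho0, rho1) of any noisy labeling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label as cc_label
from skimage.morphology import convex_hull_image, dilation, disk

from .errors import ConfigError, DegenerateInputError
from .slide import BinaryMask, NoisyPatchSet

__all__ = [
    "NoiseSpec",
    "simulate_uniform_flip",
    "simulate_omit_small_lesions",
    "noise_rates",
]


@dataclass
class NoiseSpec:
    """Parameters of one synthetic-annotation corruption.

    mode: "uniform_flip" or "omit_small_lesions"; rho0/rho1: flip fractions
    for true negatives / true positives (uniform-flip mode); dilation_radius:
    disk radius in pixels (omit mode).
    """

    mode: str = "uniform_flip"
    rho0: float = 0.3
    rho1: float = 0.3
    dilation_radius: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("uniform_flip", "omit_small_lesions"):
            raise ConfigError(f"unknown noise mode {self.mode!r}")
        if not (0 <= self.rho0 < 1 and 0 <= self.rho1 < 1):
            raise ConfigError("noise rates must lie in [0, 1)")
        if self.dilation_radius < 0:
            raise ConfigError("dilation_radius must be >= 0")


def flip_labels(
    true_labels: np.ndarray, rho0: float, rho1: float, seed: int
) -> np.ndarray:
    """Flip exactly round(rho1*|P|) positives and round(rho0*|N|) negatives.

    Exact-count flipping (rather than per-label Bernoulli draws) makes the
    realized noise rates match the nominal ones up to rounding, which noise-
    sensitivity sweeps rely on.
    """
    labels = np.asarray(true_labels, dtype=np.int8)
    if not (0 <= rho0 < 1 and 0 <= rho1 < 1):
        raise ConfigError("noise rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    out = labels.copy()
    for cls, rho in ((1, rho1), (0, rho0)):
        ids = np.flatnonzero(labels == cls)
        k = int(round(rho * len(ids)))
        if k > 0:
            chosen = rng.choice(ids, size=k, replace=False)
            out[chosen] = 1 - cls
    return out


def simulate_uniform_flip(
    patches: NoisyPatchSet, rho0: float, rho1: float, seed: int
) -> NoisyPatchSet:
    """Corrupt true patch labels by exact-count uniform flipping.

    Requires ``patches.true_labels`` to be known; returns a copy whose
    ``noisy_labels`` are the flipped labels (true labels untouched).
    """
    if (patches.true_labels < 0).any():
        raise ConfigError("uniform flip requires known true labels")
    return patches.with_labels(flip_labels(patches.true_labels, rho0, rho1, seed))


def simulate_omit_small_lesions(
    gt: BinaryMask, dilation_radius: int = 0
) -> BinaryMask:
    """Geometric annotation corruption: keep-largest / dilate / convex hull.

    With two or more lesion components (8-connectivity): retain only the
    largest (by pixel area), dilate it by a disk of ``dilation_radius`` and
    return the convex hull of the result.  With exactly one component the
    mask is divided in half instead: the component is split by the line
    through its centroid perpendicular to its longest principal axis, and
    the half with more pixels is kept (ties: the half containing the first
    foreground pixel in scan order).
    """
    values = gt.values
    labeled, n_comp = cc_label(values, connectivity=2, return_num=True)
    if n_comp == 0:
        raise DegenerateInputError("ground-truth mask has no lesion component")
    if n_comp == 1:
        return BinaryMask(_half_of_component(values), role="annotation")
    areas = np.bincount(labeled.ravel())[1:]
    largest = int(np.argmax(areas)) + 1
    kept = labeled == largest
    if dilation_radius > 0:
        kept = dilation(kept, disk(dilation_radius))
    return BinaryMask(convex_hull_image(kept), role="annotation")


def _half_of_component(component: np.ndarray) -> np.ndarray:
    """Split a connected mask through its centroid, perpendicular to the
    longest principal axis; keep the larger half."""
    ys, xs = np.nonzero(component)
    pts = np.stack([ys, xs], axis=1).astype(float)
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    cov = centered.T @ centered / len(pts)
    eigvals, eigvecs = np.linalg.eigh(cov)
    axis = eigvecs[:, int(np.argmax(eigvals))]  # longest principal axis
    side = centered @ axis
    half_a = np.zeros_like(component)
    half_b = np.zeros_like(component)
    half_a[ys[side >= 0], xs[side >= 0]] = True
    half_b[ys[side < 0], xs[side < 0]] = True
    na, nb = int(half_a.sum()), int(half_b.sum())
    if na > nb:
        return half_a
    if nb > na:
        return half_b
    # tie: keep the half containing the first foreground pixel in scan order
    first = (ys[0], xs[0])
    return half_a if half_a[first] else half_b


def noise_rates(
    true_labels: np.ndarray, noisy_labels: np.ndarray
) -> tuple[float | None, float | None]:
    """Realized noise rates (rho0, rho1) of a noisy labeling.

    rho1 is the fraction of truly-positive patches labeled 0; rho0 the
    fraction of truly-negative patches labeled 1.  A rate is None when its
    class is absent from the true labels.
    """
    t = np.asarray(true_labels).astype(np.int8)
    n = np.asarray(noisy_labels).astype(np.int8)
    if t.shape != n.shape:
        raise ConfigError("label vectors differ in length")
    if not (np.isin(t, (0, 1)).all() and np.isin(n, (0, 1)).all()):
        raise ConfigError("labels must be binary")
    pos = t == 1
    neg = t == 0
    rho1 = float((n[pos] == 0).mean()) if pos.any() else None
    rho0 = float((n[neg] == 1).mean()) if neg.any() else None
    return rho0, rho1
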