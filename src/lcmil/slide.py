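"""Slide rasters, tissue detection, patch lattices and score maps.

A slide is held as a plain 8-bit RGB array; annotations and tissue masks are
boolean rasters on the same pixel frame.  The slide is latticed into square
patches on a regular stride; each patch becomes one *instance* for the MIL
machinery, labeled positive or negative by where its center pixel falls in
the coarse-annotation mask.  Per-patch risk scores are re-assembled onto the
patch grid as a low-resolution heatmap (:class:`ScoreMap`).

Conventions (fixed for reproducibility):

* coordinates are 0-based, row-major, origin at the top-left; a patch with
  top-left ``(r, c)`` covers the half-open box ``[r, r+P) x [c, c+P)``;
* the center of an even-sized patch is ``(r + P//2, c + P//2)`` — the
  lower-right of the four central pixels;
* patches that would extend past the slide edge are never emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

from .errors import AlignmentError, ConfigError, DegenerateInputError, StateError

__all__ = [
    "SlideImage",
    "BinaryMask",
    "NoisyPatchSet",
    "ScoreMap",
    "compute_tissue_mask_hsv",
    "compute_tissue_mask_rgb",
    "extract_patch_grid",
    "assign_noisy_labels",
    "assemble_score_map",
]


@dataclass
class SlideImage:
    """An 8-bit RGB slide raster.

    ``downsample`` records the factor relative to the native scan resolution
    (1 for plain rasters); ``source_id`` identifies the slide in reports.
    """

    pixels: np.ndarray
    downsample: float = 1.0
    source_id: str = "slide"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ConfigError(f"slide must be HxWx3 RGB, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ConfigError("slide pixel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class BinaryMask:
    """A boolean raster aligned to a stated frame.

    ``role`` is one of ``tissue`` / ``annotation`` / ``ground_truth`` /
    ``refined``; ``frame`` is ``"slide"`` (pixel frame) or ``"heatmap"``
    (patch-grid frame).
    """

    values: np.ndarray
    role: str = "annotation"
    frame: str = "slide"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class NoisyPatchSet:
    """The slide's full patch set S, partitioned into S_P and S_N.

    ``coords`` holds the top-left pixel coordinate of each patch (N x 2,
    row/col); ``noisy_labels`` the annotation-derived labels y_i in {0, 1}
    (-1 while unassigned); ``true_labels`` the ground-truth labels when
    known (-1 otherwise); ``scores`` the per-patch risk scores (NaN while
    unscored).
    """

    coords: np.ndarray
    patch_size: int
    stride: int
    slide_shape: tuple[int, int]
    noisy_labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    true_labels: np.ndarray = field(default=None)  # type: ignore[assignment]
    scores: np.ndarray = field(default=None)  # type: ignore[assignment]
    source_id: str = "slide"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        n = len(self.coords)
        if self.noisy_labels is None:
            self.noisy_labels = np.full(n, -1, dtype=np.int8)
        if self.true_labels is None:
            self.true_labels = np.full(n, -1, dtype=np.int8)
        if self.scores is None:
            self.scores = np.full(n, np.nan)
        self.noisy_labels = np.asarray(self.noisy_labels, dtype=np.int8)
        self.true_labels = np.asarray(self.true_labels, dtype=np.int8)
        self.scores = np.asarray(self.scores, dtype=float)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def centers(self) -> np.ndarray:
        return self.coords + self.patch_size // 2

    @property
    def positive_ids(self) -> np.ndarray:
        """Indices of S_P — patches the coarse annotation labels positive."""
        return np.flatnonzero(self.noisy_labels == 1)

    @property
    def negative_ids(self) -> np.ndarray:
        """Indices of S_N — patches the coarse annotation labels negative."""
        return np.flatnonzero(self.noisy_labels == 0)

    def extract_pixels(self, slide: SlideImage, idx: int) -> np.ndarray:
        r, c = self.coords[idx]
        p = self.patch_size
        return slide.pixels[r : r + p, c : c + p]

    def with_labels(self, noisy_labels: np.ndarray) -> "NoisyPatchSet":
        labels = np.asarray(noisy_labels, dtype=np.int8)
        if labels.shape != (len(self),):
            raise AlignmentError("label vector length does not match patch count")
        return replace(self, noisy_labels=labels)

    def with_scores(self, scores: np.ndarray) -> "NoisyPatchSet":
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (len(self),):
            raise AlignmentError("score vector length does not match patch count")
        return replace(self, scores=scores)


@dataclass
class ScoreMap:
    """Per-patch risk scores arranged on the patch grid (the heatmap).

    Cell ``(i, j)`` corresponds to the patch with top-left pixel
    ``(grid_origin[0] + i*stride, grid_origin[1] + j*stride)``.  Lattice
    positions with no extracted patch (non-tissue) hold NaN and are treated
    as score 0 downstream.
    """

    scores: np.ndarray
    stride: int
    grid_origin: tuple[int, int] = (0, 0)
    downscale: float = 1.0

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def cell_of(self, row: int, col: int) -> tuple[int, int]:
        """Grid cell of the patch with top-left pixel (row, col)."""
        return (
            (row - self.grid_origin[0]) // self.stride,
            (col - self.grid_origin[1]) // self.stride,
        )


def compute_tissue_mask_hsv(slide: SlideImage) -> BinaryMask:
    """Tissue detection by per-channel Otsu on hue and saturation.

    The RGB raster is converted to HSV; Otsu's threshold is applied to the H
    and S channels independently and the two foreground (above-threshold)
    masks are intersected.  Stained tissue is both saturated and hued
    relative to the near-white glass background, so the intersection keeps
    tissue and drops background.

    Raises :class:`DegenerateInputError` when either channel is constant
    (Otsu is undefined there).
    """
    hsv = rgb2hsv(slide.pixels)
    masks = []
    for ch in (0, 1):  # hue, saturation
        channel = hsv[..., ch]
        if np.ptp(channel) == 0:
            raise DegenerateInputError(
                f"HSV channel {ch} is constant; Otsu threshold undefined"
            )
        t = threshold_otsu(channel)
        masks.append(channel > t)
    return BinaryMask(masks[0] & masks[1], role="tissue")


def compute_tissue_mask_rgb(
    slide: SlideImage, thresholds: tuple[int, int, int] = (235, 210, 235)
) -> BinaryMask:
    """Tissue detection by strict RGB upper thresholds.

    A pixel is tissue iff R < r and G < g and B < b, excluding near-white
    background.  Default thresholds (235, 210, 235).
    """
    r, g, b = thresholds
    for t in (r, g, b):
        if not 0 <= t <= 255:
            raise ConfigError("RGB thresholds must lie in [0, 255]")
    px = slide.pixels
    mask = (px[..., 0] < r) & (px[..., 1] < g) & (px[..., 2] < b)
    return BinaryMask(mask, role="tissue")


def grid_positions(
    height: int, width: int, patch_size: int, stride: int
) -> tuple[np.ndarray, np.ndarray]:
    """Top-left row/col lattice positions of fully-contained patches."""
    rows = np.arange(0, height - patch_size + 1, stride)
    cols = np.arange(0, width - patch_size + 1, stride)
    return rows, cols


def _stride_from_overlap(patch_size: int, overlap_fraction: float) -> int:
    if not 0 <= overlap_fraction < 1:
        raise ConfigError("overlap_fraction must lie in [0, 1)")
    stride = patch_size * (1.0 - overlap_fraction)
    if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
        raise ConfigError(
            f"patch_size*(1-overlap) = {stride} is not a positive integer stride"
        )
    return int(round(stride))


def extract_patch_grid(
    slide: SlideImage,
    tissue: BinaryMask | None,
    patch_size: int,
    overlap_fraction: float = 0.0,
) -> NoisyPatchSet:
    """Lattice the slide into square patches, keeping tissue-centered ones.

    Patches are laid on a regular stride ``patch_size*(1-overlap_fraction)``
    starting at (0, 0); a patch is kept iff its center pixel is tissue
    (``tissue=None`` keeps all).  Patches extending past the slide edge are
    not emitted.  Labels are left unset.
    """
    h, w = slide.shape
    if patch_size > min(h, w):
        raise ConfigError("patch_size exceeds slide dimensions")
    stride = _stride_from_overlap(patch_size, overlap_fraction)
    if tissue is not None and tissue.shape != (h, w):
        raise AlignmentError("tissue mask shape does not match slide")
    rows, cols = grid_positions(h, w, patch_size, stride)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()], axis=1)
    if tissue is not None:
        centers = coords + patch_size // 2
        keep = tissue.values[centers[:, 0], centers[:, 1]]
        coords = coords[keep]
    return NoisyPatchSet(
        coords=coords,
        patch_size=patch_size,
        stride=stride,
        slide_shape=(h, w),
        source_id=slide.source_id,
    )


def assign_noisy_labels(grid: NoisyPatchSet, coarse: BinaryMask) -> NoisyPatchSet:
    """Label each patch by whether its center pixel lies in the coarse mask.

    Returns a new patch set with ``noisy_labels`` set (1 inside the
    annotation, 0 outside); S_P/S_N index sets follow from the labels.
    """
    if coarse.shape != grid.slide_shape:
        raise AlignmentError(
            f"coarse mask shape {coarse.shape} != slide shape {grid.slide_shape}"
        )
    centers = grid.centers
    labels = coarse.values[centers[:, 0], centers[:, 1]].astype(np.int8)
    return grid.with_labels(labels)


def rasterize_to_grid(grid: NoisyPatchSet, mask: BinaryMask) -> np.ndarray:
    """Per-patch labels of a slide-frame mask via the patch-center rule."""
    if mask.shape != grid.slide_shape:
        raise AlignmentError("mask shape does not match slide")
    centers = grid.centers
    return mask.values[centers[:, 0], centers[:, 1]].astype(np.int8)


def assemble_score_map(patches: NoisyPatchSet) -> ScoreMap:
    """Arrange per-patch scores on the stride-resolution patch grid.

    Every patch must carry a score.  Lattice cells with no patch hold NaN.
    """
    if np.isnan(patches.scores).any():
        raise StateError("cannot assemble a score map from unscored patches")
    h, w = patches.slide_shape
    p, s = patches.patch_size, patches.stride
    rows, cols = grid_positions(h, w, p, s)
    scores = np.full((len(rows), len(cols)), np.nan)
    ri = patches.coords[:, 0] // s
    ci = patches.coords[:, 1] // s
    scores[ri, ci] = patches.scores
    return ScoreMap(scores=scores, stride=s, grid_origin=(0, 0), downscale=float(s))
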