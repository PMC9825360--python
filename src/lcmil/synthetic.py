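"""Synthetic two-texture slides with exact ground-truth lesion masks.

Real stained tissue slides are Gigapixel images; the generator here emulates
the property the refinement method actually exploits — lesion regions whose
local texture statistics (first/second order gray-level statistics, optional
periodic structure) differ from the surrounding background — at a desk-scale
raster size.  Lesions are unions of smooth random blobs (thresholded smoothed
Gaussian noise around random centers), so boundaries are irregular as in real
annotations, and the ground-truth mask is exactly the lesion support.

Everything is driven by a single integer seed, so fixtures are fully
reproducible and generated at test time rather than stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, DegenerateInputError
from .slide import BinaryMask, SlideImage

__all__ = [
    "TextureParams",
    "SyntheticSlideSpec",
    "generate_synthetic_slide",
    "lesion_area_fraction",
]


@dataclass
class TextureParams:
    """A stationary gray-level texture model.

    base_gray: mean gray level in [0, 255]; noise_scale: s.d. of the Gaussian
    noise field before smoothing; smooth_sigma: Gaussian smoothing scale in
    pixels (controls correlation length); stripe_freq: optional sinusoidal
    stripe frequency in cycles/pixel (0 disables); stripe_amp: stripe
    amplitude in gray levels.
    """

    base_gray: float = 200.0
    noise_scale: float = 40.0
    smooth_sigma: float = 1.5
    stripe_freq: float = 0.0
    stripe_amp: float = 0.0

    def render(self, shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
        noise = rng.normal(0.0, self.noise_scale, size=shape)
        if self.smooth_sigma > 0:
            noise = gaussian_filter(noise, self.smooth_sigma)
            # restore the requested marginal s.d. after smoothing
            sd = noise.std()
            if sd > 0:
                noise *= self.noise_scale / (sd * 2.0)
        tex = self.base_gray + noise
        if self.stripe_freq > 0 and self.stripe_amp > 0:
            rr = np.arange(shape[0])[:, None]
            cc = np.arange(shape[1])[None, :]
            phase = rng.uniform(0, 2 * np.pi)
            tex = tex + self.stripe_amp * np.sin(
                2 * np.pi * self.stripe_freq * (rr + cc) + phase
            )
        return tex

    def differs_from(self, other: "TextureParams") -> bool:
        return any(
            getattr(self, f) != getattr(other, f)
            for f in ("base_gray", "noise_scale", "smooth_sigma", "stripe_freq", "stripe_amp")
        )


def _default_background() -> TextureParams:
    return TextureParams(base_gray=205.0, noise_scale=25.0, smooth_sigma=1.5)


def _default_lesion() -> TextureParams:
    return TextureParams(
        base_gray=150.0, noise_scale=35.0, smooth_sigma=1.0,
        stripe_freq=0.08, stripe_amp=10.0,
    )


@dataclass
class SyntheticSlideSpec:
    """Parameters of one synthetic slide.

    Defaults give a 2048x2048 slide with 2-3 lesions whose area covers
    between 10% and 90% of the tissue (enforced by rejection sampling,
    mirroring the inclusion rule that a refinable slide needs a workable
    balance of positive and negative patches).
    """

    height: int = 2048
    width: int = 2048
    n_lesions: int = 3
    lesion_radius_range: tuple[float, float] = (180.0, 320.0)
    background_texture: TextureParams = field(default_factory=_default_background)
    lesion_texture: TextureParams = field(default_factory=_default_lesion)
    lesion_fraction_bounds: tuple[float, float] = (0.10, 0.90)
    max_rejections: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ConfigError("slide dimensions must be positive")
        lo, hi = self.lesion_radius_range
        if not 0 < lo <= hi:
            raise ConfigError("lesion_radius_range must be positive and ordered")
        if self.n_lesions > 0 and 2 * hi > min(self.height, self.width):
            raise ConfigError("lesion radius too large for the slide")
        if not self.background_texture.differs_from(self.lesion_texture):
            raise ConfigError("lesion and background textures must differ")


def _lesion_blob(
    shape: tuple[int, int],
    center: tuple[float, float],
    radius: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One smooth random blob of roughly the given radius around center."""
    rr = np.arange(shape[0])[:, None]
    cc = np.arange(shape[1])[None, :]
    dist = np.hypot(rr - center[0], cc - center[1])
    # radial falloff perturbed by smoothed noise -> irregular boundary
    bump = gaussian_filter(rng.normal(0, 1, size=shape), radius / 4.0)
    sd = bump.std()
    if sd > 0:
        bump /= sd
    return (dist / radius + 0.35 * bump) < 1.0


def _draw_mask(spec: SyntheticSlideSpec, rng: np.random.Generator) -> np.ndarray:
    shape = (spec.height, spec.width)
    mask = np.zeros(shape, dtype=bool)
    lo, hi = spec.lesion_radius_range
    margin = hi
    for _ in range(spec.n_lesions):
        radius = rng.uniform(lo, hi)
        cy = rng.uniform(margin, spec.height - margin)
        cx = rng.uniform(margin, spec.width - margin)
        mask |= _lesion_blob(shape, (cy, cx), radius, rng)
    return mask


def generate_synthetic_slide(
    spec: SyntheticSlideSpec,
) -> tuple[SlideImage, BinaryMask]:
    """Render a synthetic slide and its exact ground-truth lesion mask.

    The lesion support is a union of smooth random blobs; lesion and
    background pixels are drawn from their respective texture models.  The
    lesion-area fraction is forced into ``spec.lesion_fraction_bounds`` by
    re-drawing the geometry (fresh sub-seed) up to ``max_rejections`` times.
    Fully determined by ``spec.seed``.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    mask = np.zeros((spec.height, spec.width), dtype=bool)
    if spec.n_lesions > 0:
        lo_f, hi_f = spec.lesion_fraction_bounds
        for child in ss.spawn(spec.max_rejections):
            rng = np.random.default_rng(child)
            mask = _draw_mask(spec, rng)
            frac = mask.mean()
            if lo_f <= frac <= hi_f:
                break
    tex_rng = np.random.default_rng(ss.spawn(spec.max_rejections + 1)[-1])
    bg = spec.background_texture.render((spec.height, spec.width), tex_rng)
    fg = spec.lesion_texture.render((spec.height, spec.width), tex_rng)
    gray = np.where(mask, fg, bg)
    gray = np.clip(gray, 0, 255).astype(np.uint8)
    pixels = np.stack([gray, gray, gray], axis=-1)
    slide = SlideImage(pixels=pixels, source_id=f"synthetic-{spec.seed}")
    return slide, BinaryMask(mask, role="ground_truth")


def lesion_area_fraction(
    mask: BinaryMask, tissue: BinaryMask | None = None
) -> float:
    """Lesion pixels over tissue pixels (whole raster when no tissue mask).

    Used to enforce the 10%-90% lesion-area inclusion window on generated
    fixtures; callers flag fixtures falling outside it.
    """
    lesion = mask.values
    if tissue is not None:
        if tissue.shape != mask.shape:
            raise DegenerateInputError("tissue and lesion masks differ in shape")
        denom = int(tissue.values.sum())
        numer = int((lesion & tissue.values).sum())
    else:
        denom = lesion.size
        numer = int(lesion.sum())
    if denom == 0:
        raise DegenerateInputError("empty tissue region")
    return numer / denom
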