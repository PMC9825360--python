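"""End-to-end coarse-annotation refinement.

The trained MIL predictor is deployed on *singleton bags*: every patch is
scored as a bag of one instance, so the (calibrated) bag score becomes an
instance-level risk score with no bag/instance gap.  The resulting heatmap
is binarized at a threshold v0 obtained by Otsu's method on the scores of
the originally-positive patches only — the population whose label quality
the coarse annotation is meant to guarantee — and cleaned with small-object
removal and small-hole filling on the heatmap grid.  The cleaned binary map
is the refined annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import remove_small_holes, remove_small_objects

from .errors import ConfigError, DegenerateInputError, InfeasibleError
from .features import PatchFeatureExtractor, standardize_features
from .metrics import MetricsReport, confusion_counts, metrics_from_counts
from .mil import MILBag, MILModel, TrainConfig, build_bags, fit_mil
from .slide import (
    BinaryMask,
    NoisyPatchSet,
    ScoreMap,
    SlideImage,
    assemble_score_map,
    assign_noisy_labels,
    compute_tissue_mask_hsv,
    compute_tissue_mask_rgb,
    extract_patch_grid,
    rasterize_to_grid,
)

__all__ = [
    "RefinementConfig",
    "RefinementResult",
    "score_all_patches",
    "otsu_threshold",
    "binarize_and_clean",
    "refine",
    "build_multislide_bags",
    "fit_multislide",
]

OTSU_BINS = 256


@dataclass
class RefinementConfig:
    """Post-processing settings for turning a heatmap into a refined mask.

    Sizes are in heatmap-grid pixels.  ``threshold_mode`` is
    ``"otsu_on_positives"`` (v0 from Otsu on S_P scores) or ``"fixed"``
    (use ``fixed_threshold``).
    """

    min_object_px: int = 100
    min_hole_px: int = 100
    threshold_mode: str = "otsu_on_positives"
    fixed_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.min_object_px < 0 or self.min_hole_px < 0:
            raise ConfigError("morphology sizes must be >= 0")
        if self.threshold_mode not in ("otsu_on_positives", "fixed"):
            raise ConfigError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed":
            if self.fixed_threshold is None or not 0 <= self.fixed_threshold <= 1:
                raise ConfigError("fixed threshold_mode needs fixed_threshold in [0,1]")


def score_all_patches(
    model: MILModel, pset: NoisyPatchSet, features: np.ndarray
) -> NoisyPatchSet:
    """Score every patch as a singleton bag.

    Each patch's risk score is the bag score of the one-instance bag holding
    it, so instance inference reuses the bag-scoring code path verbatim.
    """
    scores = np.array(
        [model.bag_score(features[i : i + 1]) for i in range(len(pset))]
    )
    return pset.with_scores(scores)


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram of scores on [0, 1].

    Maximizes the between-class variance over all 255 cut points; ties go to
    the lowest bin.  Returns the midpoint of the maximizing cut bin.
    Requires at least two distinct values.
    """
    v = np.asarray(values, dtype=float).ravel()
    if len(v) < 2 or np.ptp(v) == 0:
        raise DegenerateInputError("Otsu threshold needs >= 2 distinct values")
    counts, edges = np.histogram(v, bins=OTSU_BINS, range=(0.0, 1.0))
    centers = (edges[:-1] + edges[1:]) / 2.0
    w = counts.astype(float)
    total = w.sum()
    cum_w = np.cumsum(w)
    cum_mu = np.cumsum(w * centers)
    # cut after bin k: lower class = bins [0..k], upper = bins [k+1..]
    w0 = cum_w[:-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.divide(cum_mu[:-1], w0, out=np.zeros(OTSU_BINS - 1), where=w0 > 0)
    mu1 = np.divide(
        cum_mu[-1] - cum_mu[:-1], w1, out=np.zeros(OTSU_BINS - 1), where=w1 > 0
    )
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    k = int(np.argmax(sigma_b))  # first maximizer -> lowest bin on ties
    # threshold = center of the first upper-class bin, consistent with the
    # downstream `score >= v0` rule (lower-class values fall strictly below)
    return float(centers[k + 1])


def binarize_and_clean(
    score_map: ScoreMap, v0: float, cfg: RefinementConfig | None = None
) -> BinaryMask:
    """Threshold the heatmap at v0 and clean with morphology.

    Foreground is ``score >= v0`` (missing cells count as 0); connected
    objects smaller than ``min_object_px`` are removed, then background
    holes smaller than ``min_hole_px`` are filled, both at 8-connectivity
    and measured in heatmap-grid pixels.
    """
    cfg = cfg or RefinementConfig()
    with np.errstate(invalid="ignore"):
        mask = score_map.scores >= v0  # NaN compares False -> treated as 0
    # max_size is inclusive: removing/filling areas <= size-1 means "< size"
    if cfg.min_object_px > 1:
        mask = remove_small_objects(mask, max_size=cfg.min_object_px - 1, connectivity=2)
    if cfg.min_hole_px > 1:
        mask = remove_small_holes(mask, max_size=cfg.min_hole_px - 1, connectivity=2)
    return BinaryMask(mask, role="refined", frame="heatmap")


def _threshold_from_scores(
    pset: NoisyPatchSet, cfg: RefinementConfig
) -> float:
    if cfg.threshold_mode == "fixed":
        return float(cfg.fixed_threshold)
    pos = pset.positive_ids
    if len(pos) == 0:
        raise InfeasibleError("no originally-positive patches to compute v0 from")
    return otsu_threshold(pset.scores[pos])


def _tissue_mask(slide: SlideImage, tissue) -> BinaryMask | None:
    if tissue is None or tissue == "none":
        return None
    if isinstance(tissue, BinaryMask):
        return tissue
    if tissue == "hsv":
        return compute_tissue_mask_hsv(slide)
    if tissue == "rgb":
        return compute_tissue_mask_rgb(slide)
    raise ConfigError(f"unknown tissue option {tissue!r}")


@dataclass
class RefinementResult:
    """Everything produced by one refinement run.

    ``refined_mask`` lives on the heatmap grid; metrics (when ground truth
    is available) compare coarse and refined patch labels against
    ground-truth patch labels on that same grid, rasterized by the
    patch-center rule so before/after are judged on identical supports.
    """

    refined_mask: BinaryMask
    score_map: ScoreMap
    v0: float
    patches: NoisyPatchSet
    refined_labels: np.ndarray
    coarse_labels: np.ndarray
    gt_labels: np.ndarray | None
    model: MILModel
    train_config: TrainConfig
    refine_config: RefinementConfig
    method: str = "lc-mil-atten"
    metrics: dict[str, MetricsReport] = field(default_factory=dict)

    def compute_metrics(self, condition: str = "") -> dict[str, MetricsReport]:
        if self.gt_labels is None:
            raise ConfigError("no ground truth attached; metrics unavailable")
        out = {}
        for name, labels in (("coarse", self.coarse_labels), (self.method, self.refined_labels)):
            counts = confusion_counts(labels, self.gt_labels)
            out[name] = metrics_from_counts(
                *counts,
                slide_id=self.patches.source_id,
                method=name,
                condition=condition,
            )
        self.metrics = out
        return out


def _labels_from_mask(pset: NoisyPatchSet, mask: BinaryMask, smap: ScoreMap) -> np.ndarray:
    ri = pset.coords[:, 0] // smap.stride
    ci = pset.coords[:, 1] // smap.stride
    return mask.values[ri, ci].astype(np.int8)


def refine(
    slide: SlideImage,
    coarse: BinaryMask | np.ndarray,
    patch_size: int = 64,
    overlap: float = 0.0,
    tissue="none",
    train_cfg: TrainConfig | None = None,
    refine_cfg: RefinementConfig | None = None,
    variant: str = "attention",
    ground_truth: BinaryMask | None = None,
    extractor: PatchFeatureExtractor | None = None,
) -> RefinementResult:
    """Run the full refinement pipeline on one slide.

    tissue mask -> patch grid -> noisy labels from the coarse mask -> MIL
    bags -> training -> singleton-bag scoring -> Otsu v0 on S_P scores ->
    binarize + morphology.  ``coarse`` may be a slide-frame mask or a
    per-patch label vector (when the corruption was applied at patch level).
    Fully seeded through ``train_cfg.seed``.
    """
    train_cfg = train_cfg or TrainConfig()
    refine_cfg = refine_cfg or RefinementConfig()
    pset = extract_patch_grid(slide, _tissue_mask(slide, tissue), patch_size, overlap)
    if isinstance(coarse, BinaryMask):
        pset = assign_noisy_labels(pset, coarse)
    else:
        pset = pset.with_labels(np.asarray(coarse, dtype=np.int8))
    if ground_truth is not None:
        gt_labels = rasterize_to_grid(pset, ground_truth)
    else:
        gt_labels = None
    extractor = extractor or PatchFeatureExtractor(seed=train_cfg.seed)
    raw = extractor.transform(slide, pset)
    X, stats = standardize_features(raw)
    bags = build_bags(
        pset, train_cfg.n_bags, train_cfg.bag_size, train_cfg.pos_fraction, train_cfg.seed
    )
    model = fit_mil(bags, {0: X}, train_cfg, variant, feature_stats=stats)
    pset = score_all_patches(model, pset, X)
    smap = assemble_score_map(pset)
    v0 = _threshold_from_scores(pset, refine_cfg)
    refined = binarize_and_clean(smap, v0, refine_cfg)
    result = RefinementResult(
        refined_mask=refined,
        score_map=smap,
        v0=v0,
        patches=pset,
        refined_labels=_labels_from_mask(pset, refined, smap),
        coarse_labels=pset.noisy_labels.copy(),
        gt_labels=gt_labels,
        model=model,
        train_config=train_cfg,
        refine_config=refine_cfg,
        method="lc-mil-atten" if variant == "attention" else "lc-mil-minet",
    )
    if gt_labels is not None:
        result.compute_metrics()
    return result


def build_multislide_bags(
    psets: list[NoisyPatchSet], cfg: TrainConfig
) -> list[MILBag]:
    """Build bags per slide and pool them into one shuffled MIL dataset.

    Bags never mix instances across slides; ``cfg.n_bags`` bags are built
    from *each* slide.  A slide with an empty pool is skipped with a
    warning.
    """
    all_bags: list[MILBag] = []
    for sid, pset in enumerate(psets):
        try:
            all_bags.extend(
                build_bags(
                    pset, cfg.n_bags, cfg.bag_size, cfg.pos_fraction,
                    seed=cfg.seed, slide_id=sid,
                )
            )
        except InfeasibleError as exc:
            warnings.warn(f"slide {sid} skipped in bag building: {exc}")
    if not all_bags:
        raise InfeasibleError("no slide yielded any bags")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x5F)))
    rng.shuffle(all_bags)
    return all_bags


def fit_multislide(
    slides: list[SlideImage],
    psets: list[NoisyPatchSet],
    cfg: TrainConfig,
    variant: str = "attention",
    extractor: PatchFeatureExtractor | None = None,
) -> MILModel:
    """Train one MIL model on bags pooled from several slides.

    Feature standardization moments are fit on the concatenated training
    features and stored in the model, so a held-out slide can be scored
    without its labels via :func:`score_held_out`.
    """
    extractor = extractor or PatchFeatureExtractor(seed=cfg.seed)
    raws = [extractor.transform(s, p) for s, p in zip(slides, psets)]
    _, stats = standardize_features(np.vstack(raws))
    features = {
        sid: standardize_features(r, stats)[0] for sid, r in enumerate(raws)
    }
    bags = build_multislide_bags(psets, cfg)
    model = fit_mil(bags, features, cfg, variant, feature_stats=stats)
    model.extractor = extractor  # type: ignore[attr-defined]
    return model


def score_held_out(
    model: MILModel,
    slide: SlideImage,
    pset: NoisyPatchSet,
    extractor: PatchFeatureExtractor,
) -> NoisyPatchSet:
    """Score a new slide's patches with a model trained on other slides."""
    raw = extractor.transform(slide, pset)
    X, _ = standardize_features(raw, model.feature_stats)
    return score_all_patches(model, pset, X)
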