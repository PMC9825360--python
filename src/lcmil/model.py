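"""Model/Results front end for annotation refinement.

``LabelCleaningMIL`` is the user-facing entry point: construct it from a
slide and its coarse-annotation mask, call :meth:`fit`, and read the refined
mask, score map and metrics off the returned :class:`RefinementResults`.
The baselines are exposed through the same interface via ``method=``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .baselines import DkNNConfig, RankPruneConfig, dknn_relabel, rank_prune_refine
from .errors import ConfigError
from .features import PatchFeatureExtractor, standardize_features
from .metrics import MetricsReport, confusion_counts, metrics_from_counts
from .mil import TrainConfig
from .refinement import (
    RefinementConfig,
    RefinementResult,
    binarize_and_clean,
    otsu_threshold,
    refine,
)
from .slide import (
    BinaryMask,
    SlideImage,
    assemble_score_map,
    assign_noisy_labels,
    extract_patch_grid,
    rasterize_to_grid,
)

__all__ = ["LabelCleaningMIL", "RefinementResults"]

_METHODS = ("lc-mil-atten", "lc-mil-minet", "dknn", "rank-pruning")


class LabelCleaningMIL:
    """Refine a coarse lesion annotation on a single slide.

    Parameters
    ----------
    slide : SlideImage or HxWx3 uint8 array
        The slide raster.
    coarse : BinaryMask or boolean array
        Coarse annotation aligned to the slide frame.
    patch_size, overlap : patch lattice geometry.
    tissue : None | "hsv" | "rgb" | BinaryMask
        Tissue detection method (None keeps every lattice patch).
    method : one of "lc-mil-atten", "lc-mil-minet", "dknn", "rank-pruning".
    ground_truth : optional BinaryMask for evaluation.
    """

    def __init__(
        self,
        slide,
        coarse,
        patch_size: int = 64,
        overlap: float = 0.0,
        tissue=None,
        method: str = "lc-mil-atten",
        ground_truth: BinaryMask | None = None,
    ):
        if method not in _METHODS:
            raise ConfigError(f"method must be one of {_METHODS}")
        self.slide = slide if isinstance(slide, SlideImage) else SlideImage(np.asarray(slide))
        self.coarse = coarse if isinstance(coarse, BinaryMask) else BinaryMask(np.asarray(coarse))
        self.patch_size = patch_size
        self.overlap = overlap
        self.tissue = tissue
        self.method = method
        self.ground_truth = ground_truth

    @classmethod
    def from_files(cls, slide_path, coarse_path, ground_truth_path=None, **kwargs):
        from .fileio import read_mask_png, read_slide_png

        gt = read_mask_png(ground_truth_path, role="ground_truth") if ground_truth_path else None
        return cls(
            read_slide_png(slide_path),
            read_mask_png(coarse_path, role="annotation"),
            ground_truth=gt,
            **kwargs,
        )

    def fit(
        self,
        train_config: TrainConfig | None = None,
        refine_config: RefinementConfig | None = None,
        seed: int | None = None,
        dknn_config: DkNNConfig | None = None,
        rank_prune_config: RankPruneConfig | None = None,
    ) -> "RefinementResults":
        """Run the selected refinement method and return its results."""
        train_config = train_config or TrainConfig()
        if seed is not None:
            train_config = TrainConfig(**{**train_config.__dict__, "seed": seed})
        refine_config = refine_config or RefinementConfig()
        if self.method in ("lc-mil-atten", "lc-mil-minet"):
            variant = "attention" if self.method == "lc-mil-atten" else "minet"
            result = refine(
                self.slide, self.coarse, self.patch_size, self.overlap,
                self.tissue, train_config, refine_config, variant,
                ground_truth=self.ground_truth,
            )
            return RefinementResults(self, result)
        result = self._fit_baseline(train_config, refine_config, dknn_config, rank_prune_config)
        return RefinementResults(self, result)

    def _fit_baseline(self, train_config, refine_config, dknn_config, rank_prune_config):
        from .refinement import _labels_from_mask, _tissue_mask

        pset = extract_patch_grid(
            self.slide, _tissue_mask(self.slide, self.tissue), self.patch_size, self.overlap
        )
        pset = assign_noisy_labels(pset, self.coarse)
        gt_labels = (
            rasterize_to_grid(pset, self.ground_truth) if self.ground_truth is not None else None
        )
        extractor = PatchFeatureExtractor(seed=train_config.seed)
        X, stats = standardize_features(extractor.transform(self.slide, pset))
        if self.method == "dknn":
            cfg = dknn_config or DkNNConfig()
            relabeled = dknn_relabel(X, pset.noisy_labels, cfg.k)
            # binary output: the map bypasses Otsu and only gets morphology
            pset = pset.with_scores(relabeled.astype(float))
            smap = assemble_score_map(pset)
            v0 = 0.5
        else:
            cfg = rank_prune_config or RankPruneConfig(seed=train_config.seed)
            scores, _ = rank_prune_refine(X, pset.noisy_labels, cfg)
            pset = pset.with_scores(scores)
            smap = assemble_score_map(pset)
            if refine_config.threshold_mode == "fixed":
                v0 = float(refine_config.fixed_threshold)
            else:
                v0 = otsu_threshold(pset.scores[pset.positive_ids])
        refined = binarize_and_clean(smap, v0, refine_config)
        result = RefinementResult(
            refined_mask=refined,
            score_map=smap,
            v0=v0,
            patches=pset,
            refined_labels=_labels_from_mask(pset, refined, smap),
            coarse_labels=pset.noisy_labels.copy(),
            gt_labels=gt_labels,
            model=None,  # type: ignore[arg-type]
            train_config=train_config,
            refine_config=refine_config,
            method=self.method,
        )
        if gt_labels is not None:
            result.compute_metrics()
        return result


class RefinementResults:
    """Results wrapper: refined mask, heatmap, threshold and diagnostics."""

    def __init__(self, model: LabelCleaningMIL, result: RefinementResult):
        self.model = model
        self._result = result

    @property
    def refined_mask(self) -> BinaryMask:
        return self._result.refined_mask

    @property
    def score_map(self):
        return self._result.score_map

    @property
    def v0(self) -> float:
        return self._result.v0

    @property
    def patches(self):
        return self._result.patches

    @property
    def metrics(self) -> dict[str, MetricsReport]:
        return self._result.metrics

    @property
    def f1_improvement(self) -> float:
        """F1(refined) - F1(coarse) on the heatmap grid."""
        m = self._result.metrics
        if not m:
            raise ConfigError("ground truth was not supplied; no metrics")
        return m[self._result.method].f1 - m["coarse"].f1

    def summary(self) -> str:
        """Plain-text comparison of coarse vs refined patch labels."""
        r = self._result
        lines = [
            "Label-cleaning refinement results",
            "=" * 46,
            f"slide:          {r.patches.source_id}",
            f"method:         {r.method}",
            f"patches:        {len(r.patches)} "
            f"(|S_P|={len(r.patches.positive_ids)}, |S_N|={len(r.patches.negative_ids)})",
            f"patch size:     {r.patches.patch_size}px, stride {r.patches.stride}px",
            f"threshold v0:   {r.v0:.4f}",
        ]
        if r.metrics:
            df = self.metrics_frame()
            lines += ["", df.to_string(float_format=lambda x: f"{x:.3f}")]
        return "\n".join(lines)

    def metrics_frame(self) -> pd.DataFrame:
        """Coarse vs refined metrics as a tidy DataFrame."""
        rows = []
        for name, rep in self._result.metrics.items():
            d = rep.to_dict()
            d["mask"] = name
            rows.append(d)
        cols = ["mask", "tp", "fp", "fn", "tn", "ppv", "tpr", "tnr", "npv", "f1", "iou"]
        return pd.DataFrame(rows)[cols].set_index("mask")

    def evaluate(self, ground_truth: BinaryMask) -> dict[str, MetricsReport]:
        """Attach ground truth after the fact and compute metrics."""
        r = self._result
        r.gt_labels = rasterize_to_grid(r.patches, ground_truth)
        return r.compute_metrics()

    def plot_heatmap(self, ax=None):
        """Risk-score heatmap with the refined contour overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = self._result
        im = ax.imshow(np.nan_to_num(r.score_map.scores), vmin=0, vmax=1, cmap="inferno")
        ax.contour(r.refined_mask.values, levels=[0.5], colors="cyan", linewidths=1)
        ax.set_title(f"{r.method}: risk scores and refined contour")
        plt.colorbar(im, ax=ax, label="risk score")
        return ax
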