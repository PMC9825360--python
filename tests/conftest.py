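import dataclasses

import numpy as np
import pytest

from lcmil import (
    PatchFeatureExtractor,
    SyntheticSlideSpec,
    TrainConfig,
    extract_patch_grid,
    generate_synthetic_slide,
    rasterize_to_grid,
    standardize_features,
    train,
)
from lcmil.noise import flip_labels


SMALL_SPEC = SyntheticSlideSpec(
    height=512, width=512, n_lesions=2, lesion_radius_range=(60, 100), seed=11
)


@pytest.fixture(scope="session")
def small_slide():
    """A 512x512 two-lesion synthetic slide with ground truth."""
    return generate_synthetic_slide(SMALL_SPEC)


@pytest.fixture(scope="session")
def labeled_patches(small_slide):
    """32-px patch grid with true labels and 30%/30% flipped noisy labels."""
    slide, gt = small_slide
    pset = extract_patch_grid(slide, None, 32)
    true_labels = rasterize_to_grid(pset, gt)
    noisy = flip_labels(true_labels, 0.3, 0.3, seed=7)
    return dataclasses.replace(pset.with_labels(noisy), true_labels=true_labels)


@pytest.fixture(scope="session")
def patch_features(small_slide, labeled_patches):
    slide, _ = small_slide
    X, stats = standardize_features(
        PatchFeatureExtractor(seed=0).transform(slide, labeled_patches)
    )
    return X


@pytest.fixture(scope="session")
def trained_attention(labeled_patches, patch_features):
    cfg = TrainConfig(n_bags=300, bag_size=10, seed=3)
    return train(labeled_patches, patch_features, cfg, variant="attention")


@pytest.fixture(scope="session")
def trained_minet(labeled_patches, patch_features):
    cfg = TrainConfig(n_bags=300, bag_size=10, seed=3)
    return train(labeled_patches, patch_features, cfg, variant="minet")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
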