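# Methods

## Problem setting

A pathologist's coarse outline of lesion tissue on a slide image induces a
label for every patch of the slide: positive if the patch center falls inside
the outline, negative otherwise. Because the outline is approximate, a
fraction ρ₁ of truly-lesion patches is labeled negative and a fraction ρ₀ of
truly-background patches is labeled positive. Refining the annotation means
identifying and correcting these mislabeled patches using *only* the slide
itself — no external training data, no clean reference labels.

## The label-cleaning MIL model

The slide's patch set S is partitioned by the coarse annotation into pools
S_P (labeled positive) and S_N (labeled negative). The key assumption is
that the *majority* of each pool is correctly labeled. Bags of n_j patches
drawn i.i.d. with replacement from a single pool therefore carry a far
cleaner label than any individual patch: a bag is labeled Y_j = 1 if drawn
from S_P and Y_j = 0 if drawn from S_N. Any number M of such bags can be
resampled from one slide.

Two bag predictors are implemented:

* **attention** — instance embeddings h_ij are pooled with learnable gated
  softmax attention, w_ij ∝ exp(W tanh(V h_ij)), z_j = Σᵢ w_ij h_ij, and a
  linear classifier scores the bag, P_j = σ(⟨g, z_j⟩);
* **mi-Net** — the bag score is the mean of per-instance classifier outputs,
  P_j = (1/n_j) Σᵢ σ(⟨g, h_ij⟩).

Training minimizes the focal loss
L = −(Y_j (1−P_j)^γ log P_j + (1−Y_j) P_j^γ log(1−P_j)), with γ = 5 while
the predicted positive probability lies in [0, 0.2) and γ = 3 on [0.2, 1].
The focusing term down-weights easy bags and keeps the predicted
probabilities calibrated, which matters because inference consumes the raw
probabilities. The γ switch reads the current predicted P_j and is treated
as a constant in the gradient. Probabilities inside logarithms are clamped
to [1e−7, 1−1e−7].

**Inference by singleton bags.** Once trained, every patch is scored as a
bag of one instance. With one instance the attention weight is identically
1, so the bag score reduces exactly to the instance score
p̂ᵢ = σ(⟨g, f(xᵢ)⟩): there is no gap between bag-level and instance-level
prediction. The per-patch scores form a heatmap on the patch grid.

**Post-processing.** The heatmap is binarized at v₀, the Otsu threshold of
the scores of *originally positive* patches only ({p̂ᵢ : xᵢ ∈ S_P}) — the
population whose label quality the annotation nominally guarantees. Otsu
runs on a 256-equal-width-bin histogram over [0, 1]; ties pick the lowest
cut; the returned threshold is the center of the first upper-class bin so
that the downstream `score ≥ v₀` rule separates the two classes. Connected
foreground objects smaller than `min_object_px` are then removed and
background holes smaller than `min_hole_px` filled (8-connectivity, sizes in
heatmap-grid pixels). The cleaned binary map is the refined annotation.

## Feature extraction and training regime

Patch embeddings sit on top of a frozen convolutional feature bank: patches
are converted to gray, resampled to 32×32, and passed through four 3×3
convolution layers (8 channels, ReLU, average pooling after the first two)
whose weights are drawn once from a seeded Gaussian and never updated.
Per-layer response statistics (mean |response| and standard deviation per
channel) plus first-order gray statistics give a 66-dimensional feature
vector, z-scored across the slide's patches. Only the post-convolutional
parameters train: the embedding layer h = tanh(Aφ + b) (d_h = 128), the
attention parameters V (d_a = 64 × d_h) and W, and the classifier g.
Gradients are derived analytically and applied with Adam, one step per bag,
with the learning rate halved every 100 bags. A 16-layer VGG-style
pretrained extractor can be substituted behind the same interface when
pretrained weights are available; with such an extractor the published
setting used an initial learning rate of 5×10⁻⁵. For the from-scratch
random-feature head shipped here that rate cannot move the parameters
appreciably within ~10³ steps; the package default is lr₀ = 0.002, chosen
as the largest rate at which attention training was observed to be stable
across slides (at 0.01 the attention variant occasionally converges to a
degenerate solution with inverted instance scores).

All randomness (bag sampling, parameter initialization, bag order, slide
synthesis, label flipping) derives from named `numpy` SeedSequence streams
spawned from one user seed, so every run is exactly repeatable.

## Baselines

* **DkNN** flags patches whose label disagrees with the majority label of
  their k nearest neighbors (Euclidean, in the same frozen feature space;
  self excluded; k = 10 by default) and relabels flagged patches by majority
  vote among their k nearest *trusted* patches. Ties at even k keep the
  original label — the conservative choice. The output is already binary,
  so it skips the Otsu step and receives only the morphology cleanup.
* **Rank Pruning** fits a small MLP head (one 16-unit hidden layer) on the
  frozen features with 3-fold stratified cross-validation to obtain
  out-of-fold scores, prunes labeled negatives scoring above the mean score
  of labeled positives and labeled positives scoring below the mean score of
  labeled negatives, retrains on the remainder, and emits the retrained
  head's scores as a heatmap post-processed identically to the MIL methods.

## Synthetic slides and noise models

The generator emulates the one property the method exploits: lesion regions
whose local texture statistics differ from background. Textures are
parameterized Gaussian noise fields (base gray level, marginal noise scale,
smoothing scale) with optional sinusoidal stripes; lesions are unions of
smooth random blobs (radial falloff perturbed by smoothed noise), so
boundaries are irregular. The default slide is 2048×2048 with 2–3 lesions
of radius 180–320 px; rejection sampling forces the lesion-area fraction
into [0.10, 0.90], the inclusion window within which a single slide has
enough patches of both classes to learn from. Background (base gray 205,
noise 25) and lesion (base gray 150, noise 35, faint stripes) are chosen so
that simple first/second-order patch statistics separate the classes —
deliberately an *easy* texture problem, since what is under study is label
cleaning, not texture classification. Real slides differ in ways the
generator does not model (stain variation, tissue morphology, confusable
tissue types, scanner artifacts), so passing benchmarks here demonstrate
correct mechanics of the cleaning procedure, not clinical performance.

Two annotation corruptions are provided. Uniform flip inverts exactly
round(ρ₁|P|) positive and round(ρ₀|N|) negative patch labels, chosen
uniformly without replacement — exact counts rather than Bernoulli draws so
realized rates match nominal ones in sweeps. Omit-small-lesions keeps only
the largest lesion component (8-connectivity), dilates it by a disk
(default radius 5% of the slide's shorter side — the amount is a free
parameter chosen to visibly coarsen boundaries) and takes its convex hull;
a single-lesion mask is instead split through its centroid perpendicular to
its longest principal axis and the larger half kept (ties: the half holding
the first foreground pixel in scan order).

## Benchmark scale and conditions

The benchmark lattices each 2048² slide into 64-px patches at stride 64
(32×32 = 1024 patches), a patch-count regime comparable per slide to
Gigapixel slides latticed at 256 px, and trains on M = 400 bags of
n_j = 10 at equal positive/negative bag counts. Morphology sizes are 5
heatmap-grid pixels in the benchmark (the 100-pixel rule targets much
larger heatmaps; on a 32×32 grid, 100 px would delete true lesions of ~25–80
cells). Evaluation rasterizes ground-truth and coarse masks onto the patch
grid by the patch-center rule, so coarse and refined annotations are
compared on identical supports, per-slide, with F1/IoU/PPV/TPR/TNR/NPV from
patch-level confusion counts.

Across five seeded slides the attention variant's median F1 gain over the
coarse annotation is large at heavy noise (ρ₀ = ρ₁ = 0.3) and smaller but
positive at light noise (ρ = 0.1); individual seeds can fail to improve —
the attention landscape admits degenerate optima, which is why medians are
reported. The mi-Net variant is noticeably more stable at this scale.

## Numerical and design notes

* Patch coordinates are 0-based row-major; a patch occupies the half-open
  box [r, r+P) × [c, c+P); the center of an even patch is (r+P/2, c+P/2).
* Patches extending past the slide edge are never emitted (no padding).
* RGB tissue thresholds use strict `<` on all channels; the HSV method
  intersects per-channel Otsu foregrounds of hue and saturation and raises
  on constant channels. No hole filling is applied to tissue masks.
* Bag size is constant within a run; "decay every 100 bags" is a step decay
  on the bag counter (one optimizer step per bag).
* Heatmap cells with no extracted patch (non-tissue) carry NaN and count as
  score 0 downstream.
* Degenerate inputs (constant Otsu input, empty pools, empty masks,
  non-finite loss) raise typed exceptions rather than silently proceeding.

## Known limitations

* The random-feature bank suffices for texture-statistics discrimination but
  is far weaker than a pretrained deep extractor; real H&E slides would need
  the pluggable pretrained backend.
* Single-lesion slides corrupted by the geometric noise model lose half the
  lesion by construction; recovering the missing half relies entirely on
  texture, which is the hard case for every method here.
* The attention variant's training can land in degenerate optima on
  individual slides (inverted scores); inspect the training log or prefer
  the mi-Net variant when that matters.
* Multi-slide training assumes all slides share a feature distribution
  (moments are pooled); stain or scanner shifts between slides would violate
  this.
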