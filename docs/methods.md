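# Methods

## Model

The classifier is a single CNN applied three times per image. The backbone's
last convolutional stage yields feature maps `X ∈ R^{C×h×w}`. An attention
head — a 1×1 convolution with bias followed by ReLU, no batch
normalization — maps `X` to `M` nonnegative part-attention maps
`F ∈ R^{M×h×w}`. Bilinear attention pooling multiplies each map with each
feature channel and averages spatially, giving the part-feature matrix
`P ∈ R^{M×C}`; `P` is flattened, signed-square-root transformed
(`sign(p)·√|p|`) and L2-normalized, then classified by a linear `M·C → c`
layer. The square-root/L2 step follows the usual bilinear-pooling practice
and adds no parameters, so parameter accounting is unaffected by it.

With backbone width `C`, the attention variant adds
`(C·M + M) + (M·C·c + c)` parameters over the bare convolutional trunk; the
single-stream baseline instead adds a `C → c` linear head on globally
averaged features. These two constructions reproduce the published
parameter column of the backbone comparison for every registry architecture
(e.g. resnet18 at `C=512, M=32, c=2`: 11.18M → 11.23M).

## Attention-guided augmentation

One attention map guides both augmentations in a training step (crop and
erase always share the selected `k`). The map is min-max normalized to
`[0,1]`; a constant map normalizes to all zeros by convention, which makes
the crop fall back to the full image and the erase a no-op — the loop stays
total on degenerate inputs. The normalized map is bilinearly upsampled to
image resolution (align-corners convention; masks are therefore computed at
pixel accuracy) and thresholded at 0.5, boundary value included in the crop
region, so crop and erase masks are exact complements.

- Crop: smallest half-open bounding rectangle of the above-threshold set,
  extracted and bilinearly resized back to `H×W`. Empty mask → full-image
  box.
- Erase: multiplicative masking; erased pixels become 0 (no mean fill).

Thresholding is not differentiable, so no gradient flows through mask
construction: the wrapped images are treated as data. The attention head
still learns, through the raw stream's BAP classifier.

## Training

Every optimization step runs both phases of the two-phase scheme: Phase-I
forwards the raw (preprocessed) batch and collects attention; Phase-II
forwards the crop and erase wrappings through the same weights. The loss is
the unweighted mean of the three cross-entropies (equal weights; nothing in
the method favors one stream). The alternation-per-step reading keeps a
single optimizer state and matches the joint flowchart of the architecture.

Defaults follow the reference protocol: batch size 7, base learning rate
0.01, weight decay 1e-4, linear warm-up over 2 epochs, then a stepped
multiplicative decay of 0.95 every 2 epochs
(`lr(e) = base · 0.95^⌊(e−warmup)/every⌋`), input resolution 300, `M = 32`
(the ablation optimum), up to 120 epochs with early stopping. Early
stopping watches validation WF1S with patience 15 (the patience value is
not specified by the protocol; 15 epochs is long enough to survive the
post-warm-up plateau at this decay rate). The optimizer is pluggable; the
default is Adam, with SGD+momentum as the alternative. Raw images are
preprocessed with left–right/up–down flips, a small random affine
(±15° rotation, ±5% translation, 0.9–1.1 scale), occasional grayscale
conversion, and per-channel color jitter; the crop/erase streams are
derived from the already-preprocessed raw image and get no further
preprocessing.

Test-time map selection is deterministic (maximum spatial energy, ties to
the smallest index) so that repeated predictions are bitwise identical; the
training-time choice is uniform at random per image. The final label is the
plurality of the three streams' argmax labels; with `c = 2` a three-way tie
is impossible, and for `c ≥ 3` a full disagreement is resolved by the
argmax of the mean probability vector.

## Metrics

Per-class F1 uses `2TP/(2TP+FP+FN)` with the 0/0 case defined as 0. WF1S
weights per-class F1 by support. AUC is the rank statistic (ties counted
half); when reported for the voted predictor it uses the mean of the three
streams' positive-class probabilities, since a voted label has no natural
score of its own.

## Synthetic data generator

The generator emulates the geometry of stained single-cell crops: an
elliptical cell body on a light background with a darker nucleus disk. The
two classes share every nuisance distribution — cell radius 0.28–0.42 of
the image side, ellipse aspect 0.75–1.0, orientation ±180°, center offset
±10%, per-channel color shift ±0.08, background noise sd 0.03 — and differ
only inside the nucleus: the "blast" class has nucleus-to-cell ratio
0.70–0.90, chromatin speckle sd 0.18, and vacuole spots with probability
0.5, versus 0.40–0.60, sd 0.04 and no vacuoles for "normal". Confining the
signal to the nucleus is deliberate: it makes attention cropping genuinely
zoom onto informative detail and attention erasing genuinely remove the
primary cue, so the end-to-end test exercises the mechanism rather than a
generic classification task. What the generator does **not** emulate:
staining chemistry, cell segmentation artifacts, touching cells, focus
variation, or inter-patient effects — passing tests demonstrate the
mechanism works as specified, not clinical performance.

Default image size is 64 px so desk-scale training takes minutes on one
CPU; 300 px output is supported for demos at the reference resolution.

## Numerical engine

The layer engine is a compact NumPy implementation (im2col convolution
with groups, batch normalization, max/average pooling, linear layers,
squeeze-excitation, residual blocks) with explicit backpropagation,
verified against central finite differences (worst relative gradient error
~3e-6 in float64 on the toy model). Training runs in float32. All registry
backbones are buildable and forward-capable; the toy backbone (three
conv-ReLU-maxpool blocks, `C=32`, no batchnorm) is the one trained in the
test suite.

## Scaled-down end-to-end experiment

The study-condition run used by the tests and the acceptance script: 300
images per class at 64 px, toy backbone, `M=4`, batch size 32, Adam at base
learning rate 0.003 (Adam needs a smaller step than the reference SGD-scale
0.01), up to 30 epochs with the default early stopping, single thread.
Under seed 1 this early-stops after 16 epochs with voted test accuracy
1.00, WF1S 1.00, AUC 1.00, and a mean attention margin of ~0.52 between
nucleus and non-nucleus pixels. The erase stream alone scores near chance —
expected, since erasing the nucleus removes the class signal by
construction — while voting follows the agreeing raw and crop streams;
this is the designed division of labor between "see details" and
"see more".

## Known limitations

- No pretrained backbone weights are distributed; `pretrained=True` is a
  config error rather than a silent fallback.
- FLOP accounting is not implemented (input-resolution conventions vary
  and the counts would not be comparable).
- The CPU engine is desk-scale: large backbones are buildable, countable
  and runnable forward, but training them here is impractical.
- Five-fold cross-validation is not orchestrated; single split per run.
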