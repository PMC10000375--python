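# Methods

`retinopipe` implements an end-to-end analysis chain for color fundus
photographs aimed at separating healthy retinas from diabetic retinopathy
(DR) and diabetic macular edema (DME) and at grading lesion burden. This
note documents the models, the parameters that matter, the synthetic data
the package is verified on, and the numerical choices made where the
design was genuinely open.

## Synthetic fundus generator

Every stage is exercised on images from `retinopipe.synthetic`, which
renders a stylized retina with complete ground truth:

- **Geometry.** A circular aperture (radius 0.49·min(H, W)) over a
  reddish-orange radial gradient; the optic disc (radius 0.07·min(H, W))
  sits at mid-height on the nasal side; the fovea lies 2.5 disc diameters
  temporal to the disc and the macular radius equals one disc diameter.
- **Vessels.** A recursive binary tree rooted at the disc centre: child
  width 0.7× the parent, segment length decaying by 0.85 per level,
  branch angles jittered uniformly within ±25°. The rendered mask is
  guaranteed to form one connected component touching the disc (branches
  that exit and re-enter the aperture are pruned).
- **Lesions.** Microaneurysms are sharp dark-red discs of radius 1–3 px;
  hemorrhages are irregular dark-red polygons (radius 3–8 px); hard
  exudates are bright yellow blobs (radius 1.5–5 px). DME images place at
  least half of their exudates inside the macula; DR images carry red
  lesions only. Severity labels follow the lesion-count bands mild 1–3,
  moderate 4–9, severe ≥10, which gives threshold fitting a recoverable
  ground truth.
- **Corruption.** Gaussian blur (σ = 0.5 px default), a multiplicative
  linear illumination ramp across the width (strength 0.3 default,
  i.e. ±15%), then exactly `round(density·H·W)` salt-and-pepper impulses
  (1% default). Defaults are deliberately mild — the level of degradation
  a usable clinical photograph shows — while the denoiser experiments use
  5% impulse noise.

Everything is driven by one integer seed and regenerating from the same
spec is byte-identical.

What the generator does **not** emulate: camera vignetting and chromatic
aberration, texture of the nerve fiber layer, cotton-wool spots, vessel
caliber variation and tortuosity, inter-patient pigmentation variance,
and the label noise of human grading. Tests passing on these images
demonstrate that the algorithms are implemented correctly and behave
sensibly under controlled degradation; they do not certify clinical
performance on photographs.

## Preprocessing

**Impulse denoising.** Pixels are flagged when they deviate from the
local median by more than `threshold_k` (default 8) local MADs, with the
MAD floored at 4 intensity levels so flat regions do not over-flag (flag
rate on clean images is below 1%). Flagged pixels are visited in
boustrophedon ("zig-zag") row order and replaced by the clean-component
mean of a two-component mixture — Gaussian clean values plus a uniform
impulse component — fitted per 5×5 window by EM (≤20 iterations,
tolerance 1e-3). Corrections propagate: later windows see earlier
repairs.

**Anisotropic diffusion.** Perona–Malik with conductance
g(|∇I|) = exp(−(|∇I|/κ)²), explicit 4-neighbor scheme, Neumann
boundaries. κ defaults to 30 intensity levels (smooths texture well
below the ~100-level vessel/background contrast); dt is validated
against the explicit-scheme stability bound 0.25; the scheme conserves
mean intensity to rounding.

**Contrast enhancement as optimization.** The enhancement map is the
monotone sigmoid-gamma family T(v) = [1/(1+(m/(v+ε))^α)]^γ rescaled to
[0, 1], searched over α∈[1,20], m∈[0.05,0.95], γ∈[0.3,3]. The fitness is
H(I)·(E/N)·log(log(S+e)): histogram entropy in bits, edge fraction and
summed Sobel magnitude over edge pixels (threshold: half the mean Sobel
response — a relative cut, so the score is stable under tiling and
resolution changes). Harris hawks optimization maximizes the fitness
per image; a guard returns the identity transform whenever no candidate
beats the input, making "enhancement never lowers fitness" structural.
Enhancement runs on the value channel of HSV so chromatic lesion cues
survive. The search runs per image (15 hawks, 50 iterations by default);
per-dataset reuse of one transform is possible but not the default.

## Harris hawks optimization

A minimization engine over a box. Per iteration each hawk redraws its
initial energy E0 ~ U(−1, 1); the escaping energy Ep = 2E0(1 − t/T)
selects exploration (|Ep| ≥ 1) or one of four besiege strategies, two of
which take Mantegna Lévy-flight dives (β = 1.5, step scale 0.01) that
are accepted only when they improve the hawk's fitness. The prey is the
best-so-far solution (elitist), so the fitness history is non-increasing
by construction. Positions are clipped to the box after every update —
the least biased feasibility rule when nothing more is known about the
objective. The besiege displacement uses |F·Xp − X| (absolute value);
the hard-besiege rule is Xp − Ep·ΔX as stated.

## Vessel segmentation

The optic disc — the brightest compact region — is found by thresholding
luminance at the 98.5th percentile, morphologically closing the
fragments that vessels cut through it, and keeping the component with
the best circularity·area score (circularity ≥ 0.2); it is inpainted
with the median background color. Candidate vessel pixels are those with
Sato ridge response (inverted green channel, σ ∈ {1, 2}) above 0.25,
restricted to the eroded field of view because the aperture rim is
itself a strong ridge. Each candidate becomes a 4-D sample
(row/H, col/W, inverted green, vesselness), capped at 4000 strongest.

OPTICS orders the samples: core distance = distance to the MinPts-th
nearest neighbor within ε (undefined otherwise), reachability =
max(core(o), d(o, p)); unprocessed points are seeded in index order and
the candidate queue breaks ties toward the lowest index, making the
ordering fully deterministic. Defaults MinPts = 5, ε = 0.08,
extraction threshold 0.08: with spatial coordinates normalized to [0, 1]
and two intensity features in the vector, 0.08 keeps thin branch tips
density-connected to their parent vessel; smaller radii fragment the
tree into dozens of micro-clusters. Clusters are cut from the
reachability profile, merged when the Jaccard distance of their dilated
pixel footprints is below 0.3, and rasterized into the vessel mask when
elongated (principal-axis ratio ≥ 2) or spatially extensive (a branching
tree is not globally elongated but spans the image).

## Lesion features

Dark-red candidates are green-channel outliers (median − 6 MAD), bright
candidates are luminance outliers (median + 6 MAD) with a yellow cast
((R+G)/2 − B > 0.12); vessel pixels (dilated by 1 px) and the disc are
excluded, components of 2–600 px² are kept and red lesions ≤ 30 px²
count as microaneurysms, larger ones as hemorrhages. The feature vector
(length 40, fixed schema, order-invariant) holds per-type counts, lesion
area fraction, macular lesion count (ground-truth macula at train time,
disc-offset estimate at inference), mean eccentricity/circularity, an
8-bin major-axis orientation histogram, mean/std of RGB and HSV channels
inside lesions and over background, and vessel density.

## Ensemble classifier

The base network is a VGG-style stack — conv blocks of (2, 2, 4, 4, 4)
3×3 stride-1 pad-1 conv+ReLU layers with 64/128/256/512/512 filters,
five 2×2 stride-2 max pools, a 4096-unit fully connected layer and an
M-way softmax. A `scale` factor multiplies all widths; the desk profile
is scale = 0.125 on 64×64 inputs (filters 8…64, fc 512), which the
shape-propagation check keeps structurally identical to the full net.
Layers are implemented in numpy (float32, NHWC); convolutions use a
shift-and-add decomposition (nine channel GEMMs on contiguous views)
and the input gradient is a flipped-kernel convolution, which is what
makes single-core training practical. Optimizer: Adam at 1e-3, batch 32,
cross-entropy; initialization is He; batch normalization exists behind
an off-by-default flag. Geometric augmentation (rotation, shifts, shear,
zoom, flip) is available and exactly the identity when all ranges are
zero — the desk profile trains without it, since the generator already
randomizes pose.

Random-subspace construction: the input is R = 5 planes (RGB plus a
vesselness map and a soft lesion-probability map combining yellowness
and green-channel darkness); each of the L = 3 members receives a random
⌈0.8·R⌉-plane subset, with unselected planes zeroed. Fusion is the
convex combination G = Σ w_j s_j with uniform weights by default
(validation-proportional weighting is available); ties in argmax break
to the lowest class index. Diversity is the pairwise disagreement rate
averaged over ordered member pairs.

Desk-scale study conditions: 150 training and 50 test images per class
at 64×64, 15 epochs, 3 members, seeds 0–2. These sizes are the
repository's verification conditions; the full-width 224×224
configuration (235 epochs in the original protocol) remains available
through the config but is not what the tests measure.

## Severity grading

Severity is modeled as monotone in lesion count. Two integer cut points
binning counts into three groups are fitted by exhaustively minimizing
the conditional entropy H(label | bin) (base-2, 0·log 0 = 0) over all
pairs of observed count values, ties breaking toward the smallest pair.
Grading: count ≤ t1 → mild, ≤ t2 → moderate, else severe. All lesion
types count equally by default. The count used at inference is the
number of detected candidates; fitting uses the generator's severity
labels.

## Evaluation

One-vs-rest confusion counts per class; accuracy (T1+T2)/total,
precision T1/(T1+F1), recall T1/(T1+F2), F = 2PR/(P+R), error rate =
errors/samples. A printed variant of the precision formula with the
true-negative count in the numerator is not used; the implementation
follows the standard definition. Macro averages skip classes whose
denominator is undefined; micro accuracy pools counts. Wall-clock time
is reported in the run report but never asserted.

## Known limitations

- The synthetic scene is far simpler than clinical photographs; absolute
  Dice/accuracy numbers on it do not transfer.
- The OPTICS stage samples at most 4000 pixels; very high-resolution
  images are effectively subsampled.
- The denoiser assumes impulse (salt-and-pepper) corruption; it leaves
  Gaussian noise to the diffusion stage.
- Member training is sequential and single-threaded; wall-clock time
  scales linearly with L and epochs.
- The lesion-detection thresholds were chosen once against the generator
  and frozen; real fundus data would need re-tuning through the exposed
  config.
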