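# Methods

`ihcloc` implements a multilabel image-classification pipeline for protein
subcellular localization from immunohistochemistry (IHC)-style images. This
note records the models and procedures it implements, the parameters that
matter, the numerical conventions, and what the synthetic data generator
does and does not emulate.

## Problem and pipeline

An IHC image of a tissue section mixes two chromogens: a brown stain (DAB)
marking the target protein and a purple nuclear stain (hematoxylin) marking
DNA. A protein may reside in one to three of six subcellular compartments
(cytoplasm, endoplasmic reticulum, Golgi apparatus, mitochondria, nucleus,
vesicles), so each protein carries a *label set* and the task is multilabel
classification at the image level, with all images of a protein sharing its
label set.

The pipeline is:

1. **QC + stain separation** — optional hue-based quality screening, then
   per-pixel least-squares unmixing of each RGB pixel against a fixed
   two-vector stain basis (`rgb − background ≈ a·protein + b·dna`), giving
   a protein and a DNA intensity channel.
2. **Features** — global subcellular location features (SLFs): 836
   wavelet-domain Haralick statistics of the protein channel plus 4
   DNA–protein overlap features; and one of three local texture
   descriptors (LBP, CLBP, LTrP) of the protein channel.
3. **Selection** — stepwise discriminant analysis (SDA) with Wilks' λ on
   the training fold.
4. **Classification** — binary relevance ("cross-training"): one
   RBF-kernel SVM per class, positives = samples carrying the class;
   hyperparameters by cross-validated grid search.
5. **Decision + evaluation** — threshold strategy (label i assigned iff
   score ≥ T, T tuned by grid search maximising subset accuracy) with a
   guarantee strategy (highest score wins when nothing clears T), scored
   with five multilabel metrics.

Everything runs under protein-based two-fold cross-validation: a protein's
images never appear in both folds.

## Local texture descriptors

All descriptors use the 8 integer-grid neighbours at radius 1 (N=8, R=1),
enumerated east then counterclockwise, on the image quantised to 8-bit
gray. Codes are computed only where the full neighbourhood (and derivative
support) exists — no padding. Sign conventions: s(x)=1 iff x ≥ 0, so ties
code 1 everywhere (flat regions yield the all-ones pattern).

* **LBP** — code = Σ 2^k s(g_k − g_c); raw 256-bin histogram, no mapping.
* **CLBP** — the local differences d_k = g_k − g_c are decomposed into
  sign and magnitude (d_k = s′_k·m_k with s′_k = +1 iff d_k ≥ 0). Three
  operators: CLBP_S (= LBP), CLBP_M (magnitudes thresholded at τ = the
  image-wide mean of all m_k) and CLBP_C (centre vs image mean gray).
  S and M are mapped rotation-invariant-uniform (riu2, 10 bins) and
  jointly histogrammed with the C bit: 10×10×2 = 200 features. The joint
  index is `s_bin·20 + m_bin·2 + c` (C fastest).
* **LTrP** (second order) — forward differences dh = I(r,c+1) − I(r,c),
  dv = I(r+1,c) − I(r,c) define a derivative-direction quadrant 1–4 per
  pixel. Per centre pixel, each neighbour contributes its direction if it
  differs from the centre's, else 0; for each centre direction d the
  pattern is segregated into 3 binary codes (one per off-direction),
  giving 4×3 = 12 binary tetra patterns, plus a 13th magnitude pattern
  comparing √(dh²+dv²) of neighbours against the centre. Each of the 13
  codes is histogrammed under the uniform (u2, 59-bin) mapping: 767
  features. The u2 mapping for the magnitude pattern is forced by the
  59×13 arithmetic.

Pattern mappings: u2 gives every 8-bit code with ≤ 2 circular transitions
its own bin (58 uniform codes) plus one shared bin (59); riu2 maps uniform
codes to their set-bit count (0–8) plus one shared bin (10).

All histograms are L1-normalised (each LTrP sub-histogram separately), so
features are image-size independent. Consequences tested: all three
descriptors are invariant to additive intensity shifts, and the riu2 CLBP
joint histogram is invariant to 90° rotations.

## Global features

The 836-dimensional Haralick block is laid out as 26 GLCM statistics (13
classic Haralick features × {mean, range} over the four unit-distance
offsets 0°/45°/90°/135°) on 32 images — the protein channel, the level-10
approximation band, and the 30 detail subbands of a 10-level Daubechies
decomposition (db1–db10 selectable, symmetric boundary) — plus 4
first-order intensity statistics (mean, variance, skewness, kurtosis):
26×32 + 4 = 836. This layout is this package's reconstruction chosen so
that the combination widths come out at 840 / 1096 / 1040 / 1607; the
historical feature sets it follows were never itemised publicly.

Numerical conventions: each subband is min–max quantised to 32 gray levels
(a dynamic range at roundoff scale, ≤ 1e-12 relative, counts as constant);
GLCMs are symmetric; correlation-type features are 0 at zero variance; an
empty GLCM yields all-zero features; near-constant channels get
skewness/kurtosis 0. The decomposition is run to a fixed depth of 10 even
past the nominal maximum level — subbands stop shrinking at the filter
length, and the fixed depth keeps the feature layout constant across image
sizes.

The 4 DNA-overlap features: (1) fraction of above-threshold protein mass
inside the DNA mask, (2) the converse for DNA mass, (3) Pearson
correlation of the channels, (4) ratio of mean protein intensity inside vs
outside the DNA mask. Thresholds default to per-channel Otsu; degenerate
masks yield 0 with a logged warning.

## Stain model and QC

Default stain basis (unit vectors): brown protein stain from direction
(0.65, 0.45, 0.25), purple DNA stain from (0.45, 0.35, 0.60), over a
neutral dark background (0.10, 0.10, 0.10). Unmixing is a per-pixel least
squares solve with negative coefficients clamped to 0 and each coefficient
map rescaled by its 99th percentile (robust to hot pixels); a map whose
99th percentile is below 1e-9 is kept at zero rather than amplifying
numerical residue. On noiseless two-stain mixtures the solve is exact.

Hue QC converts to HSV and takes the mean hue on the 0–255 integer scale,
with near-achromatic pixels (saturation ≤ 0.05) contributing hue 0; an
image fails when the statistic exceeds the threshold (default 13). With
this statistic a brown-stained image over neutral background scores low
(brown sits at hue ≈ 21 but background pulls the mean down) while a
cyan-cast image scores high — which is what the filter targets. Averaging
over saturated pixels only, the comparison polarity, and a 0–360° scale
are all config options. In end-to-end runs the statistic is always
computed for audit but filtering is off unless a threshold is configured,
because synthetic renders contain legitimately purple nuclei that pull the
mean hue above 13.

## SDA

Wilks' λ(S) = det(W_S)/det(T_S) over the selected columns, with within-
and total-scatter matrices W and T. Entry: the candidate minimising the
partial λ enters if F = ((n−g−p)/(g−1))·(1−λ_partial)/λ_partial ≥ f_enter
(defaults f_enter = 3.84, f_remove = 2.71, the conventional stepwise
values); removal symmetric. A ridge of 1e-6·trace(W)/p is added to both
diagonals (same ridge on W and T keeps λ ∈ (0,1]). Ties break to the
lowest index; selection is capped at min(max_features, n − g − 1). For
multilabel data each distinct observed label set is one SDA class
(default); a per-label one-vs-rest union ranking is available.

## Classifier and decision

One RBF-SVM per class via scikit-learn's libsvm binding; features
z-scored by training-fold statistics; (C, γ) from C ∈ {2⁻⁵…2¹⁵},
γ ∈ {2⁻¹⁵…2³} (steps of ×4) by stratified cross-validated grid search
(3-fold at desk scale; config-exposed). A class with single-class training
data gets a constant scorer with a logged warning. Scores are signed
margins, which is why the decision-threshold grid spans −2…2 (step 0.1).
T is tuned on held-out scores from an internal protein-level two-fold
split of the training fold, maximising subset accuracy with the guarantee
strategy active; the model is then refitted on the full training fold.

Metric conventions: "point" is the Jaccard-style score |T∩P|/|T∪P|;
recall(l) and precision(l) average the point score over samples whose true
(resp. predicted) set contains l; classes with empty denominators are
skipped in the macro average (avoids 0/0) with a logged note.

## Synthetic data generator

The generator emulates exactly the structure the pipeline assumes: a
linear two-stain mixture, a shared nuclei blob field (5–8 compact soft
disks), one texture motif per class (diffuse field, reticular web,
perinuclear patches, elongated strands, nuclear blobs, punctate spots),
pixelwise-maximum superposition for multilabel proteins (avoids the
saturation bias of summation and keeps each class's texture recognisable),
additive Gaussian noise (default sd 0.02) clipped to [0,1], and one
top-level integer seed with all sub-streams spawned from it
(bit-identical regeneration). The first six proteins carry one label each
so every class is always represented; the multilabel fraction is met to
within 1/n_proteins; among multilabel proteins roughly 8% get three
labels and the rest two, mirroring a 7:83 three-to-two-label split.

Default study conditions for end-to-end runs: 24 proteins × 4 images at
96×96 px with 25% multilabel proteins — small enough to run the full
two-fold × two-combination comparison in about a minute per seed on one
CPU, large enough that every class appears in both folds in expectation.

What the generator does **not** emulate: cell morphology and segmentation
structure, staining artefacts, focus variation, inter-antibody intensity
variation, and realistic nuclear counterstain texture. One measured
consequence: the wavelet-Haralick global features separate the six clean
synthetic motifs almost completely on their own, so SDA selects few local
features on generator output — unlike real IHC, where local patterns add
substantial discriminative power. The directional property "features that
carry the class signal in the local block are preferentially selected" is
therefore exercised on feature matrices constructed with the signal placed
in the local columns. Passing tests demonstrate correctness of every stage
and the directional behaviour of the pipeline on data satisfying its
assumptions; they do not certify accuracy levels on real IHC images.

## Known limitations

* Fixed stain basis (no adaptive stain estimation / NMF).
* N=8, R=1 neighbourhoods only; no interpolated rings, no high-order
  LTrP, no hybrid CLBP combination.
* The 836-feature layout is a reconstruction (see above), not a published
  itemisation.
* SDA treats each distinct label set as a class; with many rare label
  sets and few images the per-class sample requirement (≥ 2) binds.
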