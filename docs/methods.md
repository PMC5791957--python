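# Methods

This note documents the models, numerical choices and limitations of
`gummix` at the level of detail a maintainer or reviewer needs.

## The measurement model

A mixing test treats the chewed two-colour wafer as a physical record
of masticatory function. The package's estimand is the Masticatory
Efficiency **ME = P/T**: the stroke count *P* a healthy reference
chewer would need to reach the observed degree of mixture, divided by
the stroke count *T* actually applied. Estimating *P* is a
classification problem: the specimen's observed state — the
Masticatory Performance vector MP — is assigned to one of the stroke
classes of a calibrated reference population. ME is therefore always a
ratio of calibrated stroke counts ({0, 5, 10, 15, 20}/T under the
default design), not a continuous regression output; a specimen whose
appearance matches no class is surfaced as UNCLASSIFIED.

The linguistic scale anchors ME at 0/25/50/75/100 % ("Totally
impaired" … "Normal"), with values above 100 % tagged "Better than the
norm". Intermediate ratios are mapped to the *nearest* anchor, with
midpoints rounding up (0.125 → Impeded); this nearest-level rule is the
natural completion of an anchor-only table and matches how cohort
means such as 0.26 → "Impeded" and 0.71 → "Adequate" read.

## Synthetic specimens

No public image set of masticated two-colour gums exists, so the
package ships a generator that emulates one and serves as the test bed
for every stage.

**Mixing dynamics.** Each subject carries a personal mixing rate *r*
(per stroke); after *t* strokes the specimen's mixing level is
m(t) = 1 − exp(−r·t). A saturating law reflects the diminishing
returns of additional chewing cycles. Defaults: rate mean 0.05/stroke
(a normal chewer reaches ~63 % mixing at the reference 20 strokes, so
all five calibration classes sit in the informative part of the
curve), between-subject SD 0.0025 (5 % CV). Both are configurable.

**Rendering.** The bolus is an irregular ellipse (low-order radial
harmonics on an ellipse, so the outline is smooth, star-convex, one
connected component, with a 3 px margin to the frame) over a
light-grey scanner-lid background (default 200/255). Area fraction is
drawn from U(0.30, 0.40) — a fixed gum mass pressed to a fixed 1 mm
thickness gives similar bolus areas. The red/white texture is a
smoothed Gaussian random field, **rank-remapped inside the bolus** and
passed through a logistic soft threshold: the field supplies only the
spatial arrangement of patches (characteristic scale 1.5 + 6(1−m) px,
so patches refine as mixing proceeds), while the *distribution* of the
red/pink/white blend weight is an exact function of (m, side): the red
area fraction is 1 − m/2 on the red face and m/2 on the white face
(both → 50 % as m → 1), and the pink transition mass grows linearly
with m. This makes the class signal carried by histogram features
deterministic up to pixel noise, which is the premise of the method —
that specimens chewed the same number of cycles share identifiable
patterns. At t = 0 the two faces are the pure layers (one red, one
cream-white). A ±3 % linear illumination ramp and additive Gaussian
noise (SD 5 on 8-bit values) emulate flatbed-scanner imperfections.
Frames default to 128×128 px.

**What the generator does not emulate:** saliva sheen and specular
highlights, pressing artefacts at the rim, colour bleeding between
layers, scanner colour-profile drift, and boluses with holes or
multiple fragments. Tests passing on synthetic data therefore
demonstrate the pipeline's correctness and internal consistency, not
clinical performance on real scans.

## Segmentation

Composition: (1) mean shift smoothing — each pixel's colour iterates
(3 iterations) toward the mode of its joint spatial-colour
neighbourhood with Gaussian kernels, spatial bandwidth 8 px (window
truncated there) and range bandwidth 12 L\*u\*v\* units; run in
L\*u\*v\* where Euclidean distance is perceptual; (2) a per-pixel
centre-distance feature, min-max normalised to [0, 1] — the bolus is
centred by protocol, and this is the minimal feature that lets a
2-cluster K-Means separate a central blob from a background of similar
lightness; (3) K-Means, k = 2, 10 restarts, fixed seed, on the
z-standardized (L\*, u\*, v\*, distance) stack with the distance
channel weighted 1.5. The cluster with the smaller mean centre
distance is the ROI (ties: the smaller cluster); only the connected
component containing the image centre (else the largest) survives.

The raw label field is then shape-regularized: morphological closing
with a disk of the smoothing bandwidth (8 px), hole filling, and a
convex hull (computed without half-pixel offsets, so an exactly convex
input is reproduced exactly). Rationale: colour clustering loses
low-chroma bolus wedges at the outline — cream-coloured gum resembles
the grey lid more than it resembles the bolus mean — and a
press-flattened bolus is nearly convex, so the hull is an appropriate
prior. The distance weight of 1.5 (rather than 1.0) prevents an
occasional failure mode in which K-Means splits the bolus by colour
(red vs cream) instead of region. Both cleanup steps and the weight
are parameters; setting `closing_radius=0, convex_hull=False,
distance_weight=1.0` restores the bare composition. For strongly
concave boluses the hull should be disabled.

A segmentation is rejected (typed error) when all pixels are identical
or when the two clusters' mean L\*u\*v\* colours are closer than 8
units — the signature of a scan with no bolus on it.

## Features

All statistics pool the ROI pixels of both sides of the specimen
before anything is computed. Channels: R, G, B (8-bit), L\*, u\*, v\*
(D65, sRGB primaries), H, S, I (arccos hue variant, hue in radians in
[0, 2π), undefined — and excluded, never imputed — where R = G = B),
and chromaticity-normalized Rn, Gn, Bn (black maps to equal thirds to
avoid NaNs in shadows). Histograms use 256 equal-width bins over each
channel's *fixed* full range (e.g. [0, 100] for L\*, sRGB-gamut bounds
for u\*/v\*, [0, 2π) for hue), so bin counts are comparable across
specimens.

The ten extraction models are: pixel mean (Mp) and population variance
(Vp); histogram-count variance (Vh, computed on raw counts — hence its
large magnitudes), count-weighted Fisher-Pearson skewness over bin
indices (Sh), energy Σp² (Gh), entropy −Σp·log₂p in bits with
0·log 0 := 0 (Eh); and four peak features: peak count (Nh), the raw
count heights of the tallest (V1) and second-tallest (V2) peaks, and
the second peak's bin index (P2). Peaks are strict local maxima of the
binomial-(1, 2, 1)/4-smoothed counts with prominence ≥ 1 % of the total
count; a flat 3-bin moving average was rejected because it turns an
isolated single-bin spike into a plateau with no strict maximum.
Sentinels are deterministic: V2 = 0 and P2 = −1 when fewer than two
peaks exist; V1 = 0 when none. CVOH = 1 − R̄ (R̄ the mean resultant
length of the hue angles) completes the 10 × 12 + 1 = 121 vector. The
registry is data-driven — models × channels can be revised without
code changes — and feature order is fixed by it.

The linear pixel mean of hue (MpH) ignores circularity; it is kept
because the registry treats channels uniformly, and the hues of
red/pink/cream specimens occupy a narrow arc where the distinction is
immaterial. CVOH is the circular-statistics treatment.

## Feature selection

q = (|ρ| + (γ/C(n, 2))²)/2 with ρ the Spearman correlation
(average-rank ties; a constant feature scores ρ = 0 with a degeneracy
flag) between the feature and the stroke count, and γ the number of
class pairs significant in two-sample t-tests at α/C(n, 2) after a
significant one-way ANOVA (γ = 0 otherwise; α = 0.05). The halving
bounds q in [0, 1], which is what makes the fixed 0.5 discard
threshold meaningful: a feature must either correlate strongly or
discriminate most class pairs (or both) to survive. The exact
aggregation of the two terms is a design choice isolated in one
function (`q_score`) for easy revision. PCA (standardized, unrotated
loadings) is available for further reduction but is not in the default
training path.

## Cascade training

One one-vs-rest binary MLP per stroke class: k inputs (the kept
features, z-standardized with Training-Group statistics), h logistic
hidden units, one logistic output thresholded at 0.5. For each h in
⌈k/3⌉..k (optionally thinned to a fixed number of evenly spaced
widths) several independently seeded executions run; each execution
draws a fresh stratified 40/30/30 Training/Validation/Testing split,
balances the 1-vs-rest classes by repeating positives in the Training
Group, and trains with Adam (learning rate 0.01, minibatch 64) driven
epoch-by-epoch. Early stopping monitors the Validation-Group log-loss
(patience 25 epochs after a 100-epoch warm-up — the binary VG score is
a step function of the weights and can sit flat long after the loss
has started moving); the snapshot kept is the weights with the best VG
MCC (ties broken by lower loss), and a run also stops once the VG has
been perfectly separated for 15 consecutive epochs, since further
sharpening cannot change its decisions. The candidate with the highest
Testing-Group MCC becomes the stage; it is *suitable* only if that MCC
strictly exceeds 0.95, and calibration fails loudly — naming the class
— if any stage is unsuitable. Training is stochastic by design; the
best-of-many selection against the suitability gate is the mechanism
that tames that randomness, and every seed is recorded in the MEPAT.

Suitable stages ordered by ascending stroke count form the cascade:
stages are queried in order and the first to fire sets P. Prediction
runs through the package's own forward pass on plain weight matrices
(not the training library's objects), which is what guarantees
bit-identical behaviour across serialization.

The per-execution re-splitting means stages see different partitions
of the calibration data; the pipeline's final report therefore
evaluates the assembled cascade once more on the Testing Group of an
additional fresh split.

## MEPAT records

`⟨TF, ES, CH, CLS, OP, PER⟩` plus a UUIDv4 and ISO-8601
creation/upload timestamps serialize to UTF-8 XML validated against
the XSD shipped in `gummix/data/mepat.xsd`. The schema is this
package's own dialect; its six blocks carry everything `diagnose()`
needs (segmentation settings, feature codes, scalers, weights,
thresholds) and no local paths, so a record is portable by
construction. Numbers are written as shortest-round-trip decimals
(`repr`), so write → read → write is byte-identical and a deserialized
cascade predicts bit-identically. Corrupt content fails loudly with
typed errors (schema violation, unknown feature code, truncated weight
block) rather than producing NaNs.

## Diagnosis

T must be positive and among the calibrated cycle counts — behaviour
for uncalibrated stroke numbers is undefined by the method, so they
are rejected rather than extrapolated. UNCLASSIFIED propagates as a
distinct status with ME undefined. Repeated tests of one patient are
summarized by the highest ME observed. Cohen's kappa on paired
predicted classes is provided as a repeatability diagnostic; because
the image pipeline is fully deterministic, duplicate scans always give
κ = 1 and the statistic only becomes informative across re-chewed
specimens.

## z-score baseline

The single-feature comparator: per-class mean and sample (n−1) SD of
one feature from the Training Group; z = (mp − m̄_T)/σ_T;
pre-classification into class T when |z| ≤ 0.25 (boundary inclusive),
scored per class by a "core" MCC; final assignment by argmin |z| with
ties to the smaller stroke count (the conservative ME). Zero
within-class variance is an error, not a silent division.

## Problem sizes and numerical notes

The shipped test suite and the acceptance script run the full
synthetic calibration at 80 subjects × 5 cycles (400 specimens, 800
images of 128×128 px) with the reduced hidden-width sweep (10 widths ×
3 restarts per stage); the full ⌈k/3⌉..k × 10 sweep is available
through `TrainingPolicy(h_sweep=None)`. The mean shift kernel is
JIT-compiled (numba) and costs ~0.2 s per image; K-Means uses 10
restarts with a fixed seed. All randomness flows through explicitly
seeded generators: the same configuration and seeds reproduce the same
dataset digest, masks, features, records and diagnoses bit for bit.

## Known limitations

* The segmentation shape prior (convex hull) assumes press-flattened,
  hole-free boluses; disable it for fragmented or concave specimens.
* Hue-based features lose discriminative power for colour pairs with
  similar hues; the red/white (cream) default avoids this, but the
  colour constants are module-level and a poor pair choice will
  degrade CVOH and the H-channel features first.
* The cascade can only output calibrated stroke counts; ME resolution
  is limited by the cycle grid chosen at calibration.
* Synthetic validation bounds what the tests can show (see the
  generator section); no claim is made about accuracy on real scans.
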