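# Methods

## Problem and model

`uteroflow` implements a pipeline for predicting pregnancy outcome in
patients with recurrent implantation failure (RIF) from cine MRI of
uterine peristalsis (UP) combined with clinical indices.  A cine study is
a time series of one midsagittal uterine slice — nominally T = 30 frames
at 6-s intervals on a 256×256 matrix.  Peristalsis appears only as
frame-to-frame change of the junctional zone, so the pipeline reduces the
temporal dimension before classification rather than using a 3-D
spatiotemporal model.

### Motion encoding

Four consecutive grayscale frames f1..f4 are folded into one 3-channel
"combined image":

    R = f1/2 − f2/2 + 128,  G = f2/2 − f3/2 + 128,  B = f3/2 − f4/2 + 128.

A static scene maps to uniform neutral gray (128 in every channel); at a
6-s frame interval each combined image represents 18 s of motion.  The
window slides at stride 1, so T frames yield T − 3 combined images
(20 → 17, 30 → 27).  The raw channel range is [0.5, 255.5]; values are
clamped to [0, 255] in floating point and rounded (half-to-even) only on
8-bit export, which keeps the neutral-128 identity exact.  Frames are
used on their stored [0, 255] scale with no histogram normalization.
Whether the original protocol clamped or rescaled out-of-range values is
not documented; clamping is this package's choice.

### ROI schemes

Each case carries one hand-annotated uterus rectangle, applied to all
frames (the annotation is per-study, not per-frame).  Four image types
are derived: O (original frame), R (rectangle crop), C (circle
circumscribing the rectangle, side = ⌈diagonal⌉, outside filled), and P
(fixed-diameter circle centered on the rectangle — one field of view for
every case).  The literal 644-px P diameter cannot fit a 256-px
acquisition matrix, so the constant is interpreted as defined at a
1024-px display resolution and scaled by stored_width/1024 (161 px at
256); it is exposed as a parameter.  Frames are cropped first and then
combined: with a constant fill the fill region maps to neutral 128 in
the combined image, i.e. "no motion", which is the desired encoding.
The fill value is 0 on grayscale frames.  After cropping, frames are
resized with bilinear interpolation (anti-aliasing on downscale).

### Scoring harness

Cases are split into 6 grouped folds (all images of a patient share its
fold; sizes differ by ≤ 1), and the whole cross-validation is repeated
12 times for each of the four image types: 6 × 12 × 4 = 288 model slots.
Training images are augmented 40-fold — small rotations (±10°),
translations (±5%), horizontal flips, mild intensity jitter (gain
0.9–1.1, offset ±8) — and each of the 20 epochs samples 1/20 of the
augmented pool without replacement.  The augmented pool is materialized
lazily: pool index i deterministically maps to source image i∕40 under
replica i mod 40 (replica 0 is the untouched image), so the sampling
semantics hold at O(epoch) memory.  The exact augmentation family,
optimizer, and learning-rate schedule are not documented in the source
protocol; those used here are package choices, all visible in
`TrainConfig`.

Two scorer backbones satisfy the contract (combined image → success
probability):

* **small_cnn** — a compact convolutional network authored on numpy:
  three 3×3 conv blocks (8/16/32 channels, ReLU, 2×2 max-pooling after
  the first two), global average pooling, and a sigmoid head, trained
  with Adam (lr 10⁻³) on binary cross-entropy.  Inputs are centered on
  neutral gray ((x − 128)/64) so a static scene is the zero tensor.
  It reports both total and trainable parameter counts (identical here).
* **motion_energy** — logistic regression on the per-image mean
  |value − 128| statistic, fitted on a per-repetition bootstrap of the
  training images.  It is the fast deterministic reference scorer and
  the independent oracle for the class signal (no convolutions).

A `mobilenet_v2` slot exists in the config contract for parity with the
original protocol but requires a deep-learning framework and raises a
clear error when requested.  Class labels are success = 1, failure = 0;
scores are P(success); the classification threshold is 0.5 unless stated.

### Evaluation

*Image unit*: every combined image is a sample, scored by the single
model of its fold/repetition or by the leave-one-repetition-out ensemble
(arithmetic mean of the 11 other repetitions; 12 ensembles from 12
repetitions).  *Case unit*: per case, scores are summed over 20-frame
windows (17 combined images each).  Thirty frames admit 11 distinct
20-frame windows at stride 1; the protocol states 10 windows per case,
so the default candidate set is windows starting at frames 0–9 (the
count is configurable, and the discrepancy is deliberate).  The
highest-total window is the case representative; the binary prediction
thresholds total/17 at 0.5.  Metrics: sensitivity, specificity,
accuracy, AUC by the Mann-Whitney rank statistic with mid-ranked ties
(on continuous scores image-unit, on representative totals case-unit),
and balanced accuracy ≡ (sensitivity + specificity)/2 exactly.
Repetitions are summarized as mean ± sample (n−1) SD.  The
leave-one-repetition-out construction of the "12 pairs of ensembles with
11 models" is the adopted reading of an underspecified protocol detail.

### Clinical fusion

Fifteen baseline indices (five continuous: age, gravidity, parity,
embryo transfers before/after testing; ten binary lesion/test
indicators) are extended with two composites — pathology count (sum of
six lesion indicators) and inflammation score (sum of four
endometrial/vaginal test indicators).  Imaging enters through five
descriptors of each case's 12 per-case ensemble scores: mean, sample SD
(0 when undefined), range, IQR (linear-interpolation quantiles), and
median — 22 predictors in total (17 clinical + 5 descriptors); P-type
ensemble scores feed fusion by default.  The split is a group-aware
shuffled 70/30 train/validation partition at seed 42 (188 cases →
131/57).  Missing and infinite entries are median-imputed with medians
fitted on training rows only; composites are computed **after**
imputation (the original order is unstated; computing them from imputed
indicators keeps the composite columns complete and consistent).  A
Random Forest is tuned by grouped 5-fold exhaustive grid search
maximizing accuracy (default grid: 100/200 trees × depth 3/unlimited ×
√p features — the original grid is unstated) and refit on all training
rows; validation metrics use probability threshold 0.5.

## Synthetic cohorts

No cine-MRI dataset of UP is publicly deposited, so every stage is
exercised on synthetic cohorts with a known outcome-generating
mechanism.  Each case renders an ellipse "uterus" with a darker
junctional-zone band on a 256×256 canvas; a sinusoidal traveling wave
(3 cycles per 30-frame sequence, 60-px wavelength) displaces the band
vertically, with additive Gaussian noise (SD 2 gray levels) and values
clipped to [0, 255] (8-bit on disk, float in memory).  The wave
amplitude is drawn from a class-conditional range — success 0.5–2 px,
failure 4–8 px, reflecting that excessive peristalsis during the
implantation window is the adverse state.  These amplitude and frequency
values are free parameters of the simulator (no quantitative description
of real peristalsis amplitude is available), chosen so that the
in-rectangle motion-energy statistic separates classes cleanly.

Clinical tables are drawn at the study cohort's prevalences and means
(55.3% pregnancy rate with exactly round(n × rate) positive cases;
leiomyoma 38.3%, adenomyosis 17.6%, ... ; age 36.8 ± 4.1, transfers
before testing 3.7 ± 2.3), with per-variable missingness mirroring how
often each test was performed (CD138 182/188, microbiome 42/188,
Mycoplasma/Ureaplasma 155/188) to exercise imputation.  A logit shift of
0.5 ties the risk indicators (and a small age shift) to the outcome, so
clinical-only models have a weaker but recoverable signal while imaging
carries the stronger one — the configuration under which "fusion ≥
clinical-only" is a meaningful check.  Setting the shift to 0 recovers
exact configured prevalences.

**What passing on synthetic data shows and does not show.**  The phantom
has motion structure, an ROI, class-conditional amplitude, and realistic
table marginals; it has none of MRI's anatomy, contrast, artifacts, or
inter-patient variability, and its class separation is far cleaner than
clinical reality.  Green tests demonstrate that the pipeline's machinery
— encoding, cropping, leakage-free cross-validation, ensembling,
aggregation, fusion — is correct and recovers known signal; they say
nothing about performance on real cine MRI.

## Problem sizes and numerical choices

Desk-scale runs use 40 cases × 30 frames, P-type ROI resized to 32×32,
6 folds × 2 repetitions of the small CNN; the fusion and permutation
studies use 60-case cohorts with the motion-energy backbone across the
full 6 × 12 grid, 5 simulation seeds, and 10 label permutations.  These
sizes are the package's chosen desk-scale analogue of the full protocol.
The multi-seed fusion comparison uses the motion-energy backbone so that
descriptor signal is present without repeating the CNN grid per seed;
the CNN chain itself is exercised once end-to-end.

Ties in the representative-window argmax break toward the earliest
window; AUC ties are mid-ranked; the sample SD uses n − 1; quantiles
interpolate linearly; degenerate inputs (single-class truths, empty
score vectors, all-missing training columns, sub-4-frame stacks) raise
errors rather than returning silent defaults.  All randomness flows from
explicit integer seeds through `numpy.random.default_rng`; identical
configurations are bit-reproducible.

## Known limitations

* The small CNN is a CPU-scale stand-in architecture; it shares the
  scorer contract but not the capacity of a modern pretrained backbone.
* The simulator's wave parameters are not calibrated to physiological
  peristalsis (no public quantitative reference exists).
* Case-unit windows assume scores for combined images 0..25 exist
  (≥ 20 frames); variable-length studies shorter than that are rejected.
* Only single-slice, single-rectangle studies are supported.
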