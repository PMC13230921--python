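# Methods

## Problem setting

Rare inherited retinal diseases yield cohorts of at most a few hundred fundus
photographs, far below what image classifiers normally need. `latentmix`
implements a data-expansion strategy for this regime: train a variational
autoencoder (VAE) on the available training images, then synthesise
additional training images by manipulating codes in its latent space, while
an evaluation protocol keeps every synthetic image strictly on the training
side of a patient-grouped split.

## Models

### Codec (convolutional VAE)

The encoder is a stack of stride-2 3×3 convolutions (default widths
8/16/32) followed by two linear heads producing the posterior mean μ and
log-variance log σ² of a flat Gaussian latent (default d = 128). The decoder
mirrors it with nearest-neighbour upsampling + 3×3 convolution, keeping the
full-resolution stage to a single output convolution (the full-resolution
convolutions dominate CPU cost), and a sigmoid output so decoded pixels
always lie in [0, 1]. Training minimises

    L = MSE(x, x̂) + β · KL( N(μ, diag σ²) ‖ N(0, I) ),
    KL = ½ Σᵢ (μᵢ² + σᵢ² − 1 − log σᵢ²),

with Adam (lr 2·10⁻³), β = 10⁻⁴, 60 epochs, batch 16 by default. log σ² is
clamped to [−20, 20]. The defaults were set by measuring reconstruction
fidelity at the benchmark scale (a few dozen 64-px training images): with a
stronger prior weight (β ≈ 10⁻³) or a narrow latent (d ≤ 32),
reconstructions collapse toward the cohort mean image and no longer carry
the per-image features that latent mixing is supposed to recombine — the
pixel-statistic separating the phantom classes drops from AUC ≈ 0.81 in the
originals to ≈ 0.55 in reconstructions. At β = 10⁻⁴, d = 128 and 60 epochs
reconstructions retain it (≈ 0.80, MSE ≈ 0.011). This fidelity is what makes
expansion useful at all: with a weaker codec the synthetics form a blurred
off-domain cluster that hurts rather than helps the classifier. The codec is exposed behind a plug-in contract
(`encode`/`decode`/`latent_dim`), so a pretrained backbone (e.g. an
AutoencoderKL) can replace the built-in VAE without touching the expansion
code.

All networks in the package run on a small reverse-mode autodiff core over
numpy (`latentmix.nn`), written for this package and gradient-checked
against central finite differences in the test suite. Computation is
float32 and seeded; repeated runs on one machine are bit-identical.

### Expansion schemes

*Gen 1 (noise perturbation).* For each real training image, encode to μ, add
one noise vector, decode. The noise kind is drawn uniformly from
{constant, gaussian, uniform, sinusoidal} and the strength s uniformly from
[0.05, 1]; one synthetic per real image, so the pool exactly doubles.
Definitions: constant = ±s (one shared sign per vector); gaussian = s·N(0, I);
uniform = s·U(−1, 1)^d; sinusoidal component i = s·sin(2π f i/d + φ) with
seeded f ∈ {1..4}, φ ∈ [0, 2π). The constant and sinusoidal families are
declared conventions of this package (the underlying idea fixes only the
four family names), with their free parameters seeded.

*Gen 2 (pairwise combinatorial mixing).* Within each label class, every
unordered pair (A, B) of training images — C(n, 2) pairs, no self-pairs —
contributes decoded mixtures r·μ_A + (1−r)·μ_B. In `all_ratios` mode every
ratio in {0.1, 0.3, 0.5, 0.7, 0.9} is decoded (|R|·C(n,2) synthetics per
class); in `one_ratio_per_pair` mode one seeded ratio per pair (C(n,2) per
class). Both conventions circulate for pairwise mixing counts ("n × n" vs
"C(n, 2)"); the manifest records both numbers and unordered-without-self is
the implemented reading, consistent with the symmetry
mix(A, B, r) = mix(B, A, 1−r). Mixing operates on the posterior mean μ, not
a sampled z, so synthesis is deterministic given codec weights and seed.

*DCGAN baseline.* An unconditional convolutional GAN (default latent 100,
output side configurable up to 224) trained per class with alternating
binary-cross-entropy updates; it serves as the comparison generator for
FID and latent-overlap rankings, not as a recommended expansion method.

### Classifiers

Two compact from-scratch architectures sit behind one contract so
architecture comparisons are a config change: a patch-embedding transformer
(patch 8 on side 64, 2 pre-norm single-head attention blocks, width 32) and
a conv-residual network (3 stride-2 stages with identity residual blocks,
global average pooling). Training uses AdamW with linear learning-rate decay
to zero and per-epoch augmentation (random resized crop, scale ∈ [0.7, 1],
then horizontal flip with p = 0.5). The configured default learning rate,
5·10⁻⁵ over 30 epochs, is the regime appropriate for fine-tuning pretrained
backbones; the phantom benchmark, which trains from scratch, uses 10⁻³,
since cold-started compact networks need larger steps. Batch size
16 (benchmark 48) and crop-scale bounds are package conventions. For binary
runs the positive class is `x_linked`; every report records this polarity.

## Evaluation protocol

Splits are patient-grouped (both eyes of a patient on one side) and
stratified by class at the patient level; train counts use round-half-up per
class, capped so every ≥2-patient class keeps a test patient. Stratification
is a deliberate addition: in cohorts of a dozen patients per class an
unstratified 80/20 split regularly empties a class's test fold
(`grouped_split` also serves unstratified callers via its per-class logic
only when classes exist — the `--no-stratify` escape hatch was judged not
worth carrying). "Cross-validation by resampling" is implemented as k
independent grouped 80/20 splits with derived seeds — not a k-way partition —
which is the only reading consistent with both an 80/20 ratio and five
folds. Class balancing (patient-preserving undersampling of majority
classes) is applied to the train side of each resample before codec
training, so expansion counts are class-symmetric.

Per fold the package reports accuracy, recall, specificity, precision, F1
(zero-denominator ratios are reported as missing, never as 0) and ROC AUC;
across folds their mean ± SD; and the pooled AUC, computed once on the
concatenation of all out-of-fold labels and scores. The ROC AUC equals the
Mann–Whitney statistic with half-weight ties. Binary confusion matrices
threshold at 0.5.

FID between feature distributions uses sample means and (n−1) covariances,
with the matrix square root computed as Tr((S₁^½ S₂ S₁^½)^½) via
eigendecomposition with eigenvalues floored at 0. The default feature
extractor is a fixed-seed random convolutional projection: FID values from
it are comparable only within one run/extractor, not to published
ImageNet-feature FIDs; any image→vector extractor can be plugged in.
Latent-distribution agreement is summarised as the overlap coefficient
Σ min(p̂ᵢ, q̂ᵢ) of 32-bin histograms of both sets projected on the first
principal axis of the real set. For VAE-based synthetics the synthetic set's
latent codes are the codes the images were decoded from (recorded in their
provenance); GAN samples, which have no code in the VAE's latent space, are
embedded through the encoder. Re-encoding decoded images instead would
confound the comparison with the codec's cycle-consistency error: a compact
VAE's reconstructions all lack the high-frequency content that dominates the
real set's first principal axis, so every decoded image — whatever its
origin — would project to nearly the same point. Age-binned subgroup tables (default bins
[10, 20) and [50, 60) years) report per-class precision and F1 and flag
single-class bins instead of letting them appear silently perfect.

The codec is retrained per resample on that resample's training reals: the
alternative — one codec fit on all data — would leak test-side pixel
statistics into the training pool through the decoder.

## Phantom cohorts

The phantom generator renders 64-px fundus-like images: circular field,
optic disc (nasal side, mirrored for pre-flip right eyes), macula, two
vessel arcades, plus two class-dependent degeneration features — peripheral
dark speckle (a bone-spicule analog) and mid-peripheral ring attenuation.
Class means of both features are separated by `effect_size` (default 1.0)
in units of the between-patient SD; fellow eyes share a patient latent with
correlation 0.8. Illumination (U[0.85, 1.1]), vessel rotation (±0.5 rad) and
vignetting act as nuisances. Simulated ages are class-conditional
(autosomal ≈ N(51, 16²), X-linked ≈ N(26, 19²), truncated to [5, 95]) and
never influence pixels except through the class label, so age-matched
subgroup analyses can isolate image signal. At effect 1.0 a simple pixel
statistic (mean peripheral darkness) separates the classes with AUC ≈ 0.7 at
12 patients/class — a deliberately hard but learnable regime. Phantoms model
none of: real anatomical variation, acquisition physics, device differences,
disease heterogeneity; benchmark results demonstrate protocol correctness
and direction of effect, not clinical performance.

## The standard benchmark

`latentmix.benchmark` freezes the package's reference conditions: 2 classes
× 12 phantom patients (2 eyes each) at side 64, k = 5 grouped 80/20
resamples, VAE codec as above trained for 100 epochs, conv-residual
classifier (channel widths 6/12/24, 30 epochs, lr 10⁻³, batch 48, crop
scale [0.9, 1] — the benchmark narrows the default crop range because the
phantoms' class signal lives in the image periphery, which aggressive
cropping excises, and uses the smaller channel widths because they gave the
most seed-stable classifiers at this pool size), gen2 in
`one_ratio_per_pair` mode, five master seeds. The acceptance suite checks
the direction of effect these conditions are designed to expose — expanded
arms beating the unexpanded arm in most master seeds — not any absolute
performance level. Per
master seed it reports pooled AUC for base / gen1 / gen2 arms and the
latent-overlap comparison of gen2 synthetics vs DCGAN samples (DCGAN: 15
epochs, side 64). Problem sizes are chosen so the whole benchmark runs in
minutes on one CPU core. `scripts/acceptance.py` reruns it from scratch and
writes the resulting numbers as JSON.

## Known limitations

- The built-in codec and classifiers are compact stand-ins trained from
  scratch; absolute metric levels are far below what pretrained backbones
  reach on real images. Only within-run comparisons are meaningful.
- FID from the random-projection extractor is not on the ImageNet-FID scale.
- The GAN baseline at benchmark size is under-trained by design (it exists
  to anchor the comparison, and a small GAN on ~20 images per class cannot
  do better); its FID/overlap should be read as "a poorly matched
  generator", which is also its observed role at full scale.
- `balance_classes` drops whole patients only; with very uneven eyes-per-
  patient counts the achieved balance is within one patient's image count.
- Multiclass pooled AUC is micro-averaged one-vs-rest over the flattened
  label/score matrix.
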