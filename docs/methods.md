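# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic cohorts do and do not emulate, and the
decisions taken where the design was genuinely open. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Diffusion-tensor metrics

The pipeline starts at sorted eigenvalue maps λ₁ ≥ λ₂ ≥ λ₃ (mm²/s);
tensor estimation from diffusion-weighted signals is out of scope. The
six metrics are MD, AD = λ₁, RD = (λ₂+λ₃)/2, the deviatoric magnitude
q = √Σᵢ(λᵢ−MD)², the total magnitude L = √Σᵢλᵢ², and FA. q and L follow
the standard decomposition of the tensor into isotropic and deviatoric
parts, which makes FA = √(3/2)·q/L an internal consistency identity that
the tests verify to 1e−12. An all-zero tensor has FA defined as 0 and is
counted in QC.

**Smoothing.** Maps are smoothed *after* metric computation (the
alternative — smoothing eigenvalues first — changes little for smooth
fields but is not what this pipeline does), slice-wise, with a Gaussian
of σ = 1 voxel truncated at 2σ. Kernel weights are renormalised over
in-mask voxels so masked-out neighbours contribute nothing: a constant
in-mask map is reproduced exactly and interior mass is conserved. Note
that mass sitting within a kernel radius of the mask boundary is *not*
exactly conserved — renormalisation trades conservation for unbiasedness
at edges.

**Normalisation.** Each smoothed map is rescaled linearly to [0, 1] over
the whole brain mask of both hemispheres, per animal and per map, with
the (min, max) bounds stored. The purpose is cross-animal comparability;
relative features (below) are computed from the smoothed, unnormalised
maps, since a ratio to the homologous voxel is already unit-free.

## Perfusion quantification

DSC signal is converted to relative concentration C(t) = −ln(S/S₀)/TE
with S₀ the mean over a pre-bolus baseline window; values are clipped at
zero and non-positive samples floored with a QC count. No arterial input
function deconvolution is attempted — only relative CBF is needed.

The bolus is fitted with a gamma-variate K(t−t₀)^α e^{−(t−t₀)/β} by
bounded Levenberg–Marquardt (trust-region reflective) least squares with
an analytic Jacobian, parameterising ln K for scale robustness.
Initialisation is moment-matched: t₀ from bolus-arrival detection (first
sample above baseline mean + 3 SD), α = 3, β = (time-to-peak − t₀)/α and
K from the peak height. Recirculation is excluded by fitting only up to
the first post-peak sample below 20 % of the peak (config-exposed). A
curve with no detectable peak is marked unconverged and the voxel is
excluded downstream with a QC count.

Summary measures use closed forms: rCBV = Kβ^{α+1}Γ(α+1) (curve
integral), rMTT = β(α+1) (normalised first moment **measured from bolus
arrival t₀**, not from acquisition start — including t₀ would make rCBF
depend on injection timing), and rCBF = rCBV/rMTT. Map-level fitting
deduplicates byte-identical concentration curves, which collapses the
cost on noiseless synthetic data and is a no-op on noisy data.

## PDM labeling

Hemispheres split at the image midline (even column count required). The
*threshold* reference is the contralateral-hemisphere mean (ventricles
excluded from the reference as well as from candidacy); the voxel-mirror
homologue is used only for relative features, where a voxel-wise
correspondence is the stated intent. Thresholds use strict inequality —
a voxel exactly at threshold is not lesion:

- IC: MD < 0.70 × contralateral mean, ipsilateral, non-ventricle;
- deficit: rCBF < 0.54 × contralateral mean;
- IP = deficit ∖ IC; NT = ipsilateral remainder. IC voxels outside the
  deficit keep the IC label (diffusion lesion takes precedence) with a
  QC count.

Coregistration between the rCBF and MD grids is an identity transform
(phantom grids are aligned); resampling hooks exist but registration is
out of scope.

**Contiguity correction.** A labeled voxel whose within-slice
8-neighbourhood contains ≥ 6 voxels of a single *other* class is
reassigned to it (ties toward the lower class code; excluded voxels never
count and never change), one synchronous pass by default. This is a
declared minimal rule — the literature it stands in for does not fix an
algorithm. The phantom generator stores its geometric truth *after* the
same correction so that ground truth and the labeling stage's output are
defined on identical terms; on a noiseless cohort the round trip is then
voxel-exact, which the acceptance suite checks.

## Feature engineering (110 per voxel)

Order: [18 relative-DTI | 90 histogram | 2 Mahalanobis].

- **Relative DTI (18).** rX = (X − X_mirror)/X_mirror for the six
  metrics at the voxel and at (slice−1, slice+1) with nearest-slice
  replication at the stack edges. A mirror value below 1e−12 (or outside
  the mask) yields 0 with a QC count.
- **Histogram (90).** Per metric: an 11-bin normalised histogram
  (equal-width bins on [−1, 1], outliers clipped into end bins — relative
  reductions are bounded below by −1) over the 7×7 coronal window, plus
  its skewness and kurtosis (13 features), and skewness and kurtosis over
  a 3×3 window in the axial projection rebuilt from the coronal stack
  (2 features): 6 × 15 = 90. Bin counts come from the coronal window only
  — 49 samples support 11 bins, the axial window's 9 do not. Windows are
  centred with edge replication; moments are population moments (kurtosis
  is excess) with a zero-variance convention of 0.
- **Mahalanobis (2).** Distances from the voxel's relative-DTI features
  to the Gaussian summary (mean, covariance) of the *training* IC voxels,
  in the 6-dim same-slice space and the 18-dim three-slice space. The
  110-total fixes the Mahalanobis count at two; this composition is a
  declared reconstruction. The covariance gets a ridge of
  1e−6 × mean(diagonal) (absolute floor 1e−12), escalated ×10 if a
  Cholesky factorisation fails. Distances use Cholesky solves, not an
  explicit inverse.

Eligible voxels are the ipsilateral, in-brain, non-ventricle set. The
matrix is emitted as a pandas DataFrame/CSV with meta columns
(rat_id, slice, row, col, label) and a fixed, documented column order.

## Classification

Level 1: IC vs non-IC on the 18 DTI features. The IC distribution is
fitted on the *labelled* training IC voxels, frozen into the model, and
used to fill the Mahalanobis block of the non-IC rows (training uses the
labelled non-IC rows; prediction uses the level-1-predicted non-IC rows).
Level 2: IP vs NT on all 110 features. The single-level baseline is one
3-class model on the 18 features.

Backend hyperparameters are declared defaults, not tuned: RBF SVM with
C = 1 and γ = 1/(2m²) from the median pairwise distance m of (up to 500,
seeded) standardised training rows; KNN with k = 5; CART with default
depth control and a fixed random state. Features are standardised to
train-set mean/SD before SVM/KNN. Class weighting is off by default (a
`balanced` flag exists for experimentation).

## Evaluation

LOOCV over animals is the held-out estimate; a voxel-level stratified
5-fold split of the pooled training data (`kfold_cv_report`) is the
within-training estimate — the two are reported separately because their
roles differ. Per fold and pooled: accuracy (percent), sensitivity and
specificity (fractions) and rank-based AUC for IC vs non-IC over all
hemisphere voxels, and for IP vs NT over voxels that both the reference
and the prediction call non-IC (only those carry a level-2 score).
Slice-to-slice volume correspondence uses voxel counts × voxel volume
(in-plane 0.16 × 0.16 mm; slice thickness defaults to 1 mm and is
config-exposed — volumes are internally consistent either way) and a
Pearson correlation per tissue. Per-animal total volumes are compared
with a two-sided Mann–Whitney U-test (exact null for small untied
samples, tie-corrected normal approximation otherwise, p = 1 for fully
tied data).

## Synthetic cohorts

The generator emulates the acquisition geometry the analysis assumes:
multi-slice coronal volumes (64×64 acquisitions zero-filled to 128×128 at
0.16 mm in-plane can be emulated with the `kspace_zerofill` flag, default
off since zero-filling affects smoothness only), ~5 slices per animal,
and a DSC series of 300 samples at TR = 1 s, TE = 20 ms with bolus
arrival at 30 s.

Structure per animal: a mirror-symmetric elliptical brain mask; small
symmetric periventricular regions at 2.5 × normal MD; one random
ellipsoidal IC spanning contiguous slices with an IP rim 1–3 voxels thick
(range config-exposed), confined to one hemisphere. Normal tissue has
λ = (1.2, 0.9, 0.6)×10⁻³ mm²/s with a smooth, mirror-symmetric
*trace-preserving* anisotropy modulation — MD stays flat and FA stays
left-right symmetric, matching the hyperacute observation that lesions
show in diffusivity but not FA. Lesions scale all three eigenvalues
uniformly: 40 % drop in the IC, 10 % in the rim. CBF drops are graded
IC 0.80 > IP 0.60 > ipsilateral NT 0.10 (contralateral 0): the
per-tissue magnitudes are not reported in the stroke literature this
emulates beyond the 46 % viability threshold, so they are chosen to
straddle that threshold with a margin, and the spec validator rejects
configurations whose ground truth the thresholds could not recover.
DSC curves are forward-modelled through the same gamma-variate/signal
equations the analysis inverts, with amplitude ∝ (1 − drop), so
recovered rCBF ratios equal (1 − drop) exactly in the noiseless limit.

Noise is additive Gaussian on eigenvalues (clipped at 0, re-sorted;
default SD 5×10⁻⁶ mm²/s ≈ 0.6 % of NT MD, a high-quality acquisition)
and on the DSC signal (default SD 1 % of baseline). Not emulated: Rician
noise statistics, partial-volume mixtures, anatomically realistic
geometry, motion, susceptibility artefacts, multifocal or non-convex
lesions, and perfusion-lesion mismatch of arbitrary shape. Passing tests
therefore demonstrate that the *pipeline machinery* is correct and that
the classifier recovers labels under the assumed contrasts — not that
the reported accuracies would transfer to animal data.

## Problem sizes and study conditions used by the tests

- Unit and oracle tests run on grids of 10²–10³ voxels.
- The shared LOOCV cohort: 8 animals, 3 slices, 48×48 grid, noiseless —
  the separable condition under which two-level SVM LOOCV is required to
  reach ≥ 95 % IC-vs-non-IC and ≥ 90 % hemisphere accuracy.
- The baseline comparison cohort: same geometry with a 1-voxel IP rim
  and eigenvalue noise SD 1.2×10⁻⁴ mm²/s (≈ 13 % of NT MD, a noisy
  acquisition): with penumbral DTI contrast partially masked by noise,
  the single-level 18-feature model loses penumbra sensitivity relative
  to the two-level model — the qualitative contrast the hierarchy is
  designed to produce.
- `scripts/acceptance.py` reruns both cohorts from scratch plus the
  closed-form and round-trip oracles; everything is a pure function of
  `--seed`.

## Known limitations

- Gamma-variate fitting is per-voxel and costs ~5 ms per noisy curve;
  large noisy cohorts are slow (noiseless curves deduplicate).
- The hemisphere-mean threshold reference assumes a lesion-free
  contralateral hemisphere and a midline-aligned acquisition.
- The contiguity rule and the 110-feature composition are declared
  reconstructions where the source conventions are underspecified.
- Model serialisation uses joblib; portability across library versions
  is not guaranteed.
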