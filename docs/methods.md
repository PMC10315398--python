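# Methods

This note records the scientific and numerical choices behind the package:
the signal and kinetic models, the estimators, the synthetic-data
generator's assumptions, and the places where the design was genuinely open.

## Signal model and synthesis

Each acquisition of the dual-gradient-echo (DGE) sequence produces two
spoiled-gradient-echo readouts sharing one T1-weighted steady state:

    F(t) = M0 sinθ (1 − E(t)) e^(−TE1/T2*(t)) / (1 − cosθ E(t)),
    S(t) = M0 sinθ (1 − E(t)) e^(−TE2/T2*(t)) / (1 − cosθ E(t)),

with E(t) = exp(−TR/T1(t)). Contrast agent shortens both relaxation times:
R1(t) = 1/T1pre + ΔR1(t), and 1/T2*(t) = 1/T2*pre + κ·ΔR1(t). The default
κ = 0 (pure-T1 synthesis) makes the relaxometry inversion exact; κ > 0 is a
stress mode. Noise is additive zero-mean Gaussian per echo (a Rician
magnitude model is deferred; at the configured baseline SNR of 20 the
magnitude bias is negligible). "SNR" always means first-echo baseline
signal over noise standard deviation, averaged over the brain — noise is
spatially uniform, as in a real image.

Protocol defaults are the study conditions: TR/TE1/TE2 = 24/2/4 ms, flip
angle 18°, 400 acquisitions at 1.55 s, bolus at acquisition 15 (1-based),
hematocrit 0.45 (a typical rat value; configurable).

### Phantom

The phantom is a 64×64×3 ellipse "brain" containing a tumor disk split into
a rim (model 3: leakage with back-flux) and core (model 2: leakage without
measurable back-flux), normal tissue (model 1), and a square
caudate-putamen reference patch pinned to vp = 0.01 for AIF normalization
(grown to at least ~4×4 voxels on small grids). Parameters are drawn per
voxel, uniformly: vp 0.006–0.02 (normal) / 0.01–0.04 (tumor), Ktrans
0.05–0.15 min⁻¹, kep 0.3–0.8 min⁻¹, T1pre 1.7–2.1 s, T2*pre 20–30 ms.
These are typical rodent-glioma scales; nothing in the pipeline depends on
them beyond being physiologically plausible.

### Arterial input function

No published population AIF shape accompanies this protocol, only the
normalization rule (vp = 1% in caudate putamen). The default is a
gamma-variate bolus peaking 10 s after injection, a smaller recirculation
bump, and a washout plateau decaying with a 600 s time constant — slow,
as gadolinium plasma clearance over a 10-minute experiment is modest. The
absolute amplitude is irrelevant: the reference-region normalization fixes
the scale in closed form (the model-1 fit is linear in Cp).

The post-study T1 map is emitted from truth as the T1 whose steady-state
amplitude equals the mean amplitude over the late saturated window — the
map a T1-mapping sequence run right after the DCE study would see.

## Relaxometry

With μ = TE2/TE1, the combination F^(μ/(μ−1))/S^(1/(μ−1)) cancels the T2*
factor exactly and isolates the T1-dependent amplitude A(T1). Window sums
over a pre-injection baseline (acquisitions 5–14 by default — the last ten
before the bolus) and an equally long late window (last ten acquisitions)
give the amplitude ratio Q = A_sat/A_pre, from which the flip angle follows
by exact algebraic inversion of the steady-state equation using E_pre and
E_post from the T1 maps:

    cosθ = [(1 − E_post) − Q(1 − E_pre)] / [E_pre(1 − E_post) − Q E_post(1 − E_pre)]

ΔR1(t) then follows from the per-timepoint amplitude ratio ρ(t) = A(t)/A_pre
(same sum-then-power window structure, including the (n−m+1) factor):

    E(t) = [(1 − cosθ E_pre) − ρ(1 − E_pre)] / [(1 − cosθ E_pre) − cosθ ρ(1 − E_pre)]
    ΔR1(t) = −(1/TR) ln(E(t)/E_pre)

Two structural properties are preserved exactly: at baseline the window
product telescopes and ΔR1 ≡ 0, and ΔR1 never uses the post-study T1 map
(only the flip angle does). The noiseless round trip recovers θ to < 1e−4
degrees and ΔR1 to < 1e−6 s⁻¹ over the whole phantom.

**Flip-angle pooling.** The per-voxel arccos is ill-conditioned wherever
tissue barely enhances (E_post ≈ E_pre gives 0/0); at SNR 20 most
normal-tissue estimates are unusable. Since the flip angle reflects the
smooth shared B1 field, the default policy estimates it per voxel, takes
the median over the most strongly enhancing quartile of estimable voxels,
and applies that angle brain-wide; each voxel's ΔR1 still comes from its
own signals. Strict per-voxel estimation with exclusion of degenerate
voxels remains available (`theta_policy="voxel"`) and is what the noiseless
round-trip test exercises.

## Pharmacokinetic fitting and model selection

Models 1–2 are linear in their parameters and solved exactly by least
squares; model 3 is nonlinear only in kep. The single-curve API runs a
Nelder–Mead simplex over (vp, Ktrans, √kep) from the model-2 solution plus
two jittered restarts at alternative kep starting points; the whole-map API
profiles kep over a 60-point geometric grid (0.02–5 min⁻¹) with
log-parabolic refinement and one exact re-solve — the two routes minimize
the same residual and agree to the grid-refinement accuracy (~1e−3 relative
RSS). The convolution uses trapezoidal quadrature on the acquisition grid
via an O(n) exponential-kernel recursion; curves are fitted on the full
grid including the pre-injection baseline. Internally time is in seconds;
Ktrans and kep are converted to min⁻¹ at the fitting boundary.

Three deliberate choices, made because the obvious alternatives provably
fail:

* **A per-voxel baseline nuisance offset** is fitted in every model. The
  log-domain ΔR1 estimator leaves a small voxel-specific constant bias in
  noisy data (Jensen bias of the noisy window sums); unmodeled, it projects
  onto the ∫Cp regressor and inflates the false-leakage rate by an order of
  magnitude.
* **Unconstrained vp/Ktrans in the fit** (kep ≥ 0 via squaring), with
  non-negativity enforced only on the exported maps. An active bound at the
  Ktrans = 0 null halves the realized type-I error of the F-test and breaks
  its calibration; the classical F(1, N−k) null requires the unconstrained
  optimum.
* **Selection gate = the 2-df F of model 3 against model 1**, followed by
  the 1-df F of model 3 against model 2. A strict forward 1→2→3 scheme is
  blind to washout voxels: a rise-and-fall curve cannot be approximated by
  the monotone model-2 term at all, so the 1-vs-2 gate never fires even
  when model 3 fits almost perfectly. The gate keeps the parsimony logic
  and the exact α under the model-1 null up to ~1 percentage point of
  inflation from kep profiling (measured 5.98% at nominal 5%). An RSS
  improvement below 1e−12 of the curve energy is treated as a numerical
  tie, so noiseless fits never advance on floating-point residue.

Operating characteristics at the study conditions (SNR 20, default
phantom): type-I error within the binomial band of 5%; ~95% 3-class label
accuracy (~98% balanced); voxels with fast back-flux (kep ≳ 0.5 min⁻¹)
equilibrate toward an elevated-vp appearance and are the dominant residual
confusion — an identifiability limit of the model family, not an optimizer
artifact. Parameter bias over 100 SNR-20 replicates is < 1% (vp, Ktrans,
kep well within the 10%/15% design bands).

## Radiomics

Echo profiles are normalized per voxel by the mean of the last 10
first-echo timepoints (both echoes divided by the first-echo factor), then
quantized per slice per timepoint to 128 levels by fixed bin number over
the brain mask — per-slice quantization matches the 2-D convolutional
processing and keeps timepoints comparable after the global normalization.
Features are computed in a sliding 5×5 window, only where the full window
lies inside the mask (no padding), and assigned to the central voxel.

The 133-feature registry (IH 21, IBS 17, GLCM 25, GLRLM 16, GLSZM 16,
GLDZM 16, NGTDM 5, NGLDM 17) ships as a JSON manifest validated at load
time. The IBSI reference lists are slightly larger in two categories; to
reach the designed counts the two histogram-gradient grey-level locator
features are omitted from IH and root-mean-square from IBS. Intensity-based
statistical features use the normalized (unquantized) window values;
intensity-histogram features use the quantized levels. GLCM and GLRLM are
built per 2-D direction (0°, 45°, 90°, 135°, Chebyshev distance 1, GLCM
symmetric) and averaged over directions; GLSZM/GLDZM zones and the NGTDM/
NGLDM neighborhoods use 8-connectivity, computed once per window. NGLDM
uses coarseness α = 0 and dependence j = (equal neighbors) + 1.

Degenerate conventions, mirrored by the tests' independent brute-force
oracle: spread-normalized statistics (skewness, kurtosis, coefficient of
variation) fall back to 0 when the spread vanishes, GLCM correlation is 1
for a constant window, information correlation 1 is 0 when the marginal
entropy vanishes, NGTDM coarseness saturates at 1e6, histogram mode ties
break to the lowest level, and percentiles interpolate linearly. Every
feature is verified against a loop-level reimplementation to 1e−9 on random
and degenerate windows.

## Screening, SOM, statistics, NCV

**NCER.** The contrast-enhancement ratio of a region is the plateau-window
mean over the baseline-window mean (the exact published formula is not
restated in the source literature; this reconstruction is scale-invariant
and reduces to 1 for non-enhancing dynamics). NCER = CER_tumor/CER_normal
with tumor = models 2∪3 and normal = model 1 from the model-choice map.
Modalities are retained when mean NCER ≥ 1.2; raw echoes are always
retained as the comparison baseline, and the study configuration keeps the
13 highest-NCER features per echo (28 modalities total). On the default
phantom roughly 45–50 of 133 features clear the threshold per echo.

**SOM.** 10×10 hexagonal lattice (axial coordinates, unit spacing), batch
training: BMU by minimum Euclidean distance (ties to the lowest node
index), then every node weight becomes the Gaussian-kernel-weighted mean of
assigned profiles, h = exp(−d²/2σ²) with σ = current radius. The radius
decays linearly 3 → 1 over the 100 ordering epochs ("cover steps") and
holds at 1 for the remainder of the 200 epochs. Weights initialize from a
seeded sample of training profiles (PCA-plane initialization available).
Zero-hit nodes carry explicit missing probabilities and are excluded from
silhouette analysis, never imputed. Plain-BMU batch training minimizes the
kernel-smoothed distortion, not the raw quantization error, and at fixed
radius can sit in a sub-percent QE limit cycle; the monotonicity test
allows that wobble.

**Silhouette sweep.** Samples are the SOM node weight vectors (a 10×10
topology analysis operates on the feature space, not on 10⁵ voxels). At
each of 100 thresholds a node is included if its maximum class probability
reaches the threshold and labeled by argmax (ties to the lower class);
silhouettes are Euclidean with the singleton-cluster score 0. The mean SC
at a threshold weights all clusters by node count. DSC% compares
threshold-averaged mean SCs. Levene's test is mean-centered (with W = 0,
p = 1 for identical-spread degenerate inputs); homogeneous pairs get a
two-sample ANOVA, heterogeneous pairs Welch's test; Holm–Bonferroni is
applied across the feature comparisons of each echo; significance requires
adjusted p < 0.05 and DSC% > 0.

**NCV.** Profiles are permuted once (seeded) and chunked into 10 disjoint
near-equal folds shared by all modalities. Per fold, the SOM and its class
probabilities are built from the training portion only — screening and
labeling never see the test fold — and held-out profiles are scored by
their BMU restricted to hit nodes. Because the classes are heavily
imbalanced, "adjusted" metrics are micro-averaged: AUC pools all
(sample, class) one-vs-rest decisions (mid-rank ties), balanced accuracy is
the mean per-class recall, F1 comes from pooled confusion counts at argmax.
Confidence bounds are a seeded 1000-resample bootstrap over folds (the CI
construction was an open choice). Voxel-wise folds ignore animal-level
grouping; with a single synthetic subject per run there is no grouping to
respect.

## Problem sizes

Default configuration = study conditions: 64×64×3 phantom, 400
acquisitions, SNR 20, 128 levels, 5×5 window, 13 features/echo, 10×10 SOM,
200 epochs, 10 folds. The test suite and the acceptance script run
reduced-size instances chosen as the package's own desk-scale defaults:
single-slice phantoms (24–32 px), strided dynamic sampling (every 10th of
the 390 retained timepoints), 15–40 SOM epochs, and a few hundred profiles
per modality — every stage still executes end to end, and the full-duration
400-acquisition grid is always used for synthesis, relaxometry, and
kinetics. What passing tests show is that the estimators are exact where
exactness is claimed and well calibrated under the generator's noise model;
they do not show that real rat data would rank the same features highly —
the generator has no motion, B1 inhomogeneity, partial-volume mixing,
k-space effects, or inter-animal variability.

## Known limitations

* ΔR2* quantification is synthesized (κ > 0) but never inverted.
* The sequential F-selection inherits the identifiability limit for fast
  back-flux voxels described above.
* Silhouette samples are SOM nodes; with ≤ 100 nodes the per-threshold SC
  means are grainy compared to voxel-level analysis.
* The NCER formula is a reconstruction (see above), flagged here
  prominently.
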