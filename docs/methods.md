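# Methods

## Phantom model

A phantom subject is a regular grid (default 40×40×10 voxels, 2 mm
isotropic) representing an axial slab at the lateral-ventricle-body level.
The deterministic region map mirrors left/right hemispheres around the
midline: a central ventricle block (isotropic CSF, 3.0×10⁻³ mm²/s), then —
moving laterally in each hemisphere — a projection-fiber band (principal
axis z), an association-fiber band (principal axis y) and a subcortical
band (principal axis x); corpus-callosum blocks (principal axis x) sit
medially, anterior and posterior to the ventricle. Background tissue is
isotropic at 0.8×10⁻³ mm²/s and lesions, when configured, are isotropic at
1.2×10⁻³ mm²/s (edema-like). All fiber tensors are axis-aligned and
diagonal, so ground truth is known per voxel in closed form.

Baseline fiber eigenvalues default to (1.4, 0.4, 0.4)×10⁻³ mm²/s — typical
deep white matter. Perivascular fluid mobility is a per-hemisphere
*glymphatic coefficient* g ≥ 0 multiplying λ3 to give the x-axis diagonal
element inside the projection and association bands only. Because λ2 = λ3
at the defaults, the ground-truth index

ALPS = mean(g·λ3, g·λ3) / mean(λ2, λ2) = g,

which makes parameter recovery transparent: the measured index should equal
the coefficient. Configurations with g·λ3 > λ1 are rejected (the band's
principal axis would flip and the region labels would lie); g·λ3 = λ1 is
allowed so a fully isotropic phantom (equal eigenvalues, g = 1) remains
expressible.

Signals follow the monoexponential tensor model S = S0·exp(−b·gᵀDg) with
S0 = 1000. Noise is Rician — each magnitude sample becomes
√((S+n₁)² + n₂²) with n₁, n₂ ~ N(0, σ²) — since DWI magnitudes are
Rician-distributed; additive Gaussian is available for comparison. All
noise is seeded through `numpy.random.default_rng`.

## Acquisition scheme

The default scheme has 129 volumes: one b = 0 plus 128 distinct directions
from a spherical-Fibonacci lattice, with 17 evenly spaced non-zero b-values
up to 3,000 s/mm² assigned cyclically (18 distinct b-values in total). This
emulates a DSI-style multi-b acquisition without reproducing any vendor
table; the exact shell list of any given scanner protocol can be supplied
through `AcquisitionScheme` directly or bval/bvec files.

## Tensor fit

Fitting restricts to shells with b ≤ 1,150 s/mm² (the monoexponential model
degrades at high b). The estimator solves log S = log S0 − b·gᵀDg by
ordinary least squares jointly for the six tensor elements and log S0 —
one pooled `lstsq` because the design matrix is shared across voxels. WLS
(weights S²) is available for noisy data; both agree exactly on noise-free
input. S0 is fitted, not averaged from b = 0 volumes, keeping one
consistent least-squares system. Signals are floored at 1e-10 before the
log; design rank < 7 (coplanar directions) is rejected with the condition
number. Eigenvalues are clamped at 1e-9 mm²/s before FA/MD so noisy
background voxels cannot produce NaN; an all-zero tensor yields FA = 0.

## ROIs and the index

ROIs are axis-aligned cuboids defined by a center voxel and physical size:
12×4×2 mm for the projection/association (ALPS) ROIs, 4×4×2 mm for CST and
corpus callosum — at 2 mm voxels, 12 and 4 voxels respectively. An
auto-placement helper seeds centers from the phantom's region labels using
band-bounds midpoints, so even-extent ROIs sit exactly inside their bands;
explicit `RoiDefinition` lists override it for custom placements. The CST
ROI lives inside the projection band (the corticospinal tract is a
projection pathway), offset from the ALPS ROI center. A lesion mask
overlapping any ROI flags the *subject* as excluded; ROIs are never trimmed
or nudged, mirroring clinical practice where such subjects leave the
analysis.

"Diffusivity along axis a" is the diagonal element eᵃᵀDeᵃ of the fitted
tensor in the image frame — not an eigenvalue — averaged over the ROI
before the ratio is formed. The index is mean(Dxx_proj, Dxx_assoc) /
mean(Dyy_proj, Dzz_assoc), computed independently per hemisphere.

## Cohort simulator

`simulate_cohort` draws per-subject variables from a group-specific
multivariate normal (Cholesky, seeded) and clips bounded scores afterwards:
motor score to 0–100, sensory to 0–24, FA to 0–1, days post onset to 7–40.
Clipping slightly attenuates tail correlations but preserves the monotone
associations that the rank-based (Spearman) analyses consume; a
rank-preserving transform was considered and rejected as unnecessary
complexity. Defaults encode the published design: 20 IS / 30 HC; left/right
ALPS means±SDs 1.424±0.132 and 1.381±0.172 (IS) versus 1.565±0.197 and
1.454±0.107 (HC); age 59.2±12.1 vs 54.6±7.4; 80% vs 67% male; targeted IS
correlations corr(ALPS_left, motor) = 0.5 and
corr(ALPS_left, CST-FA_right) = −0.55. Motor/sensory scores and onset
times for controls are structurally missing. Values the study did not
summarize (CST/CC FA and MD moments, motor-score spread) use typical
white-matter and rehabilitation-cohort magnitudes and are stated in
`data/cohort_defaults.yaml`. Correlation targets are validated for positive
semidefiniteness; the error message includes the nearest PSD matrix.

What the simulator does *not* emulate: skewed onset-time and score
distributions (the published medians suggest skew; we use clipped
normals), lesion-size heterogeneity, scanner/site effects, and any causal
structure — correlations are targets, not mechanisms. Passing tests
therefore validate the statistical machinery and the measurement chain,
not clinical effect sizes on real patients.

## Statistical plan

Group comparisons default to Welch's t (unpooled variances,
Welch–Satterthwaite df). Both Welch and Student variants accept printed
summaries (mean, SD, n) or raw samples through one shared formula, so
summary- and sample-based results agree exactly. Welch is pinned for the
ALPS and age group comparisons because it reproduces the published t
statistics from the published summaries (−3.03 and 1.52 against printed
−3.02 and 1.50), where Student's pooled t gives −2.80 and 1.67. The 2×2
sex comparison uses Pearson χ² with Yates continuity correction, which
reproduces the published χ² = 0.50 exactly. The published right-side ALPS
comparison (t = −1.87) is not reproducible from its summaries under either
variant (−1.69 Welch, −1.85 Student), presumably because the underlying
per-subject values were rounded for print; it is reported by the analysis
scripts but asserted nowhere. Lateralization uses a paired t on
within-subject left–right differences. ALPS–FMA associations use Spearman
mid-rank correlation; ALPS–CST associations use Pearson partial correlation
(residual method, df = n−2−k) controlling age and days post onset.
Correlation-family p-values receive a Benjamini–Hochberg adjustment by
default (Bonferroni optional) — the original analysis names no procedure.
α = 0.05, two-sided throughout.

Calibration uses 2,000 vectorized replicate cohorts at the published group
sizes and SDs: with equal means the Welch rejection rate at α = 0.05 is
≈ 0.05 (observed 0.054 at seed 314159); at the published means the
replicate t averages ≈ −3.08, confirming the printed effect size and test
statistic are mutually consistent.

## Problem sizes and numerical choices

Image-level tests run on a 40×24×4 slab (the smallest grid the default
geometry supports) and acceptance-level recovery on 40×40×10 — both carry
the full 129-volume scheme, and noise-free recovery is exact to ≲1e-8
regardless of grid size because the fit is linear. The image-level cohort
driver defaults to a handful of subjects per group; group-level inference
at n = 20/30 is exercised through the table-level simulator, which is where
sample size matters. Monte-Carlo checks (Rayleigh mean of pure-noise
magnitudes, FA recovery at SNR 30) use seeds fixed in the tests.

## Known limitations

Axis-aligned diagonal phantom tensors cannot probe errors specific to
oblique fibers (off-diagonal recovery is covered by randomized-tensor
tests, but ROI extraction always reads image-frame diagonals, as the
method prescribes). Preprocessing of real acquisitions — eddy/motion
correction, brain extraction, susceptibility distortion — is out of scope;
phantoms are motion-free and pre-masked. No GQI/ODF reconstruction or
tractography: CST metrics come from fixed ROIs. The file interface reads
uncompressed or gzipped NIfTI-1 only.
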