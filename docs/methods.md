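# Methods

This note documents the statistical models implemented in `spatmsi`, the
parameter defaults and why they were chosen, the numerical decisions that
matter for reproducibility, and what the synthetic benchmark does and does
not demonstrate.

## Data model and conventions

A dataset is a 2D pixel raster with one profile-mode mass spectrum per
pixel plus per-pixel block labels (tumour model, section/slice, treatment
arm).  Coordinates are 0-based `(row, col)` integers, row-major; all
distances are Euclidean in pixel units.  The physical raster pitch
(typically 100 µm) is carried as metadata only — a lag distance of 5
always means 5 pixels.  Ion images hold NaN outside the tissue mask, and
every spatial statistic is computed over mask pixels only, including the
mean and standard deviation used for autoscaling.

## Pre-processing

**Tissue mask.** The marker-ion window (default m/z 281.1–281.44, a lipid
ion that separates tissue from the glass slide) is summed per pixel and
thresholded — Otsu by default, or a manual cut-off.  A 3×3 morphological
closing fills single-pixel holes; the result is unioned with the
pre-closing mask so closing can only add pixels (plain closing erodes at
the grid border under zero padding), and intersected with the acquired
pixel set.  Otsu is a deterministic stand-in for a visual confirmation
step; it is a design choice of this package, not a canonical procedure.

**Reference spectrum and peak picking.** The reference spectrum is the
pointwise maximum over all spectra (linear interpolation onto the longest
axis when axes differ), which preserves the location and shape of every
ion peak present anywhere in the dataset.  Spectra are denoised by a
discrete wavelet transform with the least-asymmetric Daubechies 8-tap
filter (`sym4` in PyWavelets) and hard shrinkage at the universal
threshold σ√(2 ln n), where σ is the median absolute deviation of the
finest-detail coefficients scaled by 1/0.6745.  Peaks are local maxima of
the denoised signal (plateaus count once) with apex ≥ `snr` × σ; `snr`
defaults to 3.  A relative prominence floor of 1e-8 of the signal scale
suppresses float-level ripple so that constant spectra yield no peaks.
At snr = 3 an occasional noise excursion above the universal threshold
survives (~7 % of random spectra in our fixtures gain one spurious peak);
raising `snr` trades sensitivity for that false-positive rate.

**Adaptive binning.** Chains of reference peaks with consecutive spacing
below `merge_tol` (default 0.05 Da, the instrument's mass-alignment
tolerance) collapse into one merged bin spanning the chain.  Boundaries
between adjacent bins sit at the midpoint between their edge peaks,
clipped to at most 0.25 Da from the apex.  Inter-bin gaps wider than
`gap_threshold` (1 Da) are tiled with contiguous filler bins of width
`gap_bin_width` (0.5 Da, last tile truncated), so ions present only in
weak single-pixel spectra still land in some bin.  Tiling the whole gap —
rather than inserting a single extra bin — is our reading of the rule; it
guarantees the covered range has no holes.  Per-pixel peak picking then
uses the same wavelet rule, and cell (pixel, bin) holds the maximum apex
intensity of the pixel's in-bin peaks (0 if none); the maximum was chosen
over the sum to keep merged bins on the apex scale.

**Per-ion cleaning.** Bins nonzero in fewer than `min_frac` (20 %) of all
tissue pixels, or whose nonzero pixels all lie in one tumour model, are
dropped.  Each ion image is median-filtered with a mask-aware 3×3 window
(median over in-mask neighbours only); then every rim pixel — fewer than
8 in-mask 8-neighbours — is replaced by the median of its in-mask
neighbours, suppressing the inflated intensities at the tissue/glass
boundary; isolated pixels are left unchanged with a warning.

**Normalisation and transformation.** Each pixel's spectrum is rescaled so
its median over nonzero bins equals the grand median of those per-pixel
medians (the grand median keeps the output on the original intensity
scale; pixels with no nonzero feature are dropped).  The generalised log
g(x) = ln((x + √(x² + λ))/2) then stabilises the variance; λ defaults to
1.0 on the post-normalisation scale and is configurable — we do not
reproduce any package-specific estimator of λ, and g coincides with ln(x)
at λ = 0.

**Batch correction.** Per ion, a least-squares model with an intercept,
optional protected factors (e.g. treatment) and sum-to-zero batch
contrasts is fitted; the fitted batch contribution, centred across pixels,
is subtracted.  Centring makes every batch mean equal the grand mean
exactly, and the output equals the residuals-plus-grand-mean of an
explicit indicator regression.  A batch factor perfectly confounded with
a protected factor is rejected.

**Drug decorrelation.** The drug bin is moved out of the clustering
features, and any remaining feature whose Pearson correlation with the
drug image exceeds `r_max` (0.9) is dropped, so drug-related signal cannot
drive the segmentation.  The signed (not absolute) correlation is used:
the filter targets features tracking the drug, not mirroring it.

## Segmentation

Pixels are clustered by bisecting k-means under correlation distance
d(a, b) = 1 − r(a, b): assignments depend only on spectral shape and are
invariant to positive affine transforms of a pixel's spectrum, which
suits ion-count data with nuisance intensity scaling.  Centroids are
arithmetic means of member rows; each bisection is a best-of-`n_init`
(10) Lloyd run, and an emptied cluster is reseeded with the worst-fitting
point.  Constant pixel spectra are rejected by name since their
correlation is undefined.

The largest cluster is always the split target.  Splits are mandatory
while the largest cluster holds more than `max_share` (40 %, with ≤
interpreted inclusively) of all pixels; afterwards splitting continues
only while the global Calinski–Harabasz score strictly increases, up to
`k_max` (10).  The two printed stopping criteria are under-specified in
combination; this mandatory-then-greedy order honours both
deterministically.  CH is computed with its standard Euclidean definition
on the (glog) feature matrix even though assignments use correlation
distance.  Under a fixed seed the segmentation is deterministic.

## Size-zone homogeneity

For one cluster on one section, the homogeneity ratio is

    ratio = (sum of connected-component sizes ≥ Nu) / tissue pixels,

with `Nu` = 5 and 8-connectivity by default (both configurable, including
4-connectivity and, via the zone list, a largest-zone-only numerator).
The ratio lies in [0, cluster share], is non-increasing in `Nu`, and is
higher when the cluster forms large contiguous regions rather than
scatter — "more homogeneous" in the tissue-architecture sense.  The exact
formula of the original continuous-intensity homogeneity index is not
reproduced; this is the cluster-image variant.

## Spatial statistics

**Weights.** W is a binary distance-band matrix: w_ij = 1 iff
0 < d(i, j) ≤ threshold, optionally row-standardised.  The binary
relation is symmetric; the row-standardised matrix is similar to a
symmetric one (D^-1/2 A D^-1/2), so its spectrum is real — this gives the
feasible parameter intervals and exact log-determinants of the regression
likelihoods from one cached eigendecomposition per W.

**Moran's I** = (n/S0) · Σ w_ij z_i z_j / Σ z_i², z = x − mean(x), with
E[I] = −1/(n−1) under spatial randomness.  **Correlograms** compute I per
annulus (d−1, d] for d = 1..max_lag with per-annulus row-standardised
weights; empty annuli yield NaN with a warning.  The annulus convention is
ours (an alternative is neighbour-order lags); the **LISA map** instead
uses the cumulative disk ≤ threshold, default 5 — on rook-generated SAR
fields the autocorrelation range at ρ = 0.6 is shorter than 5 pixels, and
analyses beyond lag 5 admit noise, so larger defaults are discouraged.

**LISA quadrants.** With z the autoscaled variable and lag = Wz, a pixel
is HH if z > 0 and lag > 0, LL if z ≤ 0 and lag ≤ 0, HL if z > 0 and
lag ≤ 0, LH otherwise.  Values exactly at the mean go to the low side — a
deterministic tie-break, measure-zero on real intensities.  All pixels
are classified; no permutation significance filter is applied to the
quadrants (quadrant membership, not local-statistic inference, is the
object here).

## Association

The LISA zones and cluster labels are cross-tabulated over shared mask
pixels.  Cramér's V is computed on the HH/LL row subset by default —
HL/LH hold few pixels and are transitional — as
V = √(χ²/(T·min(r−1, c−1))) with χ² the Pearson statistic against
independence expectations from the subset's own margins and T the subset
total.  V is invariant to rescaling all cells, so pixel counts,
fractions, and rounded percentages agree to rounding error; zero-margin
rows/columns are dropped with a warning.  The bundled percentage tables
for six ovarian-xenograft tumour images reproduce the published V values
to ±0.005 for five of the six images (the sixth, printed as 0.69,
recomputes to 0.699 from its rounded percentages and is excluded from the
reproduction script).

## Spatial regression and ion selection

The spatial lag model y = ρWy + Xβ + ε and spatial error model
y = Xβ + u, u = λWu + ε are fitted by maximum likelihood.  The
concentrated log-likelihood over the scalar parameter a ∈ {ρ, λ},

    ℓc(a) = −(n/2)·ln(SSE(a)/n) + Σ_i ln(1 − a·ω_i),

uses the cached eigenvalues ω of W for the log-determinant (exact, no
sparse approximation; fits refuse n > 5000 by default) and is maximised
by bounded Brent search on the feasible interval (1/ω_min, 1/ω_max),
shrunk by 1e-6, to 1e-8 tolerance; a solution at the boundary warns.  For
SL, SSE(a) comes from the residuals e0 − a·e_d of y and Wy on X; for SE,
from the filtered regression of (I − aW)y on (I − aW)X.  Wald standard
errors come from the observed information — the central-difference
Hessian of the full log-likelihood at (β̂, â, σ̂²) — which avoids the
trace terms of the analytic expected information that cannot be expressed
through the eigenvalues alone; at ρ = 0 the likelihood and β̂ reduce
exactly to Gaussian OLS.

Marker selection for a cluster regresses each ion image on a one-vs-rest
cluster indicator per section, adjusts the indicator p-values across ions
within the section by Benjamini–Hochberg (α = 0.05 per section; per-slice
rather than pooled adjustment is our choice), and intersects the
significant sets over all sections examined.  Constant ion images get
p = 1.  The coefficient sign records whether the ion is high (+) or low
(−) inside the cluster.  Analysis weights are rebuilt per section at the
chosen lag distance (default 5).

## Synthetic benchmark

The generator emulates the structure the selection step assumes and
nothing more: per section, a spatially coherent two-class image (a
Gaussian random field smoothed with σ = grid/8, thresholded at its
median), informative ions δ·1[class 2] + SAR noise, and pure SAR noise
ions, with SAR fields y = (I − ρW)⁻¹ε on rook weights, ρ_gen = 0.6,
σ = 1, δ = 1 by default.  It does not emulate real MSI features: no
intensity-dependent noise, no m/z-correlated features, no mask geometry,
no batch structure, and classes are exactly two.  Passing benchmarks
therefore demonstrate the statistical behaviour of the estimators under
spatial autocorrelation — OLS's anti-conservative p-values and the
spatial models' calibration — not performance on real tissue.

On this benchmark the spatial lag model matches or beats OLS and SE in
final-set accuracy, keeps the per-section false-positive rate at or below
the nominal level where OLS exceeds 0.10, and holds its sensitivity
across analysis lag distances 1–10 (the intersection-over-sections rule
masks much of OLS's inflation in the final set; the per-section rates
expose it).

**Problem sizes.** Function defaults keep the illustrative scale (60×60
grid, 10 + 40 ions, 5 sections, 50 replicates).  The test-suite and
benchmark runs use desk-scale configurations — 20×20–40×40 grids, 15–25
ions, 3–6 sections, 8–50 replicates — chosen so the full suite runs in
minutes on one CPU; the qualitative orderings above are stable at these
sizes, and all Monte-Carlo assertions carry explicit MC tolerances.

## Pipeline

`run_pipeline` executes preprocess → segment → homogeneity → lisa →
associate → select from a single YAML config (unknown keys rejected),
writes every artifact as CSV plus a JSON manifest with SHA-256 hashes,
records any stage failure with the stage name while retaining partial
outputs, and is byte-reproducible under a fixed seed.  CSV floats are
written at 10 significant digits; determinism relies on fixed seeds, not
on floating-point environment tricks.

## Known limitations

- No m/z recalibration, isotope deconvolution, adduct annotation, or ion
  identification; no vendor raw formats; no 3D MSI or optical-image
  coregistration.
- Dense eigendecomposition bounds spatial ML fits to n ≤ 5000 pixels per
  section by default; larger sections need tiling.
- LISA quadrants carry no permutation-based significance.
- The mixed-model treatment comparisons of pixel/homogeneity ratios are
  out of scope (standard `nlme`-style fits on the exported CSVs).
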