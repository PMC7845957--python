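# Methods

## The measurement model

The package estimates the arithmetic-mean surface roughness
Ra = (1/N)·Σ|h − h̄| of a surface from a single 8-bit speckle image of the
laser light it backscatters.  The underlying assumption is empirical: as a
surface roughens at the nanoscale, its speckle image darkens, its bright
patches grow, and its gray-level co-occurrence matrices (GLCMs) concentrate
toward the principal diagonal.  No single texture statistic tracks Ra
reliably across distances and directions, so the method pools many
correlated statistics and lets principal component analysis extract the one
direction of variation they share, which is then calibrated against
reference Ra values.

### Texture features

For each image, symmetric GLCMs are computed at distances d = 1…10 px along
the four principal directions.  The direction offsets, in 0-based
(row, col) coordinates, are 0°: (0, +d), 45°: (−d, +d), 90°: (−d, 0),
135°: (−d, −d); in symmetric mode the reverse offset is counted as well, so
the count matrix equals its transpose exactly.  Neighbours falling outside
the image are skipped (no padding).  Pixels are used at native 8-bit depth
(256 levels, no re-quantisation); an optional level reduction is available
through the GLCM spec.  Which image-axis diagonal is called 45° versus 135°
is a convention; swapping it only exchanges the two diagonal feature blocks
and does not affect any downstream result.

Eight Haralick statistics are evaluated per GLCM.  Three conventions:

* Logarithms in the entropies (ENT, DE) are natural by default and
  configurable; the choice only rescales those features and is removed by
  standardisation.  0·log 0 := 0.
* DE is the entropy of the absolute-difference marginal
  P_{x−y}(k) = Σ_{|i−j|=k} P(i,j), consistent with DA and DV.
* The correlation statistic divides by the *standard deviations* of the row
  and column marginals (square roots of their variances), which is what
  bounds CORR to [−1, 1].  When either marginal has zero spread, CORR is
  undefined and propagated as NaN — never silently zero.  Feature assembly
  fails loudly on NaN unless the CORR block is excluded from the run, in
  which case it is never computed.

Each statistic-versus-distance curve (10 points per direction) is fitted
with y = y₀ + A·e^(−Bx).  The decay constants A and B describe how quickly
pixel pairs decorrelate with distance and vary erratically between
realisations; the asymptote y₀ is stable and is kept as the 11th feature of
each (parameter, direction) block.  Fitting uses trust-region least squares
with B constrained positive, initial guesses y₀ = y(x_max),
A = y(x_min) − y₀, B from a log-linear regression of |y − y₀|, and a restart
grid B₀ ∈ {0.1, 0.5, 1, 2}·9/(x_max − x_min) (on the distance curves, span
9, this is the plain grid {0.1, 0.5, 1, 2}); the best sum of squares among
converged restarts wins.  A constant curve short-circuits to y₀ = y, A = 0,
with R² defined as 1.  Non-convergence of every restart is reported
honestly (`converged=False`) and aborts dataset assembly with the offending
(image, parameter, direction) named.

With the default grid the feature matrix has
p = 8 parameters × (4 directions × 10 distances + 4 fit constants) = 352
columns, ordered parameter-major, then direction, then distance with y₀
last — the order is fixed so that serialised models and CSVs are stable.

### Conditioning and PCA

ASM, IDM and CORR grow with roughness while the other five statistics fall;
replacing those three blocks cell-wise by their reciprocals gives every
feature the same rating (decreasing in Ra).  Cells smaller than 1e−12 in
magnitude abort with the cell named rather than produce infinities.

Feature screening drops blocks that do not share the common variation.  Two
modes: *explicit* (drop a named block list — the default configuration drops
CORR, whose directional anisotropy makes it inconsistent across specimens)
and *block* (data-driven: drop any parameter block whose median absolute
correlation with all out-of-block columns falls below the threshold,
default 0.8).  On the default synthetic study the block rule reproduces the
explicit choice exactly: CORR's median out-of-block |r| is ≈ 0.44 while
every other block exceeds 0.89, and the minimum pairwise |r| among retained
columns is ≈ 0.81.

Columns are standardised with sample (n−1) statistics, after which the
covariance C = XᵀX/(n−1) equals the correlation matrix.  The
eigendecomposition uses the symmetric eigensolver; eigenvalues are sorted
descending and eigenvalues below 1e−10·λ_max count as zero, which for n
observations of centred data leaves at most n−1 components (eleven for the
twelve-image study).  Eigenvector signs are fixed by requiring a
non-negative entry sum (ties: first non-zero entry positive); with all
features rating-aligned this makes every PC1 weight positive.  Scores are
Y = XA; the sample variance of Y_j equals λ_j, and variance fractions are
reported as percentages of Σλ.

### Calibration and prediction

PC1 score versus Ra is fitted with the same exponential model
(s = y₀ + A·e^(−B·Ra)); the fit requires at least five observations whose
labels span more than a decade of Ra.  Reported quality figures are R² of
the fit and the RMSE of fitted-versus-observed scores, in PC1-score units
(the score is a dimensionless combination of standardised features).
Prediction inverts the curve, Ra = −ln((s − y₀)/A)/B, after pushing the
image through the frozen pipeline (training GLCM configuration, reciprocal
blocks, retained columns, stored means/stds, stored first eigenvector).
Scores at or below the asymptote y₀ are outside the model's domain and
raise; scores inside the domain but outside the fitted score range, or
inverted Ra outside the training label range, are flagged as extrapolation
but still returned.

## The speckle simulator

No public image corpus pairs nanoscale Ra references with speckle images,
so the package generates its own study data.  The simulator is a standard
phase-screen model of the objective-speckle geometry with two empirical
couplings.

* **Surface.**  White Gaussian noise smoothed by a Gaussian kernel of
  standard deviation ℓc/pitch cells, centred, and rescaled so the achieved
  Ra equals the target exactly.  Defaults: correlation length ℓc = 150 µm,
  grid 400×400 at 32 µm pitch (grid extent 12.8 mm, comfortably larger than
  the 4 mm illuminated spot).
* **Field.**  E = A(x,y) · e^(−Ra/R0) · exp(i[(4π/λ)·h·cosθ + φ_m]) with
  λ = 632 nm and incidence θ = 15°.  φ_m is a correlated microstructure
  phase screen (std 20 rad, correlation length 150 µm) standing for the
  sub-resolution scattering of biological tissue.  It keeps the speckle
  fully developed (contrast ≈ 1) at every Ra; without it, surfaces with
  Ra ≪ λ/4π are weak phase screens whose diffuse energy *grows* with Ra,
  inverting the observed darkening trend.  The 20 rad default makes the
  per-pixel phase gradient exceed π, so speckle fills the frame uniformly.
* **Roughness couplings.**  Two configurable scales tie image statistics to
  Ra.  The backscattered amplitude falls as e^(−Ra/R0) (R0 = 2000 nm), so
  the mean gray level decays roughly exponentially with roughness.  The
  effective coherent spot shrinks as D/(1 + Ra/R1) (R1 = 1500 nm), so the
  far-field grain — whose size is set by the autocorrelation of the
  illuminated spot, 1.22·N·pitch/D_px pixels — grows from ≈ 4 px at low Ra
  to ≈ 10 px at 2500 nm and bright patches enlarge and merge.  The aperture
  energy loss is compensated (amplitude ×(1 + Ra/R1)) so the two knobs stay
  independent: R0 alone controls darkening, R1 alone controls grain size.
  An alternative coupling — growing the *surface* correlation length with
  Ra — cannot produce the patch-growth trend: it only narrows the scattered
  halo, and the σ_φ ∝ Ra growth of the height phase overwhelms it, while
  the grain size itself stays aperture-determined.  Both scales are
  phenomenological calibrations of the simulator, not tissue physics.
* **Detection.**  The image is the centred squared magnitude of the 2-D
  FFT of the field, quantised to 8 bits by one batch-wide scale: the 99th
  intensity percentile of the batch's lowest-Ra (brightest) image maps to
  gray 250, the same scale applies to every image, values clip at 255 and
  round half-up.  A shared scale preserves the cross-image gray-level
  ordering on which the analysis relies.  No further camera model (noise,
  MTF, vignetting) is applied.
* **Determinism.**  One master seed is expanded by a seed sequence into
  per-image surface and rendering sub-seeds; identical inputs give
  bit-identical images.

The default study grid is twelve Ra values —
{10, 40, 90, 170, 300, 480, 700, 980, 1280, 1600, 2000, 2500} nm — spanning
the degeneration range roughly geometrically.

**What passing on synthetic data shows.**  The simulator reproduces the
qualitative image-statistics trends of degenerating cartilage (darkening,
patch growth, GLCM diagonal concentration, fully developed grain
statistics) with realistic feature correlations, so it exercises every
stage of the analysis under the conditions the method assumes.  It does
not model tissue light transport, subsurface decorrelation, polarisation,
specimen curvature or camera noise, and its Ra-to-image couplings are
smooth by construction; performance figures on synthetic data therefore
bound what the pipeline can do under its own assumptions and do not certify
accuracy on measured tissue images.

## Problem sizes and runtime choices

The reference study — twelve 400×400 images, 40 GLCMs each at 256 levels,
352 features, PCA of a 12×308 matrix — runs in well under a minute on one
CPU, so tests and the acceptance script use it at full size.  Unit tests
that need many realisations (speckle contrast, fit recovery) use 24–128 px
grids, which preserve the statistics at a fraction of the cost.

## Known limitations

* The exponential distance-fit is an empirical description; on simulated
  images the contrast curves along the image axes have a slightly rounded
  top at d = 1–2 (the grain autocorrelation of a circular aperture), where
  the exponential fit is marginally poorer than along the diagonals.
* CORR of a near-constant image is undefined; such images abort feature
  assembly unless CORR is excluded.
* Calibration requires labels spanning a decade of Ra; inversion is
  single-valued only because the fitted curve is monotone.
* The prediction pathway assumes the new image was acquired under the
  training imaging configuration; no transfer between optical setups is
  attempted.
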