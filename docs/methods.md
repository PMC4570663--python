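# Methods

`soilchem3d` produces micro-scale 3D maps of chemical elements inside a soil
volume from two complementary measurements: a non-destructive X-ray CT scan
(3D, grayscale attenuation, here 8-bit at 15.8 µm voxels) and destructive
SEM-EDX element maps measured on faces exposed by cutting the sample (2D,
per-pixel characteristic X-ray counts). The statistical problem is to carry
the dense 2D chemical information into the interior of the volume using the
3D grayscale as the auxiliary variable.

## Model

For an element with concentration field `Z_u` and CT grayscale `Z_v`, the
prediction at an interior voxel `x0` decomposes as

    Z_u(x) = f(Z_v(x)) + ε(x)

with a deterministic trend `f` and a spatially correlated residual `ε`
(regression kriging). Two predictors are built from each pair of faces:

* **rt** — `ẑ_u(x0) = T(z_v(x0))`, the regression-tree trend alone;
* **rtk** — `ẑ_u(x0) = T(z_v(x0)) + ε̂(x0)`, trend plus ordinary kriging
  (OK) of the tree residuals.

### Trend: regression tree on grayscale

Because CT grayscale reflects local material density, the grayscale-to-
concentration relationship is close to a step function (each material phase
has a characteristic gray band and chemical make-up). A CART regression tree
with a single covariate *is* a step function, so the trend is stored as
ordered split thresholds plus leaf means. Splitting minimizes squared error
(backed by scikit-learn's `DecisionTreeRegressor`); a value equal to a
threshold falls in the right leaf. Because the step family can absorb
arbitrarily many parameters, cost-complexity pruning is applied by default:
the pruning path is computed, candidate subtrees are scored by seeded K-fold
cross-validation, and the 1-SE rule picks the smallest subtree within one
standard error of the best. Defaults: `min_leaf = 50` pixels,
`max_leaves = 32`, 5 folds, fixed seed; all recorded in the fitted model. A
plain linear trend is available behind the same interface for comparison but
is not a supported pathway.

### Residuals: isotropic variography and ordinary kriging

Residual spatial structure is summarized by the Matheron method-of-moments
semivariance over 3D point pairs (default bin width 1 voxel, max lag 64).
Full faces have ~10⁵–10⁶ pixels, so variography uses a seeded random
subsample (default 5 000 points per face, both faces pooled; under isotropy
inter-layer pairs are valid, though with the 65-voxel face gap and the
64-voxel default lag cutoff they rarely occur).

Candidate models are the single and nested ("double") exponential and
spherical structures, each with or without nugget:

* exponential `γ(h) = c0 + c (1 − exp(−h/r))` — `r` is the *distance
  parameter* (effective range ≈ 3r). This convention is stated explicitly
  because "range" is ambiguous across texts.
* spherical `γ(h) = c0 + c (1.5u − 0.5u³)`, `u = h/r ≤ 1`, else `c0 + c`.

Fitting is weighted least squares with pair counts as weights, multi-start
trust-region optimization, and selection by `AIC = n ln(RSS/n) + 2p` over
the lag bins (constant terms dropped). Ties resolve to fewer parameters.

The OK system is the standard semivariance matrix augmented with the
unbiasedness constraint; the solver returns weights (summing to 1), the
Lagrange multiplier and the kriging variance `Σ λᵢ γ(xᵢ, x0) + μ`. A cheap
post-solve residual check replaces an explicit condition number; on failure
the semivariance diagonal receives a `1e-10 · sill` jitter once before the
solve is declared singular. With one observation the augmented system forces
`λ = 1` and `μ = γ(d)`, giving variance `2γ(d) = E[(z0 − z1)²]` — the
correct error variance for predicting one point from another.

### Sampling-grid optimizer

Kriging from two full faces is both infeasible and unnecessary: pixels next
to each other are nearly redundant. Observations are therefore taken on two
`n × n` square grids (default 9 × 9, i.e. 162 points) centred on the
target's projection onto the two faces. The kriging variance depends only on
the grid geometry and the variogram — not on data — so the grid spacing is
chosen by evaluating the variance profile over candidate spacings (default
1–20 voxels, restricted to grids that physically fit the faces) for a target
midway between faces 65 voxels apart, and taking the argmin (ties to the
smallest spacing; denser grids never lose information). Too-small spacings
waste points on redundant neighbours; too-large spacings push points out of
correlation range — for residual ranges in the 20–30 voxel-parameter regime
the profile is U-shaped with its minimum at spacings 5–10. For *short*
ranges (distance parameter ≲ 15) the target midway between the faces is
essentially decorrelated from both and the profile decreases monotonically;
the optimizer then simply returns the largest feasible spacing, which is
correct behaviour (all configurations are nearly equivalent there).

Because the grid translates rigidly with the target, the grid-to-grid
semivariance matrix is one and the same for every target; a single LU
factorization is reused and only right-hand sides vary (per z-offset and per
boundary shift). This turns millions of voxel predictions into one
factorization plus batched triangular solves, and is verified against a
fresh per-voxel solve to 1e-10. Grids that would protrude beyond a face are
shifted minimally inward (flagged); grid points on masked (broken-face)
pixels trigger a per-target solve on the remaining points.

## Registration of faces in the volume

A cut face is a plane tilted by small angles, parametrized by slopes
`(a, b)` about a rotation center `(i0, j0)` and a base slice `k0`:
`z(i, j) = a (i − i0) + b (j − j0) + k0`, rounded to the nearest slice
(ties away from zero), producing a staircase plane. The face is located by
maximizing the *cumulative absolute Pearson correlation* between the
reconstructed grayscale plane and all element maps simultaneously, over a
discrete grid of `(a, b)` (default ±0.05 in steps of 0.001, ≈ ±3°), a `k0`
window, and all crop offsets of the map window inside the plane window
(default 750 × 800 inside 830 × 880).

The naive search is ~10⁹ evaluations. Two exact accelerations make it
tractable: (1) for a fixed plane, windowed sums over *every* crop offset are
valid-mode FFT cross-correlations, giving the whole offset map in a few
FFTs; (2) the `(a, b)` grid is searched coarse-to-fine (stride 0.005, top-25
candidates refined at 0.001), with an `exhaustive` switch. Winning
candidates are re-scored with the direct correlation formula, so reported
correlations do not inherit FFT round-off; ties resolve deterministically to
the smallest `|a| + |b|`, then smallest `k0`, then first offset in row-major
order. Correlation uses raw counts versus grayscale with no transform;
masked pixels are excluded via the joint mask (intersection over elements).
Constant inputs give an explicit "undefined correlation" error, never a
silent zero.

## Validation scheme

The cutting geometry produces faces in pairs: each ~250 µm slice spans 15 CT
layers and the saw kerf removes 50, so two faces of one slice plus the
nearest face of the adjacent slice are 65 voxels apart. Every consecutive
face triple whose outer faces are 65 apart forms one fold: fit on the outer
pair, predict the middle face, score RMSE and `R² = 1 − Σ(O−P)²/Σ(O−mean O)²`
over its pixels. Ten faces yield eight folds, the middle face 15 or 50
layers from the upper face (never equidistant). Methods are compared by
two-sided paired t-tests across folds on RMSE and R², and each method's
per-fold prediction mean/SD against the observed ones. Zero-variance
differences are reported as explicitly undefined, never as `p = 0`. No
multiple-testing correction is applied (raw p-values are reported); this is
a known limitation. Negative rtk predictions are reported as-is unless
`clamp_nonnegative` is set, since clamping alters RMSE.

## Synthetic data generator

No reference data ship with the package, so a generator with known ground
truth stands in for the instrument chain:

* **Volume** — a correlated Gaussian field (spherical, range 12) is
  thresholded at the normal quantiles of the phase proportions into
  pore/resin (45 %, gray 60 ± 12), mineral (50 %, 130 ± 18) and sparse
  Fe-rich material (5 %, 225 ± 12); voxel grays are truncated-normal draws
  (inverse-CDF, exact) clipped to 8 bits. Default volume 256 × 256 × 300.
* **Faces** — ten faces at z = 10, 25, 75, 90, 140, 155, 205, 220, 270, 285
  (slice 15, kerf 50, fold gap 65). Faces are untilted by default so the
  fold geometry is exact; a tilt option exists for exercising alignment.
* **Element maps** — `trend(gray) + residual + noise`, clipped at zero
  (counts are non-negative). The trend is a step law per element (C high in
  pores, Si/O on the solid phase, Fe concentrated in the bright phase); the
  residual is sampled from a *single* 3D Gaussian field per element
  (exponential, distance parameter 22) evaluated on the face planes — one
  coherent 3D field, not independent 2D fields, so that kriging between
  faces has true signal to exploit, which is precisely the property rtk
  depends on. Trend levels sit ≥ ~2 residual SDs above zero so the clipping
  rarely binds. Per-element sills (C 2.0, Si 6.0, Fe 0.15, O 1.2) and noise
  SDs (0.3/0.5/0.05/0.2) make C, Si, O "diffuse" elements that benefit
  strongly from kriging while Fe is sparse and already well explained by
  the trend.
* **Fields** — circulant embedding: the covariance kernel is laid out on a
  torus padded past the covariance decay length (range for spherical, 7
  distance parameters for exponential), its FFT gives the eigenvalues
  (clipped at zero if negligibly negative, error otherwise), and one complex
  FFT of white noise yields two independent real fields. Exact Cholesky
  sampling covers arbitrary point sets up to 4096 points. Large 3D fields
  use float32; everything is seeded and bit-reproducible.

What the generator does **not** emulate: partial-volume blur at phase
boundaries, beam hardening and reconstruction artefacts, spatially varying
noise, anisotropy, tilted-face kriging geometry (faces are treated as flat
layers at their nominal z during kriging), and any physical X-ray
attenuation model. Passing tests therefore demonstrate the correctness and
the qualitative behaviour of the machinery — trend recovery, residual
structure exploitation, the U-shaped variance profile, the direction and
significance of the rtk improvement — not instrument-grade realism.

## Numerical choices and problem sizes

* Rounding of plane z: nearest integer, half away from zero, applied to the
  full expression `a(i−i0) + b(j−j0) + k0`.
* 0-based indices and half-open windows throughout; 1-based conventions in
  external descriptions of the reference setup are converted by
  subtracting 1. Physical coordinates are `index × voxel_size` at voxel
  centers.
* Alignment score ties are compared after rounding to 1e-9 before applying
  the deterministic tie-break; candidates tied with the top score are all
  re-scored exactly.
* AIC's `RSS` is floored at 1e-300 to keep perfect fits finite; candidate
  fits that fail are skipped with a warning, and an error is raised only if
  all fail.
* Degenerate residuals (variance < 1e-12 of the mean square signal) flag
  the model trend-only; kriging is skipped and rtk equals rt exactly.
* Test problem sizes are chosen to exercise the full pipeline at desk
  scale: the default study (256 × 256 × 300, ten faces, four elements,
  eight folds) runs end-to-end in a few minutes; alignment recovery uses a
  256³ volume with windows of roughly 130–170 pixels; oracle comparisons
  run on 64³–96³ volumes where exhaustive enumeration is feasible.

## Known limitations

* Isotropic variograms only; soils are often anisotropic. Universal kriging
  / REML-based E-BLUP is out of scope (regression kriging is the
  approximation).
* The regression tree uses grayscale alone — no texture or neighbourhood
  covariates, no regression splines.
* Sub-voxel (continuous) plane orientation is not estimated; the staircase
  discretization is the model.
* Pruning settings of the tree are package defaults; numerical equality
  with trees fitted by other toolboxes is not expected.
* Element-map units are treated as arbitrary non-negative concentrations;
  no calibration to weight percent is attempted.
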