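# Methods

## Data model and conventions

All positions are continuous nanometres with the origin at the top-left
camera corner, x rightward, y downward; camera or mask pixel `i` covers the
half-open interval `[i·ps, (i+1)·ps)`.  This single stated convention
governs every nm→pixel lookup (mask membership, window cropping) and
prevents off-by-one disagreement between modules.  Molecule lists are
pandas tables with canonical columns `x_nm, y_nm[, z_nm], frame[, photons,
channel, molecule_id]`; a z column is carried but all statistics are
lateral (2D), matching how SMLM precision and spatial structure are
reported in practice.  Masks are boolean rasters with a physical pixel
size and nm origin; analysis regions are simple polygons (closed: boundary
points count as inside, a documented tie-break since counting rules are
rarely stated in imaging work).

## Synthetic scenes

The generator emulates what the analyses assume about real data, nothing
more:

* **Structures** — disks (bouton-like varicosities), annuli (membrane
  outlines) and persistent-random-walk ribbons (axon segments), rasterized
  at a 10 nm grid by pixel-center membership.  Placement is best-effort
  non-overlapping; a structure that cannot fit inside the raster is a
  hard error.
* **Molecules** — two independent homogeneous Poisson processes, one on
  the union of structures and one on the remaining ROI area, with
  intensities in molecules/µm².  Their ratio is the scene's enrichment;
  equal intensities give complete spatial randomness (CSR).  Positions are
  uniform within their stratum (structure placement samples a uniform
  pixel plus a uniform in-pixel offset; off-structure placement uses
  rejection sampling).
* **Blinks** — each molecule emits `k` localization points with `k` drawn
  from a finite discrete table.  A named parametric family is deliberately
  not imposed: the observable anchored by measurement is the single-LP
  probability (0.78 for a one-fluorophore pharmacoprobe, 0.36 for a
  multi-fluorophore secondary antibody), and the tails
  (`{1: .78, 2: .12, 3: .10}` and `{1: .36, 2: .22, 3: .15, 4: .10,
  5: .07, 6: .05, 7: .03, 8: .02}`) are plausible short/long-tailed
  completions chosen once.  Every LP is displaced by independent Gaussian
  error per axis (default σ = 9.42 nm, the tissue-scale lateral
  precision); blinks of one molecule occupy a contiguous frame burst with
  gaps ≤ `dark_frame_gap` (default 5) within a 10,000-frame acquisition.
  Uniform background LPs are tagged `molecule_id = −1`; all other LPs
  keep their generating molecule id, so the molecule→LP map partitions
  the non-background table and every recovery test has exact ground
  truth.

Not emulated: photoswitching kinetics, PSF/camera image formation, drift,
detection failures, and axial structure.  Passing tests therefore
demonstrate correctness of the *analysis* under the stated statistical
assumptions — they do not certify performance on data whose blink
statistics or backgrounds violate them.

## Density quantification

Densities are counts over area (LPs/µm²).  The inner-window crop keeps
LPs in the centered `n×n`-pixel window (64 px → 104.86 µm², 32 px →
26.21 µm² at 160 nm/px; "inner quarter" and "inner sixteenth" of a
256×256 px field are read as the 128 px and 64 px centered windows).
Background handling is subtraction of the density measured on probe-free
control fields; negative corrected densities are clamped to zero and
flagged.  An alternative reading — divide by background, then subtract —
is dimensionally awkward and was rejected; under CSR both orders give the
same hypothesis-test conclusions, but printed densities would differ.
Two-channel ratios are pharmacoprobe/antibody counts; group normalization
divides by the mean raw ratio of the control group, making that group
average exactly 1.  The occupancy curve expresses each concentration's
mean ratio as a percentage of the reference (saturating) concentration's
mean ratio.

## Spatial statistics

**NND.** KD-tree nearest-neighbor queries; no edge correction is applied
(none is standard in this workflow), so calibration tests restrict to
interior points with a margin of 3× the median NND before comparing to the
closed-form CSR CDF `1 − exp(−λπr²)`.  Observed and randomized distance
sets are compared by the two-sample two-tailed KS test — exact p-values
below 50 samples, asymptotic above.

**Dilation ratio.** The confocal structure raster is binarized at
intensity ≥ threshold and upsampled 80 → 10 nm by block replication
(area-exact, binarity-preserving).  The neighborhood is 50 iterations of
an 8-connected 3×3 dilation, computed in one pass as a chessboard
distance-transform threshold (exactly equivalent, ~100× faster at 50
iterations); the iterated-dilation route is retained in the test suite as
an independent oracle.  The denominator region *includes* the original
structure: under CSR both the inclusive and exclusive readings have
expectation 1, but the inclusive one is the natural "neighborhood
average"; the exclusive ring is available behind
`StructureAssocConfig(include_original=False)`.  The randomized control
re-distributes the LPs that fall on the analyzed raster uniformly over the
raster extent — randomization over the image window, not the mask — so a
structure holding only the average density reads 1.  Ratios from ≥5
images are tested against median 1 with the two-tailed Wilcoxon
signed-rank test (all-ratios-exactly-1 is degenerate and returns p = 1).
Thresholds up to `max+1` are accepted (yielding an empty mask that
downstream analysis rejects); values outside `[min, max+1]` raise.

**Hull distances.** Convex hulls are fitted per bouton ROI to the
antibody LPs inside it; ROIs with <3 non-collinear LPs are excluded and
reported rather than raised.  A drug LP inside or on a hull scores 0
(signed-inside distances would break the cumulative curves, which start at
zero); outside LPs take the minimum Euclidean distance to any hull
boundary segment (shapely exact segment distance).  Distances above the
1000 nm cutoff are discarded before the KS comparison with a matched
uniform randomization.

## Stoichiometry

Blink grouping is chained density linkage: transitive closure of the
"within `radius` nm and within `max_frame_gap` frames" relation
(union-find over KD-tree pairs).  This is permutation-invariant and
matches the "LP cluster" notion; centroid-based merging was rejected
because it is order-dependent.  The default radius is 30 nm (~3× the
expected precision) and the temporal constraint is off by default —
sparse-labeling acquisitions make it unnecessary.  Recovery analyses use
radius 60 nm at ~0.7 molecules/µm²: the distance between two blinks of
one molecule has per-axis σ of `σxy·√2` ≈ 13 nm, so 60 nm (~4.5σ) keeps
multi-LP clusters intact while the ~1.2 µm mean molecule spacing (20× the
radius) keeps distinct molecules separate.  Precision per cluster is the
sample standard deviation (n−1) of x and of y about the centroid, and the
lateral value is their arithmetic mean — the combination rule is a
package definition, stated because "lateral (x-y)" does not pin one down.
The sample SD is slightly biased low (the c₄ factor, ≈0.991 at 30
blinks), which is why the recovered median sits ~1 % under the generator
σ; no bias correction is applied, matching common practice.

## Binding fits

Both models are fitted by bounded Levenberg–Marquardt least squares
(`scipy.optimize.curve_fit`) from a multi-start grid of log-spaced
Kd/EC50 initial values (4 per decade across the sampled range, extended a
decade each way), keeping the lowest-SSE solution; standard errors come
from the residual-scaled covariance.  Fits are unweighted by default
(optional 1/Y²).  The one-site model fixes the Hill slope at 1 by
definition.  The sigmoid defaults to the 4-parameter form (baseline
free); slope and baseline can each be fixed, and with `h=1, baseline=0`
the model reduces algebraically to the one-site form with EC50 = Kd.
Zero concentrations map to the baseline (the h>0 limit).  Fitting
requires ≥4 distinct concentrations spanning ≥2 log units;
non-convergence is reported via a flag, never silently, while all-zero
responses raise (Kd unidentifiable).

## Pipeline and reproducibility

A run is a YAML stage list with one global seed.  Per-stage streams are
derived by hashing the stage name into a `SeedSequence` together with the
seed, so inserting a stage never perturbs another stage's draws.  Every
output file is checksummed into a manifest; identical config+seed
reproduces identical checksums, and a stage failure aborts with the stage
name while preserving partial outputs.  Reports are regenerated
idempotently from the manifest and echo the stage outputs verbatim.

## Problem sizes

Validation suites use desk-scale scenes chosen to make the Monte-Carlo
error comfortably smaller than the tolerance being checked: 10⁴ points
for CDF sup-norm and fraction-recovery checks (binomial SE ≈ 0.005), 10³
LP scenes over 100 replicates for KS power, 200 replicate 12-image
experiments for Wilcoxon type-I calibration, 100 seeds for noisy-fit
recovery, and 4×4 µm rasters at the 10 nm analysis grid for the
dilation statistic.

## Known limitations

* The blink-count tails beyond the single-LP probability are modeled, not
  measured; stoichiometry recovery validates the estimator, not any
  particular antibody chemistry.
* The grouping radius trades fragmentation against fusion; outside the
  sparse regime (spacing ≲ 20× radius) the single-LP fraction is biased
  and no correction is attempted.
* No NND edge correction: estimates near region boundaries are biased
  high and analyses should use interior margins.
* The dilation neighborhood is Chebyshev (square) rather than Euclidean
  (disk), exactly as iterated 3×3 dilation implies; at 50 iterations the
  reach is 500 nm along axes and ~707 nm diagonally.
* Binding SEs assume independent homoscedastic residuals; replicate
  correlation is not modeled.
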