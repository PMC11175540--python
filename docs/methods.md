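# Methods

## Overview

The package implements a reconstruction chain for free-running radial
cardiac MRI in five stages: (1) trajectory generation with interleaved
self-gating readouts, (2) forward simulation of a beating, breathing
numerical phantom, (3) similarity-driven binning of the self-gating
projections, (4) gridded per-cluster reconstruction, and (5) a
compressed-sensing reconstruction with cyclic total variation over the
cluster dimension, optionally motion-compensated by frozen inter-cluster
deformation fields. Image-quality metrics (contrast ratio, sigmoid
sharpness) close the loop. Every stage is deterministic given its seed.

## Trajectory

3D readouts are full diameters through the k-space center whose
endpoints follow a spiral-phyllotaxis (sunflower) pattern: azimuth
advances by the sunflower golden angle (~137.508°) per point and the
polar angle follows the equal-area law cos θₙ = 1 − (n+½)/N, which
behaves like θ ∝ √(n/N) near the pole and makes the symmetrized
endpoint set statistically uniform on the sphere (verified by a
spherical-cap counting test against a Monte-Carlo uniform baseline).
Interleave m takes every N_int-th point and is additionally rotated by
m sunflower angles about z. 2D mode — used by the desk-scale studies —
advances spoke azimuths by the 2D radial golden angle (~111.246°).
When self-gating is enabled the first readout of every interleave
points along the SI axis (+z in 3D, the last axis in 2D), giving one SI
readout per interleave; at the in-vivo protocol values (22 readouts,
TR 2.84 ms) this reproduces the ~16 Hz self-gating rate. k-space
coordinates are normalized to cycles/voxel in [−0.5, 0.5); image
positions are centered at the grid midpoint.

The exact phyllotaxis of the in-vivo sequence is not reproduced; the
contract enforced here is geometric (collinearity, unit directions,
golden-angle increments) and statistical (sphere-uniformity), which is
what the downstream operators depend on.

## Phantom and forward simulation

The phantom is a set of smooth-edged ellipsoids labelled background,
lung, liver, myocardium, blood (a torso slab with a bright blood pool
over darker myocardium, the intravascular-contrast regime; planted
intensities 1.0 / 0.3 give an ideal contrast ratio of 2.33). Cardiac
contraction scales the heart ellipsoids' semi-axes by 1 − a·w(t) with a
raised-cosine systole w occupying one third of the cardiac cycle;
respiration translates heart and liver along the SI axis. Motion is
affine-per-structure, so ground-truth correspondence is available in
closed form for registration tests.

Two temporal modes exist. Continuous mode drives w(t) and a sinusoidal
breathing shift directly. Discrete-state mode — used by the validation
studies, because it provides exact phase labels — cycles through a
periodic schedule of labelled states with unequal dwell fractions.
Defaults: four states (diastole/systole × end-expiration/inspiration)
with dwell 0.40/0.25/0.20/0.15 ("default", diastole-dominated) or
0.28/0.26/0.24/0.22 ("balanced", the regime where the four selected
clusters land at undersampling R ≈ 3–6, matching the published
per-cluster data fractions of ~9–12%). Each state carries a residual
within-state SI wobble ("jitter", 0 / 0.5 / 0.8 / 1.2 voxels): the
resting diastolic end-expiratory state is quiescent while rarer, more
active states move more. This mirrors the empirical observation that
the most populated similarity cluster is also the most
motion-consistent one, and it is what makes the cluster-count selection
well-posed (see below).

The forward model renders the phantom at each interleave's start time
(motion frozen per interleave, matching the clustering granularity),
multiplies by smooth synthetic coil maps (Gaussian lobes around the
FOV with random gentle linear phases), evaluates the exact non-uniform
Fourier sum via the gridding NUFFT, and adds i.i.d. complex Gaussian
noise scaled to the peak k-space magnitude. SI readouts are stored
additionally as 1D inverse-FT z-projections computed from the *noisy*
samples. What the simulator does not model: relaxation/contrast
kinetics, B0 or gradient imperfections, coil noise correlation,
arrhythmia, through-plane motion (2D mode), intra-interleave motion.
Passing tests therefore demonstrate algorithmic correctness and the
expected qualitative orderings, not in-vivo image quality.

## Similarity clustering

SI projections are concatenated into one feature-by-time matrix, rows
mean-centered. Feature combination is configurable: complex per-coil
stacking (default of the library function) or coil root-sum-of-squares
magnitude. The desk-scale pipeline configs use RSS: the simulator's
coil phases are arbitrary random ramps, and the real part of a
complex-feature PCA projection inherits that arbitrariness (measured
state separability varies by a factor ~3 across coil seeds with
stacking, and is stable under RSS). With measured coil data the richer
complex stacking remains available.

PCA is computed by SVD; by default the smallest number of components
explaining 95% of variance (capped at 10) is kept, configurable — the
studies fix 4 components, matching the number of anticipated motion
states, because at self-gating SNR ≈ 20 the variance criterion keeps
mostly-noise components that drown the state geometry. k-means
(k-means++, 10 restarts, seeded) runs on the real scores for each k in
the search range; the selected k minimizes the mean Euclidean distance
between the most populated cluster's points and its centroid. Points
are clustered in a canonical lexicographic order so the result is
invariant to permuting the acquisition. Ties in the selection score
resolve to the smallest k. The in-vivo search range 10–14 is the
default; desk-scale studies use 4–8 (the in-vivo range presumes
thousands of interleaves).

A note on the selection criterion's behavior: if all states had equal
within-state spread, splitting the most populated cluster would always
lower the score and the argmin would sit at the top of the search
range. The criterion selects a physiologically meaningful k exactly
because the resting state is tighter than the others — which the
jittered generator reproduces.

Whole interleaves inherit their SI readout's label; SI readouts are
excluded from the imaging data. The four most populated clusters are
selected, ordered by population, and treated cyclically by the
reconstruction.

## NUFFT and gridded reconstruction

The NUFFT is Kaiser–Bessel gridding: 2× oversampled centered FFT,
separable kernel interpolation (width 8 points per axis, Beatty shape
parameter), and Gauss–Legendre-quadrature deapodization. Measured
accuracy against the exact Fourier sum is ~7×10⁻⁸ max relative error;
the adjoint is the literal conjugate transpose (gather ↔ scatter), so
adjointness holds to machine precision by construction.

Density compensation: the analytic radial ramp w ∝ |k|^(d−1) (the
weight of the first nonzero ring shared among the coincident DC
samples) is the `density_weights` default and matches Voronoi cell
areas exactly for uniformly spaced spokes. For golden-angle azimuths at
non-Fibonacci spoke counts the azimuthal gaps are irregular (three-gap
structure) and the per-radius ramp deviates from Voronoi areas by
~25% median; the gridded chain therefore defaults to Pipe–Menon-style
iterative refinement (10 iterations of w ← w / (GGᴴw) with the gridding
kernel), which restores the dense-acquisition round-trip to NRMSE
≈ 0.03 against the rendered phantom (the disk-truncation floor is
0.024). Weights are normalized to unit sum so a dense impulse
round-trip has unit amplitude.

Coil sensitivities are estimated from the central k-space disk
(|k| < 0.125, cosine-tapered), lightly smoothed, divided by their
root-sum-of-squares, and extended into the background by
nearest-support values; ground-truth maps are used in unit tests to
decouple reconstruction from calibration errors. The gridded
reconstruction is x = Σ_c conj(C_c)·F†(w·y_c) / max(RSS², ε).

## Registration and the warp operator

The warp T_u is pull-back linear interpolation, warp(x, u)(r) =
x(r + u(r)), with nearest-edge clamping, applied independently to real
and imaginary parts. Its adjoint is the exact transpose of the
interpolation weights (scatter); the solver's normal equations use this
exact adjoint, never the approximation T(−u).

Deformation estimation wraps SimpleITK's multiresolution B-spline
free-form registration (control spacing ~8 voxels at the finest level,
3 levels, L-BFGS-B capped at 300 iterations per level, full-image
metric sampling and single-threaded evaluation for bit determinism).
The default similarity is normalized cross-correlation — the synthetic
images share contrast, and mutual-information histogram binning is
noisy on small desk-scale images — with Mattes mutual information
available to mirror the histogram-based objective used in vivo.
Complex images are registered on their magnitude. A guardrail returns
the identity field (flagged non-converged) whenever registration fails
to reduce the image residual. Fields are estimated once from the
gridded images — cluster i registered to cluster i−1, cyclically — and
frozen during the iterative reconstruction.

## The ADMM solver

The solver minimizes Σ‖A_i x_i − y_i‖² + λΣ‖T_i x_i − x_{i−1}‖₁ with
A_i = F_i C in the **unitary convention** (operators scaled by
1/√N_voxels): this keeps the data and L1 terms on comparable scales and
makes λ transferable across grid sizes. The raw-DFT convention leaves
the data term ~10⁵× the penalty on typical problems, rendering the
regularizer inert. Data are additionally normalized so the initial
gridded series peaks at 1 (configurable), making λ = 0.3 meaningful
across simulations.

ADMM splits z = Dx (the cyclic, possibly warped differences): z-update
by complex magnitude soft-thresholding with τ = λ/ρ; x-update by 3
warm-started CG iterations on the coupled normal equations
(2A*A + ρD*D)x = 2A*y + ρD*(z − η); scaled dual update. ρ defaults to
λ (standard heuristic; stable on all test problems). Initialization is
the density-compensated gridded series. 40 outer iterations. On 1D toy
problems the 40×3 objective sits within ~0.02% of a 10,000-iteration
Chambolle–Pock reference, and at λ=0 with dense data the solver matches
plain CG-SENSE to machine precision. The convergence log records the
objective, data and L1 terms (entry 0 = initialization) and the
relative primal residual ‖Dx − z‖ / max(‖z‖, ‖Dx‖). Divergence
(objective above 10× initial) and non-finite values raise immediately.

With fields = None the same code path solves the uncompensated
problem; identity fields reproduce it to the bit, which is tested.

The output "image" of each method is the volume in the most populated
cluster's motion state (the first of the rank-ordered series).

## Image-quality metrics

Contrast ratio: (blood − myo)/myo of ROI mean magnitudes; ROIs come
from the phantom label map (or user masks). Sharpness: the slope a of
L + (U−L)/(1+exp(−a(t−t₀))) least-squares-fitted to a profile sampled
by linear interpolation at 4× voxel density between user endpoints;
initialization from plateau means and the midpoint crossing; flat or
non-convergent profiles return NaN with a quality flag. Both metrics
are invariant to global intensity scaling. At native desk-scale
resolution a sharp synthetic edge crosses within ~1 voxel and the
fitted slope saturates (values of order 10–100 per voxel that wobble
with streak noise), so sharpness comparisons between reconstructions
are meaningful mainly when one side is visibly blurred; the validation
relies on NRMSE orderings instead and reports sharpness as-is.

## Study configurations

Two canonical configurations are shipped (and used by the tests and
the acceptance script):

* **Clustering study** — 240 interleaves × 4 readouts, 48² grid, 8
  coils, self-gating SNR ≈ 20 (noise 2% of peak k-space), default
  (diastole-dominated) states. Validates state recovery (adjusted Rand
  index vs planted labels ≥ 0.9 on the selected clusters) and the
  selection argmin against a brute-force oracle.
* **End-to-end study** — 96 interleaves × 2 readouts, 64² grid, 6
  coils, balanced states, so the four selected clusters land at
  R ≈ 3–6. Validates the qualitative ordering NRMSE(XD-MC) <
  NRMSE(gridded) and NRMSE(XD-MC) < NRMSE(XD) when a systole-like
  state is among the selected clusters — the plain cluster-TV
  reconstruction degrades below the gridded image, as observed in vivo.

Problem sizes were chosen so each study completes in well under a
minute while staying in the published undersampling regime.

## Known limitations

2D desk-scale studies stand in for the 3D in-vivo setting (all
operators are dimension-agnostic and 3D-tested at small grids). The
coil model is a stand-in; no claim of equivalence with measured
calibrations. Intra-cluster motion is simulated (jitter) but not
corrected, matching the method's scope. The sharpness metric's absolute
scale depends on position normalization and is not comparable across
implementations. The selection criterion's behavior on equal-spread
states (argmin at the top of the range) is inherent to the criterion,
not an implementation artifact.
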