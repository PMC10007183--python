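# Methods

This note describes the models and procedures implemented in `fatiguefc`,
the assumptions behind them, the choices made where the design was open,
and what the synthetic validation does and does not establish.

## Overview

The pipeline classifies paired alert/fatigue EEG segments (one pair per
subject) from the phase structure of brain activity:

1. **Preprocessing** — resampling, SOBI / BSS-CCA artifact removal, and
   band decomposition into delta (0.5–4 Hz), theta (4–7 Hz), alpha
   (8–12 Hz), beta (13–30 Hz) and gamma (32–45 Hz). The band edges leave
   small gaps (7–8, 12–13, 30–32 Hz) by construction; we keep the stated
   clinical edges rather than tiling the spectrum.
2. **Source reconstruction** — sLORETA on a three-shell spherical head
   model (or an imported leadfield).
3. **Parcellation** — ROI time series by sign-flip averaging over parcel
   vertices (34 ROIs per hemisphere at full scale, 68 total).
4. **Connectivity** — phase lag index (PLI) per ROI pair and band;
   the strict lower triangle of the 68×68 matrix gives 2278 features.
5. **Classification** — recursive feature elimination (13 % retained =
   296 of 2278 at full scale), grid-searched SVM, repeated two-fold
   cross-validation, and a paired permutation test.

## Forward model

The scalp potential of a current dipole is computed analytically for a
three-shell concentric-spheres conductor (inner skull, outer skull,
scalp). In units scaled by the outer radius R, the potential of a dipole
**q** at radius b observed at scalp point **r**_s is the truncated series

    V = 1/(4 pi sigma_1 R^2) * sum_{n>=1} F_n beta^(n-1)
        q . [ n P_n(c) r0_hat + P_n'(c) (rs_hat - c r0_hat) ]

with beta = b/R, c the cosine of the dipole–sensor angle, P_n Legendre
polynomials, and F_n per-degree factors obtained by solving the 5×5
boundary-condition system of the three shells (potential and radial
current continuity at the two inner interfaces, insulating outer
boundary). For equal conductivities F_n reduces to the classical
homogeneous-sphere factor (2n+1)/n, which the implementation reproduces
to machine precision and the tests assert.

Defaults: radii (0.087, 0.092, 0.100) m and conductivities
(0.33, 0.0042, 0.33) S/m — standard literature values for skull/scalp;
80 series terms (convergence at 70 % source depth is < 1e-6 relative by
40 terms). The average reference is always applied, so gain columns sum
to zero and sensor data of rank 31 are handled by pseudo-inversion.

Electrode positions come from the packaged idealized 32-channel 10–20
montage, centered on its best-fit sphere and projected radially to the
scalp radius. A custom montage (`name x y z` text) and a precomputed
leadfield (delimited text) can be supplied instead, which is the route
for realistic BEM/FEM forward models.

The source space is a quasi-uniform Fibonacci lattice on a cortical
shell at 75 % of the inner-skull radius, laid out per hemisphere (the
sagittal plane x = 0 separates hemispheres; the lattice is constructed
strictly off the plane, so the split is unambiguous). Each vertex
carries an orthonormal triad with the first axis radial, standing in for
the cortical normal. The full-scale space uses 10,242 vertices per
hemisphere (20,484 vertices, 61,452 dipoles); the desk-scale default is
162 per hemisphere, and most validation runs use 64 per hemisphere.

## Inverse solution (sLORETA)

Minimum-norm kernel K = G' (G G' + lambda C)^+ with noise covariance C
(identity by default — the data are whitened only by scale) and
pseudo-inversion at relative eigenvalue cutoff 1e-10. Each vertex's
3-vector estimate is standardized by the inverse matrix square root of
its 3×3 diagonal block of the resolution matrix R = K G. Free
orientations are retained through standardization; orientation pooling
happens at parcellation.

Regularization defaults to the conventional heuristic
lambda = trace(G G') / (n_sensors · SNR²) with SNR = 3; both lambda and
the noise covariance are exposed. The defining property — zero
localization error for a noiseless single source as lambda -> 0 — is
verified exhaustively on the 162-per-hemisphere space.

## Parcellation and sign-flip averaging

The synthetic atlas clusters each hemisphere's vertex coordinates with
seeded k-means and relabels parcels in a deterministic spatial order;
parcels are contiguous by construction of the distance objective. Lobe
labels (frontal, parietal, temporal, occipital, cingulate, insula) are
assigned from parcel centroids; for anatomical (Desikan–Killiany) ROI
names a fixed 34-entry lookup table is built in.

Per vertex, the three standardized dipole series are collapsed onto one
axis — by default the anatomical (radial) axis; optionally the first
principal component of the vertex's 3×T block (`collapse="data"`).
Within each ROI the dominant orientation is the first right singular
vector of the stacked vertex orientations; vertices whose orientation
has a **negative dot product** with it (angle > 90°) are sign-flipped
before averaging. An exactly anti-parallel vertex pair carrying one
common current cancels under plain averaging and is recovered exactly by
the flip — the degenerate case that motivates the procedure. A tie in
the leading singular values (perfectly balanced orientation fans) is
reported as a warning; the sign convention (majority-positive
projection, then positive first nonzero component) keeps the output
deterministic.

## Phase lag index

For windowed signals x, y the PLI is |E_w[sign(Im S_xy(f))]| per
frequency bin, averaged over the bins whose center lies in the half-open
band [f_low, f_high), where S_xy is the Hann-tapered cross-spectrum of a
window and E_w averages windows. Window length defaults to the minimum
admissible length — 5 cycles of the band's central frequency — rounded
up to a whole sample count; windows are contiguous and non-overlapping.
Imaginary parts below 1e-12 of the cross-spectral magnitude count as
exactly zero, so proportional (volume-conducted, zero-lag) signals give
PLI = 0 instead of numerical noise.

Properties held by construction and asserted by tests: values in [0,1],
symmetry, zero diagonal, amplitude invariance, zero-lag blindness, and
bin-for-bin equality with a brute-force per-window sign-count
implementation (the independent oracle, kept deliberately loop-based).

Spectral features: Welch PSD (2 s Hann segments, 50 % overlap) and
relative band power, i.e. band power divided by total power over
0.5–45 Hz with the same half-open bin convention (so the full range
yields exactly 1). One feature per channel per band (32 per band for the
standard montage).

## Classification

Feature selection is recursive elimination with a linear SVM ranker:
each round drops the features with the smallest squared weights —
1 % of the original count per round by default — until the requested
fraction remains (13 % of 2278 = 296). By default selection and
standardization run **inside each training fold**; a whole-dataset
selection mode exists for comparison with protocols that selected
features before cross-validation, but it leaks information into the
cross-validated estimate and is not the default.

Evaluation is repeated two-fold cross-validation (1000 repetitions at
full scale; validation runs use 50). Folds split **subjects**, never a
subject's alert/fatigue pair, preventing pairing leakage; a sample-level
mode exists for comparison. Per repetition both fold directions are
tested, confusion counts pooled, and sensitivity TP/(TP+FN), specificity
TN/(TN+FP) and accuracy (TP+TN)/total computed from the pooled counts;
headline numbers are means over repetitions (per-repetition arrays are
kept so any other pooling can be recomputed).

The grid search (exhaustive, inner 2-fold accuracy, ties broken by grid
order) covers kernel {linear, RBF} x C {0.1, 1, 10, 100} x RBF width
{scale, 0.01, 0.1, 1} by default. Validation runs fix a linear SVM with
C = 1 — on the synthetic contrast the grid adds cost, not information.

The permutation test flips each subject's pair of labels with
probability 1/2 (the exchangeable transformation for a paired design)
and recomputes the identical cross-validated statistic; p is the
fraction of permutations strictly exceeding the observed accuracy, with
the smoothed (b+1)/(n+1) estimate also reported and p = 0 rendered as
"< 1/n_perm". By default any feature selection is re-run per permutation
(honest null); a fast mode freezes the observed selection, which is
cheaper and slightly anti-conservative about the selection step — the
calibration suite therefore runs without selection.

Calibration: on label-independent features the rejection rate at
alpha = 0.05 over 200 meta-runs (99 permutations each) is required to
stay within 5 % ± 3 %. The statistic's discreteness (accuracies on a
1/96 grid) makes ties possible and the strict-inequality p slightly
conservative; three CV repetitions per statistic keep the granularity
fine enough.

## Synthetic data generator

Each ROI receives a unit-variance 1/f background (spectrally shaped
white noise, exponent 1.0). A planted coupling adds band-limited
(FFT-masked) unit-variance oscillations to a ROI pair: the source ROI
gets the oscillation, the target gets the mixture
((1−s)·independent + s·delayed) / sqrt((1−s)² + s²), where the delay is
phase_lag/(2π f_center) seconds. The normalization means coupling
strength changes phase structure only, never band power — a
zero-strength coupling is an exact power-matched control. The phase lag
is realized exactly at the band center and approximately across the
band; PLI needs only a consistent lead/lag sign, which a lag in (0, π)
at all in-band frequencies provides. Lags of exactly 0 or π are rejected
at construction because they produce a purely real cross-spectrum and
are invisible to PLI.

Vertices inherit their ROI's signal along the first orientation axis
with per-vertex gains drawn uniformly from [0.5, 1.5]; sensor data are
the leadfield projection plus white noise scaled to a target amplitude
SNR (default 5). Per-subject coupling strengths are jittered ±20 % so
the dataset is not two waveforms copied 48 times. All randomness derives
from one master seed through a seed sequence; identical configurations
reproduce byte-identical datasets.

The canonical study (`default_study_config`) emulates the target
experiment's dimensions — 48 subjects × 2 conditions × 20 s × 32
channels at 256 Hz — with a beta-band **rewiring** contrast: two distant
homologous ROI pairs oscillate in both conditions; alert phase-couples
the first pair (s = 0.9, lag π/2), fatigue the second. Band power is
thus uninformative by design and classification must exploit phase.

What the generator does **not** emulate: physiologically realistic
artifact waveforms (the injector is a crude ramp + broadband burst used
only to exercise the removal stage), non-stationarity within a segment,
inter-subject anatomical variability (all subjects share one head model
and atlas), and realistic conduction geometry (spherical shells, not
BEM). Passing tests therefore establish the pipeline's correctness and
its sensitivity to planted phase couplings under these idealizations,
not performance on real driving data.

## Problem sizes for validation

Validation and the reproduction script run at desk scale, chosen as the
smallest sizes at which every effect of interest is comfortably
detectable: a 64-vertex-per-hemisphere source space with an
8-ROI-per-hemisphere atlas (16 ROIs, 120 connection features) for
end-to-end runs; 162 vertices per hemisphere for localization and the
68-ROI structural checks; 50 CV repetitions and 99 permutations; 20-seed
suites for the planted-recovery and feature-space-ordering properties.
Full-scale structural counts (20,484 vertices / 61,452 dipoles; 2278
features; 296 selected) are computed exactly at their printed sizes.

## Numerical choices

- Legendre recurrences for P_n and P_n' (stable at |c| = 1, where the
  tangential term vanishes).
- Pseudo-inverse cutoffs: 1e-10 relative (inverse operator), 1e-12
  (standardizer blocks, SOBI whitening, CCA whitening).
- Joint diagonalization: Jacobi sweeps with the closed-form angle from
  the 2×2 Gram matrix of ([c_pp − c_qq, 2 c_pq]) rows; convergence when
  every |sin θ| in a sweep is below 1e-8, at most 100 sweeps.
- BSS-CCA solves the canonical problem by whitened SVD; component
  autocorrelations are the singular values, and components below the
  threshold (default 0.6) are zeroed before back-projection.
- sign(0) in the PLI contributes 0; the imaginary-part deadband is
  1e-12 relative to the cross-spectral magnitude.
- k-means parcels are relabelled anterior→posterior (ties by height,
  then laterality), making atlas indices reproducible across runs.

## Known limitations

- The spherical forward model misstates skull conductivity effects
  relative to BEM; absolute gain values should not be interpreted,
  only used consistently within a run (the import path accepts real
  leadfields).
- The geometric atlas is not anatomical; lobe labels are heuristic.
  Anatomical name → lobe lookups are exact but only for the built-in
  34-name table.
- The fast permutation mode (frozen selection) is anti-conservative
  about the selection step and is flagged as such wherever used.
- PLI is blind to genuinely zero-lag physiological coupling by design;
  that is the cost of its volume-conduction robustness.
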