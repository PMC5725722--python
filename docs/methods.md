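# Methods

This note documents the models, numerical choices and limitations behind
`megconsist`. The package asks a single question — how consistent are MEG
source-space power, connectivity and network estimates when the assumed
source geometry is displaced, as happens when a template anatomical image
replaces a subject's own — and answers it end-to-end on synthetic data.

## Synthetic recording model

**Geometry.** The head is a homogeneous conducting sphere (radius 90 mm).
ROI centers sit on a quasi-uniform (Fibonacci) upper-hemisphere shell at
0.50–0.72 of the conductor radius; each ROI is a compact patch of voxels on
a 2 mm grid around its center. Dipole orientations are random but
tangential: radial dipoles in a sphere are magnetically silent, so purely
random orientations would occasionally produce near-invisible sources and
make reconstruction quality a lottery of geometry rather than of the
displacement under study. Sensors are a Fibonacci spiral of radial point
magnetometers on a hemisphere at 1.1 × the conductor radius (default 151
channels), a generic stand-in for a whole-head axial system.

**Signals.** Each ROI carries one unit-variance component per analysis band:
Gaussian white noise FFT-filtered with a hard (brick-wall) mask on
[f_low, f_high). A coupling (i → j, band, lag φ, strength c) replaces ROI
j's component by `c · shift(s_i, φ) + (1 − c) · independent noise`,
re-standardized, where `shift` rotates the analytic signal by e^{−iφ}. At
c = 1 the pair has an exactly constant phase difference φ; at c = 0 the
phases are independent. When no coupling graph is configured, a random
disjoint-pair matching per band is generated (lag magnitude uniform in
[π/8, 7π/8], random sign, strength 0.8) so that every band carries lagged
interactions a phase-based measure can detect, while zero-lag leakage-like
coupling — to which the PLI is deliberately blind — is avoided.

**Forward model.** Sarvas' closed-form field of a current dipole in a
sphere, projected on the channel orientations. An exact property used as a
test oracle: volume currents in any spherically symmetric conductor
contribute nothing to the radial field component, so B·r̂ must equal the
radial component of the primary (Biot–Savart) dipole term.

**Noise.** White Gaussian sensor noise scaled so that sensor-level signal
power over noise power equals the configured SNR (default 5). Both anatomy
conditions see the *same* sensor data — as in a real study, where only the
co-registration differs — so at zero displacement the two conditions are
bit-identical by construction.

**Anatomy perturbation.** `per_voxel` mode moves every voxel by exactly the
requested magnitude along an independent uniform random direction (re-drawn
up to 100 times if the move would leave the conductor); `rigid` mode applies
one random translation of that magnitude plus a small rotation
(angle = displacement / conductor radius) about the center. Per-voxel is the
default: it perturbs both the representative-voxel selection and the lead
fields without preserving the patch shape, which is the harder, more
informative condition.

## Reconstruction

Band-filtered epochs are pooled into one covariance per band, regularized as
C + λ·(tr C / M)·I with λ = 0.01 (the covariance of narrowband data over
short recordings is otherwise ill-conditioned). The dipole orientation per
voxel maximizes unit-gain beamformer output power: the eigenvector of the
smallest non-null eigenvalue of LᵀC⁻¹L, with the quasi-radial null space
(eigenvalues below 1e−8 of the largest) excluded and the sign fixed by the
first non-zero component. Weights are W = C⁻¹L/(LᵀC⁻¹L); pseudo-Z is
√(WᵀCW / σ²WᵀW) with σ² the mean of the smallest ⌈M/4⌉ covariance
eigenvalues — a noise-floor estimate that requires no separate empty-room
recording. Representative voxels are the per-band pseudo-Z peak or the
band-independent geometric centroid (minimum summed distance to the other
ROI voxels); all ties break to the lowest voxel id for determinism.

Relative power per ROI and band is computed from the broadband
(0.5–48 Hz) virtual electrode at that band's representative voxel; power
fractions use the same half-open frequency-bin convention as the filters, so
the six default bands partition the analyzed range and fractions sum to one.
The DC bin lies in no band, so filtering implicitly demeans each epoch.

## Connectivity and networks

PLI uses sign(sin Δφ) with sign(0) = 0, so exactly zero-lag samples are
neutral — the index's defining insensitivity to volume conduction. Phases
come from the Hilbert analytic signal of the band-filtered virtual
electrodes, per epoch.

Weighted clustering uses the triple-product form
Σ w_ik w_il w_kl / Σ w_ik w_il (0 when the denominator vanishes). Path
length uses Dijkstra on edge lengths 1/w, averaged over connected ordered
pairs, with the harmonic-mean fallback when pairs are disconnected (a guard
only: PLI matrices are almost surely fully weighted). Modularity is the
weighted Newman quality maximized by simulated annealing — random initial
partition, single-node moves to a neighboring or fresh module, Metropolis
acceptance, T₀ = 1, geometric cooling 0.995, floor 1e−4, stall stop after
100·R rejections — with the best partition per run kept, clipped below by
the always-admissible single-module partition (Q = 0), and Q and the module
count averaged over runs (default 100; reduced profiles use fewer for
speed). The per-epoch annealing seed is derived from (experiment seed,
subject, band, epoch) and deliberately *not* from the condition, so
identical adjacency matrices receive identical algorithmic noise; without
this the zero-displacement identity would be polluted by annealing variance.
The MST is Kruskal on 1/PLI lengths with ties broken by (length, smaller
node id, larger node id); the diameter is exact two-pass BFS in hops.

## Agreement statistics

ICC(3,1) — two-way mixed, consistency, single measure — treats the two
reconstruction conditions as fixed raters: (MSR − MSE)/(MSR + MSE) for
k = 2, with the residual sum of squares computed from the paired differences
(exact for identical or additively shifted raters) and the McGraw–Wong
F-based 95% interval. Ratings band the point estimate with right-closed
intervals ((0.8, 1] very good … ≤ 0.2 poor); negative values are rated poor
and flagged not reliable. Bland–Altman limits use the n−1 sample SD and
mean ± 1.96 SD on differences (template − native). Regional consistency
pools epochs across subjects (items = subject × epoch) per (measure, band,
ROI) for relative power, nodal mean PLI (row mean of the adjacency,
excluding the diagonal) and MST degree; global consistency works on
epoch-averaged per-subject values for the eight global measures. The
distance–consistency analysis correlates each ROI's mean representative-
voxel displacement with its power ICC, per band; within a single
displacement level the distance range is narrow and the correlation weak, so
the sweep-level analysis pools ROIs across displacement levels (and runs).

## Study conditions of the desk-scale experiment

`desk_scale_config()` pins the sweep exercised by the tests and the
acceptance script: 5 subjects, 20 ROIs × 4 voxels, 60 channels, 10 epochs of
1024 samples at 625 Hz, theta and beta bands, SNR 5, displacements
0/5/15/30 mm, peak-voxel method, 3 modularity runs per epoch. These sizes
were chosen once as the smallest configuration that still exercises every
stage with stable statistics; a single run takes ~10 s on one CPU, so a
10-seed sweep completes in minutes. The full-size defaults (17 subjects,
78 ROIs, 45 epochs of 4096 samples, 151 channels, six bands, 100 modularity
runs) remain available through `validate_config({})`.

## What the synthetic data does and does not show

The generator reproduces the *structure* of a resting-state atlas study —
band-limited lagged coupling, volume-conducted mixing through a physically
valid forward model, shared sensor noise across conditions, anatomy-only
differences between conditions — so passing tests demonstrate that the
analysis chain is correct and that its consistency conclusions respond to
geometric error in the expected direction. It does not emulate: 1/f
background spectra, amplitude dynamics or non-stationarity, physiological
artifacts (cardiac, ocular, muscle — a likely contributor to real gamma-band
inconsistency), realistic head shapes or multisphere/BEM conduction,
inter-subject anatomical variability, or the spatial error structure of real
template co-registration (which is correlated across neighbors, closer to
`rigid` than to `per_voxel` mode). Absolute ICC values from the sweep are
therefore not comparable to values from human cohorts; the qualitative
behavior (exact agreement at zero displacement, monotone decay, negative
distance–consistency correlation) is the claim under test.

## Other design decisions

- Band edges are half-open [low, high) so touching bands never double-count
  a bin; the denominator of relative power is fixed to the 0.5–48 Hz union.
- Epochs are filtered whole with no taper; brick-wall FFT masks are exact in
  the bin domain, at the usual cost of edge ringing in the time domain —
  worked examples in the tests therefore use bin-aligned tones, and
  phase-based checks exclude filter edges.
- The covariance warns (but proceeds, regularized) when samples < channels.
- `n_modules` is averaged over annealing runs as a real number.
- The rigid-mode rotation angle is tied to the translation magnitude; an
  isometry by construction, verified as such in the tests.
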