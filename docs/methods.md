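# Methods

`megbayes` compares four Bayesian source-reconstruction priors for MEG
under one optimization framework, on fully synthetic geometry. This note
records the model, the choices made where the design was open, and what
the synthetic benchmark does and does not show.

## Hierarchical model and reduction

Sensor epochs follow the linear forward model B = L·S + ς, with L the
gain matrix of unit dipoles fixed along the cortical surface normals and
ς white sensor noise. The problem is compressed before inversion:

- **Spatial modes.** Rows of U are eigenvectors of L·Lᵀ; modes with an
  eigenvalue below e⁻¹⁶ of the mean are discarded. U depends only on the
  forward model.
- **Temporal modes.** The spatially reduced epochs are DCT-II transformed
  along time (orthonormal convention; an optional band mask can window
  frequencies), and the eigenvectors of the coefficient cross-product are
  the candidate modes. The retained set is the *signal subspace*:
  eigenvalues above the Marchenko–Pastur white-noise bulk edge
  σ²R(1+√(N/R))², with σ²R estimated by the median eigenvalue (R =
  trials × spatial modes observation rows, N samples). When no eigenvalue
  clears the edge — noise-dominated data — the selection falls back to
  keeping modes at or above the mean eigenvalue. In practice a single
  clean source keeps ν = 1–2 modes down to roughly −20 dB, and only at
  −30 dB does the reduction stop denoising and retain ~half the spectrum.
  A cumulative-variance rule (`variance_fraction`) is available but it is
  not the default: measured on these simulations it retains nearly every
  mode at every SNR (white noise spreads a fixed variance share over all
  modes) and therefore never denoises.

The reduced data Ỹ = U·B·T, leadfields L̃ = U·L, and the trial-averaged
covariance S = meanₜ ỸₜỸₜᵀ/ν are the inputs to every scheme. Temporal
correlations among reduced samples are fixed to the identity.

## Covariance components and ReML

Each prior is a source covariance Q_i; its sensor projection
P_i = L̃·Q_i·L̃ᵀ enters C(λ) = Σ exp(λ_i)·P_i + exp(λ₀)·I_u. ReML
maximizes the Laplace free energy

F = −N/2·tr(C⁻¹S) − N/2·log|C| − uN/2·log 2π
    − ½(λ−η)ᵀΠ(λ−η) + ½·log|Σ_λ·Π|,

a lower bound on the log model evidence, by Fisher scoring with
Levenberg damping (the damped step is only accepted when F does not
decrease, so the trace is monotone by construction; when no damped step
improves F the iteration is at a numerical maximum and stops). Σ_λ is
the inverse expected information; hyperpriors default to η = −32,
Π = 1/256 per component — weakly informative log-normal scale priors.
Convergence is ΔF < 10⁻² (configurable), at most 512 iterations.
exp(λ) is clipped to [e⁻⁶⁴, e⁶⁴].

Because correctness of the update algebra cannot be checked line-by-line
against a closed-form reference derivation, it is anchored to a dense grid search of
the same free energy on small problems (≤3 components, u ≤ 6): the
scoring optimum must land within one 0.05 grid step of the grid maximum.

**Component normalization.** Inside `reml` every P_i is rescaled to
trace u before fitting (reported λ are mapped back to the raw scale).
Without this, a deep patch with a weak leadfield would need a log-scale
tens of units above η to contribute at all, and a single common
hyperprior over components would be meaningless. The η + 2 pruning
threshold and the hyperprior act on this normalized scale. Scheme
drivers additionally rescale the data covariance to trace u per dataset;
the MAP extractor is invariant to that common rescaling.

**MAP extraction.** Q_total = Σ exp(λ_i)Q_i (diagonal plus low-rank
factored form), M = Q_total·L̃ᵀ(L̃·Q_total·L̃ᵀ + exp(λ₀)I)⁻¹, and the
per-vertex power image is diag(M·S·Mᵀ).

## The four schemes

- **MNM** — identity source covariance (all sources equiprobable,
  uncorrelated). One signal hyperparameter.
- **EBB** — diagonal source covariance with per-vertex LCMV power
  σ²_θ = (l̃_θᵀC̃⁻¹l̃_θ)⁻¹ from the ridge-loaded (10⁻⁸·tr/u) reduced
  covariance. By default leadfield columns are unit-normalized first
  (unit-gain variant): the raw estimate carries a 1/‖l̃‖² factor whose
  spatial structure dominates the image as soon as noise is appreciable,
  and with it the characteristic beamformer SNR profile (near-perfect at
  ≥ −10 dB, degraded at −20, collapsed at −30) never emerges — the image
  peaks at depth-bias maxima instead of sources below +10 dB.
  `normalize_leadfields=False` restores the raw estimate.
- **ARD** — one hyperparameter per patch component over the full
  library; components whose normalized log-scale falls below η + 2 are
  frozen out during iteration; survivors are summed with their weights
  into the global prior.
- **GS** — candidate *sets* of patches, one hyperparameter per set,
  starting from the all-patch set. Each outer iteration re-estimates set
  weights by ReML, ranks the newest set's members by their MAP power
  summed over the patch support, and appends the top half as a new set.
  Unsupported sets are dropped (the best-supported is always kept, pool
  capped at 8, oldest evicted first); the search stops when F fails to
  increase twice in a row or the newest set is a single patch. The
  synthesized prior comes from the best-F state seen, which is what
  "stop when F stops increasing" implies — taking the last state instead
  measurably mislocalizes whenever late halvings overshoot.

All four feed a common final stage: a fresh two-hyperparameter ReML
(synthesized source prior + noise) followed by the MAP E-step, so the
final free energies are directly comparable across schemes and invariant
to any rescaling of the synthesized prior.

Hyperparameters are estimated from the pooled trial-average covariance
with N = ν × trials effective samples by default; `per_trial=True`
inverts each trial separately at
proportionally higher cost.

## Patch priors

Patch profiles are columns of a graph Green-function smoother
G = expm(τ(D⁻¹A − I)) on the mesh adjacency A, with diffusion time
τ = 6·s·(5 mm / mean edge)². The factor 6 (the mean degree of a
triangulated sphere) makes the operator the unit-per-neighbour-rate
diffusion expm(s(A−D)) on a regular 5 mm mesh; the (5/edge)² factor
pins the patch extent in millimetres, so coarser desk-scale meshes carry
patches of the same physical size (without it, patches on an 8 mm mesh
reach 40 mm radius and every patch scheme mislocalizes by tens of mm).
At the default s = 0.6 the effective coherence is roughly 10–13 mm.
Columns are truncated to the 8th-order graph neighbourhood and to
entries ≥ 10⁻⁴ of the column maximum, then peak-normalized. The library
holds one rank-one component per centre (farthest-point-sampled per
hemisphere) and, optionally, one bilateral component per left centre,
pairing it with the right centre nearest its mid-sagittal reflection.

## Synthetic head

A subdivided icosahedron (closest achievable count to the request) whose
radius is modulated by a seeded sum of eight surface plane waves
(amplitude 7 mm, wavelength 18 mm by default). The wrinkle emulates
cortical folding in the two respects that matter here: it stretches the
surface so the ~10k-vertex default mesh has a ≈5 mm mean edge like a
real cortical tessellation, and it tilts vertex normals away from the
radial direction so sources are not magnetically silent. Hemispheres are
the x<0 / x≥0 halves. Sensors are point magnetometers on a Fibonacci
cap at 1.3× the conductor radius with tangential orientations.
Leadfields use the closed-form single-sphere (Sarvas) solution with unit
1 nAm moments along the vertex normals; correctness is tested against a
numerical gradient of the magnetic scalar potential and a Biot–Savart
check of the radial component.

What the synthetic head does *not* emulate: true cortical folding
geometry (sulcal banks facing each other, strongly varying depth),
gradiometer pickup, head-position variability, correlated brain noise.
Accuracy numbers transfer to real data only qualitatively.

## Simulations

Per dataset: dipoles at patch centres drawn from the 50 locations (out
of 10⁴ random candidate sets) with minimally correlated leadfields;
time courses sin(2π·cumsum(f)/fs + φ₀) with f ~ N(10 Hz, (2 Hz)²) per
sample and uniform random phase (10 ± 2 Hz is a typical alpha-band
choice; both parameters are configurable and echoed in every dataset's
metadata); multi-dipole sets
rejection-sampled until all pairwise |r| > 0.8 (high) or < 0.3 (low);
100 epochs of 0.8 s at 200 Hz with the identical clean signal and fresh
white noise per trial. The noise SD is calibrated as
signal/10^(SNR/20), where the signal level is the average over sensors
of the per-sensor RMS noiseless reading (a few dB below the pooled RMS
for dipolar field patterns, where most sensors see little signal). A 10·log₁₀ power-ratio option exists behind a flag.

## Accuracy metrics

**SAI.** Image local maxima (strictly greater than all first-order
neighbours, ties to the lower index; peaks below 5% of the global peak
dropped) are walked in descending magnitude; within search radius r of a
true dipole a peak is TP, else FP. The accumulated-magnitude PPV
Y = TP_acc/(TP_acc+FP_acc) against the fraction of peaks visited,
extended flat to fraction 0, gives a trapezoidal AUC in [0,1] per
radius. Distances are Euclidean in mm; radii default to 10 log-spaced
values in [3, 30] mm. Implementations are verified against brute-force
step-by-step accumulation on random instances.

**TAI.** R² of the reduced data explained by regressing each trial onto
the span of the MAP time courses of the TP-labelled peaks. The span only
grows with r, so the curve is monotone non-decreasing by construction (a
variant predicting L̃_sel·Ŝ_sel over all vertices within r was measured
to violate monotonicity by up to 0.3 through partial-patch field
cancellation, contradicting the metric's defining property). With a
single temporal mode any non-zero regressor is exact, so R² is reported
as NaN at ν = 1. The headline TAI is the per-radius R²; the AUC over
the normalized log-radius axis is also reported.

**Statistics.** Two-sample t-tests between schemes per condition × SNR
cell, Bonferroni-corrected by (#conditions × #SNRs); free energies are
compared as fixed effects (mean ΔF, sign counts, fraction of simulations
favouring each scheme). Random-effects model selection is out of scope.

## Desk-scale benchmark conditions

The acceptance benchmark (`megbayes.benchmark`, `scripts/acceptance.py`)
runs a 2562-vertex head with 120 sensors, 64 patches per hemisphere,
100-trial simulations and 10 simulations per condition, with
hyperparameters estimated from the pooled trial-average covariance —
a reduced replica of the full-scale design (8196-vertex cortex, 275
channels, 256 patches per hemisphere, 50 simulations per condition). Problem sizes are the package's own desk-scale
choice; all are parameters of `benchmark_assets`.

## Known limitations

- The minimum-norm scheme is the weak point of this benchmark at low
  SNR (SAI ~0–7% at 10 mm / −30 dB): there the MNM image is dominated by
  its data-independent depth-bias baseline diag(MMᵀ), whose maxima sit
  on superficial wrinkle crests away from any source. Reports of
  minimum-norm robustness in that regime on real cortical geometry do
  not transfer to the wrinkled sphere; the other three schemes (and MNM
  at high SNR) behave as expected, so the simulator and SNR calibration
  are unlikely causes.
- The beamformer's sensitivity to inter-source correlation is
  directionally reproduced but small at desk scale: with |r| just above
  0.8 the LCMV power at both sites is suppressed by a common factor, and
  the image still peaks at the sources whenever the background is low.
  The effect concentrates around −20 dB; detecting it reliably needs
  on the order of a hundred simulations per group (measured d ≈ 0.4
  pooled over SNRs at desk scale).
- GS accuracy degrades quickly below −10 dB; ARD is the robust scheme
  at −20/−30 dB, and the free-energy comparison ranks the schemes the
  same way without access to the ground truth.
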