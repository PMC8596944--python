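# Methods

## Problem

Whole post-mortem brains are usually immersion-fixed in formalin and then
transferred into a susceptibility-matched, signal-free fluid (a
perfluorocarbon such as fluorinert) for scanning. From that moment fixative
starts to diffuse out of the tissue into the bath. Because the presence of
formalin shortens T2 roughly linearly in its concentration, the partially
depleted rim near the brain surface acquires a spatial T2 bias that
confounds quantitative comparisons across the brain. `fixflux` simulates
that fixative transport, predicts the voxelwise concentration at scan time,
and removes the linear concentration confound from the measured T2 map.

## Transport model

Fixative concentration c(t, r) — a unitless fraction of full-strength
fixative, c ∈ [0, 1] — obeys Fick's second law with a spatially varying
diffusion tensor:

    ∂c/∂t = ∇ · ( D(r) ∇c ),

where D(r) (mm²/s, symmetric, positive semi-definite) is taken from
diffusion MRI of the same specimen. Using the water self-diffusion tensor
for fixative transport is the kinetic tensor (KT) model's central
assumption: transport is faster along fibre bundles and differs between
tissues exactly as water diffusivity does. Initial and boundary conditions:

* outflux (the scanning scenario): c = 1 in tissue, c = 0 in the medium;
* influx (immersion fixation): c = 0 in tissue, c = 1 in the medium;
* the medium is an infinite bath: every medium voxel is pinned to its
  boundary value after every step (Dirichlet), and the grid border behaves
  as medium.

Because the update is linear and the two settings swap initial/boundary
data, the outflux field is exactly the complement (1 − influx) of the
influx field; the solver preserves this to rounding.

Comparison models sharing the same solver and interface:

* **KI (kinetic isotropy)** — D(r) replaced by d·I with a single scalar d
  (default 2.4 × 10⁻⁴ mm²/s, the whole-brain mean diffusivity of fixed
  post-mortem tissue); only a mask and one coefficient are needed.
* **KI-MD** — d(r)·I with the voxelwise mean diffusivity map: voxel-specific
  rates without anisotropy.
* **D2S (distance to surface)** — no transport at all; the regressor is the
  Euclidean distance (mm) from each tissue voxel centre to the nearest
  medium voxel centre (`scipy.ndimage.distance_transform_edt` with the
  physical voxel spacing).

### Tensor preparation

Diffusion-tensor estimates in post-mortem data contain sporadic voxels with
spuriously high diffusivity (vessel remnants, partial volume with free
fluid). Any tissue voxel whose principal diffusivity strictly exceeds
1 × 10⁻³ mm²/s has its whole tensor replaced by the component-wise mean of
the unflagged tissue voxels in its 26-neighbourhood, iterated until no
voxel exceeds the threshold; a voxel that can never be resolved raises an
error listing its indices. After cleanup, any residual negative eigenvalues
can be clipped to zero (`project_to_psd`), with a count of modified voxels
returned. Medium tensors are zeroed; the face-weight convention below makes
them irrelevant to tissue dynamics.

### Discretization

Explicit Euler in time with τ = T/n (default T = 48 h, n = 2000, hence
τ = 86.4 s). In space the tensor is decomposed per voxel into non-negative
1-D diffusion chains along the three grid axes and the six face diagonals:

    D = Σᵢ aᵢ eᵢeᵢᵀ + Σ_{i<j} |D_ij| (eᵢ + s·eⱼ)(eᵢ + s·eⱼ)ᵀ,
    aᵢ = D_ii − Σ_{j≠i} |D_ij| · hᵢ/hⱼ,    s = sign(D_ij),

and each chain is discretized with face-centred fluxes using
arithmetic-mean face weights. All stencil weights are then non-negative
whenever the tensor is (spacing-weighted) diagonally dominant — for axially
symmetric tensors this holds up to FA ≈ 0.71, comfortably above the white
matter anisotropy the phantom generates — which makes the explicit update a
convex combination under the stability bound: the discrete solution
satisfies the maximum principle (c stays in [0, 1]) and per-voxel monotone
outflux decay *exactly*, not just approximately. Where diagonal dominance
fails, that voxel's chain weights are scaled down just enough to restore
non-negativity (the count of such voxels is reported; it is zero for the
default phantom). For diagonal tensors the scheme reduces identically to
the standard 7-point face-flux discretization, so the kinetic-isotropy path
and an isotropic tensor field produce bit-equal trajectories.

A second discretization of the mixed terms — cell-centred central
differences of (D_ij ∂c/∂xⱼ), second-order consistent but not monotone —
is retained (`mixed_scheme="central"`) purely as a cross-check: the two
schemes agree to ~2% relative L2 on the 32³ anisotropic phantom at 0.9 mm
resolution, evidence that both discretize the same operator. The lattice
scheme is the default because a concentration fraction that leaves [0, 1]
(the central scheme overshoots by ~10⁻²) is physically meaningless for this
application, and the correction pipeline consumes the concentration values
directly.

At a tissue–medium face the tissue-side diffusivity is used instead of the
arithmetic mean, so the Dirichlet node couples at full strength and the
(zeroed) medium tensors genuinely cannot influence the solution.

### Stability

The solver refuses any τ above

    τ_max = min over voxels of  h_min² / (2 Σ_ij |D_ij|),

with the sum over all nine tensor entries. For the lattice scheme this
guarantees the row sum of off-centre update weights stays below 1, i.e.
monotonicity, not merely boundedness. For isotropic D and isotropic spacing
it reduces to the familiar τ ≤ h²/(6D).

### Validation oracles

Analytic series solutions validate the solver end to end:

* **Slab**: outflux from a slab of width L between absorbing walls,
  c(x,t) = Σ_{odd n} (4/nπ) sin(nπx/L) exp(−D(nπ/L)²t). The discrete wall
  sits at the pinned medium voxel centre, so a slab of W tissue voxels has
  L = (W+1)h. Agreement is ~0.03% relative L2 at the mid-transient.
* **Sphere**: influx into a ball held at c = 1 on its surface,
  c(0,t) = 1 + 2 Σ_k (−1)ᵏ exp(−Dk²π²t/R²) at the centre. A digitized
  (staircase) ball is not a sphere of radius exactly R·h; its effective
  continuum radius is derived independently of the transient being
  validated, from the principal Dirichlet eigenvalue λ₁ of the discrete
  spatial operator via λ₁ = D(π/R_eff)² (a pure geometry calibration,
  computed with a matrix-free Lanczos solve). With R_eff the centre
  concentration tracks the series to well under 2% through the
  mid-transient at R = 21 voxels.

Structural invariants tested on anisotropic phantoms: influx/outflux
complement to 1e-10; c ∈ [0,1] and per-voxel monotone outflux decay at
every step to 1e-12 (measured violation: exactly zero); halving τ changes
the 48-h map by far less than 0.1% relative L2 (first-order-in-time
consistency with a heavily damped leading error).

## T2/B1 mapping (EPG)

At 7 T the transmit field is inhomogeneous, so TSE refocusing pulses are
b1·180° with b1 dropping toward the brain surface; the echo train then
deviates from mono-exponential decay through stimulated-echo pathways. The
extended phase graph (EPG) model tracks the configuration states (F₊, F₋,
Z) through the train and predicts echo amplitudes for arbitrary refocusing
angles.

Implementation choices:

* The printed echo times (13, 25, 38, 50, 63, 76 ms) are not exact
  multiples of the first, so the train is modelled with per-interval
  half-spacings (TE_k − TE_{k−1})/2 around each refocusing pulse and ideal
  crushers per interval (one configuration-order shift per half-interval).
  At b1 = 1 this collapses exactly to exp(−TE/T2) at every printed TE; for
  equally spaced TEs it is the textbook CPMG train.
* Excitation is treated as ideal and amplitudes are normalized to unity at
  TE → 0; the per-voxel amplitude S0 absorbs any excitation scaling.
* b1 is searched and reported in (0, 1]: a refocusing angle α and 360° − α
  produce identical echo trains, so the branches are indistinguishable.
* T1 cannot be separated at TR = 1000 ms and is fixed (default 500 ms,
  configurable). Relaxation during the ~6–13 ms half-intervals makes the
  echo amplitudes only weakly T1-sensitive; S0 absorbs most residual
  error, and the T1 choice is exposed for sensitivity analysis.
* The oracle for the signal model is a stratified isochromat Bloch
  simulation (explicit rotation matrices, crusher phase 2πs/N). With N
  spins exceeding the number of configuration orders the two descriptions
  are related by an exact discrete Fourier transform and agree to rounding;
  this equivalence is asserted as a property test over random (T2, b1).
  Note the echo train itself is *not* monotone for b1 < 1: stimulated-echo
  pathways make echo 2 exceed echo 1 at low flip angles, with a sustained
  even/odd oscillation; both descriptions reproduce this.

### Two-stage fitting

**Stage 1** fits (S0, T2, b1) per voxel by nonlinear least squares. The
objective over (T2, b1) is multi-modal, so the global search is an
exhaustive dictionary match: normalized EPG signatures on a 40-point
geometric T2 grid (3–300 ms) × 19-point b1 grid (0.1–1.0), matched by
correlation, then refined by damped Gauss–Newton with S0 solved by linear
projection at every step (signals are normalized per voxel). The refinement
is vectorised over voxels with an active set; converged voxels drop out.
Noiseless inversion recovers T2 to ≪0.1 ms and b1 to ≪0.005.

**Stage 2** first projects the stage-1 b1 map onto a 3-D polynomial basis
(total degree ≤ order, default 2; coordinates normalized to [−1, 1] for
conditioning) — the physical transmit field is smooth, so any anatomical
contrast in the raw b1 map is fit noise — then refits (S0, T2) with b1
frozen to the smoothed field. With regularisation weight λ > 0 the
objective gains λ(T2 − ref)², where ref is the 26-neighbourhood median T2
from an unregularised pass: voxels whose echoes carry almost no information
(low b1, low SNR near the surface) are anchored to surrounding tissue while
well-determined voxels are unaffected. The quadratic neighbourhood-anchored
penalty is this package's design; λ is in (normalized signal)²/ms² and the
default is 0 (off).

## Confound regression

The fixative effect on T2 is modelled as linear: T2 = T2⁰ + β·c, with a
single (T2⁰, β) per brain. To avoid tissue-type bias — T2 and concentration
share a centre-to-periphery spatial pattern — the fit uses white matter
voxels only. Voxels within 2 mm of the brain surface are excluded
(boundary voxels carry large T2 errors), as are T2 outliers outside
median ± 3×MAD over the masked voxels; the MAD is deliberately unscaled (no
1.4826 factor), and the same exclusions apply identically in fitting and in
every reported statistic. Surviving voxels are binned by regressor value
(100 equal-width bins; range 0–1 for concentration, 0–23 mm for distance),
and bin-mean T2 is regressed on bin centre by weighted least squares with
the voxel count as weight; empty bins are dropped. The correction
T2 − β·c is then applied voxelwise over the whole brain, both tissue
types, including voxels excluded from the fit.

Evaluation: inhomogeneity is the sample SD (ddof = 1) of T2 within one
tissue type after the same exclusions. Because the fit sees only white
matter, a reduction of the grey-matter SD is a held-out validation of the
transport model, not a fitting tautology. Groups of per-brain summaries are
compared with Welch's unequal-variance t-test (two-sided, Satterthwaite
degrees of freedom) and Cohen's D in the pooled-SD form. The regressor
interface is generic — concentration, distance, or a B1 map pass through
unchanged — so comparing KT, KI, KI-MD, D2S and a B1-based correction is
purely a change of regressor.

## Synthetic phantom

The generator emulates the statistical structure the pipeline sees in a
whole fixed post-mortem brain, at desk scale (default 48³ voxels at 0.9 mm
isotropic):

* **Geometry** — an ellipsoid whose surface is modulated by a smooth random
  field (sulci-like bumps), with a ≥2-voxel medium margin; optional
  ventricle-like internal medium cavity (off by default, reflecting
  fluorinert-filled ventricles being treated as part of the bath only when
  requested).
* **Tissue classes** — white matter is the deep core (depth > 2.8 mm,
  smoothly perturbed), grey the remaining shell.
* **Tensors** — axially symmetric, MD lognormally jittered (CV 15%) around
  the post-mortem class means (white 1.37 × 10⁻⁴, grey 3.1 × 10⁻⁴ mm²/s;
  realized class means match targets exactly in expectation and within 5%
  per realization); white FA 0.6 along bent-arc tracts (azimuthal around
  the vertical axis with a smooth pitch — oblique to the grid so all six
  tensor components are exercised), grey FA 0.05.
* **T2⁰** — 45 ms (white) / 60 ms (grey) plus a smooth ±1 ms field;
  plausible fixed-tissue values at 7 T.
* **Fixative effect** — T2 = T2⁰ + β·c with β = −12 ms per unit
  concentration, the midpoint of the reported 10–15 ms linear decrease
  over the full concentration range.
* **B1** — 1 − 0.35ρ² (ρ the normalized radius), clipped to [0.3, 1]:
  smooth, ~1 centrally, decreasing toward the surface.
* **Noise** — Gaussian (default) or Rician (magnitude of complex Gaussian)
  at SNR 50 referenced to the mean first-echo tissue signal.

Everything is deterministic given (spec, seed); the default is seed 7.

What the phantom does **not** emulate: real cortical folding and partial
volume, spatially correlated coil noise, registration error between
diffusion and TSE spaces (grids are assumed aligned), exchange or binding
chemistry of formalin, and fixative accumulation in the bath (negligible
over 48 h for realistic bath volumes). Passing tests therefore demonstrate
the correctness of the numerics and the recoverability of the model's
parameters under the stated conditions — not the adequacy of the KT model
for any particular real specimen.

## Problem sizes and numerical defaults

Defaults mirror the reference workflow: 48-h outflux in 2000 steps
(τ = 86.4 s), 0.9 mm isotropic grids, 100 bins, 2 mm surface exclusion,
k = 3 MAD. Validation suites run at 32³–48³; the slab oracle uses a
64-voxel slab and the sphere oracle a radius-21-voxel ball on a 48³ grid —
sizes at which the analytic comparisons resolve well below their tolerance
while the full suite stays desk-scale. Snapshot times map to the nearest
integer step. All internal arithmetic is double precision; NIfTI output is
float32 (uint8 for masks).

## Known limitations

* The explicit scheme's τ_max scales with h²: halving the voxel size
  quadruples the step count. Implicit/ADI solvers are out of scope.
* The lattice scheme's mixed-term treatment loses accuracy (and slightly
  reduces effective anisotropy) at voxels beyond the diagonal-dominance
  cone (FA ≳ 0.71); such voxels are counted and reported.
* Magnitude (Rician) noise bias is simulated but not modelled in the
  fitting likelihood; at SNR 50 the bias on T2 is negligible relative to
  the 5% recovery tolerance.
* A single global β cannot represent tissue-specific fixative sensitivity;
  that is a modelling assumption inherited from the confound-regression
  design, not a numerical limitation.
* The median ± 3×MAD outlier gate attenuates the recovered β by a few
  percent whenever the fixative effect itself dominates within-tissue T2
  variance (the unscaled-MAD window then clips the legitimate extremes of
  the concentration range). On real brains, biological T2 variance widens
  the window and the effect shrinks; on the phantom it is visible and is
  the main contributor to the residual β recovery error.
* Smooth within-tissue T2⁰ variation can correlate by chance with the
  concentration field in a finite volume, shifting the global β by several
  percent on some phantom seeds — the synthetic counterpart of biological
  T2 variation influencing the fit, and a reason the correction is
  validated on held-out grey matter rather than by β alone.
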