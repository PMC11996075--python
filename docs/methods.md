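# Methods

This note records the models implemented in `aortaflow`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data do and do not establish about real acquisitions.

## Synthetic acquisitions

The generator (`aortaflow.synth`) emulates what a velocity-encoded
phase-contrast scan of pulsatile tube flow delivers: per cardiac timeframe,
three phase volumes (one per encoding axis), a magnitude volume, and a
static binary lumen mask, with metadata (V_enc per axis, frame duration,
voxel spacing, origin, seed) in a JSON sidecar.

**Phase convention.** Stored phase is signed and normalised to [−1, 1];
velocity component c is `phase_c · venc_c`. This matches how phase-contrast
grey values are decoded by multiplication with the encoding limit while
avoiding any scanner-specific integer scaling. Additive velocity noise can
push a near-peak voxel's phase marginally past ±1; phase is saturated
(clipped), not wrapped. True aliasing is refused outright: a configuration
whose peak noiseless speed exceeds V_enc on any axis raises an error,
because phase unwrapping is not part of the modelled workflow.

**Array convention.** Velocity-like arrays are `[frame, i0, i1, i2,
component]`, 0-based, voxel-centred, world coordinate = origin + spacing ·
index; the tube axis lies along the third spatial axis and component c
points along world axis c.

**Flow model.** The axial profile is a quasi-steady Poiseuille parabola
whose peak tracks the configured volumetric flux waveform (periodic linear
interpolation of control points). The discrete profile is normalised so the
voxel-sum flux is exact at every frame, which is what makes the
per-frame flux a usable oracle for downstream stages. A separate
`womersley_profile` evaluator provides the classical Bessel-function
solution for genuinely pulsatile laminar pipe flow (flux-normalised per
harmonic, exactly no-slip); it serves as the analytic reference against
which the quasi-steady assumption can be quantified, not as the generator's
default, because the emulated protocols resolve 20–25 frames per cycle at
which the parabolic approximation is the conventional reading.

**Stenotic jet.** A reduced-orifice valve is emulated by remapping each
cross-section's axial profile into a footprint of area `orifice_frac`
times the lumen area, centred `eccentricity_frac · R` off-axis: in-plane
coordinates shrink by √orifice_frac, amplitude scales by 1/orifice_frac, a
tanh edge window (half-width half a voxel) smooths the rim, and the section
is rescaled so its flux exactly matches the unjetted section. The remap
preserves the profile shape, so at equal flux the peak velocity rises by
1/orifice_frac (4× at a quarter orifice), consistent with the area-ratio
bound that flux conservation imposes. A flat top-hat would cap the gain at
the area ratio of means (2× over a parabola) and was rejected for that
reason.

**Helical component.** In-plane secondary flow is a solid-body rotation
about the lumen axis, right-handed with respect to the flow direction (the
physiologically dominant handedness in the aortic arch), scaled per frame
so the lumen-averaged in-plane speed is `helical_frac` times the
lumen-averaged axial speed. The pattern is the simplest one with a
controllable area-averaged magnitude ratio; real secondary flow is not
solid-body, so tests built on it validate the *ratio bookkeeping*, not
in-vivo swirl morphology.

**Noise.** Independent Gaussian noise of standard deviation
`noise_sigma_frac · venc_c` is added to every voxel's velocity (lumen and
background alike) per component. The default fraction is 0.05 — the
conventional estimate of phase-contrast velocity noise, and the level the
emulated protocols report (≈57 mm/s at V_enc 1140 mm/s, ≈46 mm/s at
920 mm/s).

**Defaults.** Lumen radius 12.5 mm and a 0.8 s cycle with a systolic pulse
peaking at 400 mL/s describe a healthy adult ascending aorta; 2 mm
isotropic voxels and 20 frames are typical reconstructed resolutions;
V_enc defaults to 2000 mm/s (a stenosis-capable setting that accommodates
the default waveform's peak velocity). `curvature_radius` is accepted in
the configuration for forward compatibility but only straight tubes are
generated; a curved lumen raises a geometry error rather than silently
approximating.

**What the generator does not model:** k-space physics, phase wrapping,
eddy-current or Maxwell-term offsets, partial-volume magnitude effects,
segmentation error, wall motion. Passing tests therefore demonstrate the
correctness of the processing chain on ideal velocity-encoded data, not
robustness to scanner artefacts.

## Acquisition processing

Decoding, masking and sampling work in mm and mm/s throughout; conversion
to SI happens once, at the entry to the hemodynamics module. This single
unit boundary is deliberate: clinical flow values are reported in cm/s or
mm/s while stress and Reynolds computations are SI, and a per-function
convention invites silent errors.

**Noise estimation** follows the operational definition of measurement
noise: the standard deviation of decoded velocity over background voxels
during diastole, where no flow signal should exist. Background is the
complement of the lumen mask dilated by 3 voxels, excluding the
partial-volume rim. Diastole, when not given, is auto-detected as the
frames whose lumen-mean speed lies in the lowest 10% of its cycle *range*;
the range normalisation (rather than a fraction of the raw maximum) is
required because the noise floor alone lifts quiescent frames above 10% of
peak speed at realistic noise levels — for noiseless data the two rules
coincide. The estimator reports both σ in mm/s (RMS across axes) and the
σ/V_enc ratio (mean of per-axis ratios, since axes may use different
encoding limits).

**Plane sampling** is trilinear (exact for fields linear in space); samples
outside the lumen are flagged and excluded — not zero-filled — from area
averages, because zero-filling biases wall-adjacent means low.

## Inlet boundary conditions

**Measured route.** The inlet plane series is the decoded, masked velocity
sampled on the plane grid per frame; refinement to a solver grid/time base
is bilinear in-plane and linear in time, with the cycle treated as periodic
(consistent with simulating several cycles and post-processing a converged
one). The solver time step is the MRI frame duration divided by 40.

**Synthetic healthy route.** The axial field is a generalized parabola
`v = v_peak (1 − r̃²)` with `r̃ = 1 − d/d_max` built from the in-plane
Euclidean distance-to-wall d (computed by exact distance transform); on a
circular lumen this is the Poiseuille parabola, on any lumen it satisfies
no-slip, and v_peak is rescaled so the numerically integrated flux matches
the target exactly (the profile is linear in v_peak, so the match is to
machine precision, not 1e-6). The flux waveform and the secondary-flow
schedule s(t) are least-squares Fourier fits; with sample count equal to
parameter count the fit interpolates. Default order is 8 harmonics (capped
at the interpolating order), enough to resolve a systolic upstroke at
20–30 frames per cycle. The in-plane field is the solid-body swirl pattern
scaled so the area-averaged in-plane/axial speed ratio equals s(t); since
the swirl adds no axial flux, the composed field's flux equals the fitted
flux identically. Negative fitted flux reverses the axial direction
(retrograde flow); the swirl scaling uses the speed magnitude. Fitted
schedule values below zero (possible between data points for aggressive
orders) are clamped to zero at composition time.

The secondary-flow fraction is defined here as the ratio of area-averaged
in-plane speed to area-averaged axial speed; whether the cited per-phase
percentages are exactly this statistic is not specifiable from the source,
so the definition is stated rather than inferred. `two_phase_schedule`
builds the single-harmonic schedule through a systolic and a diastolic
anchor (e.g. 32% and 111%) when only per-phase values are available.

## Outlet boundary conditions

Each branch i obeys `p_i − p_b = ξ_i · ½ ρ u_i²` with a common far-field
pressure p_b (set to 0 Pa: only differences matter in the surrogate) and
blood density ρ = 1060 kg/m³. The junction surrogate finds the single
junction pressure at which the loss law and mass conservation hold; total
outflow is strictly increasing in pressure, so Brent's method on a
geometrically grown bracket converges to 1e-12 relative, and the flows are
rescaled to make conservation exact. Flows are constrained non-negative —
the loss law uses u², leaving it undefined under backflow, so backflow is
excluded by construction. ξ = 0 is rejected as singular (zero resistance
admits unbounded flow).

**Calibration.** The update `ξ ← ξ (f/f_target)²` is chosen because the
quadratic pressure–velocity relation makes it exactly self-correcting on a
single branch; on the common-junction surrogate the branch weights
A_i/√ξ_i become proportional to the targets after one update, so
calibration typically converges in two iterations from any positive start.
Tolerance is 1e-3 in absolute fraction — below the precision of prescribed
splits quoted to 0.001. Prescribed fractions are accepted when they sum to
1 within 1e-4, admitting printed-precision rounding (the standard
four-branch split sums to 99.999%); the residual floor this puts under the
max fraction error (≈7e-6) is far below tolerance. Per-timestep
calibration warm-starts from the previous coefficients; because the flow
split at fixed coefficients is independent of flow magnitude, warm starts
converge immediately and only the pressures change (quadratically with
flow). The converged fixed point — achieved fractions equal targets — is
taken as the normative behaviour of the feedback loop; the bookkeeping a
particular 3D solver uses internally is not reproduced.

## Bulk hemodynamic metrics

All metrics are computed in SI on uniform structured grids.
Derivatives are central differences in the interior, one-sided at domain
and mask boundaries (exact for affine fields, second-order in the
interior). Shear rate is `γ̇ = √(2 S:S)` from the symmetric strain-rate
tensor.

**Rheology.** Carreau–Yasuda with the standard human-blood parameter set
used in aortic CFD: η0 = 0.16 Pa·s, η∞ = 0.0035 Pa·s, λ = 8.2 s, a = 0.64,
n = 0.2128, ρ = 1060 kg/m³. A `newtonian()` constructor pins both
viscosities for analytic tests.

**Stress scalarization.** VSS = η(γ̇)·γ̇ and RSS = μ_t·γ̇ via the
Boussinesq eddy-viscosity analogy, TSS = VSS + RSS pointwise. These are
*chosen* scalarizations — consistent with an additive total in a
Reynolds-averaged setting — not a reconstruction of any particular
reference implementation; an alternative based on principal Reynolds
stresses would require the full stress tensor, which a RANS eddy-viscosity
closure does not carry.

**TKE** is reported as k in m²/s² (per unit mass, the variable of
two-equation closures), taken from the input field when present or
estimated from velocity ensembles as half the summed unbiased component
variances about the ensemble mean.

**Helicity.** H = v·ω and LNH = H/(|v||ω|), clipped to [−1, 1] against
rounding; where |v||ω| < 1e-12 (SI units) the point is degenerate — LNH is
reported as 0 and flagged, so ROI means are not biased by 0/0 artefacts.
Positive LNH denotes right-handed swirl.

**Reynolds numbers** use the local Carreau–Yasuda viscosity:
Re(x) = ρ|v(x)|D/η(γ̇(x)); both the mask-volume average and maximum are
reported against a caller-supplied diameter.

## Validation

Area-averaged velocity-magnitude curves per analysis plane are paired at
the reference frame times (candidate resampled linearly in time), pooled
across planes into one OLS regression of candidate on reference, with
R² = 1 − SS_res/SS_tot and the slope's t-test p-value. Velocity magnitude
is used because the compared quantity is an unsigned area-averaged speed;
a component-wise comparison would require a stated component convention.
Ties in the bias fraction count one half so the identical-pairs case reads
0.5. An in-vivo-grade regression (R² ≈ 0.9 against an independent 3D
solve) is not reproducible without patient data and a solver; the package
instead establishes the two ends that bracket it: self-validation
(candidate = reference) returns R² = 1 to machine precision, and seeded
noisy pairs return R² within ±0.02 of the population value
Var(ref)/(Var(ref)+σ²) at n = 10³.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances chosen to keep every check analytic: tubes of 6–12.5 mm radius
on 0.25–2 mm grids, 2–20 frames per cycle, a 64³ Beltrami grid for the
LNH oracle, 10⁴-realization ensembles on 2³ grids for the TKE estimator,
and ≥10⁴ background voxels for noise recovery. These sizes are the
package's own choice of the smallest instances on which each property is
identifiable; every tolerance quoted above was verified at these sizes.

## Known limitations

* No curved or branching lumens in the generator; masks for such
  geometries must come from elsewhere.
* The junction surrogate shares one pressure node; it exercises the
  calibration loop but cannot exhibit inter-branch wave phenomena.
* Mask-aware one-sided differences are first-order at boundaries; metrics
  very close to the wall carry larger discretisation error than interior
  values.
* The ensemble TKE estimator assumes statistically independent
  realizations; it is a plumbing substitute for a closure-model k field,
  not a turbulence measurement.
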