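# aortaflow

Patient-specific models of aortic blood flow are built by coupling 4D Flow
MRI measurements to computational fluid dynamics: the scan supplies the
time-resolved inlet velocity profile and the branch flow split, the solver
supplies the resolution needed for gradient-based quantities such as shear
stresses acting on circulating red blood cells. `aortaflow` implements the
measurement-and-boundary-condition side of that workflow as a tested Python
library, for researchers in cardiovascular biofluid mechanics who need the
bespoke stages between a velocity-encoded acquisition and a 3D solver —
without the solver itself.

The package covers:

* **Synthetic acquisitions** (`aortaflow.synth`) — velocity-encoded 4D
  phase/magnitude/mask volumes of pulsatile tube flow with analytic ground
  truth: quasi-steady parabolic or Womersley profiles, an optional eccentric
  stenotic jet (flux-conserving), helical secondary flow, and Gaussian phase
  noise at a set fraction of the encoding limit V_enc.
* **Decoding and characterisation** (`aortaflow.flowmri`) — velocity
  decoding v = phase · V_enc, lumen masking, noise estimation from
  non-vessel voxels during diastole, oblique plane sampling and
  area-averaged velocity curves.
* **Inlet boundary conditions** (`aortaflow.inlet`) — measured-profile
  extraction with separable linear space–time refinement and the CFD time
  step rule Δt = T_frame/40; and the *synthetic healthy* inlet: a parabolic
  profile flux-matched to the measured volume flux, Fourier-series waveform
  fits, and an in-plane swirl prescribed as a scheduled percentage s(t) of
  the axial speed.
* **Outlet boundary conditions** (`aortaflow.outlet`) — each arch branch is
  an opening obeying the loss-coefficient law
  p_i − p_b = ξ_i · ½ ρ u_i², with ξ_i calibrated iteratively on a junction
  surrogate until the branch mass-flow fractions match their prescribed
  values (constant over the cardiac cycle).
* **Bulk hemodynamic metrics** (`aortaflow.hemodynamics`) — Carreau–Yasuda
  viscosity η(γ̇) = η∞ + (η0 − η∞)[1 + (λγ̇)^a]^((n−1)/a), shear rate
  γ̇ = √(2 S:S), the scalar stress decomposition TSS = VSS + RSS with
  VSS = η γ̇ and RSS = μ_t γ̇, turbulent kinetic energy, vorticity, helicity
  density H = v·ω and local normalized helicity LNH = v·ω/(|v||ω|), and
  Reynolds numbers.
* **Validation** (`aortaflow.validation`) — paired MRI-vs-model
  area-averaged velocity curves, pooled ordinary least-squares regression
  with R² and p, noise bands and bias inspection.

A thin CLI (`aortaflow run --config config.json`) chains the stages into a
reproducible pipeline with a manifest; see `aortaflow --help`.

## Worked example: calibrating the four arch branches

```python
from aortaflow.outlet import OutletSpec, calibrate, AORTIC_ARCH_TARGETS

outlets = [OutletSpec(name=k, area=2e-4, target_fraction=v, xi=1.0)
           for k, v in AORTIC_ARCH_TARGETS.items()]
specs, state, log = calibrate(outlets, inlet_flow=0.3, rho=1060.0)
print(f"converged in {log.iterations} iterations")
for o, f, p in zip(specs, state.fractions, state.pressures):
    print(f"{o.name:22s} flow {100*f:7.3f}%   xi {o.xi:8.4f}   p_i {p:8.1f} Pa")
```

```
converged in 2 iterations
brachiocephalic        flow  15.789%   xi   2.5071   p_i     66.3 Pa
left_common_carotid    flow   7.895%   xi  10.0271   p_i     66.3 Pa
left_subclavian        flow   7.895%   xi  10.0271   p_i     66.3 Pa
descending_aorta       flow  68.421%   xi   0.1335   p_i     66.3 Pa
```

Starting from identical loss coefficients (a 25/25/25/25 split), the
feedback loop reaches the prescribed brachiocephalic / left-carotid /
left-subclavian / descending-aorta split of 15.789 / 7.895 / 7.895 /
68.42 % of inlet flow in two iterations. The per-branch pressures `p_i`
(equal here because all branches share one far-field pressure and the
junction is common) are what a 3D solver would receive as its outlet
boundary condition at this time step; `schedule_calibration` repeats the
process for every step of a pulsatile inlet-flow series, warm-starting
from the previous coefficients.

## Scope

The package deliberately stops at the solver boundary: no 3D RANS solve,
mesh generation, image segmentation or wall-shear analysis. Turbulence
fields (k, eddy viscosity) are treated as upstream inputs where metrics
need them. See `docs/methods.md` for the models, assumptions, parameter
defaults and known limitations.
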