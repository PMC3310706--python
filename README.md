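# hemowave

Poroelastic spatiotemporal hemodynamic modelling for high-resolution fMRI:
simulate BOLD responses that travel as damped waves across the cortical
sheet, and estimate the wave parameters back from flat-map data.

## The problem

Most fMRI analyses treat the BOLD response as space–time separable: a
temporal hemodynamic response function (HRF) convolved voxel-wise with the
neural signal, times a static Gaussian spatial kernel. That assumption
erases a whole class of dynamics. When cortical tissue is modelled as a
poroelastic medium — blood vessels as elastic pores threading the tissue —
a local increase in arterial inflow raises blood mass and pressure, and the
pressure perturbation propagates outward as a **damped traveling wave**. At
sub-millimeter voxel sizes and sub-second sampling, these waves are
measurable: on flattened visual cortex a thin line stimulus produces BOLD
activity that spreads several millimeters at a few mm/s before damping out.

`hemowave` implements the linearized model, its spatiotemporal hemodynamic
response function (stHRF), a synthetic flat-map experiment generator, and
the full empirical pipeline that detects the waves and regresses out their
parameters. It is aimed at researchers studying spatiotemporal BOLD
dynamics, and at pipeline developers who need a forward model plus a
validated parameter-recovery harness.

## The model

Five linear stages connect neural activity z(**r**, t) to the BOLD signal:

1. **Inflow** F: a damped harmonic oscillator driven by z (signal decay
   rate κ, elimination constant γ), normalized to unit DC gain.
2. **Blood mass** ξ: conservation of mass with inflow source and
   pressure-driven venous outflow.
3. **Momentum**: blood accelerates down pressure gradients, resisted by
   viscosity D.
4. **Constitutive law**: P = c₂ ξ^β, with 1/β the Grubb exponent
   (vessel elasticity).
5. **dHb** Q: oxygen conversion (ψξ − Q)η and outflow washout; **BOLD**:
   y = V₀[k₁(1−q) + k₂(1−q/v) + k₃(1−v)], linearized.

Eliminating P and **v** from stages 2–4 gives a damped wave equation for
the blood-mass perturbation,

    (∂t + D/ρ_f)(∂t + β/τ) ξ − v_β² ∇²ξ = (∂t + D/ρ_f) F,

with **damping rate** 2Γ = β/τ + D/ρ_f (outflow + viscosity) and
**propagation speed** v_β² = c₁c₂β ξ₀^(β−1). Γ and v_β are the two
measurable wave parameters; their ratio K = Γ/v_β (mm⁻¹) is the spatial
decay constant. At k = 0 the model reduces to the classical balloon model.
Responses are computed spectrally (transfer functions T_Lz(k, ω) for
L ∈ {F, ξ, Q, y}) and cross-checked against an explicit finite-difference
integrator.

The estimation pipeline mirrors the empirical procedure for line-stimulus
experiments: zero-phase Butterworth low-pass (0.1 Hz), stimulus-driven
voxel masks (normalized Fourier power > 0.40, coherence > 0.4), AIC-selected
polynomial centerline, isoeccentric averaging to y(x, t), temporal Hilbert
transform for instantaneous phase, phase-front tracking through the central
peak, and straight-line / log-linear regressions yielding v, Γ_t, K, and the
response FWHM with 1-s.d. uncertainties.

## Worked example

Simulate a noiseless session with wave speed 2.3 mm/s and damping
0.86 s⁻¹ (a subject-level parameterization), then recover the parameters:

```python
from hemowave import BoldWaveModel, ReducedWaveParams, NoiseSpec

model = BoldWaveModel.simulate(
    ReducedWaveParams(v_beta=2.3, Gamma=0.86),
    noise=NoiseSpec(white_sd=0.0, ar1_coefficient=0.0, drift_amplitude=0.0))
res = model.fit()
print(res.summary())
```

```
BOLD traveling-wave estimates
==============================================
analysis frequency f0: 0.0511 Hz
centerline polynomial order: 0

parameter     estimate    1 s.d.  unit
----------------------------------------------
v_F              2.323     0.010  mm/s
Gamma_F         -0.872     0.005  1/s
K_F              0.376     0.001  1/mm
v_P              2.323     0.010  mm/s
Gamma_P         -0.872     0.005  1/s
K_P              0.376     0.001  1/mm
FWHM              5.02            mm
consistency F: |Gamma_t| = 0.872 vs K*v = 0.872
consistency P: |Gamma_t| = 0.872 vs K*v = 0.872

ground-truth comparison (relative errors)
  F: v +1.0%, Gamma +1.4%, K +0.4%
  P: v +1.0%, Gamma +1.4%, K +0.4%
```

`v_F`/`v_P` are the wave speeds fitted on the two sides of the stimulus
centerline (toward the fovea / periphery on a real flat map), `Gamma_*` the
signed temporal decay of amplitude along the phase front, `K_*` the spatial
decay per mm, and FWHM the width of the response envelope. The internal
consistency |Γ_t| = K·v is the signature of nondispersive damped-wave
propagation. With the default measurement noise (peak SNR ≈ 4) the same
recovery is unbiased to within a typical ~7% median error.

The same runs are available from the shell:

```bash
hemowave recover --config config.yaml --out out/   # simulate + analyze + compare
hemowave sweep   --config config.yaml --out out/   # (v_beta, Gamma) gallery
hemowave analyze data.nii.gz --out out/            # external flat-map data
```

where `config.yaml` holds sections `model`, `grid`, `stimulus`, `noise`,
`analysis`, `sweep` (all optional; defaults reproduce the study's line
stimulus: σ = 1 mm Gaussian line, 8 s on / 12.25 s off, 8 blocks, 0.75 mm /
250 ms sampling).

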