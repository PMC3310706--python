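# Methods

This note documents the model, the numerical choices, and the design
decisions behind `hemowave`, in the spirit of a model card: what is
computed, under which assumptions, and what the validation does and does
not demonstrate.

## Linearized poroelastic hemodynamics

Cortical tissue is treated as a poroelastic medium whose pores are the
vasculature. The state variables on the 2-D cortical sheet are arterial
inflow F(**r**, t), blood mass density in tissue ξ, blood velocity **v**,
pore pressure P, and deoxyhemoglobin (dHb) concentration Q; the measured
quantity is the BOLD signal y in percent signal change. The governing
equations are (i) a damped-oscillator flow response to neural drive z,
(ii) blood-mass conservation with inflow source and pressure-proportional
venous outflow c_P·P, (iii) momentum conservation with viscous resistance D
and pressure-gradient coupling c₁, (iv) the constitutive law P = c₂ξ^β
(1/β = Grubb exponent), (v) dHb conservation with oxygen-conversion source
(ψξ − Q)η and outflow washout, and (vi) a semi-empirical BOLD observation
equation with coefficients (k₁, k₂, k₃) and resting volume fraction V₀.

All computations use the linearization about the resting state; amplitudes
scale out exactly, so "weak stimulus" is an interpretive contract rather
than a numerical one.

### The wave operator

Eliminating P and **v** from (ii)–(iv) yields, in fractional variables,

    (∂t + a)(∂t + b) ξ̃ − v_β² ∇²ξ̃ = a_F (∂t + a) f,     a = D/ρ_f,  b = β/τ,

verified symbolically in the test suite (sympy derivation against the
implementation's closed forms). Hence

* damping rate: 2Γ = a + b = β/τ + D/ρ_f,
* speed: v_β² = c₁c₂β ξ₀^(β−1),
* k = 0 limit: (∂t + β/τ)ξ̃ = a_F f — the balloon-model volume relaxation.

The product term a·b is retained in all transfer functions: it is what
keeps the response finite at DC and reproduces the balloon limit. The ideal
damped-wave dispersion relation (roots ω = −iΓ ± sqrt(v_β²k² − Γ²), the
a·b → 0 form) is exposed separately by `dispersion()`, since it is the
standard reduced description of the traveling-wave component.

### The symmetric damping split

A dataset parameterized only by (v_β, Γ) does not identify the two damping
channels separately. `HemoParams.from_reduced` uses the symmetric split
a = b = Γ (i.e. τ = β/Γ, D = ρ_f Γ). This choice is not arbitrary: with
a = b = Γ the operator factorizes as (∂t + Γ)² − v_β²∇², whose solutions
are exactly translating, exponentially damped waves (substituting
ξ = e^(−Γt) u reduces it to the pure wave equation). Phase speed is v_β and
the spatial decay is Γ/v_β at *every* frequency — the nondispersive
structure implied by the empirical identity Γ = K·v. Asymmetric splits
introduce mild dispersion at analysis frequencies; the symmetric split is
the maximally consistent representative.

### Drive gain a_F

The flow stage has unit DC gain; a_F is the calibrated amplitude of the
flow perturbation per unit neural drive. It multiplies f everywhere f
enters the linear system (wave drive and the direct dHb dilution term), so
the full response is exactly proportional to a_F and calibration never
changes the response shape. `calibrate_drive_gain` fixes a_F so the central
peak response to the default line stimulus is 0.4% signal change, anchoring
amplitude to the observed response scale.

### dHb stage

Linearizing (v) with the resting balance (ψξ₀ − Q₀)η = Q₀/τ gives

    (∂t + η + 1/τ) q̃ = [η + 1/τ − (β−1)/τ] ξ̃ + V₀(∂t + β/τ) ξ̃ − a_F (V₀/τ) f,

with q̃ = Q₁/Q₀, ξ̃ = ξ₁/ξ₀. The −(β−1)/τ term is pressure-driven washout
(volume raises outflow faster than it dilutes dHb); the f term is dilution
by fully oxygenated arterial inflow and produces the early dHb dip. Q₀ may
be left unset, in which case it is derived from the resting balance.

## Default parameters

Temporal constants follow standard balloon-model values; poroelastic
constants are chosen so the derived reduced parameters sit at v_β = 3 mm/s,
Γ = 0.8 s⁻¹ — the middle of the empirically observed group ranges
(v ≈ 4 ± 2 mm/s, Γ ≈ 0.8 ± 0.2 s⁻¹).

| parameter | default | units | role |
|---|---|---|---|
| κ | 0.65 | 1/s | flow signal decay |
| γ | 0.41 | 1/s² | flow elimination |
| τ | 2.5 | s | mean transit time (ξ₀/F₀) |
| β | 1/0.38 ≈ 2.63 | – | reciprocal Grubb exponent |
| D/ρ_f | 0.547 | 1/s | viscous damping rate |
| ρ_f | 1050 | kg/m³ | blood density |
| ξ₀ | 31.5 | kg/m³ | resting blood mass (V₀ρ_f) |
| P₀ | 1500 | Pa | resting pore pressure (sets c₂) |
| η | 0.15 | 1/s | oxygen transfer rate |
| ψ | 2.2 | mmol/kg | hemoglobin per unit blood mass |
| V₀, k₁, k₂, k₃ | 0.03, 2.8, 2.0, 0.6 | – | BOLD observation |

η = 0.15 s⁻¹ keeps the dHb washout dominant over conversion during
activation (positive BOLD with an early dip and post-stimulus undershoot)
across the physiological (τ, β) range; larger η moves the model toward
volume-tracking dHb and weakens the BOLD response. All defaults are
config-overridable and echoed, with the derived (Γ, v_β), into every run
report.

## Numerics

**Spectral solver.** Responses are inverse FFTs of T_yz(k, ω)·ẑ(k, ω) on a
zero-padded periodic box. Spatial padding is 7·v_β/Γ mm (wrap-around below
e⁻⁷ ≈ 10⁻³ of edge amplitude, capped at 4× the box for extreme parameter
corners); temporal padding covers the slowest settling rate to 10⁻⁵. With
`pad=False` the solver works on the grid's own periodic box, the
configuration comparable with the oracle. Impulse (non-band-limited) drives
carry an acausal ripple at the temporal aliasing level |T(ω_Nyquist)|
(~2·10⁻³ of peak at 250 ms sampling); band-limited drives are causal to
much tighter tolerance.

**Finite-difference oracle.** The same linear system integrated as a
first-order ODE system: classical RK4 with 8 sub-steps per sample, 4th-order
periodic Laplacian, drive band-limited-interpolated to sub-step resolution.
The grid must satisfy dt ≤ dx/v_β (explicit stability contract; violations
raise with a suggested dt). On 32×128 and 64×256 (x, t) grids the two
solvers agree within 10⁻³ relative L2; the remaining gap is dominated by
the finite-difference Laplacian error, as confirmed by sub-step halving.

**2-D line sources.** For curved centerlines the generator extends the line
~5 spatial e-foldings beyond the requested box before simulating and crops
afterwards, so edge voxels see an effectively infinite line (as in the
experiment, where the isoeccentric line continues across the flat map).

## Synthetic experiment generator

The generator emulates the V1 line-stimulus protocol on a flat 2-D sheet:
a Gaussian line source (σ = 1 mm) under a block design (8 s on / 12.25 s
off, 8 blocks, 14 s lead-in; 176 s session), sampled at 0.75 mm / 250 ms
over a 21.75 × 24.75 mm map. The 20.25 s block period is the fractional-TR
design: onsets shift by 250 ms per block against a 2 s TR grid, which is
how the experiment reached 250 ms effective sampling; the generator samples
natively at 250 ms and records `dephase_step` as provenance. The block
fundamental is 1/20.25 ≈ 0.049 Hz; because the 176 s window holds a
non-integer number of cycles, the empirical peak-power bin lands at
~0.051 Hz, and the analysis always uses the detected peak bin rather than a
nominal frequency.

Noise is AR(1) (innovation sd `white_sd`, coefficient 0.3) plus white
innovations and a random low-order Legendre drift, per voxel, seeded.
Defaults give peak SNR ≈ 4 (0.4% response vs ~0.1% noise sd), matching the
visibly smooth averages of the motivating data. The generator does **not**
emulate scanner physics (motion, distortion, spatially correlated noise,
draining veins) or 3-D folded anatomy; passing recovery tests therefore
demonstrates estimator correctness under the stated noise model, not
robustness to every artifact of real acquisitions.

## Estimation pipeline choices

* **Zero-phase filtering** everywhere (forward–backward Butterworth):
  one-pass filtering would bias front timing, which is the measurement.
* **Masks**: normalized Fourier power > 0.40 at the peak bin and magnitude
  coherence > 0.4 with the stimulus reference (block design convolved with
  a canonical double-gamma HRF; Welch estimate, 64-sample segments). The
  experiment additionally used a retinotopic spatial prior to restrict
  candidate voxels to the stimulus locus; the flat-map analogue is a
  response-ridge criterion (voxels within half of the maximum amplitude).
  On noiseless data power and coherence saturate everywhere and the ridge
  carries the localization alone.
* **Centerline**: least-squares polynomials of order 0–5, AIC =
  n·ln(RSS/n) + 2(order+2), tie-break toward the smallest order within
  ΔAIC < 2 (numerically-zero residuals are clamped to a common floor so
  exact fits of different orders tie). Near-vertical geometries are fit
  with axes swapped and flagged.
* **Averaging**: signed perpendicular distance to the centerline (dense
  curve sampling + nearest-neighbor query), binned at the voxel pitch;
  empty bins are missing, not zero; positive x is the configured fovea-ward
  side.
* **Phase**: 2nd-order zero-phase band-pass of half-width 0.5·f₀, analytic
  signal, per-x unwrapping. Rows are masked below 10% of the central peak
  envelope or below 3× the spectral noise floor at f₀ (phase jitter at the
  analysis frequency converts to large time jitter, ~1/(SNR·2πf₀)).
* **Fronts**: the constant-phase trajectory through the central peak,
  tracked outward from the 1 mm exclusion radius by nearest-crossing
  continuity. Leading points whose step time is below 0.75× the median step
  are trimmed (fronts are nearly stationary inside the local region; the
  straight-line fits address the propagating region). Isolated crossing-time
  outliers are screened against a straight-line front (3× robust sd, floor
  2·dt). Fewer than 4 points, or a systematically non-advancing front,
  yields the verdict "no detectable propagation" instead of a fit.
* **Regressions**: OLS of t on |x| (x is the controlled variable), v =
  1/slope with delta-method sd; log-amplitude vs t over the propagating
  front (signed Γ_t) and vs |x| (K). By default the spatial fit uses the
  same points as the temporal fit, which makes |Γ_t| = K·v an internal
  identity of the estimator; a fixed window (e.g. 1 mm < |x| ≤ 5 mm, as in
  the empirical spatial-decay fits) can be configured instead. The
  |Γ_t| vs K·v comparison is reported and flagged when violated by >3 s.d.

## Validation scope and problem sizes

The recovery harness runs the full pipeline on generated sessions
(29×33×704 voxels; 1-D fast path for straight centerlines, full 2-D
spectral solves for curved ones; a 4-block session for the curved fixture).
Noiseless recovery over v_β ∈ {1.5, 3, 6} mm/s × Γ ∈ {0.4, 0.8, 1.2} s⁻¹ is
accurate to a few percent except at (v_β, Γ) = (1.5, 1.2): there K =
0.8 mm⁻¹ confines the usable front to ≲4 samples at the 0.75 mm pitch and
estimates are pitch-limited (speed error ~16%) or flagged — the regime the
model itself predicts to be undetectable. With default noise, 20 seeds per
cell give a pooled median absolute recovery error of ~7%, with occasional
"no detectable propagation" verdicts concentrated in the strong-damping
cells.

## Known limitations

* Flat 2-D geometry only; no cortical folding, no surface reconstruction.
* Linear regime only; strong stimuli engage the nonlinear poroelastic
  terms that are outside this package's scope.
* The two damping channels (viscous vs outflow) are reported only through
  their sum 2Γ when fitting data; separating them needs interventions the
  model can simulate but the estimator cannot identify.
* The estimator's near-field is contaminated within ~2–3 source widths of
  the centerline; with very small K the residual curvature biases
  fixed-window spatial fits by a few percent.
* The noise model is temporally colored but spatially independent;
  spatially structured physiological noise is not emulated.
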