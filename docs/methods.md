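# Methods

`shortqt` simulates the ventricular phenotype of the KCNQ1 S140G
gain-of-function substitution across four scales: single myocyte, 1D/2D
tissue, rotor/frequency analysis, and a lumped electromechanical pump.
This note records the models, the parameters that matter, the numerical
choices, and what the desk-scale geometry can and cannot show.

## Myocyte electrophysiology

The membrane model is the 2006 ten Tusscher–Panfilov human ventricular
formulation: twelve membrane currents (I_Na, I_CaL, I_to, I_Kr, I_Ks,
I_K1, I_NaCa, I_NaK, I_pCa, I_pK, I_bCa, I_bNa), a CICR calcium subsystem
with a dyadic subspace and a load-sensitive ryanodine-receptor open
probability, and rapid-equilibrium Ca buffering in cytosol, SR and
subspace.  The 2006 formulation is the base: the conductance set below
is native to it, and the 2004 calcium subsystem cannot reproduce the
long mid-myocardial action potential these conditions produce.

Transmural heterogeneity enters through two conductances (mS/µF):

| cell type | G_Ks        | G_to  |
|-----------|-------------|-------|
| endo      | 0.392 × 1.3 | 0.073 |
| M         | 0.098 × 2.0 | 0.294 |
| epi       | 0.392 × 1.3 | 0.294 |

The mutation adds a constitutively active, instantaneously gating
component to the slow delayed rectifier:

    I'_Ks = G_Ks · x_s² · (V − E_Ks)  +  φ · G_Ks · (V − E'_rev)

with expressivity φ = 0.1 (intermediate expression) and mutant reversal
potential E'_rev = −75.3 mV.  The x_s gate dynamics are untouched; its
initial value is 0.00357.  At φ = 0 the model is exactly the wild type.
E_Ks is computed from the Nernst relation at every step (a fixed value
would make I_Ks inward over most of the action potential, which the
current's physiology excludes).

Stimulus: −52 pA/pF for 1 ms (≈2× diastolic threshold; the protocol
convention for this model family).  Initial conditions are the published
1 Hz steady state, followed by 100 conditioning beats at the protocol BCL
before any reported metric; this is enough for the APD to settle to
<0.1 ms/beat under both conditions.

Integration: Rush–Larsen exponential updates for all Hodgkin–Huxley
gates, forward Euler for concentrations and the RyR recovery variable,
fixed dt = 0.02 ms.  Gate steady states/time constants and the
voltage-dependent current factors are tabulated on a 0.02 mV grid (with
the Rush–Larsen exponential baked in per dt) and linearly interpolated
inside compiled (numba) kernels; the inward-rectifier gate is tabulated
against V − E_K.  The tables are generated from the same rate functions
the pure-NumPy reference implementation uses, and a test asserts the two
paths agree step-for-step.  Halving dt changes APD90 by well under 1 ms.

### Measured conventions

* **APD90**: from the maximum-dV/dt fiducial to the linearly interpolated
  crossing of V_rest + 0.1·(V_peak − V_rest), with V_rest sampled just
  before the stimulus.  The mutant endo/epi AP has a slowly decaying foot
  between −60 and −75 mV, so its APD90 is sensitive to the fiducial
  convention: the same beats measured as "time above −30 mV" read ~25%
  shorter.  We keep the 90%-repolarization definition throughout.
* **Dynamic restitution**: after conditioning at BCL 1000 ms the BCL
  descends 1000→400 ms in 50 ms steps and 400→20 ms in 10 ms steps,
  30 beats per level, state carried across levels.  DI = BCL − previous
  APD; the maximum slope is the largest finite-difference dAPD/dDI over
  non-alternating captured levels.
* **Alternans onset**: largest BCL whose final four captured beats
  alternate by more than 5 ms beat-to-beat.  2:1 block levels never flag.
* **I_Ks summary**: sustained duration is the time the current exceeds 5%
  of its beat maximum; the mean is taken over that window.

## Myofilament force and ATP

Cross-bridge cycling follows the Rice mean-field myofilament model:
nonpermissive/permissive regulatory states N ↔ P, strongly bound
pre-/post-rotation states XB_PreR ↔ XB_PostR (rates f_app = 0.5,
g_app = 0.07, h_f = 2.0, h_b = 0.4, g_xb = 0.07 ms⁻¹), mean-distortion
ODEs with strain-dependent h_f and g_xb, and two regulatory-troponin Ca
pools (k_on = 50 mM⁻¹ms⁻¹, k_off = 0.25/0.025 ms⁻¹) whose
overlap-weighted occupancy drives the steeply cooperative N→P switch
(exponent ±7.5 about a half-activation occupancy of 0.5).  The sarcomere
is held isometric at 2.0 µm, so the single-overlap factors are constants;
there is no shortening feedback and no viscoelastic branch.

Normalized force is SOVF_thick·(xXB_PreR·XB_PreR + xXB_PostR·XB_PostR) /
(x₀·XB_PostR_max) with x₀ = 7 nm and XB_PostR_max the optimal-condition
occupancy.  Contractile ATP consumption is the beat integral of the
detachment flux g_xbT·XB_PostR divided by the beat length (one ATP per
detachment); only wild-type/mutant orderings of this rate are meaningful,
not its absolute value.  The ODEs are integrated with LSODA driven by an
interpolated periodic Ca transient, three beats to a cyclic steady state.

## Tissue: monodomain conduction

The monodomain model adds diffusive coupling,
D = 1/(ρ·S·C_m) per axis, with surface-to-volume ratio S = 2000 cm⁻¹,
C_m = 1 µF/cm² and axial resistivity ρ as the calibration knob (default
0.3247 kΩ·cm, D ≈ 1.54·10⁻³ cm²/ms).  Each step is operator-split:
reaction (the cell kernel) then second-order central-difference diffusion
with a zero-gradient ghost node at the boundary, which makes the no-flux
scheme strictly conservative.  dt = 0.02 ms everywhere.

Geometries (all synthetic, generated by `shortqt.geometry`):

* **Transmural cable**, 2.0 cm, dx = 0.02 cm, contiguous endo:M:epi
  blocks of 0.45:0.25:0.30 (fractions chosen to keep a substantial
  M-band driving the repolarization gradient).
* **Sheet**, 6.4 × 6.4 cm, dx = 0.05 cm, uniform epicardial tissue by
  default (see limitations), CV anisotropy 1.5 via ρ_y = ρ_x·1.5².
  dx = 0.05 cm keeps a full re-entry episode tractable on one CPU; CV is
  re-calibrated at this spacing, so the target velocities are exact by
  construction and the solver's grid convergence is verified separately
  in its asymptotic range.

Sinus-like activation of the cable is emulated by stimulating the
endocardial end (the Purkinje system's ~100 cm/s ≫ myocardial CV); the
stimulated strip is at least 0.15 cm wide so capture survives high
diffusivity.  Conduction velocity is measured from the −30 mV activation
times at the 25% and 75% positions; calibration bisects ρ (seeded by
CV ∝ √(1/ρ)) until the measured CV is within 2% of target.  EAT/EDT maps
are the first −30 mV upstroke and last −75 mV downstroke, linearly
interpolated, both online in the solver and from recorded fields.
Conduction wavelength is CV·APD90 with APD90 at the cable midpoint.

**S1–S2 cross-field induction** (sheet): three planar S1 from the left
edge at 600 ms intervals; the S2 depolarizes the lower-left quadrant at
the first instant the entire left half has repolarized below −75 mV
(the wave-tail timing rule), which places the S2 edge against the
refractory tail of the third wave.  An episode is *terminated* when every
node stays below −70 mV for a contiguous 100 ms after the S2 (the solver
also stops early then); otherwise it is *sustained*.  A low-CV variant
(induce at 20 cm/s, checkpoint the full cellular state, restart at
70 cm/s) is provided for state-transfer experiments.

## Rotor and frequency analysis

Per-node dominant frequency: mean-detrended periodogram of the final 3 s
of the episode sampled at 100 Hz, zero-padded to 2¹⁴ points (bin
≈ 0.006 Hz), argmax above a 0.5 Hz drift cutoff, computed in node chunks
to bound memory.  Rotation rate: upward −30 mV crossings at a fixed
probe divided by the window length.  On periodic fixtures the DF matches
the fundamental to within one natural frequency bin (1/3 Hz for a 3 s
window).

## Pump and circulation

The ventricles are time-varying-compliance chambers,

    P = (V − V_rest(y_v)) / C(y_v),
    C(y_v) = y_v (C_act − C_pass) + C_pass,
    V_rest(y_v) = (1 − y_v) V_rest,d + y_v V_rest,s,

where activation y_v(t) ∈ [0,1] is the transmurally weighted
(0.45/0.25/0.30) myofilament force of the three cell types at BCL 600 ms,
peak-normalized to the wild-type beat.  Activation *stiffens* the
chamber, so C_act < C_pass.  The closed
loop has eight compartments — LV, systemic artery/vein, RA, RV, pulmonary
artery/vein, LA — joined by resistances with ideal-diode valves (mitral,
aortic, tricuspid, pulmonary).  The atria are passive compliance
compartments, a standard Windkessel closure without atrial contraction.
Parameters are standard human lumped values,
integrated with forward Euler at dt = 0.5 ms; total blood volume is
conserved identically by construction.

The left ventricle's C_pass and C_act are calibrated once (fixed-point
iteration) so the wild-type beat reproduces stroke volume ≈ 58.6 mL and
ejection fraction ≈ 54.2%; the mutant run changes only the cellular
inputs.  Metrics: EDV/ESV/SV from the last cycle, stroke work as the
pressure–volume loop (shoelace) area, efficiency = stroke work / ATP per
beat.

The exponential transversely isotropic strain-energy law
W = (C/2)(e^Q − 1), Q = b₁E_ff² + b₂(E_rr² + E_cc² + 2E_rc²) +
2b₃(E_fr² + E_fc²) (C = 2 kPa, b₁ = 8, b₂ = 2, b₃ = 4; every quadratic
term enters Q with positive sign, so W is positive-definite about the
reference) and the Green–Lagrange strain E = ½(FᵀF − I) are
provided as evaluatable material functions; they are not coupled into the
lumped pump.

## What the desk scale shows — and does not

The synthetic geometry replaces an image-based 3D biventricular mesh with
Purkinje network and a finite-element mechanics model.  Consequences
observed with this code (all orderings below are computed by the tests
and analysis scripts, not asserted from literature):

* Single-cell WT APDs, the mutant M-cell APD, the calibrated CVs and
  the WT wavelength track the full-scale setting closely; the mutant
  endo/epi APD90 is the quantity most sensitive to the measurement
  convention — read as "time above −30 mV" instead of 90% repolarization
  it is ~25% shorter (see above).
* On the 6.4 cm sheet the mutant forms a single stable fast rotor while
  the wild-type S2 wave breaks up over its steep-restitution substrate
  into slower turbulence.  The mutant's mean DF and DF bandwidth exceed
  the wild-type's on matched geometry, but both rhythms are faster than
  in the 3D setting, and wild-type turbulence does not self-terminate
  within a 10 s horizon — in the full-size heterogeneous ventricle the
  long wild-type wavelength cannot be accommodated and activity dies out.
  Sheet-scale rotor frequencies should therefore be read as
  qualitative.
* The pump inherits the mutant's severe desk-scale calcium deficit: the
  5×-shortened AP admits so little Ca per beat that the SR store drains
  (Ca_SR ~1.7 vs ~3.8 mM) and myofilament force collapses, where the 3D
  electromechanical setting shows only a mild contractile deficit.  EF,
  ATP rate and stroke work all fall under the mutation (correct
  direction, exaggerated magnitude); the subtle rightward loop shift and
  the efficiency gain of the full model are lost once the beat nearly
  vanishes.

## Problem sizes

Default problem sizes are chosen for a single CPU: 100-beat conditioning
per cell (~5·10⁶ steps), ~50-level restitution ladders, 100-node cables,
and one 128×128 sheet episode of 4.2 s per condition.  All simulations
are deterministic; the only randomness anywhere is in property-test
fixtures, which are seeded.
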