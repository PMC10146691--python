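# Methods

## The measurement principle

Two immiscible-looking laminar streams — a test fluid (typically blood) and
a reference fluid of known viscosity µ_r — flow side by side through a
shallow rectangular microchannel (depth h ≪ width w). The position of their
interface, expressed as the test-stream width fraction α ∈ (0, 1), encodes
the viscosity ratio. Driving the test stream with a square on/off pump
program turns a single recording into two measurements:

* **steady phase** (pump on): α settles and the test-fluid viscosity
  follows from the coflow viscometry law,
* **transient phase** (pump off): α relaxes as a sum of two exponentials
  whose decay rates encode two compliance coefficients — C₁ for the
  measurement hardware (flexible tubing + soft channel walls) and C₂ for
  the sample's elastic phase (red blood cells). Separating the two is the
  point of the method: a single lumped compliance confounds the instrument
  with the sample.

## Lumped-circuit model

The network is modelled with discrete fluidic elements. Each channel
segment of length l contributes a hydraulic resistance R = 12µl/(wh³)
(plane-Poiseuille limit, valid for aspect ratio h/w < 0.1; the constructor
warns when violated). The interface is treated as a virtual wall splitting
the coflow channel of length l₂ into two parallel resistors, R_r2 for the
reference stream (width (1−α)w) and R_b2 for the test stream (width αw).
An empirical correction factor CF(α) multiplies the test-stream conductance
to absorb the error of the virtual-wall idealization. Both inlets are ideal
flow sources — a series resistance on the reference branch therefore has
no dynamical effect and is not a model parameter. Compliances C₁ and C₂
(µm³/mPa) sit at the test-channel inlet node and at the junction node.

Units are µm / s / mPa·s throughout, so R·C products are seconds and
compliances are natively in the units in which they are reported for
microfluidic systems. Flow rates are entered in mL/h and converted
(1 mL/h = 1e12/3600 µm³/s).

Mass conservation at the two pressure nodes gives, with β = 1/(1−α) and
g(α) = α·CF(α)/(1−α), the exact second-order equation

    a₀β″ + b₀β′ + e₀·dg/dt + f₀·g(α) = Q_b/Q_r

with a₀ = R_b1R_r3C₁C₂, b₀ = R_r3(C₁+C₂), e₀ = R_r3C₁(l₁/l₂),
f₀ = µ_r/µ_b, and R_r3 the coflow-channel resistance at reference
viscosity. Its steady state is the viscometry law

    µ_b = µ_r · CF(α)·α/(1−α) · Q_r/Q_b.

Replacing CF(α) by a constant CF₀ linearizes the equation to
aβ″ + bβ′ + cβ = c + Q_b/Q_r with

    a = R_b1R_r3C₁C₂,  b = R_r3(C₁ + C₂ + C₁(l₁/l₂)CF₀),  c = (µ_r/µ_b)CF₀.

After switch-off (Q_b = 0) the solution is
β(t) = d₁e^{−λ₁t} + d₂e^{−λ₂t} + 1, where λ₁ ≥ λ₂ > 0 solve
aλ² − bλ + c = 0. The model is used only in its overdamped regime; a
negative discriminant raises, and a repeated root (discriminant ≈ 0 at
relative 1e-12) is rejected rather than handled with the t·e^{−λt} form,
because the method requires two distinguishable modes (C₁ ≪ C₂).

**Switch-off initial conditions.** The pressures stored on both compliances
are continuous at the switch, which implies β(0⁺) = β_steady and
β′(0⁺) = 0, hence d₁ = −λ₂(β₀−1)/(λ₁−λ₂), d₂ = λ₁(β₀−1)/(λ₁−λ₂). The
same continuity argument makes (α, α′) continuous across every pump
switch, which is how the nonlinear integrator chains program segments.

## Correction factor

CF is calibrated with a test fluid of known viscosity via
CF = (µ_t/µ_r)·(1−α_t)/α_t·(Q_t/Q_r) and fitted as a low-order polynomial
in α per channel depth. The package ships the stock polynomials and their
CF₀ constants for h = 4, 10, 20 µm as authoritative calibration constants
(degrees 3, 2, 5; CF₀ = 1.637, 1.41, 1.183). CF₀ is defined as the
weighted mean of CF(α) with weight α/(1−α); `cf0_constant` recomputes it on
a uniform α grid over [0.1, 0.9] (step 0.01, the stated viscometry validity
range), but the exact averaging set behind the shipped constants is part of
the original calibration campaign and a uniform-grid recomputation of the
h = 20 µm model gives ≈ 1.13, near but not equal to the shipped 1.183.
Recomputation therefore never silently overrides the shipped values.

## Inverse pipeline

Per on/off cycle:

1. **Steady window** — the first 70 s after switch-on are discarded
   (settling) and the last n = 50 samples before switch-off are averaged.
2. **Viscosity** — the viscometry law with the full polynomial CF(α̅).
3. **Transient fit** — (β−1) against d₁e^{−λ₁t} + d₂e^{−λ₂t}, re-zeroed at
   the switch-off instant. Initialization by exponential peeling (tail
   log-linear fit for λ₂, early-residual fit for λ₁) plus a
   variable-projection multi-start over a log-spaced rate grid; every
   available start is refined by Levenberg–Marquardt and the lowest-SSE
   admissible (positive-rate) solution wins, which guards against a
   shallow local minimum with coincident rates. Amplitudes are
   unconstrained in sign. Because the observation noise lives on α and
   Var(β) = β⁴·Var(α), residuals are weighted by 1/β² by default (the
   homoscedastic-in-α maximum-likelihood weighting); the unweighted
   β-space fit is available with `weighting="none"`.
4. **Compliance inversion** — with S = λ₁+λ₂, P = λ₁λ₂,
   k = 1 + (l₁/l₂)CF₀ and the cycle's own µ_b estimate, Π ≡ C₁C₂ and
   Σ ≡ kC₁+C₂ follow from the sum/product relations and C₁ solves
   kC₁² − ΣC₁ + Π = 0, choosing the root with C₁ < C₂.

Cycles are fitted independently and reported as mean ± sd with no outlier
rejection.

**Identifiability.** The quadratic factors as (C₁−C₁*)(kC₁−C₂*): the
companion root of the true pair is (C₂*/k, kC₁*), which also satisfies the
ordering when C₂* < k²C₁* (k² ≈ 8.1 for the stock h = 20 µm setup). Inside
that band the system is genuinely ambiguous given only (λ₁, λ₂, µ_b); the
smaller-C₁ root is returned and both candidates appear in the diagnostics.
Measured compliance ratios (C₂/C₁ ≈ 10–20) sit comfortably in the unique
regime. `complete_parameter_set` generalizes the inversion: given the two
rates and any one of {µ_b, C₁, C₂} it solves for the remaining two (each
case reduces to a quadratic; for a known C₂ the only failure mode is a
negative discriminant, reached when S²/P < 4(1 + l₂/(l₁CF₀))).

The fast rate λ₁ is intrinsically the fragile quantity: its mode amplitude
is small (|d₁|/d₂ = λ₂/λ₁ ≈ 0.06 for switch-off from steady state), so C₁
carries far more statistical uncertainty than C₂ at any given noise level.
The recovery suite quantifies this honestly rather than hiding it.

## Numerical choices

* Nonlinear ODE: `scipy.integrate.solve_ivp` with LSODA (the two
  well-separated rates make the system mildly stiff), rtol 1e-8,
  atol 1e-10, state (α, α′), dense output sampled on the program grid,
  terminal event at the CF validity bounds (series truncated and flagged).
* Steady interface: bracketed Brent root finding on a 400-point scan of
  the validity range; multiple sign changes raise with all roots listed.
* Transient fit: `scipy.optimize.least_squares` (LM), xtol 1e-8,
  ftol/gtol 1e-14, ≤ 4000 function evaluations; canonical ordering
  λ₁ ≥ λ₂; fits with any non-positive rate are rejected; near-equal rates
  or |d₁| < 1e-6·(|d₁|+|d₂|) flag the result degenerate.
* CF polynomial fits in the natural (unscaled) basis so coefficients are
  comparable with published calibrations; rank deficiency raises.

## Synthetic experiments

`GroundTruth`/`simulate_measurement` emulate the stock protocol: square
program Q₀ = Q_r = 1 mL/h, period T = 240 s with equal on/off halves,
0.5 s sampling, one cycle by default, started from the on-phase steady
state. Observation noise is additive Gaussian on α with σ_α = 0.005
(≈ 1 px at the 150 px channel width — the quantization floor of the
imaging chain), clipped to (0.001, 0.999); a single global seed spawns
independent sub-streams for noise and frame rendering, so runs are
bit-reproducible.

The generator's default CF model is the **constant-CF₀ (linearized)**
model for the configured depth. This is deliberate: the compliance
coefficients are defined through the linearized eigenvalue relations, so a
self-consistent ground truth must generate from the same dynamics.
Generating from the full polynomial CF instead (pass
`cf_model=builtin_cf_model(h)`) produces a transient that is not exactly
two-exponential; the mismatch is small in β but concentrates in the
small-amplitude fast mode and shifts the fitted λ₁ far more than its share
— a real limitation of the linearized readout that the test suite
documents (the polynomial-CF turn-off is asserted to be a bounded,
monotone decay, not to reproduce λ₁).

What passing tests do show: the algebra and its inversion are exact, the
integrator agrees with the analytic solution, and the full pipeline is
unbiased with correctly seeded noise of realistic size. What they cannot
show: behavior under pump ramps, shear-thinning or hematocrit-dependent
rheology, illumination drift, or cell-scale image texture, none of which
the generator emulates.

`parameter_recovery_suite` draws truths (C₁ log-uniform 10–200, C₂
log-uniform 500–5000 µm³/mPa, µ_b uniform 1–4 mPa·s), shares the same
truths and the same scaled noise realizations across noise levels (common
random numbers), and tabulates relative bias/RMSE per parameter; failed
fits are counted, not dropped silently.

## Imaging

Frames are binarized with a global Otsu threshold (256-bin histogram of
the ROI); blood is the darker phase under bright-field (configurable
polarity). The blood-filled width is the per-column count of foreground
pixels (robust to speckle, which is flagged via a wall-contiguity check),
averaged along the ROI and divided by the channel width in pixels. Stock
optics: 1.67 µm/px, 250 µm width → 150 px, 330 µm ROI length → 198
columns; ROI bounds are 0-based half-open row/column indices. The
synthetic renderer places the interface with sub-pixel area weighting,
then applies Gaussian blur (σ = 1 px) and additive Gaussian noise (σ = 5
gray levels of a 40/200 dark/light contrast); extraction bias across
α ∈ [0.2, 0.8] is below one pixel-width equivalent (< 0.007).

## Known limitations

* The shear-rate helper implements γ̇ = 6Q/(wh²) with the full channel
  width; published ranges for this device type imply a smaller effective
  width, so absolute shear rates should be taken as indicative.
* Printed steady viscosities for real blood are not exactly reproduced by
  inserting printed mean interfaces into the viscometry law with the
  shipped polynomials (per-run calibration and flow details differ); the
  package asserts the algebraic law, not those endpoints.
* No cell-free-layer (Fåhraeus) correction, no non-Newtonian constitutive
  law, no 3D duct hydrodynamics — all outside the lumped model's scope.
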