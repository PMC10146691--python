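# coflow — two-compliance coflow viscoelastometry

`coflow` implements a microfluidic method for measuring blood
viscoelasticity from a single co-flowing-stream recording. Blood and a
reference fluid (e.g. 1× PBS, viscosity µ_r) run side by side through a
shallow rectangular channel; the fraction of the channel width occupied by
blood, α, is the only observable. Driving the blood stream with a square
on/off pump program (amplitude Q₀, period T) yields:

* **viscosity** from the steady interface: µ_b = µ_r · CF(α)·α/(1−α) · Q_r/Q_b,
  where CF(α) is an empirically calibrated correction factor;
* **two compliance coefficients** from the switch-off transient: in
  β = 1/(1−α) coordinates the relaxation is
  β(t) = d₁e^{−λ₁t} + d₂e^{−λ₂t} + 1, and the decay rates satisfy

      λ₁ + λ₂ = (C₁ + C₂ + C₁·(l₁/l₂)·CF₀) / (R_b1·C₁·C₂)
      λ₁ · λ₂ = (µ_r/µ_b)·CF₀ / (R_b1·R_r3·C₁·C₂)

  with R = 12µl/(wh³) the shallow-channel resistances. Solving the pair
  for (C₁, C₂) separates the compliance of the measurement hardware
  (tubing + soft channel walls, C₁) from that of the red-blood-cell phase
  (C₂) — the quantity of hemorheological interest.

The package contains the forward lumped-circuit model (including the full
nonlinear interface ODE), the correction-factor calibration tools, the
inverse pipeline, an Otsu-threshold imaging chain that turns microscope
frame stacks into interface time series, and a seeded synthetic-experiment
generator for validating every inference stage against known ground truth.
It is aimed at microfluidics/hemorheology researchers running coflow
viscometers and at anyone studying two-mode lumped models of soft fluidic
networks.

## Worked example

Simulate one on/off cycle (Q₀ = Q_r = 1 mL/h, T = 240 s, 0.5 s sampling,
h = 20 µm device) for a sample with µ_b = 2.2 mPa·s, C₁ = 50 and
C₂ = 1400 µm³/mPa under pixel-scale interface noise, then run the full
inverse pipeline:

```python
import coflow as cf

truth = cf.GroundTruth(mu_b=2.2, C1=50.0, C2=1400.0,
                       sigma_alpha=0.005, seed=7)
series = cf.simulate_measurement(truth)
result = cf.analyze_experiment(series, truth.analysis_setup())

print(f"mu_b = {result.mu_b:.3f} mPa·s")
print(f"C1   = {result.C1:.1f} µm³/mPa")
print(f"C2   = {result.C2:.1f} µm³/mPa")
fit = result.cycles[0].eigenfit
print(f"lambda1 = {fit.lambda1:.4f} 1/s, lambda2 = {fit.lambda2:.5f} 1/s")
```

prints

```
mu_b = 2.194 mPa·s
C1   = 50.8 µm³/mPa
C2   = 1401.9 µm³/mPa
lambda1 = 0.2072 1/s, lambda2 = 0.01286 1/s
```

The steady window (last 50 samples before switch-off, after a 70 s
settling exclusion) recovers the viscosity to 0.3%; the two-exponential
fit of the off-phase pins the slow rate λ₂ — and with it C₂ — to a
fraction of a percent, while the fast rate λ₁ (small mode amplitude
|d₁|/d₂ = λ₂/λ₁ ≈ 0.06) carries most of the statistical uncertainty,
here leaving C₁ within 2% of truth. See `docs/methods.md` for the model,
its assumptions and the estimator choices.

The same pipeline is scriptable from the shell:

```sh
coflow simulate --truth truth.yaml --out series.csv
coflow extract  --stack frames.tif --dt 0.5 --out series.csv
coflow fit      --series series.csv --config cfg.yaml --out result.json
```

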