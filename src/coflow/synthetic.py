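"""In-silico coflow experiments with known ground truth.

The generator reproduces the study protocol: a square on/off test-fluid
program (amplitude 1 mL/h, period 240 s, equal on/off halves) against a
constant 1 mL/h reference flow, sampled every 0.5 s. The interface
trajectory comes from the full nonlinear circuit model (polynomial CF), and
observation noise is additive Gaussian on α with sd σ_α = 0.005 by default
— about one pixel at the 150 px channel width, i.e. the quantization floor
of the imaging chain. Frames can optionally be rendered for every sample to
exercise the extraction pipeline end to end.

What this emulates: pump-driven square-wave forcing, the two-mode
viscoelastic relaxation, and pixel-scale measurement noise. What it does
not: pump ramp dynamics, shear-thinning or hematocrit-dependent rheology,
illumination drift, or cell-scale image texture — condition metadata
(hematocrit, fixative concentration, tubing length, ...) is carried as
labels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import CorrectionFactorModel, builtin_cf_model
from .circuit import (
    ChannelGeometry,
    CircuitParameters,
    FlowProgram,
    FluidPair,
    InterfaceSeries,
    simulate_nonlinear,
)
from .errors import InvalidInputError
from .imaging import CoflowFrame, render_coflow_frame
from .inference import AnalysisSetup, analyze_experiment

__all__ = [
    "GroundTruth",
    "generate_flow_program",
    "simulate_measurement",
    "parameter_recovery_suite",
    "DEFAULT_SIGMA_ALPHA",
]

#: Default observation noise on α (~1 px at 150 px channel width).
DEFAULT_SIGMA_ALPHA: float = 0.005


@dataclass
class GroundTruth:
    """Complete specification of one synthetic experiment.

    ``labels`` carries condition metadata (hematocrit, fixative
    concentration, diluent, tubing length, ...) that does not enter the
    simulation — the model is agnostic to how a sample acquired its
    viscosity and compliances.

    ``cf_model`` defaults to the constant-CF₀ (linearized) model for the
    geometry's depth: the compliance coefficients are *defined* through the
    linearized circuit, so ground-truth validation of the inverse pipeline
    must generate from the same dynamics. Pass the full polynomial model
    (``builtin_cf_model(h)``) to study linearization bias instead.
    """

    mu_b: float = 2.2
    C1: float = 50.0
    C2: float = 1400.0
    mu_r: float = 1.0
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    cf_model: CorrectionFactorModel | None = None
    program: FlowProgram = field(default_factory=FlowProgram)
    sigma_alpha: float = DEFAULT_SIGMA_ALPHA
    seed: int = 0
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.C1 < self.C2:
            raise InvalidInputError("require 0 < C1 < C2")
        if self.sigma_alpha < 0:
            raise InvalidInputError("sigma_alpha must be >= 0")
        if self.cf_model is None:
            stock = builtin_cf_model(self.geometry.h)
            self.cf_model = CorrectionFactorModel.constant(
                stock.cf0, depth=stock.depth
            )

    @property
    def params(self) -> CircuitParameters:
        cf0 = self.cf_model.cf0
        return CircuitParameters(
            geometry=self.geometry,
            fluids=FluidPair(mu_r=self.mu_r, mu_b=self.mu_b),
            C1=self.C1,
            C2=self.C2,
            CF0=cf0,
        )

    def analysis_setup(self) -> AnalysisSetup:
        return AnalysisSetup(
            geometry=self.geometry,
            mu_r=self.mu_r,
            cf_model=self.cf_model,
            program=self.program,
        )


def generate_flow_program(
    Q0_mL_h: float = 1.0,
    T_s: float = 240.0,
    cycles: int = 1,
    dt_s: float = 0.5,
    Qr_mL_h: float | None = None,
    on_fraction: float = 0.5,
) -> FlowProgram:
    """Square-wave pump program (on/off halves of the period).

    Defaults to the stock protocol: Q₀ = Q_r = 1 mL/h, T = 240 s, 0.5 s
    sampling. The sampling interval must resolve the square wave
    (dt ≤ T/4).
    """
    if cycles < 1:
        raise InvalidInputError("cycles must be >= 1 (empty program)")
    if dt_s > T_s / 4.0:
        raise InvalidInputError(
            f"dt={dt_s} s cannot resolve a period of {T_s} s (need dt <= T/4)"
        )
    return FlowProgram(
        Q0_mL_h=Q0_mL_h,
        Qr_mL_h=Qr_mL_h if Qr_mL_h is not None else Q0_mL_h,
        T_s=T_s,
        on_fraction=on_fraction,
        n_cycles=cycles,
        dt_s=dt_s,
    )


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Deterministic per-component generator streams from one global seed."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_measurement(
    truth: GroundTruth,
    render_frames: bool = False,
) -> InterfaceSeries | tuple[InterfaceSeries, list[CoflowFrame]]:
    """Simulate one recording of the interface under the truth's program.

    The noiseless trajectory is integrated from the full nonlinear model;
    observations are α + ε with ε ~ N(0, σ_α²), clipped to (0.001, 0.999).
    Bit-identical for a fixed seed. If the trajectory leaves the
    correction-factor validity range the series is truncated and flagged.
    With ``render_frames`` each sample is additionally rendered into a
    synthetic frame (seeded from the same global seed).
    """
    noise_rng, frame_rng = _spawn_rngs(truth.seed, 2)
    series = simulate_nonlinear(
        truth.params, truth.cf_model, truth.program
    )
    alpha_true = series.alpha.copy()
    if truth.sigma_alpha > 0:
        noisy = alpha_true + noise_rng.normal(
            0.0, truth.sigma_alpha, size=alpha_true.shape
        )
        observed = np.clip(noisy, 0.001, 0.999)
    else:
        observed = alpha_true
    out = InterfaceSeries(
        series.times,
        observed,
        program=truth.program,
        truncated=series.truncated,
        meta={**series.meta, "alpha_true": alpha_true,
              "sigma_alpha": truth.sigma_alpha, "seed": truth.seed,
              "labels": dict(truth.labels)},
    )
    if not render_frames:
        return out
    frames = [
        render_coflow_frame(a, seed=frame_rng) for a in out.alpha
    ]
    return out, frames


def parameter_recovery_suite(
    n_draws: int = 20,
    sigma_levels: tuple[float, ...] = (0.0, DEFAULT_SIGMA_ALPHA, 0.01),
    seed: int = 0,
    geometry: ChannelGeometry | None = None,
) -> pd.DataFrame:
    """Monte-Carlo recovery study of the full inverse pipeline.

    Draws ground truths (C₁ log-uniform on [10, 200], C₂ log-uniform on
    [500, 5000] µm³/mPa, µ_b uniform on [1, 4] mPa·s), simulates one
    recording per truth and noise level, runs the end-to-end analysis and
    tabulates relative bias and RMSE per parameter per noise level. The
    same truths and the same underlying noise realizations (scaled by σ)
    are shared across levels, so the noise axis is compared with common
    random numbers. Failed fits are counted, not hidden.
    """
    if n_draws < 1:
        raise InvalidInputError("n_draws must be >= 1")
    geometry = geometry or ChannelGeometry()
    draw_rng, seed_rng = _spawn_rngs(seed, 2)
    truths = []
    for _ in range(n_draws):
        c1 = float(np.exp(draw_rng.uniform(np.log(10.0), np.log(200.0))))
        c2 = float(np.exp(draw_rng.uniform(np.log(500.0), np.log(5000.0))))
        mu = float(draw_rng.uniform(1.0, 4.0))
        truths.append((mu, c1, c2))
    sub_seeds = seed_rng.integers(0, 2**31 - 1, size=n_draws)

    rows = []
    for sigma in sigma_levels:
        rel_err: dict[str, list[float]] = {"mu_b": [], "C1": [], "C2": []}
        n_failed = 0
        for (mu, c1, c2), s in zip(truths, sub_seeds):
            truth = GroundTruth(
                mu_b=mu, C1=c1, C2=c2, geometry=geometry,
                sigma_alpha=sigma, seed=int(s),
            )
            try:
                series = simulate_measurement(truth)
                result = analyze_experiment(series, truth.analysis_setup())
            except Exception:
                n_failed += 1
                continue
            rel_err["mu_b"].append(result.mu_b / mu - 1.0)
            rel_err["C1"].append(result.C1 / c1 - 1.0)
            rel_err["C2"].append(result.C2 / c2 - 1.0)
        for param, errs in rel_err.items():
            e = np.asarray(errs)
            rows.append(
                {
                    "sigma_alpha": sigma,
                    "parameter": param,
                    "n_ok": int(e.size),
                    "n_failed": n_failed,
                    "bias_rel": float(e.mean()) if e.size else np.nan,
                    "rmse_rel": float(np.sqrt(np.mean(e**2)))
                    if e.size
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)
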