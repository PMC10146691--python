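"""Lumped fluidic-circuit forward model of two-stream coflow.

A shallow rectangular network (blood channel of length l₁ feeding a
coflowing channel of length l₂ shared with a reference stream) is modelled
as discrete fluidic elements: resistances for each channel segment,
and two compliances — C₁ for the soft channel walls and tubing, C₂ for the
elastic particle phase (red blood cells) of the test fluid. Both streams are
driven by ideal flow sources; the reference flow Q_r is constant while the
test flow Q_b(t) follows a square on/off program.

The observable is the interface fraction α(t) (test-stream width over
channel width). Writing β = 1/(1−α), mass conservation at the two pressure
nodes gives the exact second-order equation

    a₀·β″ + b₀·β′ + e₀·d/dt[g(α)] + f₀·g(α) = Q_b/Q_r,
    g(α) = α·CF(α)/(1−α),

with a₀ = R_b1·R_r3·C₁·C₂, b₀ = R_r3·(C₁+C₂), e₀ = R_r3·C₁·(l₁/l₂) and
f₀ = µ_r/µ_b, where R_r3 = 12µ_r l₂/(wh³) is the coflow-channel resistance
at reference viscosity. Replacing the empirical correction factor CF(α) by
its interface-averaged constant CF₀ linearizes this to

    a·β″ + b·β′ + c·β = c + Q_b/Q_r,

whose homogeneous decay rates λ₁ ≥ λ₂ (roots of aλ² − bλ + c = 0) are the
two measurable eigenvalues that encode the compliances.

Units follow :mod:`coflow.units`: µm, s, mPa·s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp

from .calibration import CorrectionFactorModel
from .errors import (
    DegenerateStreamError,
    InvalidInputError,
    ModelAssumptionWarning,
    MultipleRootsError,
    NoRootError,
    RepeatedRootError,
    UnderdampedError,
    ValidityWarning,
)
from .units import ml_per_h_to_um3_per_s

__all__ = [
    "ChannelGeometry",
    "FluidPair",
    "CircuitParameters",
    "FlowProgram",
    "InterfaceSeries",
    "rect_resistance",
    "stream_resistances",
    "characteristic_coefficients",
    "eigenvalues_from_coefficients",
    "eigenvalues_forward",
    "analytic_beta",
    "beta_to_alpha",
    "turnoff_solution",
    "turnoff_amplitudes",
    "simulate_nonlinear",
    "steady_interface",
    "shear_rate",
    "ALPHA_VALIDITY",
]

#: Interface range over which the viscometry law is considered valid.
ALPHA_VALIDITY: tuple[float, float] = (0.1, 0.9)

#: Relative discriminant below which eigenvalues are treated as repeated.
_REPEATED_ROOT_RTOL = 1e-12


@dataclass(frozen=True)
class ChannelGeometry:
    """Channel and tubing dimensions.

    l1 : blood-channel length, µm.
    l2 : coflowing-channel length, µm.
    w : channel width, µm (common to all three channels).
    h : channel depth, µm.
    L_in, L_out : inlet/outlet tubing lengths, mm (metadata only — tubing
        enters the model through the compliance C₁, not as a resistance).
    """

    l1: float = 7500.0
    l2: float = 4800.0
    w: float = 250.0
    h: float = 20.0
    L_in: float = 300.0
    L_out: float = 300.0

    def __post_init__(self) -> None:
        for name in ("l1", "l2", "w", "h", "L_in", "L_out"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")
        if self.h / self.w >= 0.1:
            warnings.warn(
                f"aspect ratio h/w = {self.h / self.w:.3f} >= 0.1; the "
                "two-dimensional (shallow-channel) flow approximation "
                "degrades",
                ModelAssumptionWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class FluidPair:
    """Viscosities of the reference and test fluids, mPa·s."""

    mu_r: float
    mu_b: float

    def __post_init__(self) -> None:
        if self.mu_r <= 0 or self.mu_b <= 0:
            raise InvalidInputError("viscosities must be > 0")


def rect_resistance(mu: float, l: float, w: float, h: float) -> float:
    """Hydraulic resistance of a shallow rectangular channel, mPa·s/µm³.

    R = 12·µ·l / (w·h³), the two-dimensional (h ≪ w) limit of plane
    Poiseuille flow.
    """
    if mu <= 0 or l <= 0 or w <= 0 or h <= 0:
        raise InvalidInputError("all of mu, l, w, h must be > 0")
    return 12.0 * mu * l / (w * h**3)


def stream_resistances(
    alpha: float,
    geom: ChannelGeometry,
    fluids: FluidPair,
    cf: float,
) -> tuple[float, float]:
    """Resistances (R_r2, R_b2) of the two parallel coflow streams.

    The interface at fraction α acts as a virtual wall: the reference
    stream occupies width (1−α)·w and the test stream α·w, the latter
    corrected by the empirical factor ``cf``:

        R_r2 = 12 µ_r l₂ / ((1−α) w h³),  R_b2 = 12 µ_b l₂ / (CF α w h³).
    """
    if not 0.0 < alpha < 1.0:
        raise DegenerateStreamError(
            f"alpha={alpha}: one stream has zero width"
        )
    if cf <= 0:
        raise InvalidInputError("cf must be > 0")
    lo, hi = ALPHA_VALIDITY
    if not lo < alpha < hi:
        warnings.warn(
            f"alpha={alpha:.4g} outside validity range {ALPHA_VALIDITY}",
            ValidityWarning,
            stacklevel=2,
        )
    r_r2 = rect_resistance(fluids.mu_r, geom.l2, geom.w, geom.h) / (1.0 - alpha)
    r_b2 = rect_resistance(fluids.mu_b, geom.l2, geom.w, geom.h) / (cf * alpha)
    return r_r2, r_b2


@dataclass(frozen=True)
class CircuitParameters:
    """Complete lumped-element parameter set of the microfluidic circuit.

    C1 : compliance of tubing + soft channel walls, µm³/mPa.
    C2 : compliance of the elastic particle phase (RBCs), µm³/mPa.
    CF0 : constant correction factor linearizing the coflow term.

    The series resistance drawn on the reference inlet branch has no
    dynamical role (the reference stream is driven by an ideal flow source)
    and is deliberately not a parameter.
    """

    geometry: ChannelGeometry
    fluids: FluidPair
    C1: float
    C2: float
    CF0: float

    def __post_init__(self) -> None:
        if self.C1 <= 0 or self.C2 <= 0 or self.CF0 <= 0:
            raise InvalidInputError("C1, C2, CF0 must be > 0")
        if not self.C1 < self.C2:
            raise InvalidInputError(
                f"model requires C1 < C2 (got C1={self.C1}, C2={self.C2}): "
                "the sample compliance dominates the device compliance"
            )

    @property
    def R_b1(self) -> float:
        """Blood-channel resistance, mPa·s/µm³."""
        g = self.geometry
        return rect_resistance(self.fluids.mu_b, g.l1, g.w, g.h)

    @property
    def R_r3(self) -> float:
        """Coflow-channel resistance at reference viscosity, mPa·s/µm³."""
        g = self.geometry
        return rect_resistance(self.fluids.mu_r, g.l2, g.w, g.h)


@dataclass(frozen=True)
class FlowProgram:
    """Square-wave test-fluid flow program with constant reference flow.

    Q0_mL_h : pump amplitude during the on-phase, mL/h.
    Qr_mL_h : constant reference flow, mL/h.
    T_s : period (on + off), s.
    on_fraction : fraction of the period with the pump on (default 0.5).
    n_cycles : number of periods.
    dt_s : sampling interval, s.
    """

    Q0_mL_h: float = 1.0
    Qr_mL_h: float = 1.0
    T_s: float = 240.0
    on_fraction: float = 0.5
    n_cycles: int = 1
    dt_s: float = 0.5

    def __post_init__(self) -> None:
        if self.Q0_mL_h <= 0 or self.Qr_mL_h <= 0 or self.T_s <= 0:
            raise InvalidInputError("Q0, Qr and T must be > 0")
        if not 0.0 < self.on_fraction < 1.0:
            raise InvalidInputError("on_fraction must be in (0, 1)")
        if self.n_cycles < 1:
            raise InvalidInputError("n_cycles must be >= 1")
        if self.dt_s <= 0:
            raise InvalidInputError("dt_s must be > 0")

    @property
    def Q0(self) -> float:
        """On-phase test flow, µm³/s."""
        return ml_per_h_to_um3_per_s(self.Q0_mL_h)

    @property
    def Qr(self) -> float:
        """Reference flow, µm³/s."""
        return ml_per_h_to_um3_per_s(self.Qr_mL_h)

    @property
    def t_on(self) -> float:
        """Duration of the on-phase within one period, s."""
        return self.on_fraction * self.T_s

    @property
    def total_time(self) -> float:
        return self.n_cycles * self.T_s

    def times(self) -> np.ndarray:
        """Sampling grid [0, total) at dt_s."""
        n = int(round(self.total_time / self.dt_s))
        return np.arange(n) * self.dt_s

    def switch_times(self) -> np.ndarray:
        """All on→off and off→on switch instants, ascending (excluding 0)."""
        edges = []
        for k in range(self.n_cycles):
            edges.append(k * self.T_s + self.t_on)
            edges.append((k + 1) * self.T_s)
        return np.asarray(edges)

    def segments(self) -> list[tuple[float, float, bool]]:
        """(t_start, t_end, pump_on) tuples covering the whole program."""
        out = []
        for k in range(self.n_cycles):
            t0 = k * self.T_s
            out.append((t0, t0 + self.t_on, True))
            out.append((t0 + self.t_on, t0 + self.T_s, False))
        return out

    def is_on(self, t) -> np.ndarray:
        """Pump state at time(s) t (on-phase is [kT, kT + t_on))."""
        t = np.asarray(t, dtype=float)
        return np.mod(t, self.T_s) < self.t_on

    def qb_at(self, t) -> np.ndarray:
        """Test-fluid flow rate at time(s) t, µm³/s."""
        return np.where(self.is_on(t), self.Q0, 0.0)


@dataclass
class InterfaceSeries:
    """Timestamped interface-fraction samples, the method's observable.

    ``alpha`` must lie strictly in (0, 1); samples outside the viscometry
    validity range (0.1, 0.9) are retained but flagged via
    :meth:`validity_mask`. β = 1/(1−α) is derived on demand.
    """

    times: np.ndarray
    alpha: np.ndarray
    program: FlowProgram | None = None
    truncated: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.times.shape != self.alpha.shape or self.times.ndim != 1:
            raise InvalidInputError("times and alpha must be equal-length 1-D")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidInputError("times must be strictly increasing")
        if self.times.size and (
            np.any(self.alpha <= 0) or np.any(self.alpha >= 1)
        ):
            raise InvalidInputError("alpha samples must lie strictly in (0, 1)")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def beta(self) -> np.ndarray:
        """β = 1/(1−α)."""
        return 1.0 / (1.0 - self.alpha)

    def validity_mask(self) -> np.ndarray:
        """True for samples inside the viscometry validity range."""
        lo, hi = ALPHA_VALIDITY
        return (self.alpha > lo) & (self.alpha < hi)

    def slice(self, t_start: float, t_end: float) -> "InterfaceSeries":
        """Samples with t_start <= t < t_end (program dropped)."""
        m = (self.times >= t_start) & (self.times < t_end)
        return InterfaceSeries(self.times[m], self.alpha[m], program=None,
                               truncated=self.truncated, meta=dict(self.meta))


# ---------------------------------------------------------------------------
# Linearized model
# ---------------------------------------------------------------------------

def characteristic_coefficients(
    params: CircuitParameters,
) -> tuple[float, float, float]:
    """Coefficients (a, b, c) of the linearized equation a·β″+b·β′+c·β = c
    (pump off), with

        a = R_b1·R_r3·C₁·C₂,
        b = R_r3·(C₁ + C₂ + C₁·(l₁/l₂)·CF₀),
        c = (µ_r/µ_b)·CF₀.
    """
    g = params.geometry
    a = params.R_b1 * params.R_r3 * params.C1 * params.C2
    b = params.R_r3 * (
        params.C1 + params.C2 + params.C1 * (g.l1 / g.l2) * params.CF0
    )
    c = (params.fluids.mu_r / params.fluids.mu_b) * params.CF0
    return a, b, c


def eigenvalues_from_coefficients(
    a: float, b: float, c: float
) -> tuple[float, float]:
    """Decay rates (λ₁, λ₂), λ₁ ≥ λ₂, as roots of aλ² − bλ + c = 0.

    A negative discriminant (underdamped response) is outside the model's
    validity and raises; a vanishing discriminant warns (repeated root,
    the two modes are not distinguishable).
    """
    if a <= 0 or b <= 0 or c <= 0:
        raise InvalidInputError("coefficients a, b, c must be > 0")
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise UnderdampedError(
            f"discriminant b²−4ac = {disc:.3g} < 0: underdamped response, "
            "outside the overdamped two-mode model"
        )
    if disc <= _REPEATED_ROOT_RTOL * b * b:
        warnings.warn(
            "repeated eigenvalue (discriminant ~ 0); the two decay modes "
            "are not distinguishable",
            ValidityWarning,
            stacklevel=2,
        )
    sq = np.sqrt(disc)
    return float((b + sq) / (2.0 * a)), float((b - sq) / (2.0 * a))


def eigenvalues_forward(params: CircuitParameters) -> tuple[float, float]:
    """Decay rates (λ₁, λ₂), λ₁ ≥ λ₂ > 0, of the linearized transient.

    They satisfy the sum/product relations

        λ₁+λ₂ = (C₁ + C₂ + C₁·(l₁/l₂)·CF₀) / (R_b1·C₁·C₂),
        λ₁·λ₂ = (µ_r/µ_b)·CF₀ / (R_b1·R_r3·C₁·C₂).
    """
    return eigenvalues_from_coefficients(*characteristic_coefficients(params))


def analytic_beta(d1: float, d2: float, lam1: float, lam2: float, t):
    """β(t) = d₁·e^{−λ₁t} + d₂·e^{−λ₂t} + 1 (pump-off analytic solution)."""
    if lam1 <= 0 or lam2 <= 0:
        raise InvalidInputError("decay rates must be > 0")
    t = np.asarray(t, dtype=float)
    return d1 * np.exp(-lam1 * t) + d2 * np.exp(-lam2 * t) + 1.0


def beta_to_alpha(beta) -> tuple[np.ndarray, np.ndarray]:
    """α = 1 − 1/β; where β ≤ 1 the test stream has washed out and α is
    reported as 0 with the accompanying mask set.

    Returns (alpha, washed_out_mask).
    """
    beta = np.asarray(beta, dtype=float)
    washed = beta <= 1.0
    alpha = np.where(washed, 0.0, 1.0 - 1.0 / np.where(washed, np.inf, beta))
    return alpha, washed


def turnoff_amplitudes(
    beta0: float, lam1: float, lam2: float
) -> tuple[float, float]:
    """Mode amplitudes after pump switch-off from steady β₀.

    Pressure continuity at both compliance nodes implies β(0⁺)=β₀ and
    β′(0⁺)=0, giving

        d₁ = −λ₂(β₀−1)/(λ₁−λ₂),  d₂ = λ₁(β₀−1)/(λ₁−λ₂),

    so d₁+d₂ = β₀−1 and d₁λ₁+d₂λ₂ = 0.
    """
    if lam1 == lam2:
        raise RepeatedRootError(
            "turn-off amplitudes undefined for repeated decay rates"
        )
    d1 = -lam2 * (beta0 - 1.0) / (lam1 - lam2)
    d2 = lam1 * (beta0 - 1.0) / (lam1 - lam2)
    return d1, d2


def turnoff_solution(
    beta0: float, params: CircuitParameters
) -> tuple[float, float]:
    """(d₁, d₂) for switch-off from steady β₀ under ``params``.

    Requires β₀ > 1 (a test stream present) — β₀ = 1 yields the trivial
    rest state (0, 0).
    """
    if beta0 < 1.0:
        raise InvalidInputError("beta0 must be >= 1")
    lam1, lam2 = eigenvalues_forward(params)
    if beta0 == 1.0:
        return 0.0, 0.0
    return turnoff_amplitudes(beta0, lam1, lam2)


# ---------------------------------------------------------------------------
# Steady state and full nonlinear model
# ---------------------------------------------------------------------------

def _steady_lhs(alpha, mu_r, cf_model, flow_ratio):
    return mu_r * cf_model(alpha) * alpha / (1.0 - alpha) / flow_ratio


def steady_interface(
    mu_b: float,
    flow_ratio: float,
    mu_r: float,
    cf_model: CorrectionFactorModel,
    n_scan: int = 400,
) -> float:
    """Steady interface fraction α solving the viscometry law

        µ_r · CF(α) · α/(1−α) · (Q_r/Q_b) = µ_b

    by bracketed root finding over the model's validity range.
    ``flow_ratio`` is Q_b/Q_r. Raises if no root lies in the range, and
    reports all roots if CF(α)·α/(1−α) is non-monotone enough to admit
    several.
    """
    from scipy.optimize import brentq

    if mu_b <= 0 or mu_r <= 0 or flow_ratio <= 0:
        raise InvalidInputError("mu_b, mu_r, flow_ratio must be > 0")
    lo, hi = cf_model.valid_range
    lo = max(lo, 1e-6)
    hi = min(hi, 1.0 - 1e-9)
    grid = np.linspace(lo, hi, n_scan)
    resid = _steady_lhs(grid, mu_r, cf_model, flow_ratio) - mu_b
    sign_changes = np.nonzero(np.diff(np.sign(resid)) != 0)[0]
    if len(sign_changes) == 0:
        raise NoRootError(
            f"no steady interface in ({lo:.3g}, {hi:.3g}) for mu_b={mu_b}"
        )
    roots = [
        brentq(
            lambda x: _steady_lhs(x, mu_r, cf_model, flow_ratio) - mu_b,
            grid[i],
            grid[i + 1],
            xtol=1e-14,
            rtol=8.9e-16,
        )
        for i in sign_changes
    ]
    uniq = []
    for r in roots:
        if not any(abs(r - u) < 1e-10 for u in uniq):
            uniq.append(r)
    if len(uniq) > 1:
        raise MultipleRootsError(uniq)
    return float(uniq[0])


def simulate_nonlinear(
    params: CircuitParameters,
    cf_model: CorrectionFactorModel,
    program: FlowProgram,
    t_span: tuple[float, float] | None = None,
    alpha0: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> InterfaceSeries:
    """Numerically integrate the full nonlinear interface equation.

    State is (α, α′); the nonlinear coflow term g(α) = α·CF(α)/(1−α) keeps
    the full polynomial CF(α), with its derivative applied by the chain
    rule. Integration proceeds segment-by-segment over the square-wave
    program (Q_b piecewise constant), with (β, β′) — equivalently (α, α′) —
    continuous across switches. The start state defaults to the on-phase
    steady interface with α′ = 0; pass ``alpha0`` to override.

    If α reaches the correction-factor validity bounds the integration
    halts there and the returned series is truncated and flagged
    (``series.truncated``); the two well-separated decay rates make the
    system mildly stiff, hence the implicit-capable default solver.

    The output is sampled on the program grid. With a constant CF this
    reproduces the analytic linear solution, which serves as a cross-check
    of the integrator (and vice versa).
    """
    g = params.geometry
    a0 = params.R_b1 * params.R_r3 * params.C1 * params.C2
    b0 = params.R_r3 * (params.C1 + params.C2)
    e0 = params.R_r3 * params.C1 * (g.l1 / g.l2)
    f0 = params.fluids.mu_r / params.fluids.mu_b

    lo, hi = cf_model.valid_range

    def rhs(t, y, qb_over_qr):
        alpha, dalpha = y
        beta = 1.0 / (1.0 - alpha)
        dbeta = dalpha * beta * beta
        cf = cf_model(alpha)
        dcf = cf_model.derivative(alpha)
        # d/dα [α·CF(α)/(1−α)] = CF/(1−α)² + α·CF′/(1−α)
        dg = cf * beta * beta + alpha * dcf * beta
        gval = alpha * cf * beta
        ddbeta = (qb_over_qr - b0 * dbeta - e0 * dg * dalpha - f0 * gval) / a0
        ddalpha = (ddbeta - 2.0 * dalpha * dalpha * beta**3) / (beta * beta)
        return (dalpha, ddalpha)

    def exit_event(t, y, qb_over_qr):
        return min(y[0] - lo, hi - y[0])

    exit_event.terminal = True
    exit_event.direction = -1

    if t_span is None:
        t_span = (0.0, program.total_time)
    t0, t1 = t_span
    times = program.times()
    times = times[(times >= t0) & (times < t1)]

    if alpha0 is None:
        alpha0 = steady_interface(
            params.fluids.mu_b,
            program.Q0 / program.Qr,
            params.fluids.mu_r,
            cf_model,
        )
    if not lo < alpha0 < hi:
        raise InvalidInputError(
            f"initial alpha {alpha0} outside CF validity range ({lo}, {hi})"
        )

    y = (float(alpha0), 0.0)
    out_t: list[np.ndarray] = []
    out_a: list[np.ndarray] = []
    truncated = False
    for seg_start, seg_end, on in program.segments():
        if seg_end <= t0 or seg_start >= t1:
            continue
        s0, s1 = max(seg_start, t0), min(seg_end, t1)
        qb_over_qr = (program.Q0 / program.Qr) if on else 0.0
        seg_times = times[(times >= s0) & (times < s1)]
        sol = solve_ivp(
            rhs,
            (s0, s1),
            y,
            method=method,
            rtol=rtol,
            atol=atol,
            dense_output=True,
            events=exit_event,
            args=(qb_over_qr,),
        )
        if sol.status == -1:
            raise RuntimeError(f"ODE solver failed: {sol.message}")
        t_reach = sol.t[-1]
        keep = seg_times[seg_times <= t_reach]
        if keep.size:
            out_t.append(keep)
            out_a.append(sol.sol(keep)[0])
        if sol.status == 1:  # validity-range exit
            truncated = True
            break
        y = tuple(sol.y[:, -1])
    series = InterfaceSeries(
        np.concatenate(out_t) if out_t else np.empty(0),
        np.clip(np.concatenate(out_a), 1e-12, 1 - 1e-12)
        if out_a
        else np.empty(0),
        program=program,
        truncated=truncated,
    )
    if truncated:
        series.meta["truncation_reason"] = (
            "alpha reached correction-factor validity bound"
        )
    return series


def shear_rate(q_b_mL_h: float, w: float, h: float) -> float:
    """Wall shear rate 6·Q_b/(w·h²) in s⁻¹ for a shallow rectangular channel.

    Uses the full channel width w. Note that published shear-rate ranges for
    this device type are sometimes larger than this formula gives with the
    full width, suggesting an effective (reduced) width; this helper
    implements the formula literally.
    """
    if q_b_mL_h <= 0 or w <= 0 or h <= 0:
        raise InvalidInputError("q_b, w, h must be > 0")
    return 6.0 * ml_per_h_to_um3_per_s(q_b_mL_h) / (w * h * h)
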