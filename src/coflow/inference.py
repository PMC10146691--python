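"""Inverse pipeline: viscosity and compliances from interface recordings.

Steady phase — while the test pump runs, the interface settles at a value
α_ss from which the test-fluid viscosity follows directly:

    µ_b = µ_r · CF(α_ss) · α_ss/(1−α_ss) · (Q_r/Q_b).

Transient phase — after pump switch-off the interface relaxes; in
β = 1/(1−α) coordinates the relaxation is a sum of two exponentials,

    β(t) − 1 = d₁·e^{−λ₁ t} + d₂·e^{−λ₂ t},

whose decay rates are the eigenvalues of the linearized circuit. Given µ_b
from the steady phase, the eigenvalue sum and product relations are solved
simultaneously for the two compliances C₁ (device: tubing + soft walls) and
C₂ (sample: RBC elasticity). With S = λ₁+λ₂, P = λ₁λ₂ and
k = 1 + (l₁/l₂)·CF₀ the system reduces to a quadratic:

    C₁C₂ = (µ_r/µ_b)·CF₀ / (R_b1·R_r3·P)   =: Π
    k·C₁ + C₂ = S·R_b1·Π                   =: Σ
    k·C₁² − Σ·C₁ + Π = 0,

with the physical root chosen by C₁ < C₂. Since R_b1 ∝ µ_b, the same two
relations can instead be solved for (µ_b, C₂) given C₁, or (µ_b, C₁) given
C₂ — each case again reduces to a quadratic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .calibration import CorrectionFactorModel, cf0_constant
from .circuit import (
    ALPHA_VALIDITY,
    ChannelGeometry,
    FlowProgram,
    InterfaceSeries,
    rect_resistance,
)
from .errors import (
    FitError,
    InsufficientDataError,
    InvalidInputError,
    ModelInconsistencyError,
    NonIdentifiableError,
    PipelineStageError,
    RepeatedRootError,
    ValidityWarning,
)

__all__ = [
    "EigenFit",
    "ViscoelasticResult",
    "AnalysisSetup",
    "select_steady_window",
    "steady_viscosity",
    "two_exponential_fit",
    "compliances_from_eigenvalues",
    "complete_parameter_set",
    "analyze_experiment",
]


@dataclass
class EigenFit:
    """Result of the two-exponential transient fit.

    Amplitudes are unconstrained in sign (pressure continuity predicts
    d₁ < 0 at ideal switch-off, but measured transients need not honor it);
    eigenvalues are canonically ordered λ₁ ≥ λ₂ > 0.
    """

    d1: float
    d2: float
    lambda1: float
    lambda2: float
    residual_norm: float
    n_points: int
    converged: bool
    degenerate: bool = False
    diagnostics: dict = field(default_factory=dict)


@dataclass
class SteadyWindowSummary:
    """Mean/sd/count of the interface over one steady analysis window."""

    alpha_mean: float
    alpha_sd: float
    n: int
    t_start: float
    t_end: float


@dataclass
class CycleResult:
    """Per-cycle estimates from one on/off period."""

    cycle: int
    mu_b: float
    C1: float
    C2: float
    steady: SteadyWindowSummary
    eigenfit: EigenFit


@dataclass
class ViscoelasticResult:
    """End-to-end estimates: viscosity plus the two compliances.

    ``mu_b``/``C1``/``C2`` are across-cycle means; the per-cycle values
    (and standard deviations, for recordings with several cycles) are in
    ``cycles`` and the ``*_sd`` fields. Invariant: C1 < C2, all positive.
    """

    mu_b: float
    C1: float
    C2: float
    mu_b_sd: float
    C1_sd: float
    C2_sd: float
    n_cycles: int
    cycles: list[CycleResult]
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mu_b_mPas": self.mu_b,
            "C1_um3_per_mPa": self.C1,
            "C2_um3_per_mPa": self.C2,
            "mu_b_sd": self.mu_b_sd,
            "C1_sd": self.C1_sd,
            "C2_sd": self.C2_sd,
            "n_cycles": self.n_cycles,
            "cycles": [
                {
                    "cycle": c.cycle,
                    "mu_b": c.mu_b,
                    "C1": c.C1,
                    "C2": c.C2,
                    "steady_alpha_mean": c.steady.alpha_mean,
                    "steady_alpha_sd": c.steady.alpha_sd,
                    "steady_n": c.steady.n,
                    "d1": c.eigenfit.d1,
                    "d2": c.eigenfit.d2,
                    "lambda1": c.eigenfit.lambda1,
                    "lambda2": c.eigenfit.lambda2,
                    "fit_residual_norm": c.eigenfit.residual_norm,
                    "fit_converged": c.eigenfit.converged,
                }
                for c in self.cycles
            ],
            "diagnostics": self.diagnostics,
        }


@dataclass
class AnalysisSetup:
    """Everything the inverse pipeline needs besides the series itself."""

    geometry: ChannelGeometry
    mu_r: float
    cf_model: CorrectionFactorModel
    program: FlowProgram | None = None
    n_steady: int = 50
    settle_s: float = 70.0

    @property
    def cf0(self) -> float:
        """CF₀ for the transient inversion: the model's shipped constant,
        falling back to recomputation on the default grid."""
        if self.cf_model.cf0 is not None:
            return self.cf_model.cf0
        return cf0_constant(self.cf_model)


# ---------------------------------------------------------------------------
# Steady stage
# ---------------------------------------------------------------------------

def select_steady_window(
    series: InterfaceSeries,
    program: FlowProgram,
    n: int = 50,
    settle_s: float = 70.0,
) -> list[np.ndarray]:
    """Index windows of steady samples, one per on-phase.

    After switch-on the interface needs ~70 s to settle, so the first
    ``settle_s`` seconds of each on-phase are excluded and the last ``n``
    samples before switch-off are kept (30–50 samples suffice for the
    viscosity estimate).
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if program.t_on < settle_s + n * program.dt_s:
        raise InsufficientDataError(
            f"on-phase of {program.t_on} s too short for a {n}-sample window "
            f"after a {settle_s} s settling exclusion"
        )
    windows = []
    for k in range(program.n_cycles):
        t_on0 = k * program.T_s
        t_off = t_on0 + program.t_on
        idx = np.nonzero(
            (series.times >= t_on0 + settle_s) & (series.times < t_off)
        )[0]
        if idx.size >= n:
            windows.append(idx[-n:])
    if not windows:
        raise InsufficientDataError(
            "no on-phase with enough settled samples found in the series"
        )
    return windows


def steady_viscosity(
    alpha: float,
    Q_r: float,
    Q_b: float,
    mu_r: float,
    cf_model: CorrectionFactorModel,
) -> float:
    """Test-fluid viscosity from a steady interface value (viscometry law).

    µ_b = µ_r · CF(α) · α/(1−α) · (Q_r/Q_b). Flow rates may be in any
    common unit. Values of α outside the validity range are computed but
    flagged with a :class:`ValidityWarning`.
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidInputError("alpha must be in (0, 1)")
    if Q_r <= 0 or Q_b <= 0 or mu_r <= 0:
        raise InvalidInputError("flows and mu_r must be > 0")
    lo, hi = ALPHA_VALIDITY
    if not lo <= alpha <= hi:
        warnings.warn(
            f"steady alpha={alpha:.4g} outside validity range "
            f"[{lo}, {hi}]; viscosity estimate may be biased",
            ValidityWarning,
            stacklevel=2,
        )
    return mu_r * cf_model(alpha) * alpha / (1.0 - alpha) * (Q_r / Q_b)


# ---------------------------------------------------------------------------
# Transient stage
# ---------------------------------------------------------------------------

def _two_exp(t, d1, d2, lam1, lam2):
    return d1 * np.exp(-lam1 * t) + d2 * np.exp(-lam2 * t)


def _varpro_amplitudes(t, y, lam1, lam2):
    """Linear least-squares amplitudes for fixed decay rates."""
    A = np.column_stack([np.exp(-lam1 * t), np.exp(-lam2 * t)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    pred = A @ coef
    return coef, float(np.sum((y - pred) ** 2))


def _peel_initial_guess(t, y):
    """Classic exponential peeling: log-linear tail fit for the slow rate,
    then a log-linear fit of the early residual for the fast rate. The head
    window adapts to where the residual still has consistent sign and
    non-negligible magnitude."""
    tail = slice(len(t) // 2, None)
    yt = y[tail]
    if np.any(yt <= 0):
        raise FitError("tail of β−1 not positive; peeling unavailable")
    slope, intercept = np.polyfit(t[tail], np.log(yt), 1)
    lam2 = -slope
    if lam2 <= 0:
        raise FitError("tail fit gave non-positive slow rate")
    d2 = np.exp(intercept)
    resid = y - d2 * np.exp(-lam2 * t)
    sign = np.sign(resid[0])
    if sign == 0:
        raise FitError("vanishing early residual; peeling unavailable")
    r = sign * resid
    # longest prefix with consistent sign and >=2% of the initial magnitude
    ok = np.nonzero((r <= 0) | (r < 0.02 * r[0]))[0]
    n_head = ok[0] if ok.size else len(r)
    if n_head < 4:
        raise FitError("too few usable early-residual samples for peeling")
    head = slice(0, n_head)
    slope1, intercept1 = np.polyfit(t[head], np.log(r[head]), 1)
    lam1 = -slope1
    if lam1 <= 0:
        raise FitError("head fit gave non-positive fast rate")
    return sign * np.exp(intercept1), d2, lam1, lam2


def _multistart_guess(t, y, n_grid: int = 12):
    """Variable-projection grid search over log-spaced rate pairs."""
    t_range = t[-1] - t[0] if t[-1] > t[0] else 1.0
    lams = np.geomspace(0.1 / t_range, 50.0 / t_range, n_grid)
    best = None
    for i in range(n_grid):
        for j in range(i + 1, n_grid):
            coef, ss = _varpro_amplitudes(t, y, lams[j], lams[i])
            if best is None or ss < best[-1]:
                best = (coef[0], coef[1], lams[j], lams[i], ss)
    return best[:4]


def two_exponential_fit(
    series: InterfaceSeries,
    t0: float,
    t_end: float | None = None,
    min_samples: int = 40,
    xtol: float = 1e-8,
    max_iter: int = 1000,
    weighting: str = "alpha",
) -> EigenFit:
    """Nonlinear least-squares fit of β−1 to a two-exponential decay.

    Samples with time ≥ ``t0`` (the switch-off instant; optionally capped at
    ``t_end``) are re-zeroed at t0 and β−1 = α/(1−α) is fitted to
    d₁e^{−λ₁t} + d₂e^{−λ₂t}. Initialization uses exponential peeling (tail
    log-linear fit for λ₂, residual for λ₁) with a variable-projection
    multi-start over a log-spaced rate grid as fallback. Eigenvalues are
    canonically ordered λ₁ ≥ λ₂ and must be positive for the fit to be
    accepted; near-equal rates or a vanishing fast amplitude are flagged as
    degenerate (the fast mode is then unidentifiable).

    ``weighting="alpha"`` (default) weights the β−1 residuals by 1/β²:
    measurement noise lives on α, and Var(β) = β⁴·Var(α), so this is the
    inverse-sd weighting that makes the fit the homoscedastic-in-α
    maximum-likelihood estimate. ``weighting="none"`` gives the plain
    unweighted β-space fit.
    """
    if weighting not in ("alpha", "none"):
        raise InvalidInputError("weighting must be 'alpha' or 'none'")
    m = series.times >= t0
    if t_end is not None:
        m &= series.times < t_end
    t = series.times[m] - t0
    beta = series.beta[m]
    beta1 = beta - 1.0
    w = 1.0 / beta**2 if weighting == "alpha" else np.ones_like(beta)
    if t.size < min_samples:
        raise InsufficientDataError(
            f"need >= {min_samples} post-switch-off samples, got {t.size}"
        )

    diagnostics: dict = {}
    starts: list[tuple] = []
    try:
        starts.append(("peeling", _peel_initial_guess(t, beta1)))
    except FitError as exc:
        diagnostics["peeling"] = f"unavailable ({exc})"
    starts.append(("multistart", _multistart_guess(t, beta1)))

    def resid(p):
        return w * (_two_exp(t, *p) - beta1)

    # refine from every available start and keep the best admissible
    # (positive-rate) solution — guards against the shallow local minimum
    # with coincident rates that plain refinement can fall into
    best = None
    for name, p0 in starts:
        sol = least_squares(
            resid,
            p0,
            method="lm",
            xtol=xtol,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=max_iter * 4,
        )
        la, lb = sol.x[2], sol.x[3]
        if la <= 0 or lb <= 0:
            continue
        ss = float(np.sum(sol.fun**2))
        if best is None or ss < best[2] * (1.0 - 1e-12):
            best = (name, sol, ss)
    if best is None:
        raise FitError("fit rejected: no start yielded positive decay rates")
    diagnostics["init"] = best[0]
    sol = best[1]
    d1, d2, lam1, lam2 = sol.x
    converged = bool(sol.success)
    if lam1 < lam2:
        d1, d2, lam1, lam2 = d2, d1, lam2, lam1
    amp_total = abs(d1) + abs(d2)
    degenerate = bool(
        (lam1 - lam2) <= 1e-6 * lam1
        or (amp_total > 0 and abs(d1) < 1e-6 * amp_total)
    )
    if degenerate:
        diagnostics["degeneracy"] = (
            "fast mode unidentifiable (rates coincide or d1 ~ 0)"
        )
    return EigenFit(
        d1=float(d1),
        d2=float(d2),
        lambda1=float(lam1),
        lambda2=float(lam2),
        residual_norm=float(np.linalg.norm(resid(sol.x))),
        n_points=int(t.size),
        converged=converged,
        degenerate=degenerate,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Eigenvalue inversion
# ---------------------------------------------------------------------------

def _unit_resistances(geom: ChannelGeometry) -> tuple[float, float]:
    """Per-unit-viscosity resistances (r1, r3) of blood and coflow channels."""
    r1 = rect_resistance(1.0, geom.l1, geom.w, geom.h)
    r3 = rect_resistance(1.0, geom.l2, geom.w, geom.h)
    return r1, r3


def _check_rates(lam1: float, lam2: float) -> None:
    if lam2 <= 0 or lam1 <= 0:
        raise InvalidInputError("decay rates must be > 0")
    if lam1 == lam2:
        raise RepeatedRootError(
            "equal decay rates: compliances not identifiable"
        )


def compliances_from_eigenvalues(
    lam1: float,
    lam2: float,
    mu_b: float,
    geom: ChannelGeometry,
    mu_r: float,
    CF0: float,
) -> tuple[float, float]:
    """Invert the eigenvalue sum/product relations for (C₁, C₂) at known µ_b.

    Solves k·C₁² − Σ·C₁ + Π = 0 (see module docstring) and returns the root
    with C₁ < C₂ = Π/C₁. Raises :class:`NonIdentifiableError` if no real
    solution exists and :class:`ModelInconsistencyError` if neither root
    satisfies the ordering.

    The quadratic factors exactly as (C₁ − C₁*)(k·C₁ − C₂*), so the
    companion root of the true pair (C₁*, C₂*) is (C₂*/k, k·C₁*). That
    companion also satisfies the C₁ < C₂ ordering when C₂* < k²·C₁*, in
    which case the system is genuinely ambiguous given only (λ₁, λ₂, µ_b);
    the smaller-C₁ root is returned. Measured compliance ratios
    (C₂/C₁ ≈ 10–20) lie well inside the unique regime C₂ > k²·C₁ ≈ 8·C₁.
    """
    _check_rates(lam1, lam2)
    if mu_b <= 0 or mu_r <= 0 or CF0 <= 0:
        raise InvalidInputError("mu_b, mu_r, CF0 must be > 0")
    if lam1 < lam2:
        lam1, lam2 = lam2, lam1
    r1, r3 = _unit_resistances(geom)
    R_b1, R_r3 = mu_b * r1, mu_r * r3
    S, P = lam1 + lam2, lam1 * lam2
    k = 1.0 + (geom.l1 / geom.l2) * CF0
    pi = (mu_r / mu_b) * CF0 / (R_b1 * R_r3 * P)
    sigma = S * R_b1 * pi
    disc = sigma * sigma - 4.0 * k * pi
    if disc < 0:
        raise NonIdentifiableError(
            f"eigenvalue system has no real compliance solution "
            f"(discriminant {disc:.3g})"
        )
    sq = np.sqrt(disc)
    candidates = [(sigma - sq) / (2.0 * k), (sigma + sq) / (2.0 * k)]
    for c1 in candidates:
        if c1 <= 0:
            continue
        c2 = pi / c1
        if c1 < c2:
            return float(c1), float(c2)
    raise ModelInconsistencyError(
        f"no root with 0 < C1 < C2 (candidates C1={candidates}, Π={pi:.4g})"
    )


def complete_parameter_set(
    lam1: float,
    lam2: float,
    geom: ChannelGeometry,
    mu_r: float,
    CF0: float,
    mu_b: float | None = None,
    C1: float | None = None,
    C2: float | None = None,
) -> dict:
    """Complete (µ_b, C₁, C₂) from two decay rates plus one known member.

    The eigenvalue sum/product relations constrain three unknowns with two
    equations; fixing any one of µ_b, C₁ or C₂ reduces the system to a
    quadratic in the remaining pair. The physical root is selected by
    µ_b > 0, C's > 0 and C₁ < C₂; both candidate roots are reported under
    ``diagnostics["roots"]``.

    Returns ``{"mu_b": ..., "C1": ..., "C2": ..., "diagnostics": {...}}``.
    """
    _check_rates(lam1, lam2)
    if lam1 < lam2:
        lam1, lam2 = lam2, lam1
    known = [v is not None for v in (mu_b, C1, C2)]
    if sum(known) != 1:
        raise InvalidInputError(
            "exactly one of mu_b, C1, C2 must be supplied"
        )
    r1, r3 = _unit_resistances(geom)
    S, P = lam1 + lam2, lam1 * lam2
    k = 1.0 + (geom.l1 / geom.l2) * CF0
    # µ_b²·C₁·C₂ = CF₀ / (r1·r3·P)  — viscosity-independent constant
    M = CF0 / (r1 * r3 * P)

    def _quad(qa, qb, qc):
        disc = qb * qb - 4.0 * qa * qc
        if disc < 0:
            raise NonIdentifiableError(
                f"no real solution (discriminant {disc:.3g})"
            )
        sq = np.sqrt(disc)
        return (-qb - sq) / (2.0 * qa), (-qb + sq) / (2.0 * qa)

    candidates: list[dict] = []
    if mu_b is not None:
        if mu_b <= 0:
            raise InvalidInputError("mu_b must be > 0")
        pi = M / (mu_b * mu_b)
        sigma = S * (mu_b * r1) * pi
        for c1 in _quad(k, -sigma, pi):
            candidates.append({"mu_b": mu_b, "C1": c1,
                               "C2": pi / c1 if c1 != 0 else np.inf})
    elif C1 is not None:
        if C1 <= 0:
            raise InvalidInputError("C1 must be > 0")
        # k·C₁·µ² − S·r1·M·µ + M/C₁ = 0
        for mu in _quad(k * C1, -S * r1 * M, M / C1):
            candidates.append(
                {"mu_b": mu, "C1": C1,
                 "C2": M / (C1 * mu * mu) if mu != 0 else np.inf}
            )
    else:
        if C2 <= 0:
            raise InvalidInputError("C2 must be > 0")
        # C₂·µ² − S·r1·M·µ + k·M/C₂ = 0
        for mu in _quad(C2, -S * r1 * M, k * M / C2):
            candidates.append(
                {"mu_b": mu, "C1": M / (C2 * mu * mu) if mu != 0 else np.inf,
                 "C2": C2}
            )

    physical = [
        c
        for c in candidates
        if c["mu_b"] > 0 and 0 < c["C1"] < c["C2"] < np.inf
    ]
    if not physical:
        raise ModelInconsistencyError(
            f"no root satisfies mu_b > 0 and 0 < C1 < C2; candidates: "
            f"{candidates}"
        )
    best = physical[0]
    return {
        "mu_b": float(best["mu_b"]),
        "C1": float(best["C1"]),
        "C2": float(best["C2"]),
        "diagnostics": {"roots": candidates, "n_physical": len(physical)},
    }


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def analyze_experiment(
    series: InterfaceSeries,
    setup: AnalysisSetup,
) -> ViscoelasticResult:
    """Full inverse pipeline over one recording.

    Per on/off cycle: steady window mean → viscosity (full CF polynomial) →
    two-exponential fit of the off-phase transient → compliance inversion
    using the just-estimated viscosity and CF₀. Cycles are fitted
    independently; the result carries per-cycle values and across-cycle
    mean ± sd (no outlier rejection). Stage failures are re-raised as
    :class:`PipelineStageError` naming the stage.
    """
    program = setup.program or series.program
    if program is None:
        raise InvalidInputError(
            "a flow program is required (in setup or attached to the series)"
        )

    try:
        windows = select_steady_window(
            series, program, n=setup.n_steady, settle_s=setup.settle_s
        )
    except Exception as exc:
        raise PipelineStageError("select_steady_window", exc) from exc

    cycles: list[CycleResult] = []
    failures: list[str] = []
    for k, idx in enumerate(windows):
        a = series.alpha[idx]
        summary = SteadyWindowSummary(
            alpha_mean=float(np.mean(a)),
            alpha_sd=float(np.std(a, ddof=1)) if a.size > 1 else 0.0,
            n=int(a.size),
            t_start=float(series.times[idx[0]]),
            t_end=float(series.times[idx[-1]]),
        )
        try:
            mu_b = steady_viscosity(
                summary.alpha_mean,
                program.Qr,
                program.Q0,
                setup.mu_r,
                setup.cf_model,
            )
        except Exception as exc:
            raise PipelineStageError("steady_viscosity", exc) from exc

        t_off = k * program.T_s + program.t_on
        t_cycle_end = (k + 1) * program.T_s
        try:
            fit = two_exponential_fit(series, t_off, t_end=t_cycle_end)
        except Exception as exc:
            raise PipelineStageError("two_exponential_fit", exc) from exc

        try:
            c1, c2 = compliances_from_eigenvalues(
                fit.lambda1,
                fit.lambda2,
                mu_b,
                setup.geometry,
                setup.mu_r,
                setup.cf0,
            )
        except Exception as exc:
            raise PipelineStageError(
                "compliances_from_eigenvalues", exc
            ) from exc
        cycles.append(
            CycleResult(cycle=k, mu_b=mu_b, C1=c1, C2=c2,
                        steady=summary, eigenfit=fit)
        )

    mu = np.array([c.mu_b for c in cycles])
    c1s = np.array([c.C1 for c in cycles])
    c2s = np.array([c.C2 for c in cycles])

    def _sd(x):
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    return ViscoelasticResult(
        mu_b=float(mu.mean()),
        C1=float(c1s.mean()),
        C2=float(c2s.mean()),
        mu_b_sd=_sd(mu),
        C1_sd=_sd(c1s),
        C2_sd=_sd(c2s),
        n_cycles=len(cycles),
        cycles=cycles,
        diagnostics={"failures": failures, "cf0": setup.cf0},
    )
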