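"""Extended model: adaptation loop plus a mutually repressive, self-activating
downstream target Y.

The adaptation loop keeps Her6 (h) at h* for any slow input change.  The
extension adds a target Y that Her6 represses and that represses Her6 back
while activating itself:

    dh/dt = alpha_h G(m) G(X) G-(Y; y_on_h)                       - mu_h h
    dX/dt = alpha_X G(m)                                          - mu_X X
    dY/dt = (alpha_Y + beta_Y G+(Y; y_self)) G-(h; h_on_y)        - mu_Y Y

with G(x) = 1/x and Hill functions G+(p) = p^n/(p0^n + p^n),
G-(p) = p0^n/(p0^n + p^n) = 1 - G+(p).

While h sits at its high adapted state h*, Y is repressed to a low level and
the system behaves like the basic loop.  A sufficiently large and fast (fold)
increase of m drives h transiently deep enough, for long enough, that Y's
production gate opens, Y self-activates past its unstable branch, and the
mutual repression latches: h settles into a new low steady state and stays
there even though the adaptation loop alone would have recovered (an
irreversible, hysteretic switch).  Slow ramps never produce a deep transient,
so the switch discriminates step-like from gradual input profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .adaptation import (
    BasicModelParameters,
    DomainError,
    IntegrationError,
    SolverSettings,
    Trajectory,
    integrate_piecewise,
    steady_state_h,
    steady_state_X,
)
from .profiles import InputProfile, make_steps

__all__ = [
    "HillSpec",
    "ExtendedModelParameters",
    "FixedPoint",
    "OutcomeReport",
    "FeasibilityReport",
    "hill_activating",
    "hill_repressing",
    "rhs_extended",
    "jacobian_extended",
    "y_subsystem_fixed_points",
    "full_fixed_points",
    "simulate_extended",
    "classify_outcome",
    "find_switching_threshold",
    "check_parameter_feasibility",
    "reference_extended_parameters",
    "sample_feasible_parameters",
]


@dataclass(frozen=True)
class HillSpec:
    """Hill coefficient n (>= 1) and threshold p0 (> 0) of one interaction."""

    n: float
    p0: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("Hill coefficient must be >= 1")
        if self.p0 <= 0:
            raise DomainError("Hill threshold must be > 0")


def hill_activating(p, spec: HillSpec):
    """G+(p) = p^n / (p0^n + p^n): 0 at p=0, 1/2 at p=p0, -> 1 for p >> p0."""
    if isinstance(p, (float, int)):  # fast scalar path (hot in ODE callbacks)
        if p < 0:
            raise DomainError("Hill input must be >= 0")
        r = (p / spec.p0) ** spec.n
        return r / (1.0 + r)
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise DomainError("Hill input must be >= 0")
    r = (p / spec.p0) ** spec.n
    return r / (1.0 + r)


def hill_repressing(p, spec: HillSpec):
    """G-(p) = p0^n / (p0^n + p^n) = 1 - G+(p): 1 at p=0, -> 0 for p >> p0."""
    if isinstance(p, (float, int)):
        if p < 0:
            raise DomainError("Hill input must be >= 0")
        r = (p / spec.p0) ** spec.n
        return 1.0 / (1.0 + r)
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise DomainError("Hill input must be >= 0")
    r = (p / spec.p0) ** spec.n
    return 1.0 / (1.0 + r)


def _hill_activating_deriv(p: float, spec: HillSpec) -> float:
    """d G+ / dp, finite for p >= 0 (n >= 1)."""
    if p == 0.0:
        return 1.0 / spec.p0 if spec.n == 1 else 0.0
    r = (p / spec.p0) ** spec.n
    return spec.n * r / (p * (1.0 + r) ** 2)


@dataclass(frozen=True)
class ExtendedModelParameters:
    """Basic-loop rates plus the Y branch.

    hill_Y_on_h: repression of Her6 by Y; its threshold is the parameter p1
    which sets the depth of the low Her6 state.
    hill_h_on_Y: repression of Y production by Her6 (gates the escape).
    hill_Y_self: self-activation of Y (needs n > 1 for bistability).
    """

    basic: BasicModelParameters
    alpha_Y: float
    beta_Y: float
    mu_Y: float
    hill_Y_on_h: HillSpec
    hill_h_on_Y: HillSpec
    hill_Y_self: HillSpec
    gate_basal_only: bool = False

    def __post_init__(self) -> None:
        if self.alpha_Y <= 0 or self.mu_Y <= 0:
            raise DomainError("alpha_Y and mu_Y must be > 0")
        if self.beta_Y < 0:
            raise DomainError("beta_Y must be >= 0")

    def y_production(self, h: float, Y: float) -> float:
        """Production term of Y; by default Her6 gates both the basal and the
        self-activated production (gate_basal_only switches to gating the
        basal term only)."""
        gate = hill_repressing(h, self.hill_h_on_Y)
        auto = self.beta_Y * hill_activating(Y, self.hill_Y_self)
        if self.gate_basal_only:
            return self.alpha_Y * gate + auto
        return (self.alpha_Y + auto) * gate


def rhs_extended(state, t: float, params: ExtendedModelParameters, profile: InputProfile):
    """(dh/dt, dX/dt, dY/dt); h, X, m strictly positive, Y >= 0."""
    h, X, Y = float(state[0]), float(state[1]), float(state[2])
    if h <= 0 or X <= 0 or Y < 0:
        raise DomainError("extended model requires h > 0, X > 0, Y >= 0")
    m = float(profile(t))
    if m <= 0:
        raise DomainError("input m(t) must be > 0")
    b = params.basic
    dh = (
        b.alpha_h
        * (1.0 / m)
        * (1.0 / X)
        * hill_repressing(Y, params.hill_Y_on_h)
        - b.mu_h * h
    )
    dX = b.alpha_X * (1.0 / m) - b.mu_X * X
    dY = params.y_production(h, Y) - params.mu_Y * Y
    return np.array([dh, dX, dY])


def jacobian_extended(state, m: float, params: ExtendedModelParameters) -> np.ndarray:
    """Closed-form Jacobian of the extended right-hand side w.r.t. (h, X, Y)."""
    h, X, Y = float(state[0]), float(state[1]), float(state[2])
    b = params.basic
    RY = hill_repressing(Y, params.hill_Y_on_h)
    dRY = -_hill_activating_deriv(Y, params.hill_Y_on_h)
    Sh = hill_repressing(h, params.hill_h_on_Y)
    dSh = -_hill_activating_deriv(h, params.hill_h_on_Y)
    A = hill_activating(Y, params.hill_Y_self)
    dA = _hill_activating_deriv(Y, params.hill_Y_self)

    J = np.zeros((3, 3))
    J[0, 0] = -b.mu_h
    J[0, 1] = -b.alpha_h * RY / (m * X * X)
    J[0, 2] = b.alpha_h * dRY / (m * X)
    J[1, 1] = -b.mu_X
    if params.gate_basal_only:
        J[2, 0] = params.alpha_Y * dSh
        J[2, 2] = params.beta_Y * dA - params.mu_Y
    else:
        J[2, 0] = (params.alpha_Y + params.beta_Y * A) * dSh
        J[2, 2] = params.beta_Y * dA * Sh - params.mu_Y
    return J


# ---------------------------------------------------------------------------
# fixed points


@dataclass(frozen=True)
class FixedPoint:
    state: tuple[float, float, float]
    stable: bool
    leading_eigenvalue_real: float


def _y_residual(params: ExtendedModelParameters, h: float):
    def r(Y: float) -> float:
        return params.y_production(h, Y) - params.mu_Y * Y

    return r


def _bracketed_roots(fun, lo: float, hi: float, n_scan: int) -> list[float]:
    """Roots of a scalar function located by sign-change scan + brentq."""
    ys = np.linspace(lo, hi, n_scan)
    try:  # residuals are numpy-vectorisable; fall back to a scalar loop
        vals = np.asarray(fun(ys), dtype=float)
        if vals.shape != ys.shape:
            raise TypeError
    except (TypeError, ValueError):
        vals = np.array([fun(y) for y in ys])
    roots: list[float] = []
    sign_change = np.nonzero(vals[:-1] * vals[1:] < 0)[0]
    for i in np.nonzero(vals == 0.0)[0]:
        roots.append(float(ys[i]))
    for i in sign_change:
        roots.append(float(brentq(fun, ys[i], ys[i + 1], xtol=1e-13, rtol=1e-14)))
    roots.sort()
    # deduplicate near-identical roots
    out: list[float] = []
    for r in roots:
        if not out or abs(r - out[-1]) > 1e-9 * max(1.0, abs(r)):
            out.append(r)
    return out


def y_subsystem_fixed_points(
    params: ExtendedModelParameters, h_clamped: float, *, n_scan: int = 2001
) -> list[tuple[float, bool]]:
    """Roots of the Y dynamics with Her6 clamped, with stability labels.

    Scans [0, Y_max] where Y_max bounds the largest possible steady Y; the
    bracket is widened once before giving up.
    """
    if h_clamped < 0:
        raise DomainError("h_clamped must be >= 0")
    r = _y_residual(params, h_clamped)
    y_max = 1.2 * (params.alpha_Y + params.beta_Y) / params.mu_Y + 1e-9
    for _ in range(2):
        roots = _bracketed_roots(r, 0.0, y_max, n_scan)
        if roots and r(y_max) < 0:
            break
        y_max *= 4.0
    else:
        raise IntegrationError("could not bracket the Y fixed points")
    out = []
    eps = 1e-7 * max(1.0, y_max)
    for root in roots:
        slope = (r(root + eps) - r(max(root - eps, 0.0))) / (
            root + eps - max(root - eps, 0.0)
        )
        out.append((root, bool(slope < 0)))
    return out


def full_fixed_points(
    params: ExtendedModelParameters, m: float, *, n_scan: int = 4001
) -> list[FixedPoint]:
    """All fixed points of the coupled (h, X, Y) system at constant input m.

    Substitutes X*(m) and uses the exact identity G(m) G(X*(m)) = mu_X/alpha_X
    (so h at a fixed point is h* G-(Y) and the problem reduces to one scalar
    equation in Y).  Stability comes from the eigenvalues of the analytic
    Jacobian.
    """
    if m <= 0:
        raise DomainError("m must be > 0")
    b = params.basic
    hstar = steady_state_h(b)
    Xstar = steady_state_X(b, m)

    def h_of_Y(Y: float) -> float:
        return hstar * hill_repressing(Y, params.hill_Y_on_h)

    def F(Y: float) -> float:
        return params.y_production(h_of_Y(Y), Y) - params.mu_Y * Y

    y_max = 1.2 * (params.alpha_Y + params.beta_Y) / params.mu_Y + 1e-9
    roots = _bracketed_roots(F, 0.0, y_max, n_scan)
    if not roots:
        raise IntegrationError("no fixed point found; parameters invalid")
    points = []
    for Y in roots:
        state = (h_of_Y(Y), Xstar, Y)
        J = jacobian_extended(state, m, params)
        lead = float(np.max(np.linalg.eigvals(J).real))
        points.append(FixedPoint(state=state, stable=bool(lead < 0), leading_eigenvalue_real=lead))
    return points


def _high_state_fixed_point(params: ExtendedModelParameters, m: float) -> FixedPoint:
    """The stable fixed point with the highest h (the adapted branch)."""
    stable = [fp for fp in full_fixed_points(params, m) if fp.stable]
    if not stable:
        raise IntegrationError("no stable fixed point at the initial input")
    return max(stable, key=lambda fp: fp.state[0])


# ---------------------------------------------------------------------------
# simulation and outcome classification


def simulate_extended(
    params: ExtendedModelParameters,
    profile: InputProfile,
    t_grid: np.ndarray,
    init="steady",
    settings: SolverSettings = SolverSettings(),
) -> Trajectory:
    """Integrate the three-species system under an arbitrary positive input.

    init="steady" starts from the adapted (high-h) stable fixed point at
    m(t0); an explicit (h, X, Y) triple is also accepted.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if isinstance(init, str):
        if init != "steady":
            raise DomainError(f"unknown init {init!r}")
        y0 = np.array(_high_state_fixed_point(params, float(profile(t_grid[0]))).state)
    else:
        y0 = np.asarray(init, dtype=float)
        if y0.shape != (3,) or y0[0] <= 0 or y0[1] <= 0 or y0[2] < 0:
            raise DomainError("init must be 'steady' or (h>0, X>0, Y>=0)")

    b = params.basic

    def fun(t, y):
        # trial steps may probe slightly outside the domain; clamp locally
        # (accepted solutions are positivity-checked afterwards)
        h, X, Y = y
        m = profile(t)
        hc = h if h > 0 else 0.0
        Xc = X if X > 1e-300 else 1e-300
        Yc = Y if Y > 0 else 0.0
        dh = b.alpha_h * hill_repressing(Yc, params.hill_Y_on_h) / (m * Xc) - b.mu_h * h
        dX = b.alpha_X / m - b.mu_X * X
        dY = params.y_production(hc, Yc) - params.mu_Y * Y
        return [dh, dX, dY]

    def jac(t, y):
        yc = np.maximum(y, [0.0, 1e-300, 0.0])
        return jacobian_extended(yc, float(profile(t)), params)

    ys = integrate_piecewise(
        fun, t_grid, y0, profile, settings, jac=jac, positive_components=(0, 1)
    )
    # Y may dip to tiny negative values within solver tolerance; clamp
    Y = ys[:, 2]
    if np.any(Y < -100 * settings.atol):
        raise IntegrationError("Y underflowed below 0 beyond solver tolerance")
    return Trajectory(
        t=t_grid,
        m=np.asarray(profile(t_grid)),
        h=ys[:, 0],
        X=ys[:, 1],
        Y=np.clip(Y, 0.0, None),
    )


@dataclass(frozen=True)
class OutcomeReport:
    """Terminal classification of a trajectory.

    switched:  h settled below 0.5 h* with Y above the unstable branch.
    adapted:   h settled within 5% of h* with Y below the unstable branch.
    undecided: anything else (including unsettled trajectories).
    """

    classification: str
    final_h_relative: float
    max_transient_deviation: float
    final_Y: float


def classify_outcome(traj: Trajectory, params: ExtendedModelParameters) -> OutcomeReport:
    if traj.Y is None:
        raise DomainError("classification needs an extended-model trajectory")
    hstar = steady_state_h(params.basic)
    rel = np.abs(traj.h - hstar) / hstar
    final_h_rel = float(traj.h[-1] / hstar)
    final_Y = float(traj.Y[-1])
    report = lambda c: OutcomeReport(  # noqa: E731
        classification=c,
        final_h_relative=final_h_rel,
        max_transient_deviation=float(rel.max()),
        final_Y=final_Y,
    )
    # settled? |dh/dt| at the end below 1e-6 h* per hour (finite difference)
    dh_dt = abs(traj.h[-1] - traj.h[-2]) / (traj.t[-1] - traj.t[-2])
    if dh_dt >= 1e-6 * hstar:
        warnings.warn("trajectory has not settled; classification undecided")
        return report("undecided")
    fps = full_fixed_points(params, float(traj.m[-1]))
    unstable = [fp.state[2] for fp in fps if not fp.stable]
    if unstable:
        y_sep = min(unstable)
    else:
        # monostable at the final input: fall back on the self-activation
        # threshold as the only meaningful scale separating low from high Y
        y_sep = params.hill_Y_self.p0
    if final_h_rel < 0.5 and final_Y > y_sep:
        return report("switched")
    if abs(final_h_rel - 1.0) < 0.05 and final_Y < y_sep:
        return report("adapted")
    return report("undecided")


def find_switching_threshold(
    params: ExtendedModelParameters,
    m0: float,
    fold_range: tuple[float, float] = (1.05, 100.0),
    *,
    step_time: float = 20.0,
    t_end: float = 200.0,
    settings: SolverSettings = SolverSettings(),
    rel_tol: float = 1e-3,
) -> float:
    """Smallest single-step fold change of m that flips the switch.

    Simulates a step m0 -> fold*m0 at step_time, classifies the settled
    outcome and bisects on the fold to relative tolerance rel_tol.  Raises if
    the bracket does not straddle the transition.
    """
    lo, hi = fold_range
    if not 0 < lo < hi:
        raise DomainError("need 0 < lo < hi in fold_range")

    def outcome(fold: float) -> str:
        profile = make_steps(m0, [(step_time, fold)], t0=0.0, t_end=t_end)
        t_grid = np.linspace(0.0, t_end, 600)
        traj = simulate_extended(params, profile, t_grid, settings=settings)
        return classify_outcome(traj, params).classification

    if outcome(lo) != "adapted" or outcome(hi) != "switched":
        raise DomainError(
            "fold_range does not straddle the switching threshold"
        )
    while (hi - lo) / lo > rel_tol:
        mid = np.sqrt(lo * hi)
        if outcome(mid) == "switched":
            hi = mid
        else:
            lo = mid
    return float(hi)


# ---------------------------------------------------------------------------
# feasibility


@dataclass(frozen=True)
class FeasibilityReport:
    """Pass/fail record of the three conditions the switch mechanism needs.

    c1_bistable_escape: the Y subsystem is bistable over some intermediate
        clamped Her6 level and loses its low root at h = 0 (monostable high),
        so a deep Her6 transient lets Y escape by self-activation.
    c2_repressed_at_hstar: at h = h*, Y has a unique stable low root and the
        full system's adapted fixed point sits within 5% of h*.
    c3_finite_threshold: a finite single-step switching fold exists in the
        scanned range.
    """

    c1_bistable_escape: bool
    c2_repressed_at_hstar: bool
    c3_finite_threshold: bool
    switching_threshold: float | None

    @property
    def passed(self) -> bool:
        return (
            self.c1_bistable_escape
            and self.c2_repressed_at_hstar
            and self.c3_finite_threshold
        )


def check_parameter_feasibility(
    params: ExtendedModelParameters,
    *,
    fold_range: tuple[float, float] = (1.01, 100.0),
    check_threshold: bool = True,
    settings: SolverSettings = SolverSettings(),
) -> FeasibilityReport:
    """Verify that a parameter set supports the adapted/switched dichotomy."""
    hstar = steady_state_h(params.basic)

    # C1: monostable high at h=0 ...
    at_zero = y_subsystem_fixed_points(params, 0.0)
    high_only = (
        len(at_zero) == 1
        and at_zero[0][1]
        and at_zero[0][0] > params.hill_Y_self.p0
    )
    # ... and bistable (three roots) for some intermediate clamped h
    bistable_somewhere = False
    if high_only:
        for h in np.linspace(0.01 * hstar, hstar, 100):
            roots = y_subsystem_fixed_points(params, h)
            if len(roots) == 3:
                bistable_somewhere = True
                break
    c1 = bool(high_only and bistable_somewhere)

    at_hstar = y_subsystem_fixed_points(params, hstar)
    c2 = (
        len(at_hstar) == 1
        and at_hstar[0][1]
        and at_hstar[0][0] < params.hill_Y_self.p0
    )
    if c2:
        try:
            high = _high_state_fixed_point(params, 1.0)
            c2 = abs(high.state[0] / hstar - 1.0) < 0.05
        except IntegrationError:
            c2 = False
    c2 = bool(c2)

    threshold = None
    c3 = False
    if check_threshold and c1 and c2:
        try:
            threshold = find_switching_threshold(
                params, 1.0, fold_range, settings=settings
            )
            c3 = True
        except (DomainError, IntegrationError):
            threshold = None
            c3 = False
    return FeasibilityReport(
        c1_bistable_escape=c1,
        c2_repressed_at_hstar=c2,
        c3_finite_threshold=c3,
        switching_threshold=threshold,
    )


# ---------------------------------------------------------------------------
# reference parameters


def reference_basic_parameters() -> BasicModelParameters:
    """Shipped reference rates for the adaptation loop (h* = 1)."""
    return BasicModelParameters(alpha_h=2.0, mu_h=2.0, alpha_X=0.3, mu_X=0.3)


def reference_extended_parameters() -> ExtendedModelParameters:
    """Shipped reference parameter set; passes check_parameter_feasibility."""
    return ExtendedModelParameters(
        basic=reference_basic_parameters(),
        alpha_Y=1.0,
        beta_Y=4.0,
        mu_Y=2.0,
        hill_Y_on_h=HillSpec(n=4.0, p0=0.5),
        hill_h_on_Y=HillSpec(n=4.0, p0=0.5),
        hill_Y_self=HillSpec(n=4.0, p0=0.7),
    )


def sample_feasible_parameters(
    rng: np.random.Generator,
    n: int,
    *,
    spread: float = 0.2,
    check_threshold: bool = False,
    max_tries: int = 500,
) -> list[ExtendedModelParameters]:
    """Random parameter sets near the reference that keep the switch feasible.

    Each rate and threshold is jittered log-uniformly within +/- ``spread``
    (relative); draws failing the fixed-point feasibility conditions are
    rejected.
    """
    ref = reference_extended_parameters()
    out: list[ExtendedModelParameters] = []
    tries = 0
    while len(out) < n and tries < max_tries:
        tries += 1
        j = lambda x: float(x * np.exp(rng.uniform(np.log(1 - spread), np.log(1 + spread))))  # noqa: E731
        cand = ExtendedModelParameters(
            basic=BasicModelParameters(
                alpha_h=j(ref.basic.alpha_h),
                mu_h=j(ref.basic.mu_h),
                alpha_X=j(ref.basic.alpha_X),
                mu_X=j(ref.basic.mu_X),
            ),
            alpha_Y=j(ref.alpha_Y),
            beta_Y=j(ref.beta_Y),
            mu_Y=j(ref.mu_Y),
            hill_Y_on_h=HillSpec(n=ref.hill_Y_on_h.n, p0=j(ref.hill_Y_on_h.p0)),
            hill_h_on_Y=HillSpec(n=ref.hill_h_on_Y.n, p0=j(ref.hill_h_on_Y.p0)),
            hill_Y_self=HillSpec(n=ref.hill_Y_self.n, p0=j(ref.hill_Y_self.p0)),
        )
        rep = check_parameter_feasibility(cand, check_threshold=check_threshold)
        ok = rep.c1_bistable_escape and rep.c2_repressed_at_hstar
        if check_threshold:
            ok = ok and rep.c3_finite_threshold
        if ok:
            out.append(cand)
    if len(out) < n:
        raise IntegrationError(f"only found {len(out)}/{n} feasible draws")
    return out
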