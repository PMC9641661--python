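"""Perfect-adaptation incoherent feed-forward loop for Her6.

miR-9 (input m) represses Her6 production directly and also represses an
intermediate repressor X which itself represses Her6 production; with the
repression function G(x) = 1/x the direct and indirect arms cancel exactly at
steady state:

    dh/dt = alpha_h * G(m) * G(X) - mu_h * h
    dX/dt = alpha_X * G(m)        - mu_X * X

so  X*(m) = alpha_X / (mu_X * m)  and

    h* = alpha_h * mu_X / (mu_h * alpha_X)

is independent of the input level m (perfect adaptation).  Transients after a
change in m exist because X responds with its own timescale 1/mu_X; the model
responds to fold changes of m only (an exact symmetry: rescaling m by c and
X by 1/c leaves the h dynamics unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .profiles import InputProfile

__all__ = [
    "DomainError",
    "IntegrationError",
    "BasicModelParameters",
    "SolverSettings",
    "Trajectory",
    "AdaptationMetrics",
    "repression_G",
    "steady_state_h",
    "steady_state_X",
    "rhs_basic",
    "simulate_basic",
    "adaptation_metrics",
]


class DomainError(ValueError):
    """State or input outside the model's domain (positivity violated)."""


class IntegrationError(RuntimeError):
    """Numerical integration failed or produced an invalid state."""


@dataclass(frozen=True)
class BasicModelParameters:
    """Production/degradation rates of the adaptation loop (all > 0)."""

    alpha_h: float
    mu_h: float
    alpha_X: float
    mu_X: float

    def __post_init__(self) -> None:
        for name in ("alpha_h", "mu_h", "alpha_X", "mu_X"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class SolverSettings:
    """Integration tolerances; the 1/x nonlinearity is stiff near small X."""

    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = np.inf

    def __post_init__(self) -> None:
        if self.rtol <= 0 or self.atol <= 0:
            raise DomainError("solver tolerances must be > 0")
        if self.max_step <= 0:
            raise DomainError("max_step must be > 0")


@dataclass
class Trajectory:
    """Simulated time course on a user grid (Y present for the extended model)."""

    t: np.ndarray
    m: np.ndarray
    h: np.ndarray
    X: np.ndarray
    Y: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("m", "h", "X"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.t.shape:
                raise DomainError(f"{name} must match the time grid length")
            setattr(self, name, arr)
        if self.Y is not None:
            self.Y = np.asarray(self.Y, dtype=float)
            if self.Y.shape != self.t.shape:
                raise DomainError("Y must match the time grid length")
        if np.any(np.diff(self.t) <= 0):
            raise DomainError("time grid must be strictly increasing")
        cols = [self.m, self.h, self.X] + ([self.Y] if self.Y is not None else [])
        for arr in cols:
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise DomainError("state values must be finite and >= 0")

    def to_frame(self):
        import pandas as pd

        data = {"time": self.t, "m": self.m, "h": self.h, "X": self.X}
        if self.Y is not None:
            data["Y"] = self.Y
        return pd.DataFrame(data)


def repression_G(x):
    """Repression function G(x) = 1/x (domain x > 0)."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise DomainError("G(x) = 1/x requires x > 0")
    out = 1.0 / arr
    return float(out) if arr.ndim == 0 else out


def steady_state_h(params: BasicModelParameters) -> float:
    """h* = alpha_h mu_X / (mu_h alpha_X); independent of the input m."""
    return params.alpha_h * params.mu_X / (params.mu_h * params.alpha_X)


def steady_state_X(params: BasicModelParameters, m: float) -> float:
    """X*(m) = alpha_X / (mu_X m)."""
    if m <= 0:
        raise DomainError("m must be > 0")
    return params.alpha_X / (params.mu_X * m)


def rhs_basic(state, t: float, params: BasicModelParameters, profile: InputProfile):
    """(dh/dt, dX/dt) at the given state and time."""
    h, X = float(state[0]), float(state[1])
    if h <= 0 or X <= 0:
        raise DomainError("basic model requires h > 0 and X > 0")
    m = float(profile(t))
    if m <= 0:
        raise DomainError("input m(t) must be > 0")
    dh = params.alpha_h * (1.0 / m) * (1.0 / X) - params.mu_h * h
    dX = params.alpha_X * (1.0 / m) - params.mu_X * X
    return np.array([dh, dX])


# ---------------------------------------------------------------------------
# integration machinery shared with the extended model


def integrate_piecewise(
    fun: Callable,
    t_grid: np.ndarray,
    y0: np.ndarray,
    profile: InputProfile,
    settings: SolverSettings,
    jac: Callable | None = None,
    positive_components: Sequence[int] = (),
) -> np.ndarray:
    """Integrate an ODE on t_grid, restarting at input discontinuities.

    Returns the state sampled on t_grid (first row equals y0).  Raises
    IntegrationError on solver failure or if any component listed in
    positive_components reaches <= 0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 2 or np.any(np.diff(t_grid) <= 0):
        raise DomainError("t_grid must be strictly increasing with >= 2 points")
    t0, t1 = t_grid[0], t_grid[-1]
    if profile.t_start > t0 + 1e-9:
        raise DomainError("profile does not cover the start of t_grid")

    max_step = settings.max_step
    if profile.noise is not None and profile.noise.amplitude > 0:
        # resolve the fluctuation path
        max_step = min(max_step, profile.noise.correlation_time / 2.0)

    bps = profile.breakpoints()
    bps = bps[(bps > t0) & (bps < t1)]
    legs = np.concatenate([[t0], bps, [t1]])
    out = np.empty((t_grid.size, y0.size))
    out[0] = y0
    y = np.asarray(y0, dtype=float)
    for a, b in zip(legs[:-1], legs[1:]):
        mask = (t_grid > a) & (t_grid <= b)
        t_eval = np.unique(np.concatenate([t_grid[mask], [b]]))
        sol = solve_ivp(
            fun,
            (a, b),
            y,
            method="LSODA",
            t_eval=t_eval,
            rtol=settings.rtol,
            atol=settings.atol,
            max_step=max_step,
            jac=jac,
        )
        if not sol.success:
            raise IntegrationError(f"solver failed on [{a}, {b}]: {sol.message}")
        ys = sol.y.T
        for idx in positive_components:
            if np.any(ys[:, idx] <= 0):
                raise IntegrationError(
                    f"state component {idx} underflowed to <= 0 on [{a}, {b}]"
                )
        sel = np.isin(t_eval, t_grid[mask])
        out[mask] = ys[sel]
        y = ys[-1]
    return out


def _resolve_basic_init(init, params, profile, t0) -> np.ndarray:
    if isinstance(init, str):
        if init != "steady":
            raise DomainError(f"unknown init {init!r}")
        m0 = float(profile(t0))
        return np.array([steady_state_h(params), steady_state_X(params, m0)])
    y0 = np.asarray(init, dtype=float)
    if y0.shape != (2,) or np.any(y0 <= 0):
        raise DomainError("init must be 'steady' or a positive (h, X) pair")
    return y0


def simulate_basic(
    params: BasicModelParameters,
    profile: InputProfile,
    t_grid: np.ndarray,
    init="steady",
    settings: SolverSettings = SolverSettings(),
) -> Trajectory:
    """Integrate the adaptation loop under an arbitrary positive input."""
    t_grid = np.asarray(t_grid, dtype=float)
    y0 = _resolve_basic_init(init, params, profile, t_grid[0])

    ah, mh, aX, mX = params.alpha_h, params.mu_h, params.alpha_X, params.mu_X

    def fun(t, y):
        # trial steps may probe X <= 0; clamp locally (accepted solutions
        # are positivity-checked afterwards)
        h, X = y
        m = profile(t)
        Xc = X if X > 1e-300 else 1e-300
        return [ah / (m * Xc) - mh * h, aX / m - mX * X]

    def jac(t, y):
        h, X = y
        m = profile(t)
        Xc = X if X > 1e-300 else 1e-300
        return [[-mh, -ah / (m * Xc * Xc)], [0.0, -mX]]

    ys = integrate_piecewise(
        fun, t_grid, y0, profile, settings, jac=jac, positive_components=(0, 1)
    )
    return Trajectory(t=t_grid, m=np.asarray(profile(t_grid)), h=ys[:, 0], X=ys[:, 1])


@dataclass(frozen=True)
class AdaptationMetrics:
    """Deviation of h from h* along a trajectory.

    recovery_time is measured from the last change of the input: the first
    time after it at which |h - h*|/h* drops below 1% and stays below; inf if
    the trajectory never settles into the band.
    """

    max_relative_deviation: float
    final_relative_deviation: float
    recovery_time: float


def adaptation_metrics(traj: Trajectory, params) -> AdaptationMetrics:
    """Quantify how perfectly h adapts along a trajectory.

    ``params`` may be basic or extended parameters (the reference level is
    always the basic-model h*).
    """
    hstar = steady_state_h(getattr(params, "basic", params))
    rel = np.abs(traj.h - hstar) / hstar
    # last input change, read off the m column
    m_final = traj.m[-1]
    scale = max(abs(m_final), np.max(np.abs(traj.m)))
    changed = np.abs(traj.m - m_final) > 1e-9 * scale
    if np.any(changed):
        t_change = traj.t[np.max(np.nonzero(changed))]
    else:
        t_change = traj.t[0]
    after = traj.t >= t_change
    idx_after = np.nonzero(after)[0]
    below = rel[idx_after] < 0.01
    recovery = np.inf
    # first index after t_change from which the band holds to the end
    ok = np.flip(np.cumprod(np.flip(below))).astype(bool)
    if ok.any():
        recovery = float(traj.t[idx_after[np.argmax(ok)]] - t_change)
    return AdaptationMetrics(
        max_relative_deviation=float(rel.max()),
        final_relative_deviation=float(rel[-1]),
        recovery_time=recovery,
    )
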