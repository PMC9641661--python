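"""miR-9 input profiles m(t).

The models treat mature miR-9 as a pre-defined, strictly positive input
``m(t)``.  Profiles are piecewise constant/linear deterministic curves with an
optional multiplicative log-scale fluctuation term, so that ``m(t) > 0`` holds
by construction for every time and every seed.

Conventions
-----------
* Segments tile a contiguous interval ``[t0, tN]`` with no gaps or overlaps.
* Piecewise-constant steps are left-continuous in the sense that the *new*
  value applies exactly at the step time (the value changes AT the step).
* Evaluation outside ``[t0, tN]`` clamps to the boundary value, so a profile
  can be fed to a simulation that runs past its last defined segment (the
  input is then held at its final value).
* Fluctuations are a stationary mean-reverting (Ornstein-Uhlenbeck) process
  ``eta(t)`` applied as ``m(t) = base(t) * exp(eta(t))``; the stationary
  standard deviation of ``eta`` equals the requested amplitude.  For a fixed
  seed the sampled path is a pure deterministic function of ``t``.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ProfileError",
    "NoiseSpec",
    "InputProfile",
    "make_constant",
    "make_linear",
    "make_steps",
    "make_fluctuating",
    "from_samples",
]


class ProfileError(ValueError):
    """Invalid input-profile construction or evaluation."""


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative log-scale fluctuation settings.

    amplitude
        Stationary standard deviation of ``log m`` fluctuations
        (dimensionless relative scale).
    correlation_time
        Autocorrelation time of the fluctuations, hours.
    seed
        Integer seed; identical seeds give bit-identical paths.
    """

    amplitude: float
    correlation_time: float
    seed: int

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ProfileError("noise amplitude must be >= 0")
        if self.correlation_time <= 0:
            raise ProfileError("noise correlation_time must be > 0")


# Internal OU grid: fine enough to resolve the correlation time but capped so
# pathological (tiny tau, huge window) requests stay bounded in memory.
_OU_POINTS_PER_TAU = 10
_OU_MAX_POINTS = 400_001


class InputProfile:
    """Strictly positive piecewise input profile ``m(t)``.

    Parameters
    ----------
    segments
        Iterable of ``(t_start, t_end, kind, start_value, end_value)`` with
        ``kind`` in ``{"constant", "linear"}``.  For constant segments the two
        values must agree.  Segments must tile a contiguous interval.
    noise
        Optional :class:`NoiseSpec`; applied multiplicatively on a log scale.
    continuous
        Marks the profile as containing no value discontinuities even if it
        has many segments (used by sampled profiles so integrators do not
        restart at every node).
    """

    def __init__(
        self,
        segments: Iterable[Sequence],
        noise: NoiseSpec | None = None,
        *,
        continuous: bool = False,
    ) -> None:
        segs = [tuple(s) for s in segments]
        if not segs:
            raise ProfileError("profile needs at least one segment")
        starts = np.array([float(s[0]) for s in segs])
        ends = np.array([float(s[1]) for s in segs])
        kinds = [str(s[2]) for s in segs]
        v0 = np.array([float(s[3]) for s in segs])
        v1 = np.array([float(s[4]) for s in segs])
        if np.any(ends <= starts):
            raise ProfileError("every segment needs t_start < t_end")
        if not np.allclose(starts[1:], ends[:-1], rtol=0, atol=1e-12):
            raise ProfileError("segments must tile a contiguous interval")
        for k in kinds:
            if k not in ("constant", "linear"):
                raise ProfileError(f"unknown segment kind {k!r}")
        for i, k in enumerate(kinds):
            if k == "constant" and v0[i] != v1[i]:
                raise ProfileError("constant segment with differing values")
        if np.any(v0 <= 0) or np.any(v1 <= 0):
            raise ProfileError("profile values must be strictly positive")
        self._starts = starts
        self._starts_list = starts.tolist()
        self._ends = ends
        self._kinds = kinds
        self._v0 = v0
        self._v1 = v1
        self.noise = noise
        self._continuous = bool(continuous)
        self._ou_cache: tuple[np.ndarray, np.ndarray] | None = None
        self._ou_dt = math.nan

    # -- metadata ----------------------------------------------------------

    @property
    def t_start(self) -> float:
        return float(self._starts[0])

    @property
    def t_end(self) -> float:
        return float(self._ends[-1])

    @property
    def segments(self) -> list[tuple[float, float, str, float, float]]:
        return [
            (float(a), float(b), k, float(x), float(y))
            for a, b, k, x, y in zip(
                self._starts, self._ends, self._kinds, self._v0, self._v1
            )
        ]

    def breakpoints(self) -> np.ndarray:
        """Interior times where the profile value jumps.

        Integrators restart at these times so instantaneous steps are not
        smeared by adaptive step control.
        """
        if self._continuous:
            return np.empty(0)
        bps = []
        for i in range(len(self._starts) - 1):
            left = self._v1[i]
            right = self._v0[i + 1]
            if not np.isclose(left, right, rtol=1e-12, atol=0):
                bps.append(self._starts[i + 1])
        return np.asarray(bps, dtype=float)

    @property
    def last_change_time(self) -> float:
        """Last time at which the deterministic part of m(t) changes."""
        for i in range(len(self._starts) - 1, -1, -1):
            if self._kinds[i] == "linear" and self._v0[i] != self._v1[i]:
                return float(self._ends[i])
            if i > 0 and not np.isclose(self._v0[i], self._v1[i - 1], rtol=1e-12):
                return float(self._starts[i])
        return float(self._starts[0])

    # -- evaluation --------------------------------------------------------

    def _base(self, t: np.ndarray) -> np.ndarray:
        tc = np.clip(t, self.t_start, self.t_end)
        # value changes AT a boundary -> boundary time belongs to the later
        # segment (side="right" on segment starts)
        idx = np.searchsorted(self._starts, tc, side="right") - 1
        idx = np.clip(idx, 0, len(self._starts) - 1)
        a = self._starts[idx]
        b = self._ends[idx]
        lo = self._v0[idx]
        hi = self._v1[idx]
        with np.errstate(invalid="ignore"):
            frac = np.where(b > a, (tc - a) / (b - a), 0.0)
        return lo + (hi - lo) * frac

    def _ou_path(self) -> tuple[np.ndarray, np.ndarray]:
        """Sampled OU path on an internal grid, exact discretisation."""
        assert self.noise is not None
        if self._ou_cache is not None:
            return self._ou_cache
        tau = self.noise.correlation_time
        sigma = self.noise.amplitude
        span = self.t_end - self.t_start
        n = int(min(_OU_MAX_POINTS, max(2, round(span / tau * _OU_POINTS_PER_TAU) + 1)))
        tg = np.linspace(self.t_start, self.t_end, n)
        if sigma == 0.0:
            eta = np.zeros(n)
        else:
            rng = np.random.default_rng(self.noise.seed)
            dt = tg[1] - tg[0]
            rho = np.exp(-dt / tau)
            innov_sd = sigma * np.sqrt(1.0 - rho * rho)
            eta = np.empty(n)
            eta[0] = sigma * rng.standard_normal()
            shocks = rng.standard_normal(n - 1) * innov_sd
            for i in range(1, n):
                eta[i] = eta[i - 1] * rho + shocks[i - 1]
        self._ou_cache = (tg, eta)
        self._ou_dt = float(tg[1] - tg[0])
        return self._ou_cache

    def _eval_scalar(self, t: float) -> float:
        # fast path: called once per ODE right-hand-side evaluation
        t0, t1 = self._starts[0], self._ends[-1]
        tc = t0 if t < t0 else (t1 if t > t1 else t)
        idx = bisect_right(self._starts_list, tc) - 1
        if idx < 0:
            idx = 0
        lo = self._v0[idx]
        hi = self._v1[idx]
        if lo == hi:
            m = lo
        else:
            a = self._starts[idx]
            m = lo + (hi - lo) * (tc - a) / (self._ends[idx] - a)
        if self.noise is not None and self.noise.amplitude > 0:
            tg, eta = self._ou_path()
            # uniform internal grid -> direct index
            x = (tc - tg[0]) / self._ou_dt
            i = int(x)
            if i >= eta.size - 1:
                m *= math.exp(eta[-1])
            else:
                w = x - i
                m *= math.exp(eta[i] * (1.0 - w) + eta[i + 1] * w)
        return m

    def __call__(self, t) -> np.ndarray | float:
        """Evaluate m(t); scalar in, scalar out."""
        if isinstance(t, (float, int)):
            return self._eval_scalar(float(t))
        arr = np.asarray(t, dtype=float)
        if arr.ndim == 0:
            return self._eval_scalar(float(arr))
        m = self._base(arr)
        if self.noise is not None and self.noise.amplitude > 0:
            tg, eta = self._ou_path()
            m = m * np.exp(np.interp(np.clip(arr, tg[0], tg[-1]), tg, eta))
        return m

    # -- derived profiles --------------------------------------------------

    def scaled(self, c: float) -> "InputProfile":
        """Profile with every value multiplied by ``c > 0``."""
        if c <= 0:
            raise ProfileError("scale factor must be > 0")
        segs = [(a, b, k, c * x, c * y) for a, b, k, x, y in self.segments]
        return InputProfile(segs, noise=self.noise, continuous=self._continuous)

    def to_frame(self, t: np.ndarray):
        """Tabulate the profile as a (time, m) DataFrame."""
        import pandas as pd

        t = np.asarray(t, dtype=float)
        return pd.DataFrame({"time": t, "m": np.asarray(self(t))})


def make_constant(m0: float, t0: float, t1: float) -> InputProfile:
    """Constant profile m(t) = m0 on [t0, t1]."""
    if m0 <= 0:
        raise ProfileError("m0 must be > 0")
    if not t0 < t1:
        raise ProfileError("need t0 < t1")
    return InputProfile([(t0, t1, "constant", m0, m0)])


def make_linear(m0: float, m1: float, t0: float, t1: float) -> InputProfile:
    """Linear ramp from m0 at t0 to m1 at t1 (held at m1 if extended)."""
    if m0 <= 0 or m1 <= 0:
        raise ProfileError("ramp endpoints must be > 0")
    if not t0 < t1:
        raise ProfileError("need t0 < t1")
    kind = "constant" if m0 == m1 else "linear"
    return InputProfile([(t0, t1, kind, m0, m1)])


def make_steps(
    m0: float,
    steps: Sequence[tuple[float, float]],
    *,
    t0: float = 0.0,
    t_end: float | None = None,
) -> InputProfile:
    """Piecewise-constant profile: after the k-th step the value is
    ``m0 * prod(folds[:k])``.  The new value applies AT the step time.
    """
    if m0 <= 0:
        raise ProfileError("m0 must be > 0")
    times = [float(t) for t, _ in steps]
    folds = [float(f) for _, f in steps]
    if any(f <= 0 for f in folds):
        raise ProfileError("fold changes must be > 0")
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ProfileError("step times must be strictly increasing")
    if times and times[0] <= t0:
        raise ProfileError("first step must come after t0")
    if t_end is None:
        t_end = (times[-1] if times else t0) + 10.0
    if times and t_end <= times[-1]:
        raise ProfileError("t_end must lie after the last step")
    if t_end <= t0:
        raise ProfileError("need t0 < t_end")
    bounds = [t0, *times, t_end]
    vals = m0 * np.cumprod([1.0, *folds])
    segs = [
        (bounds[i], bounds[i + 1], "constant", vals[i], vals[i])
        for i in range(len(vals))
    ]
    return InputProfile(segs)


def make_fluctuating(
    base: InputProfile, amplitude: float, correlation_time: float, seed: int
) -> InputProfile:
    """Multiplicative log-scale mean-reverting fluctuations around ``base``."""
    if amplitude < 0:
        raise ProfileError("amplitude must be >= 0")
    noise = NoiseSpec(amplitude=amplitude, correlation_time=correlation_time, seed=int(seed))
    return InputProfile(base.segments, noise=noise, continuous=base._continuous)


def from_samples(t: np.ndarray, m: np.ndarray) -> InputProfile:
    """Continuous piecewise-linear profile through sampled (t, m) points.

    Used to feed simulated population-level miR-9 curves into the ODE models;
    the result is marked continuous, so integrators do not restart at nodes.
    """
    t = np.asarray(t, dtype=float)
    m = np.asarray(m, dtype=float)
    if t.ndim != 1 or t.size < 2 or m.shape != t.shape:
        raise ProfileError("need matching 1-d arrays with >= 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ProfileError("sample times must be strictly increasing")
    if np.any(m <= 0):
        raise ProfileError("sampled values must be strictly positive")
    segs = [
        (t[i], t[i + 1], "constant" if m[i] == m[i + 1] else "linear", m[i], m[i + 1])
        for i in range(t.size - 1)
    ]
    return InputProfile(segs, continuous=True)
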