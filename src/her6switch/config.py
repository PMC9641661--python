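"""Structured-text run configuration shared by the CLI and the experiments.

The format is INI-style ``key = value`` under named sections.  Every value is
validated against the owning type's invariants before any computation;
unknown sections or keys are an error (never silently ignored).  A parsed
configuration round-trips through :func:`serialize_config`.
"""

from __future__ import annotations

import configparser
import io as _io
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .adaptation import BasicModelParameters, DomainError, SolverSettings
from .extended import ExtendedModelParameters, HillSpec
from .locus import Locus, LocusActivationConfig

__all__ = [
    "ConfigError",
    "ProfileSpec",
    "LocusModelSpec",
    "ExperimentSettings",
    "RunConfig",
    "parse_config",
    "parse_config_text",
    "serialize_config",
    "load_reference_config",
]


class ConfigError(ValueError):
    """Malformed or invalid run configuration."""


@dataclass(frozen=True)
class ProfileSpec:
    """Reference miR-9 input profiles used by the experiments.

    The stepwise profile applies step1_fold at step1_time then step2_fold at
    step2_time; the matched linear profile ramps between the same start and
    end values over [ramp_start_time, ramp_end_time].  Both live on
    [0, t_end].
    """

    m0: float = 1.0
    step1_time: float = 20.0
    step1_fold: float = 1.5
    step2_time: float = 60.0
    step2_fold: float = 4.0
    ramp_start_time: float = 20.0
    ramp_end_time: float = 100.0
    t_end: float = 150.0

    def __post_init__(self) -> None:
        if self.m0 <= 0:
            raise ConfigError("profile.m0 must be > 0")
        if self.step1_fold <= 0 or self.step2_fold <= 0:
            raise ConfigError("profile step folds must be > 0")
        if not 0 < self.step1_time < self.step2_time < self.t_end:
            raise ConfigError("profile step times must satisfy 0 < t1 < t2 < t_end")
        if not 0 <= self.ramp_start_time < self.ramp_end_time <= self.t_end:
            raise ConfigError("profile ramp window must lie inside [0, t_end]")


@dataclass(frozen=True)
class LocusModelSpec:
    """Locus-activation generator settings plus pipeline extras.

    baseline is mature miR-9 from sources other than the modelled loci
    (keeps the model input strictly positive); late_locus names the locus
    removed in the knockout contrast; control_fit_stop closes the window over
    which the linearised control input is constructed; settle_time extends
    the model simulation past the developmental window so outcomes settle.
    """

    n_cells: int = 500
    loci: tuple[Locus, ...] = ()
    decay_rate: float = 1.0
    t_start: float = 24.0
    t_stop: float = 48.0
    dt: float = 0.01
    baseline: float = 1.0
    late_locus: str = "pri-mir-9-1"
    control_fit_stop: float = 42.0
    settle_time: float = 60.0

    def __post_init__(self) -> None:
        if self.baseline <= 0:
            raise ConfigError("locus_model.baseline must be > 0")
        if not self.t_start < self.t_stop:
            raise ConfigError("locus_model window must have t_start < t_stop")
        if self.dt <= 0:
            raise ConfigError("locus_model.dt must be > 0")
        if not self.t_start < self.control_fit_stop <= self.t_stop:
            raise ConfigError("control_fit_stop must lie inside the window")
        if self.settle_time < 0:
            raise ConfigError("settle_time must be >= 0")

    def activation_config(self, seed: int) -> LocusActivationConfig:
        return LocusActivationConfig(
            n_cells=self.n_cells,
            loci=list(self.loci),
            decay_rate=self.decay_rate,
            t_grid=np.arange(self.t_start, self.t_stop + 1e-9, self.dt),
            seed=seed,
        )


@dataclass(frozen=True)
class ExperimentSettings:
    fluctuation_amplitude: float = 0.2
    fluctuation_correlation_time: float = 1.0
    fluctuation_window: float = 100.0
    fluctuation_settle: float = 60.0
    n_seeds: int = 100
    p1_factors: tuple[float, ...] = (0.5, 0.75, 1.0, 1.25, 1.5)

    def __post_init__(self) -> None:
        if self.fluctuation_amplitude < 0:
            raise ConfigError("fluctuation_amplitude must be >= 0")
        if self.fluctuation_correlation_time <= 0:
            raise ConfigError("fluctuation_correlation_time must be > 0")
        if self.n_seeds < 1:
            raise ConfigError("n_seeds must be >= 1")
        if any(f <= 0 for f in self.p1_factors):
            raise ConfigError("p1_factors must be > 0")


@dataclass
class RunConfig:
    seed: int
    output_dir: str
    basic: BasicModelParameters
    extended: ExtendedModelParameters
    profile: ProfileSpec
    locus: LocusModelSpec
    solver: SolverSettings
    experiment: ExperimentSettings


# ---------------------------------------------------------------------------

_KNOWN = {
    "run": {"seed", "output_dir"},
    "basic_model": {"alpha_h", "mu_h", "alpha_X", "mu_X"},
    "extended_model": {
        "alpha_Y", "beta_Y", "mu_Y",
        "y_on_h_n", "y_on_h_p0",
        "h_on_y_n", "h_on_y_p0",
        "y_self_n", "y_self_p0",
        "gate_basal_only",
    },
    "profile": {
        "m0", "step1_time", "step1_fold", "step2_time", "step2_fold",
        "ramp_start_time", "ramp_end_time", "t_end",
    },
    "locus_model": {
        "n_cells", "loci", "decay_rate", "t_start", "t_stop", "dt",
        "baseline", "late_locus", "control_fit_stop", "settle_time",
    },
    "solver": {"rtol", "atol", "max_step"},
    "experiment": {
        "fluctuation_amplitude", "fluctuation_correlation_time",
        "fluctuation_window", "fluctuation_settle", "n_seeds", "p1_factors",
    },
}


def _getfloat(sec, key, default) -> float:
    raw = sec.get(key)
    if raw is None:
        return float(default)
    try:
        return float(raw)
    except ValueError as exc:
        raise ConfigError(f"{sec.name}.{key}: not a number: {raw!r}") from exc


def _getint(sec, key, default) -> int:
    raw = sec.get(key)
    if raw is None:
        return int(default)
    try:
        return int(raw)
    except ValueError as exc:
        raise ConfigError(f"{sec.name}.{key}: not an integer: {raw!r}") from exc


def _getbool(sec, key, default) -> bool:
    raw = sec.get(key)
    if raw is None:
        return default
    if raw.lower() in ("true", "yes", "1"):
        return True
    if raw.lower() in ("false", "no", "0"):
        return False
    raise ConfigError(f"{sec.name}.{key}: not a boolean: {raw!r}")


def _parse_loci(raw: str) -> tuple[Locus, ...]:
    """Comma-separated ``name:onset_mean:onset_sd:production[:never_active_prob]``."""
    loci = []
    for chunk in raw.split(","):
        parts = [p.strip() for p in chunk.strip().split(":")]
        if len(parts) not in (4, 5):
            raise ConfigError(f"locus_model.loci: malformed entry {chunk!r}")
        try:
            loci.append(
                Locus(
                    name=parts[0],
                    onset_mean=float(parts[1]),
                    onset_sd=float(parts[2]),
                    production_rate=float(parts[3]),
                    never_active_prob=float(parts[4]) if len(parts) == 5 else 0.0,
                )
            )
        except (ValueError, DomainError) as exc:
            raise ConfigError(f"locus_model.loci: {exc}") from exc
    return tuple(loci)


_DEFAULT_LOCI = (
    "pri-mir-9-5:30:1:0.25:0.05, pri-mir-9-4:30:1:0.25:0.05, pri-mir-9-1:36.5:1:6.0:0.15"
)


def parse_config_text(text: str) -> RunConfig:
    cp = configparser.ConfigParser()
    cp.optionxform = str  # keys are case-sensitive (alpha_X vs alpha_x)
    try:
        cp.read_string(text)
    except configparser.Error as exc:
        raise ConfigError(f"malformed configuration: {exc}") from exc

    for section in cp.sections():
        if section not in _KNOWN:
            raise ConfigError(f"unknown section [{section}]")
        for key in cp[section]:
            if key not in _KNOWN[section]:
                raise ConfigError(f"unknown key {section}.{key}")

    def sec(name):
        return cp[name] if cp.has_section(name) else cp["DEFAULT"]

    run = sec("run")
    seed = _getint(run, "seed", 0)
    output_dir = run.get("output_dir", "results")

    b = sec("basic_model")
    try:
        basic = BasicModelParameters(
            alpha_h=_getfloat(b, "alpha_h", 2.0),
            mu_h=_getfloat(b, "mu_h", 2.0),
            alpha_X=_getfloat(b, "alpha_X", 0.3),
            mu_X=_getfloat(b, "mu_X", 0.3),
        )
    except DomainError as exc:
        raise ConfigError(f"basic_model: {exc}") from exc

    e = sec("extended_model")
    try:
        extended = ExtendedModelParameters(
            basic=basic,
            alpha_Y=_getfloat(e, "alpha_Y", 1.0),
            beta_Y=_getfloat(e, "beta_Y", 4.0),
            mu_Y=_getfloat(e, "mu_Y", 2.0),
            hill_Y_on_h=HillSpec(_getfloat(e, "y_on_h_n", 4.0), _getfloat(e, "y_on_h_p0", 0.5)),
            hill_h_on_Y=HillSpec(_getfloat(e, "h_on_y_n", 4.0), _getfloat(e, "h_on_y_p0", 0.5)),
            hill_Y_self=HillSpec(_getfloat(e, "y_self_n", 4.0), _getfloat(e, "y_self_p0", 0.7)),
            gate_basal_only=_getbool(e, "gate_basal_only", False),
        )
    except DomainError as exc:
        raise ConfigError(f"extended_model: {exc}") from exc

    p = sec("profile")
    profile = ProfileSpec(
        m0=_getfloat(p, "m0", 1.0),
        step1_time=_getfloat(p, "step1_time", 20.0),
        step1_fold=_getfloat(p, "step1_fold", 1.5),
        step2_time=_getfloat(p, "step2_time", 60.0),
        step2_fold=_getfloat(p, "step2_fold", 4.0),
        ramp_start_time=_getfloat(p, "ramp_start_time", 20.0),
        ramp_end_time=_getfloat(p, "ramp_end_time", 100.0),
        t_end=_getfloat(p, "t_end", 150.0),
    )

    lm = sec("locus_model")
    locus = LocusModelSpec(
        n_cells=_getint(lm, "n_cells", 500),
        loci=_parse_loci(lm.get("loci", _DEFAULT_LOCI)),
        decay_rate=_getfloat(lm, "decay_rate", 1.0),
        t_start=_getfloat(lm, "t_start", 24.0),
        t_stop=_getfloat(lm, "t_stop", 48.0),
        dt=_getfloat(lm, "dt", 0.01),
        baseline=_getfloat(lm, "baseline", 1.0),
        late_locus=lm.get("late_locus", "pri-mir-9-1"),
        control_fit_stop=_getfloat(lm, "control_fit_stop", 42.0),
        settle_time=_getfloat(lm, "settle_time", 60.0),
    )
    if locus.decay_rate <= 0:
        raise ConfigError("locus_model.decay_rate must be > 0")
    if locus.late_locus not in [l.name for l in locus.loci]:
        raise ConfigError(
            f"locus_model.late_locus {locus.late_locus!r} is not a configured locus"
        )

    s = sec("solver")
    try:
        solver = SolverSettings(
            rtol=_getfloat(s, "rtol", 1e-8),
            atol=_getfloat(s, "atol", 1e-10),
            max_step=_getfloat(s, "max_step", np.inf),
        )
    except DomainError as exc:
        raise ConfigError(f"solver: {exc}") from exc

    x = sec("experiment")
    raw_factors = x.get("p1_factors", "0.5, 0.75, 1.0, 1.25, 1.5")
    try:
        p1_factors = tuple(float(v) for v in raw_factors.split(","))
    except ValueError as exc:
        raise ConfigError(f"experiment.p1_factors: {exc}") from exc
    experiment = ExperimentSettings(
        fluctuation_amplitude=_getfloat(x, "fluctuation_amplitude", 0.2),
        fluctuation_correlation_time=_getfloat(x, "fluctuation_correlation_time", 1.0),
        fluctuation_window=_getfloat(x, "fluctuation_window", 100.0),
        fluctuation_settle=_getfloat(x, "fluctuation_settle", 60.0),
        n_seeds=_getint(x, "n_seeds", 100),
        p1_factors=p1_factors,
    )

    return RunConfig(
        seed=seed,
        output_dir=output_dir,
        basic=basic,
        extended=extended,
        profile=profile,
        locus=locus,
        solver=solver,
        experiment=experiment,
    )


def parse_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_config_text(fh.read())


def serialize_config(cfg: RunConfig) -> str:
    cp = configparser.ConfigParser()
    cp.optionxform = str
    cp["run"] = {"seed": str(cfg.seed), "output_dir": cfg.output_dir}
    b = cfg.basic
    cp["basic_model"] = {
        "alpha_h": repr(b.alpha_h), "mu_h": repr(b.mu_h),
        "alpha_X": repr(b.alpha_X), "mu_X": repr(b.mu_X),
    }
    e = cfg.extended
    cp["extended_model"] = {
        "alpha_Y": repr(e.alpha_Y), "beta_Y": repr(e.beta_Y), "mu_Y": repr(e.mu_Y),
        "y_on_h_n": repr(e.hill_Y_on_h.n), "y_on_h_p0": repr(e.hill_Y_on_h.p0),
        "h_on_y_n": repr(e.hill_h_on_Y.n), "h_on_y_p0": repr(e.hill_h_on_Y.p0),
        "y_self_n": repr(e.hill_Y_self.n), "y_self_p0": repr(e.hill_Y_self.p0),
        "gate_basal_only": str(e.gate_basal_only).lower(),
    }
    p = cfg.profile
    cp["profile"] = {
        "m0": repr(p.m0),
        "step1_time": repr(p.step1_time), "step1_fold": repr(p.step1_fold),
        "step2_time": repr(p.step2_time), "step2_fold": repr(p.step2_fold),
        "ramp_start_time": repr(p.ramp_start_time),
        "ramp_end_time": repr(p.ramp_end_time),
        "t_end": repr(p.t_end),
    }
    lm = cfg.locus
    loci = ", ".join(
        f"{l.name}:{l.onset_mean:g}:{l.onset_sd:g}:{l.production_rate:g}:{l.never_active_prob:g}"
        for l in lm.loci
    )
    cp["locus_model"] = {
        "n_cells": str(lm.n_cells), "loci": loci,
        "decay_rate": repr(lm.decay_rate),
        "t_start": repr(lm.t_start), "t_stop": repr(lm.t_stop), "dt": repr(lm.dt),
        "baseline": repr(lm.baseline), "late_locus": lm.late_locus,
        "control_fit_stop": repr(lm.control_fit_stop),
        "settle_time": repr(lm.settle_time),
    }
    s = cfg.solver
    cp["solver"] = {
        "rtol": repr(s.rtol), "atol": repr(s.atol), "max_step": repr(s.max_step),
    }
    x = cfg.experiment
    cp["experiment"] = {
        "fluctuation_amplitude": repr(x.fluctuation_amplitude),
        "fluctuation_correlation_time": repr(x.fluctuation_correlation_time),
        "fluctuation_window": repr(x.fluctuation_window),
        "fluctuation_settle": repr(x.fluctuation_settle),
        "n_seeds": str(x.n_seeds),
        "p1_factors": ", ".join(repr(f) for f in x.p1_factors),
    }
    buf = _io.StringIO()
    cp.write(buf)
    return buf.getvalue()


def default_config() -> RunConfig:
    """Configuration with every field at its documented default."""
    return parse_config_text("")


def load_reference_config() -> RunConfig:
    """The shipped reference configuration (passes the feasibility check)."""
    text = resources.files("her6switch.data").joinpath("reference.cfg").read_text()
    return parse_config_text(text)
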