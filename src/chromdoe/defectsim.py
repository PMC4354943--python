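"""Monte Carlo defect-rate (DR) estimation for fitted response models.

A "defect" is a simulated run in which any response falls outside its
specification limits.  Factors vary randomly around a setpoint (normal,
truncated to the factor's low/high range), responses are predicted from
fitted response-surface models with optional N(0, rmse) measurement
noise, and the defect rate is the fraction m/n of defective runs.  The
defect profiler sweeps one factor over a grid while the others vary
randomly, tracing DR as a function of that factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .designs import FactorSpec, actual_to_coded
from .errors import ConfigurationError, DomainError
from .rsm import FittedModel

RESPONSE_NOISE_NONE = "none"
RESPONSE_NOISE_RMSE = "rmse"


@dataclass
class DefectSpec:
    """Configuration of one defect-rate simulation.

    ``setpoint`` is in actual units, one entry per factor; each factor is
    drawn normal(setpoint, sim_sd) truncated to [low, high] by rejection,
    or held fixed when its ``sim_sd`` is zero.  ``spec_limits`` maps a
    response name to an (LSL, USL) pair, either bound optional.
    """

    factor_specs: list[FactorSpec]
    setpoint: np.ndarray
    spec_limits: dict[str, tuple[float | None, float | None]]
    n_runs: int = 15000
    response_noise: str = RESPONSE_NOISE_RMSE
    seed: int = 0

    def __post_init__(self) -> None:
        self.setpoint = np.asarray(self.setpoint, dtype=float)
        if self.setpoint.size != len(self.factor_specs):
            raise ConfigurationError("setpoint length must match factor count")
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")
        if self.response_noise not in (RESPONSE_NOISE_NONE, RESPONSE_NOISE_RMSE):
            raise ConfigurationError(f"unknown response_noise {self.response_noise!r}")
        if not self.spec_limits or all(
            lsl is None and usl is None for lsl, usl in self.spec_limits.values()
        ):
            raise ConfigurationError("at least one response must have a spec limit")

    def with_setpoint(self, setpoint) -> "DefectSpec":
        return DefectSpec(
            self.factor_specs, np.asarray(setpoint, dtype=float), dict(self.spec_limits),
            self.n_runs, self.response_noise, self.seed,
        )


@dataclass
class DefectReport:
    """Result of a defect-rate simulation."""

    overall_dr: float
    per_response_dr: dict[str, float]
    m: int
    n: int
    ci95: tuple[float, float]
    dpm: float = field(init=False)

    def __post_init__(self) -> None:
        self.dpm = defects_per_million(self.overall_dr)

    def defect_share_of(self, response: str) -> float:
        return defect_share(self.per_response_dr[response], self.overall_dr)


def _draw_factors(
    spec: DefectSpec, rng: np.random.Generator, fixed: dict[int, float] | None = None
) -> np.ndarray:
    """Truncated-normal factor draws (rejection sampling), actual units."""
    n, k = spec.n_runs, len(spec.factor_specs)
    out = np.empty((n, k))
    fixed = fixed or {}
    for j, fs in enumerate(spec.factor_specs):
        if j in fixed:
            out[:, j] = fixed[j]
            continue
        mu = spec.setpoint[j]
        if fs.sim_sd == 0:
            out[:, j] = mu
            continue
        draws = rng.normal(mu, fs.sim_sd, size=n)
        bad = (draws < fs.low) | (draws > fs.high)
        while bad.any():
            draws[bad] = rng.normal(mu, fs.sim_sd, size=int(bad.sum()))
            bad = (draws < fs.low) | (draws > fs.high)
        out[:, j] = draws
    return out


def _violations(
    models: dict[str, FittedModel], spec: DefectSpec, actual: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-response boolean defect indicators for a factor draw matrix."""
    coded = actual_to_coded(actual, spec.factor_specs)
    out = {}
    for name, (lsl, usl) in spec.spec_limits.items():
        if lsl is None and usl is None:
            continue
        if name not in models:
            raise ConfigurationError(f"spec limit for {name!r} has no fitted model")
        model = models[name]
        pred = model.predict(coded)
        if spec.response_noise == RESPONSE_NOISE_RMSE and model.rmse > 0:
            pred = pred + rng.normal(0.0, model.rmse, size=pred.shape)
        bad = np.zeros(pred.shape, dtype=bool)
        if lsl is not None:
            bad |= pred < lsl
        if usl is not None:
            bad |= pred > usl
        out[name] = bad
    return out


def simulate_defect_rate(models: dict[str, FittedModel], spec: DefectSpec) -> DefectReport:
    """Estimate the defect rate DR = m/n by seeded Monte Carlo simulation."""
    rng = np.random.default_rng(spec.seed)
    actual = _draw_factors(spec, rng)
    viol = _violations(models, spec, actual, rng)
    any_bad = np.zeros(spec.n_runs, dtype=bool)
    per_response = {}
    for name, bad in viol.items():
        any_bad |= bad
        per_response[name] = float(bad.mean())
    m = int(any_bad.sum())
    lo, hi = proportion_confint(m, spec.n_runs, alpha=0.05, method="beta")
    return DefectReport(
        overall_dr=m / spec.n_runs,
        per_response_dr=per_response,
        m=m,
        n=spec.n_runs,
        ci95=(float(lo), float(hi)),
    )


def defects_per_million(dr: float) -> float:
    """Convert a defect rate in [0, 1] to defects per million runs."""
    if not 0.0 <= dr <= 1.0:
        raise DomainError(f"defect rate must be in [0, 1], got {dr}")
    return dr * 1e6


def defect_share(component_dr: float, overall_dr: float) -> float:
    """Percent of the overall defect rate attributable to one response."""
    if overall_dr <= 0:
        raise DomainError("defect share is undefined for overall_dr = 0")
    if not 0 <= component_dr <= overall_dr:
        raise DomainError("component_dr must lie in [0, overall_dr]")
    return 100.0 * component_dr / overall_dr


def defect_profile(
    models: dict[str, FittedModel],
    spec: DefectSpec,
    factor: str,
    grid,
) -> np.ndarray:
    """Defect profiler: DR versus one factor, the others varying randomly.

    For each grid value (actual units) that factor is clamped while the
    remaining factors are drawn from their truncated normals; returns one
    DR per grid value.
    """
    names = [fs.name for fs in spec.factor_specs]
    if factor not in names:
        raise ConfigurationError(f"unknown factor {factor!r}; have {names}")
    j = names.index(factor)
    fs = spec.factor_specs[j]
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < fs.low - 1e-12 or grid.max() > fs.high + 1e-12):
        raise DomainError(f"grid for {factor!r} must lie within [{fs.low}, {fs.high}]")

    drs = np.empty(grid.size)
    for i, value in enumerate(grid):
        rng = np.random.default_rng((spec.seed, i))
        actual = _draw_factors(spec, rng, fixed={j: float(value)})
        viol = _violations(models, spec, actual, rng)
        any_bad = np.zeros(spec.n_runs, dtype=bool)
        for bad in viol.values():
            any_bad |= bad
        drs[i] = any_bad.mean()
    return drs
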