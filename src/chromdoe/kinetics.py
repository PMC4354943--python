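"""In-vitro drug-release kinetics: model fitting and mechanism classification.

Four classical release laws are fitted by their standard linearizations —
zero order (Q vs t), first order (ln(1-Q) vs t), Higuchi (Q vs sqrt t)
and Korsmeyer-Peppas (log Q vs log t on the early portion of the curve,
Q <= 0.6) — the best model is chosen by r², and the Peppas exponent n
classifies the transport mechanism (Fickian n <= 0.5, anomalous
0.5 < n < 1, case-II n = 1, super case-II n > 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import DataError, DomainError

ZERO = "zero"
FIRST = "first"
HIGUCHI = "higuchi"
PEPPAS = "peppas"
ALL_MODELS = (ZERO, FIRST, HIGUCHI, PEPPAS)

#: Number of kinetic parameters per model (rate constant; Peppas adds n).
N_PARAMETERS = {ZERO: 1, FIRST: 1, HIGUCHI: 1, PEPPAS: 2}

#: Validity cutoff for the Peppas power law (early-time approximation).
PEPPAS_MAX_FRACTION = 0.6

FICKIAN = "fickian"
ANOMALOUS = "anomalous"
CASE_II = "case_II"
SUPER_CASE_II = "super_case_II"


@dataclass(frozen=True)
class ReleaseProfile:
    """Cumulative release versus time.

    ``cumulative`` is the fraction released in [0, 1] unless
    ``fractional`` is False, in which case it is an amount on the
    caller's scale (log-based models then refuse to fit).
    """

    time: np.ndarray
    cumulative: np.ndarray
    fractional: bool = True

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        q = np.asarray(self.cumulative, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "cumulative", q)
        if t.ndim != 1 or t.shape != q.shape or t.size < 2:
            raise DataError("profile needs matching 1-D time and release arrays")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise DataError("time must be strictly increasing and start at >= 0")
        if np.any(np.diff(q) < 0):
            raise DataError("cumulative release must be non-decreasing")
        if self.fractional and (q.min() < 0 or q.max() > 1):
            raise DataError("fractional release must lie in [0, 1]")

    @classmethod
    def from_csv(cls, path, fractional: bool = True) -> "ReleaseProfile":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float), fractional)


@dataclass(frozen=True)
class KineticFit:
    """One fitted release law: its parameters and the linearized-fit r²."""

    model: str
    parameters: dict[str, float]
    r2: float


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    res = scipy.stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def fit_release(profile: ReleaseProfile, model: str) -> KineticFit:
    """Fit one release law by its conventional linearization.

    Rate constants are on the profile's release scale per minute:
    zero order K0 = slope of Q vs t; first order K1 = -slope of
    ln(1-Q) vs t; Higuchi K_H = slope of Q vs sqrt(t); Peppas k and n
    from log10 Q vs log10 t restricted to t > 0 and Q <= 0.6.
    """
    t, q = profile.time, profile.cumulative
    if model == ZERO:
        if t.size < 3:
            raise DataError("zero-order fit needs at least 3 points")
        k0, _, r2 = _linfit(t, q)
        return KineticFit(ZERO, {"K0": k0}, r2)
    if model == HIGUCHI:
        if t.size < 3:
            raise DataError("Higuchi fit needs at least 3 points")
        kh, _, r2 = _linfit(np.sqrt(t), q)
        return KineticFit(HIGUCHI, {"KH": kh}, r2)
    if model == FIRST:
        if not profile.fractional:
            raise DomainError("first-order fit needs release as a fraction of total")
        if np.any(q >= 1.0):
            raise DomainError("first-order fit undefined where release fraction >= 1")
        slope, _, r2 = _linfit(t, np.log(1.0 - q))
        return KineticFit(FIRST, {"K1": -slope}, r2)
    if model == PEPPAS:
        if not profile.fractional:
            raise DomainError("Peppas fit needs release as a fraction of total")
        keep = (t > 0) & (q > 0) & (q <= PEPPAS_MAX_FRACTION)
        if keep.sum() < 3:
            raise DataError(
                "Peppas fit needs at least 3 points with t > 0 and 0 < Q <= 0.6"
            )
        n, logk, r2 = _linfit(np.log10(t[keep]), np.log10(q[keep]))
        return KineticFit(PEPPAS, {"k": 10.0**logk, "n": n}, r2)
    raise DataError(f"unknown release model {model!r}")


def fit_all(profile: ReleaseProfile) -> list[KineticFit]:
    """Fit every release law that the profile's scale supports."""
    fits = []
    for model in ALL_MODELS:
        try:
            fits.append(fit_release(profile, model))
        except (DataError, DomainError):
            continue
    if not fits:
        raise DataError("no release model could be fitted to the profile")
    return fits


def select_best_model(fits: list[KineticFit]) -> str:
    """Best-fitting model by r²; ties go to the model with fewer parameters."""
    if len(fits) < 2:
        raise DataError("model selection needs at least two candidate fits")
    best = max(fits, key=lambda f: (f.r2, -N_PARAMETERS[f.model]))
    return best.model


def classify_mechanism(n: float, tol: float = 1e-9) -> str:
    """Transport mechanism from the Peppas exponent n."""
    if n <= 0:
        raise DomainError(f"Peppas exponent must be > 0, got {n}")
    if abs(n - 1.0) <= tol:
        return CASE_II
    if n <= 0.5:
        return FICKIAN
    if n < 1.0:
        return ANOMALOUS
    return SUPER_CASE_II


def simulate_release(
    times, model: str, params: dict[str, float], noise_sd: float = 0.0, seed: int = 0
) -> ReleaseProfile:
    """Generate a release profile from a known law, optionally with noise.

    Noise is additive Gaussian on the cumulative fraction, clipped to
    [0, 1] and made non-decreasing (running maximum) so the result is a
    valid profile.
    """
    t = np.asarray(times, dtype=float)
    if model == ZERO:
        q = params["K0"] * t
    elif model == FIRST:
        q = 1.0 - np.exp(-params["K1"] * t)
    elif model == HIGUCHI:
        q = params["KH"] * np.sqrt(t)
    elif model == PEPPAS:
        q = np.zeros_like(t)
        pos = t > 0
        q[pos] = params["k"] * t[pos] ** params["n"]
    else:
        raise DataError(f"unknown release model {model!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        q = q + rng.normal(0.0, noise_sd, size=t.shape)
    q = np.maximum.accumulate(np.clip(q, 0.0, 1.0))
    return ReleaseProfile(t, q)
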