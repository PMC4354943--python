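"""Calibration, encapsulation efficiency and molar extinction coefficients.

The extinction coefficient epsilon (L mol^-1 cm^-1) is recovered two
ways.  By HPLC: the detector absorbance is Ab(t) = epsilon * l * c(t)
(Beer-Lambert), and the eluting concentration profile integrates to the
injected moles divided by the volumetric flow, so the peak area obeys

    area [AU*min] = epsilon * l * moles / (flow [mL/min] / 1000)

giving epsilon = area * flow / (1000 * l * moles) — note the mL -> L
conversion.  By UV spectrophotometry: epsilon is the slope of a
zero-intercept calibration of absorbance against molar concentration,
divided by the path length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chromsim import Chromatogram, emg_profile
from .errors import DataError, DomainError


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear response-vs-concentration calibration."""

    slope: float
    intercept: float
    r2: float
    conc_range: tuple[float, float]

    def predict(self, conc):
        return self.slope * np.asarray(conc, dtype=float) + self.intercept

    def inverse(self, response):
        """Concentration back-calculated from a measured response."""
        if self.slope == 0:
            raise DomainError("cannot invert a flat calibration")
        return (np.asarray(response, dtype=float) - self.intercept) / self.slope


def calibration_fit(conc, response, zero_intercept: bool = False) -> CalibrationCurve:
    """Least-squares calibration line, optionally constrained through the origin."""
    x = np.asarray(conc, dtype=float)
    y = np.asarray(response, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("calibration needs >= 3 matched (conc, response) points")
    if np.any(x < 0):
        raise DomainError("concentrations must be >= 0")
    if np.ptp(x) == 0:
        raise DataError("all concentrations identical: calibration is rank deficient")
    if zero_intercept:
        slope = float(np.dot(x, y) / np.dot(x, x))
        intercept = 0.0
        fitted = slope * x
    else:
        slope_i = np.polyfit(x, y, 1)
        slope, intercept = float(slope_i[0]), float(slope_i[1])
        fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CalibrationCurve(slope, intercept, r2, (float(x.min()), float(x.max())))


def encapsulation_efficiency(measured_drug: float, theoretical_drug: float) -> float:
    """Percent encapsulation efficiency, 100 * measured / theoretical (% w/w)."""
    if theoretical_drug <= 0:
        raise DomainError("theoretical drug amount must be > 0")
    if measured_drug < 0:
        raise DomainError("measured drug amount must be >= 0")
    return 100.0 * measured_drug / theoretical_drug


def epsilon_from_peak_area(
    area: float, flow: float, path: float, moles: float
) -> float:
    """Molar extinction coefficient from an HPLC peak.

    ``area`` in AU*min, ``flow`` in mL/min, ``path`` in cm, ``moles`` the
    amount of analyte injected (mol).  epsilon = area * flow / (1000 *
    path * moles), in L mol^-1 cm^-1.
    """
    for name, v in (("area", area), ("flow", flow), ("path", path), ("moles", moles)):
        if v <= 0:
            raise DomainError(f"{name} must be > 0, got {v}")
    return area * flow / (1000.0 * path * moles)


def epsilon_from_uv(conc, absorbance, path: float = 1.0) -> float:
    """Extinction coefficient from a zero-intercept UV calibration.

    ``conc`` in mol/L, ``absorbance`` in AU; epsilon is the constrained
    slope divided by the path length (cm).
    """
    if path <= 0:
        raise DomainError("path length must be > 0")
    curve = calibration_fit(conc, absorbance, zero_intercept=True)
    return curve.slope / path


def simulate_absorbance_peak(
    epsilon: float,
    moles: float,
    flow: float,
    path: float = 1.0,
    retention: float = 3.2,
    sigma: float = 0.05,
    tau: float = 0.0,
    t_max: float = 8.0,
    dt: float = 0.002,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Chromatogram:
    """Synthetic Beer-Lambert detector trace for a known extinction coefficient.

    The eluting concentration profile is an EMG pulse carrying ``moles``
    of analyte at volumetric flow ``flow`` (mL/min); the detector reads
    Ab(t) = epsilon * path * c(t).  Inverting the measured area through
    :func:`epsilon_from_peak_area` recovers ``epsilon`` exactly (up to
    grid error), which makes this the round-trip oracle for the HPLC
    route.
    """
    if epsilon <= 0 or moles <= 0 or flow <= 0 or path <= 0:
        raise DomainError("epsilon, moles, flow and path must all be > 0")
    time = np.arange(0.0, t_max + dt / 2, dt)
    conc = moles / (flow / 1000.0) * emg_profile(time, retention, sigma, tau)  # mol/L per min
    signal = epsilon * path * conc
    if noise_sd > 0:
        signal = signal + np.random.default_rng(seed).normal(0, noise_sd, time.size)
    return Chromatogram(time, signal)
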