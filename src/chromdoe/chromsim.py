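"""Synthetic HPLC chromatograms and peak-shape analytics.

The generator emits detector traces for a two-drug assay (a moderately
lipophilic nucleoside analog, "STP", eluting before a highly lipophilic
non-nucleoside inhibitor, "HI443") as a sum of exponentially modified
Gaussian (EMG) peaks plus white detector noise.  The physics encoded is
the standard chromatographic behaviour the screening stage must
rediscover:

* peak area = response_factor * injected mass / flow rate — area falls
  with flow and rises with injected mass (concentration x volume);
* the exponential tail constant grows with injection volume (mass
  overload) and with the organic fraction of the mobile phase (silanol
  interactions), more steeply for the lipophilic drug;
* retention time shrinks with flow and with organic fraction;
* the detector response factor has a shallow maximum near 270 nm, so the
  wavelength factor is real but weak.

Peak metrics (area, USP tailing, theoretical plates, resolution, S/N)
follow the usual pharmacopeial formulas on the sampled grid, and the
validation statistics (%RSD, recovery, LOD) are provided as plain
computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ChromDoeError, DataError, DomainError

#: Names of the five screening factors, in canonical order.
FACTOR_ORDER = ("flow", "volume", "wavelength", "organic_init", "organic_late")

#: Mid-level operating conditions (actual units) used to fill unspecified factors.
MID_CONDITIONS = {
    "flow": 0.8,            # mL/min
    "volume": 15.0,         # uL
    "wavelength": 270.0,    # nm
    "organic_init": 70.0,   # % v/v acetonitrile at gradient start
    "organic_late": 90.0,   # % v/v acetonitrile at 4 min
}


@dataclass(frozen=True)
class Chromatogram:
    """A detector trace on a uniform time grid (minutes, absorbance units)."""

    time: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or t.size < 2 or s.shape != t.shape:
            raise DataError("chromatogram needs matching 1-D time and signal arrays")
        dt = np.diff(t)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
            raise DataError("time grid must be uniform and strictly increasing")
        if not np.all(np.isfinite(s)):
            raise DataError("signal contains non-finite values")

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])

    def window(self, t_start: float, t_end: float) -> tuple[np.ndarray, np.ndarray]:
        if t_end <= t_start:
            raise DomainError("window end must exceed window start")
        mask = (self.time >= t_start) & (self.time <= t_end)
        if mask.sum() < 5:
            raise DomainError("window contains too few samples")
        return self.time[mask], self.signal[mask]

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.time, "signal_AU": self.signal}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "Chromatogram":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


@dataclass(frozen=True)
class PeakModel:
    """EMG peak parameters for one drug under given conditions.

    ``response_factor`` converts (mass / flow) into peak area:
    area [AU*min] = response_factor * mass [ug] / flow [mL/min].
    """

    name: str
    retention: float            # min
    sigma: float                # min, Gaussian width
    tau: float                  # min, exponential tail constant (>= 0)
    mass: float                 # ug injected
    response_factor: float      # AU*min*(mL/min)/ug

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise DomainError(f"peak {self.name!r}: sigma must be > 0")
        if self.tau < 0:
            raise DomainError(f"peak {self.name!r}: tau must be >= 0")

    @property
    def area(self) -> float:
        """Nominal peak area at the flow the model was built for (set by caller)."""
        return self.response_factor * self.mass


@dataclass(frozen=True)
class DrugTemplate:
    """How one drug's peak responds to the instrument factors.

    ``tail_volume`` / ``tail_organic`` / ``tail_flow`` are the linear
    sensitivities of the EMG tail constant (min) to injection volume
    (uL), initial organic fraction (% v/v) and flow (mL/min); the
    lipophilic drug carries the larger organic sensitivity.
    """

    name: str
    concentration: float        # ug/mL in the injected standard
    base_retention: float       # min at mid conditions
    sigma0: float               # min at mid conditions
    response_factor0: float     # AU*min*(mL/min)/ug at 270 nm
    tau0: float                 # min at low-volume, low-organic conditions
    tail_volume: float          # min per uL above 10 uL
    tail_organic: float         # min per % v/v above 60 %
    tail_flow: float            # min per mL/min above 0.6
    wavelength_curvature: float = 8e-5   # fractional response loss per nm^2 off 270

    def peak_at(self, conditions: dict[str, float]) -> PeakModel:
        """Instantiate the EMG peak parameters at actual-unit conditions."""
        c = {**MID_CONDITIONS, **conditions}
        flow, vol, lam = c["flow"], c["volume"], c["wavelength"]
        org = c["organic_init"]
        if flow <= 0:
            raise DomainError("flow must be > 0")
        if vol <= 0:
            raise DomainError("injection volume must be > 0")

        # Retention shrinks with flow (inverse) and with organic strength.
        retention = self.base_retention * (MID_CONDITIONS["flow"] / flow) * (
            1.0 - 0.004 * (org - MID_CONDITIONS["organic_init"])
        )
        sigma = self.sigma0 * retention / self.base_retention
        tau = (
            self.tau0
            + self.tail_volume * (vol - 10.0)
            + self.tail_organic * (org - 60.0)
            + self.tail_flow * (flow - 0.6)
        )
        rf = self.response_factor0 * max(
            0.0, 1.0 - self.wavelength_curvature * (lam - 270.0) ** 2
        )
        mass = self.concentration * vol * 1e-3  # ug/mL * uL -> ug
        return PeakModel(self.name, retention, sigma, max(tau, 0.0), mass, rf)


#: Fixture drug templates for the two-drug assay.  The second drug is the
#: lipophilic one: later-eluting, larger response factor, and a tail that
#: reacts more strongly to the organic fraction.
STP_TEMPLATE = DrugTemplate(
    name="STP", concentration=10.0, base_retention=3.2, sigma0=0.045,
    response_factor0=1.0, tau0=0.004,
    tail_volume=0.0090, tail_organic=0.00030, tail_flow=0.030,
)
HI443_TEMPLATE = DrugTemplate(
    name="HI443", concentration=5.0, base_retention=4.6, sigma0=0.055,
    response_factor0=2.4, tau0=0.005,
    tail_volume=0.0050, tail_organic=0.00150, tail_flow=0.004,
)
DEFAULT_TEMPLATES = (STP_TEMPLATE, HI443_TEMPLATE)

#: Detector noise (AU) and relative injected-mass variability of the fixture.
DEFAULT_NOISE_SD = 0.002
DEFAULT_INJECTION_CV = 0.01

#: Default trace grid: 0..8 min at 0.002 min spacing.
DEFAULT_T_MAX = 8.0
DEFAULT_DT = 0.002


def emg_profile(t: np.ndarray, retention: float, sigma: float, tau: float) -> np.ndarray:
    """Unit-area exponentially modified Gaussian (Gaussian when tau ~ 0)."""
    t = np.asarray(t, dtype=float)
    if tau < 1e-6 * sigma or tau == 0.0:
        return scipy.stats.norm.pdf(t, loc=retention, scale=sigma)
    return scipy.stats.exponnorm.pdf(t, K=tau / sigma, loc=retention, scale=sigma)


def simulate_chromatogram(
    conditions: dict[str, float],
    templates=DEFAULT_TEMPLATES,
    noise_sd: float = DEFAULT_NOISE_SD,
    injection_cv: float = DEFAULT_INJECTION_CV,
    seed: int = 0,
    t_max: float = DEFAULT_T_MAX,
    dt: float = DEFAULT_DT,
) -> Chromatogram:
    """Simulate one detector trace at actual-unit ``conditions``.

    ``conditions`` uses the keys in :data:`FACTOR_ORDER`; missing keys
    default to mid levels.  ``injection_cv`` is the relative standard
    deviation of the injected mass (autosampler repeatability) and
    ``noise_sd`` the additive white detector noise in AU.  Same seed,
    same trace.
    """
    rng = np.random.default_rng(seed)
    c = {**MID_CONDITIONS, **conditions}
    flow = c["flow"]
    time = np.arange(0.0, t_max + dt / 2, dt)
    signal = np.zeros_like(time)
    for template in templates:
        peak = template.peak_at(c)
        mass = peak.mass * (1.0 + injection_cv * rng.standard_normal()) if injection_cv else peak.mass
        area = peak.response_factor * mass / flow
        signal += area * emg_profile(time, peak.retention, peak.sigma, peak.tau)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=time.size)
    return Chromatogram(time, signal)


def _baseline(ts: np.ndarray, ys: np.ndarray, edge: int = 5) -> float:
    """Constant baseline estimate: the lower of the two window-edge medians.

    Taking the minimum keeps the estimate honest when one edge sits on the
    flank of an adjacent peak (a common situation for windows that meet at
    the valley between two partially resolved peaks)."""
    edge = min(edge, ys.size // 4) or 1
    return float(min(np.median(ys[:edge]), np.median(ys[-edge:])))


def peak_area(chrom: Chromatogram, window: tuple[float, float]) -> float:
    """Trapezoidal integral of the baseline-corrected signal over a window (AU*min)."""
    ts, ys = chrom.window(*window)
    return float(np.trapezoid(ys - _baseline(ts, ys), ts))


def _apex_and_widths(ts: np.ndarray, ys: np.ndarray, frac: float):
    """Apex time plus interpolated front/back half-widths at ``frac`` of peak height."""
    base = _baseline(ts, ys)
    y = ys - base
    i_max = int(np.argmax(y))
    height = y[i_max]
    if height <= 0:
        raise DataError("no positive peak in window")
    level = frac * height
    if y[0] > level or y[-1] > level:
        raise ChromDoeError(
            "peak truncated by window: signal exceeds the threshold at a window edge"
        )
    # Walk outward from the apex to the first crossing on each side.
    left = i_max
    while y[left] > level:
        left -= 1
    t_left = np.interp(level, [y[left], y[left + 1]], [ts[left], ts[left + 1]])
    right = i_max
    while y[right] > level:
        right += 1
    t_right = np.interp(level, [y[right], y[right - 1]], [ts[right], ts[right - 1]])
    # A crossing pinned to the window boundary means the flank was cut off
    # and the edge-based baseline forced an artificial crossing there.
    dt = ts[1] - ts[0]
    if t_left - ts[0] < 5 * dt or ts[-1] - t_right < 5 * dt:
        raise ChromDoeError(
            "peak truncated by window: width crossing lies at the window boundary"
        )
    apex = float(ts[i_max])
    return apex, float(apex - t_left), float(t_right - apex), float(height)


def usp_tailing(chrom: Chromatogram, window: tuple[float, float]) -> float:
    """USP tailing factor T = W(5%) / (2 * front half-width at 5% height)."""
    ts, ys = chrom.window(*window)
    _, front, back, _ = _apex_and_widths(ts, ys, 0.05)
    return (front + back) / (2.0 * front)


def theoretical_plates(chrom: Chromatogram, window: tuple[float, float]) -> float:
    """Half-height plate count N = 5.54 * (t_R / W(50%))^2."""
    ts, ys = chrom.window(*window)
    apex, front, back, _ = _apex_and_widths(ts, ys, 0.5)
    return 5.54 * (apex / (front + back)) ** 2


def resolution(
    chrom: Chromatogram, window1: tuple[float, float], window2: tuple[float, float]
) -> float:
    """Resolution Rs = 2 (t_R2 - t_R1) / (Wb1 + Wb2), Wb = 1.699 * W(50%)."""
    ts1, ys1 = chrom.window(*window1)
    ts2, ys2 = chrom.window(*window2)
    a1, f1, b1, _ = _apex_and_widths(ts1, ys1, 0.5)
    a2, f2, b2, _ = _apex_and_widths(ts2, ys2, 0.5)
    if a2 < a1:
        raise DomainError("window2 must contain the later-eluting peak")
    wb1, wb2 = 1.699 * (f1 + b1), 1.699 * (f2 + b2)
    return 2.0 * (a2 - a1) / (wb1 + wb2)


def sn_ratio(
    chrom: Chromatogram,
    peak_window: tuple[float, float],
    noise_window: tuple[float, float],
) -> float:
    """Signal-to-noise: peak height over twice the baseline noise SD."""
    if not (noise_window[1] <= peak_window[0] or noise_window[0] >= peak_window[1]):
        raise DomainError("peak and noise windows must be disjoint")
    ts, ys = chrom.window(*peak_window)
    _, _, _, height = _apex_and_widths(ts, ys, 0.5)
    _, noise = chrom.window(*noise_window)
    noise_sd = float(np.std(noise - np.mean(noise), ddof=1))
    if noise_sd == 0:
        raise DomainError("noise window has zero variance; S/N is degenerate")
    return height / (2.0 * noise_sd)


def lod_from_calibration(slope: float, noise_sd: float, sn_target: float = 3.0) -> float:
    """Concentration at which S/N reaches ``sn_target`` under a linear height response.

    With S/N = height / (2 * noise SD) and height = slope * concentration,
    LOD = sn_target * 2 * noise_sd / slope.
    """
    if slope <= 0:
        raise DomainError("calibration slope must be > 0")
    if noise_sd <= 0:
        raise DomainError("noise SD must be > 0")
    return sn_target * 2.0 * noise_sd / slope


def rsd(values) -> float:
    """Percent relative standard deviation, 100 * sd / mean (sample sd)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DataError("%RSD needs at least two values")
    mean = v.mean()
    if mean == 0:
        raise DomainError("%RSD is undefined for zero mean")
    return float(100.0 * v.std(ddof=1) / mean)


def recovery(measured: float, nominal: float) -> float:
    """Percent recovery, 100 * measured / nominal."""
    if nominal <= 0:
        raise DomainError("nominal amount must be > 0")
    return 100.0 * measured / nominal


def peak_windows(
    conditions: dict[str, float], templates=DEFAULT_TEMPLATES,
    t_max: float = DEFAULT_T_MAX,
) -> list[tuple[float, float]]:
    """Integration windows per drug at given conditions, split at the midpoint
    between adjacent peaks when the generous defaults would overlap."""
    c = {**MID_CONDITIONS, **conditions}
    peaks = [t.peak_at(c) for t in templates]
    raw = []
    for p in peaks:
        lo = p.retention - 7.0 * p.sigma
        hi = p.retention + 7.0 * p.sigma + 9.0 * p.tau
        raw.append([max(lo, 0.0), min(hi, t_max)])
    order = np.argsort([p.retention for p in peaks])
    for a, b in zip(order[:-1], order[1:]):
        if raw[a][1] > raw[b][0]:
            # Windows collide: split between the first peak's 5%-tail extent
            # and the second peak's 5%-front extent so both stay measurable;
            # the earlier (tailed) peak needs most of the room on the right.
            pa, pb = peaks[a], peaks[b]
            tail_a = pa.retention + 2.5 * pa.sigma + 3.5 * pa.tau
            front_b = pb.retention - 2.5 * pb.sigma
            if tail_a < front_b:
                mid = (tail_a + front_b) / 2.0
            else:  # genuine co-elution; fall back to the apex midpoint
                mid = (pa.retention + pb.retention) / 2.0
            raw[a][1] = mid
            raw[b][0] = mid
    return [tuple(w) for w in raw]


def simulate_responses(
    actual_design: np.ndarray,
    factor_names: list[str],
    templates=DEFAULT_TEMPLATES,
    noise_sd: float = DEFAULT_NOISE_SD,
    injection_cv: float = DEFAULT_INJECTION_CV,
    seed: int = 0,
) -> pd.DataFrame:
    """Measure the four assay responses for every run of a design.

    ``actual_design`` is a run x factor matrix in actual units with
    ``factor_names`` drawn from :data:`FACTOR_ORDER`; unspecified factors
    sit at mid level.  Each run simulates a fresh chromatogram (seeded
    per run) and measures Y1/Y2 = peak areas and Y3/Y4 = USP tailing of
    the two drugs.
    """
    actual_design = np.atleast_2d(np.asarray(actual_design, dtype=float))
    unknown = set(factor_names) - set(FACTOR_ORDER)
    if unknown:
        raise DataError(f"unknown factor names: {sorted(unknown)}")
    rows = []
    for i, run in enumerate(actual_design):
        conditions = dict(zip(factor_names, run))
        chrom = simulate_chromatogram(
            conditions, templates=templates, noise_sd=noise_sd,
            injection_cv=injection_cv, seed=int(np.random.default_rng((seed, i)).integers(2**31)),
        )
        w1, w2 = peak_windows(conditions, templates)
        rows.append(
            {
                "Y1": peak_area(chrom, w1),
                "Y2": peak_area(chrom, w2),
                "Y3": usp_tailing(chrom, w1),
                "Y4": usp_tailing(chrom, w2),
            }
        )
    return pd.DataFrame(rows)
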