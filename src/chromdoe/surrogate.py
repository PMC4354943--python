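"""Defect-rate surface exploration: Latin hypercube sweep, kriging, minimization.

The simulation experiment evaluates the Monte Carlo defect rate at a
space-filling set of factor setpoints (Latin hypercube over the coded
cube), fits a Gaussian-process surrogate to log10 DR, validates it by
jackknife (leave-one-out) prediction, and minimizes the predicted DR to
propose an improved operating point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.optimize
from scipy.stats import qmc
from sklearn.exceptions import ConvergenceWarning
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .defectsim import DefectSpec, simulate_defect_rate
from .designs import DesignMatrix, coded_to_actual
from .errors import ConfigurationError, DataError
from .rsm import FittedModel


def latin_hypercube(n_points: int, n_factors: int, bounds=None, seed: int = 0) -> np.ndarray:
    """Latin hypercube sample: one point per equal-width stratum per factor.

    ``bounds`` is a list of (low, high) pairs per factor (default unit
    cube).  Same seed, same matrix; different seeds permute the strata.
    """
    if n_points < 2:
        raise ConfigurationError("a Latin hypercube needs at least 2 points")
    if n_factors < 1:
        raise ConfigurationError("n_factors must be >= 1")
    if bounds is None:
        bounds = [(0.0, 1.0)] * n_factors
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(hi <= lo):
        raise ConfigurationError("degenerate bounds: every high must exceed its low")
    sampler = qmc.LatinHypercube(d=n_factors, seed=seed)
    unit = sampler.random(n=n_points)
    return lo + unit * (hi - lo)


class GPSurrogate:
    """Constant-mean kriging with anisotropic squared-exponential kernel + nugget.

    Hyperparameters are chosen by restarted maximum likelihood; ``predict``
    returns the posterior mean (and optionally the standard deviation) at
    any in-bounds point.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, seed: int = 0, n_restarts: int = 3):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.shape[0] < 5:
            raise DataError("GP fitting needs at least 5 points")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise DataError("GP training data must be finite")
        span = np.ptp(X, axis=0)
        span[span == 0] = 1.0
        # The white-noise term must absorb sampling error in the response
        # (e.g. binomial noise of a Monte Carlo DR estimate), so its upper
        # bound is generous; for noiseless surfaces the MLE drives it down.
        kernel = ConstantKernel(1.0, (1e-3, 1e2)) * RBF(
            length_scale=span, length_scale_bounds=(1e-2, 1e3)
        ) + WhiteKernel(noise_level=1e-6, noise_level_bounds=(1e-8, 1e1))
        self._gpr = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=n_restarts,
            random_state=seed,
        )
        # Restarted MLE routinely stops at a hyperparameter bound on noisy
        # surfaces; that is expected behaviour, not a fitting failure.
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._gpr.fit(X, y)
        self.X_train = X
        self.y_train = y

    @property
    def kernel_(self):
        return self._gpr.kernel_

    @property
    def length_scales(self) -> np.ndarray:
        return np.atleast_1d(self._gpr.kernel_.k1.k2.length_scale)

    @property
    def nugget(self) -> float:
        return float(self._gpr.kernel_.k2.noise_level)

    def predict(self, X, return_std: bool = False):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = self._gpr.predict(X, return_std=return_std)
        return out

    def refit_fixed(self, X, y) -> "GPSurrogate":
        """Refit on new data with hyperparameters frozen at the current MLE."""
        clone = object.__new__(GPSurrogate)
        clone._gpr = GaussianProcessRegressor(
            kernel=self._gpr.kernel_, optimizer=None, normalize_y=True
        )
        clone._gpr.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=float).ravel())
        clone.X_train = np.asarray(X, dtype=float)
        clone.y_train = np.asarray(y, dtype=float).ravel()
        return clone


def fit_gp(X, y, seed: int = 0) -> GPSurrogate:
    """Fit the kriging surrogate to (setpoints, response) data."""
    return GPSurrogate(X, y, seed=seed)


def jackknife_predictions(X, y, seed: int = 0, gp: GPSurrogate | None = None) -> np.ndarray:
    """Leave-one-out GP predictions at each training point.

    The kernel hyperparameters are estimated once on the full data, then
    each point is predicted from a refit (fixed hyperparameters) on the
    other n-1 points — the standard fast jackknife for kriging
    goodness-of-fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 6:
        raise DataError("jackknife needs at least 6 points")
    full = gp if gp is not None else fit_gp(X, y, seed=seed)
    preds = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        sub = full.refit_fixed(X[keep], y[keep])
        preds[i] = float(sub.predict(X[i : i + 1])[0])
    return preds


def minimize_dr(gp: GPSurrogate, bounds, n_starts: int = 20, seed: int = 0):
    """Minimize the surrogate-predicted log10 DR over the box ``bounds``.

    Multi-start L-BFGS-B from a Latin hypercube of starting points plus
    the best training point.  Returns ``(argmin setpoint, predicted DR)``
    with the DR back-transformed from log10.
    """
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(~np.isfinite(lo)) or np.any(~np.isfinite(hi)) or np.any(hi <= lo):
        raise ConfigurationError("minimize_dr needs finite bounds with high > low")

    def f(x):
        return float(gp.predict(x.reshape(1, -1))[0])

    starts = latin_hypercube(n_starts, lo.size, bounds=list(zip(lo, hi)), seed=seed)
    best_train = gp.X_train[np.argmin(gp.y_train)]
    starts = np.vstack([starts, np.clip(best_train, lo, hi)])

    best_x, best_f = None, np.inf
    for x0 in starts:
        res = scipy.optimize.minimize(f, x0, method="L-BFGS-B", bounds=list(zip(lo, hi)))
        if res.fun < best_f:
            best_x, best_f = np.clip(res.x, lo, hi), float(res.fun)
    return best_x, 10.0 ** best_f


@dataclass
class SimExperiment:
    """Result bundle of one LHS defect-rate simulation experiment."""

    lhs_points: np.ndarray          # coded setpoints, point x factor
    actual_points: np.ndarray       # same points in actual units
    dr: np.ndarray
    log10_dr: np.ndarray
    dr_floor: float                 # continuity-correction floor applied to DR=0
    gp: GPSurrogate
    jackknife: np.ndarray
    optimum_coded: np.ndarray
    optimum_actual: np.ndarray
    predicted_min_dr: float

    @property
    def jackknife_r2(self) -> float:
        ss_res = float(np.sum((self.log10_dr - self.jackknife) ** 2))
        ss_tot = float(np.sum((self.log10_dr - self.log10_dr.mean()) ** 2))
        return 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot


def run_simulation_experiment(
    models: dict[str, FittedModel],
    spec: DefectSpec,
    n_points: int = 80,
    runs_per_point: int | None = None,
    seed: int = 0,
    factor_space: float = 1.0,
) -> SimExperiment:
    """LHS sweep of setpoints, DR at each, GP on log10 DR, jackknife, minimization.

    Setpoints cover the coded cube scaled by ``factor_space``; the defect
    rate at each setpoint reuses ``spec`` with the setpoint substituted.
    Zero-defect points are floored at 0.5/runs (continuity correction)
    before taking log10.
    """
    k = len(spec.factor_specs)
    runs = runs_per_point if runs_per_point is not None else spec.n_runs
    cube = [(-factor_space, factor_space)] * k
    coded_pts = latin_hypercube(n_points, k, bounds=cube, seed=seed)
    design = DesignMatrix("LHS", coded_pts, [fs.name for fs in spec.factor_specs])
    actual_pts = coded_to_actual(design, spec.factor_specs)

    dr = np.empty(n_points)
    for i in range(n_points):
        point_spec = spec.with_setpoint(actual_pts[i])
        point_spec.n_runs = runs
        point_spec.seed = int(np.random.default_rng((seed, i)).integers(2**31))
        dr[i] = simulate_defect_rate(models, point_spec).overall_dr

    floor = 0.5 / runs
    log10_dr = np.log10(np.maximum(dr, floor))

    gp = fit_gp(coded_pts, log10_dr, seed=seed)
    jack = jackknife_predictions(coded_pts, log10_dr, seed=seed, gp=gp)
    opt_coded, pred_dr = minimize_dr(gp, cube, seed=seed)
    opt_design = DesignMatrix("custom", opt_coded.reshape(1, -1),
                              [fs.name for fs in spec.factor_specs])
    opt_actual = coded_to_actual(opt_design, spec.factor_specs)[0]

    return SimExperiment(
        lhs_points=coded_pts,
        actual_points=actual_pts,
        dr=dr,
        log10_dr=log10_dr,
        dr_floor=floor,
        gp=gp,
        jackknife=jack,
        optimum_coded=opt_coded,
        optimum_actual=opt_actual,
        predicted_min_dr=pred_dr,
    )
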