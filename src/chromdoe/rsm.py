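"""Response-surface model fitting on coded factor designs.

Two model forms are supported: ``main_effects`` (intercept + linear
terms, the screening model a Plackett-Burman design can estimate) and
``full_quadratic`` (intercept, linear, two-factor interactions, pure
quadratics — the model a Box-Behnken design supports).  Fitting is
ordinary least squares in coded units; standardized effects (t-ratios)
against a Student-t critical value give the Pareto screening ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .designs import DesignMatrix
from .errors import ConfigurationError, DataError, DomainError, ShapeError, SingularFitError

MAIN_EFFECTS = "main_effects"
FULL_QUADRATIC = "full_quadratic"


def term_labels(factor_names: list[str], form: str) -> list[str]:
    """Ordered term labels for a model form: intercept, linear, interactions, squares."""
    labels = ["intercept"] + list(factor_names)
    if form == FULL_QUADRATIC:
        labels += [f"{a}*{b}" for a, b in combinations(factor_names, 2)]
        labels += [f"{x}^2" for x in factor_names]
    elif form != MAIN_EFFECTS:
        raise ConfigurationError(f"unknown model form {form!r}")
    return labels


def model_matrix(coded: np.ndarray, form: str) -> np.ndarray:
    """Expand coded factor settings into the OLS design matrix for ``form``."""
    coded = np.atleast_2d(np.asarray(coded, dtype=float))
    cols = [np.ones(coded.shape[0]), *coded.T]
    if form == FULL_QUADRATIC:
        k = coded.shape[1]
        cols += [coded[:, i] * coded[:, j] for i, j in combinations(range(k), 2)]
        cols += [coded[:, i] ** 2 for i in range(k)]
    elif form != MAIN_EFFECTS:
        raise ConfigurationError(f"unknown model form {form!r}")
    return np.column_stack(cols)


@dataclass
class FittedModel:
    """An OLS response-surface fit in coded units."""

    form: str
    factor_names: list[str]
    terms: list[str]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    residual_df: int
    rmse: float
    r2: float
    t_ratios: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        # SE = 0 happens on exact fits: t is 0 for a zero coefficient
        # (no evidence of an effect) and +-inf for a nonzero one.
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.divide(
                self.coefficients,
                self.standard_errors,
                out=np.zeros_like(self.coefficients),
                where=self.standard_errors > 0,
            )
        zero_se = self.standard_errors == 0
        ratio[zero_se & (self.coefficients != 0)] = np.inf
        ratio[zero_se & (self.coefficients != 0) & (self.coefficients < 0)] = -np.inf
        self.t_ratios = ratio
        if not hasattr(self, "_xtx_inv"):
            self._xtx_inv = None

    @property
    def n_factors(self) -> int:
        return len(self.factor_names)

    def predict(self, points, with_interval: bool = False, alpha: float = 0.05):
        """Predicted mean at coded point(s); optionally the SE of the mean.

        ``points`` is a length-k vector or an (n, k) matrix.  With
        ``with_interval`` the standard error of the predicted mean
        (rmse * sqrt(x' (X'X)^-1 x)) and the half-width of the
        (1-alpha) confidence interval are returned alongside the mean.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.shape[1] != self.n_factors:
            raise ShapeError(
                f"point has {pts.shape[1]} coordinates, model has {self.n_factors} factors"
            )
        X = model_matrix(pts, self.form)
        mean = X @ self.coefficients
        squeeze = np.ndim(points) == 1
        if not with_interval:
            return mean[0] if squeeze else mean
        if self._xtx_inv is None:
            raise DataError("prediction intervals need the fitted (X'X)^-1; refit the model")
        se = self.rmse * np.sqrt(np.einsum("ij,jk,ik->i", X, self._xtx_inv, X))
        half = t_critical(alpha, self.residual_df) * se
        if squeeze:
            return mean[0], se[0], half[0]
        return mean, se, half

    def to_dict(self) -> dict:
        return {
            "form": self.form,
            "factor_names": list(self.factor_names),
            "terms": list(self.terms),
            "coefficients": self.coefficients.tolist(),
            "standard_errors": self.standard_errors.tolist(),
            "t_ratios": self.t_ratios.tolist(),
            "residual_df": self.residual_df,
            "rmse": self.rmse,
            "r2": self.r2,
            "xtx_inv": None if self._xtx_inv is None else self._xtx_inv.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedModel":
        m = cls(
            form=d["form"],
            factor_names=list(d["factor_names"]),
            terms=list(d["terms"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            standard_errors=np.asarray(d["standard_errors"], dtype=float),
            residual_df=int(d["residual_df"]),
            rmse=float(d["rmse"]),
            r2=float(d["r2"]),
        )
        xtx = d.get("xtx_inv")
        if xtx is not None:
            m._xtx_inv = np.asarray(xtx, dtype=float)
        return m


def _aliased_terms(X: np.ndarray, labels: list[str]) -> list[str]:
    # Pivoted QR: columns pivoted past the numerical rank are linearly
    # dependent on earlier ones.
    _, r, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
    diag = np.abs(np.diag(r))
    tol = X.shape[1] * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    rank = int((diag > tol).sum())
    return [labels[i] for i in sorted(piv[rank:])]


def fit_model(design: DesignMatrix, response, form: str) -> FittedModel:
    """Ordinary least squares of a response on the coded design.

    Raises :class:`SingularFitError` (naming the aliased terms) when the
    requested form is not estimable from the design — e.g. pure quadratic
    terms on a two-level Plackett-Burman design — and :class:`DataError`
    when the model saturates the runs (residual df = 0).
    """
    y = np.asarray(response, dtype=float).ravel()
    if y.size != design.n_runs:
        raise ShapeError(f"response has {y.size} values for {design.n_runs} runs")
    if not np.all(np.isfinite(y)):
        raise DataError("response contains non-finite values")

    labels = term_labels(design.factor_names, form)
    X = model_matrix(design.coded, form)

    if np.linalg.matrix_rank(X) < X.shape[1]:
        aliased = _aliased_terms(X, labels)
        raise SingularFitError(
            f"model matrix is rank deficient; aliased terms: {', '.join(aliased)}",
            aliased_terms=aliased,
        )
    residual_df = y.size - X.shape[1]
    if residual_df < 1:
        raise DataError(
            f"saturated model: {X.shape[1]} terms for {y.size} runs leaves no residual df"
        )

    res = sm.OLS(y, X).fit()
    rmse = float(np.sqrt(res.ssr / residual_df))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if sst == 0 else float(1.0 - res.ssr / sst)

    model = FittedModel(
        form=form,
        factor_names=list(design.factor_names),
        terms=labels,
        coefficients=np.asarray(res.params, dtype=float),
        standard_errors=np.asarray(res.bse, dtype=float),
        residual_df=residual_df,
        rmse=rmse,
        r2=r2,
    )
    model._xtx_inv = np.linalg.inv(X.T @ X)
    return model


def t_critical(alpha: float, df: int) -> float:
    """Two-sided Student-t critical value at level ``alpha`` with ``df`` degrees of freedom."""
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1:
        raise DomainError(f"df must be >= 1, got {df}")
    return float(scipy.stats.t.ppf(1.0 - alpha / 2.0, df))


def pareto_effects(model: FittedModel, alpha: float = 0.05):
    """Standardized effects ranked by |t|, flagged against the critical t.

    Returns a list of ``(term, abs_t, significant, sign)`` tuples for every
    non-intercept term, sorted by decreasing |t|.  Significance uses a
    strict inequality, so an effect exactly at the critical value is not
    flagged.
    """
    tcrit = t_critical(alpha, model.residual_df)
    rows = []
    for term, t in zip(model.terms[1:], model.t_ratios[1:]):
        rows.append((term, abs(float(t)), abs(float(t)) > tcrit, int(np.sign(t))))
    rows.sort(key=lambda r: -r[1])
    return rows


def pb_main_effect_contrasts(design: DesignMatrix, response) -> dict[str, float]:
    """Brute-force main effects on the PB base block: ((mean at +1) - (mean at -1)) / 2.

    Center rows are excluded; equals the OLS linear coefficients on an
    orthogonal two-level design and serves as an independent cross-check.
    """
    y = np.asarray(response, dtype=float)[: design.n_runs - design.n_center]
    base = design.base
    out = {}
    for j, name in enumerate(design.factor_names):
        hi, lo = base[:, j] > 0, base[:, j] < 0
        out[name] = (y[hi].mean() - y[lo].mean()) / 2.0
    return out
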