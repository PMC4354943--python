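"""Screening and response-surface designs in coded units.

Plackett-Burman (PB) two-level screening designs and Box-Behnken (BB)
three-level response-surface designs, plus the affine map between coded
levels (-1, 0, +1) and actual instrument settings.  All designs are
emitted in a canonical deterministic order with center points (all
factors at their mid level) appended last; an optional seeded shuffle is
available for users who want a randomized run order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import CapacityError, ConfigurationError, ShapeError

# Canonical first row of the 12-run Plackett-Burman cyclic construction.
_PB12_GENERATOR = np.array([+1, +1, -1, +1, +1, +1, -1, -1, -1, +1, -1])


@dataclass(frozen=True)
class FactorSpec:
    """An instrument factor with its coded-level anchors.

    ``low``/``mid``/``high`` are the actual-unit settings mapped to coded
    -1/0/+1.  ``sim_sd`` is the standard deviation (actual units) of the
    run-to-run variation assumed by the defect-rate simulator.
    """

    name: str
    unit: str
    low: float
    mid: float
    high: float
    sim_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.low < self.mid < self.high):
            raise ConfigurationError(
                f"factor {self.name!r}: levels must satisfy low < mid < high, "
                f"got {self.low}, {self.mid}, {self.high}"
            )
        if self.sim_sd < 0:
            raise ConfigurationError(f"factor {self.name!r}: sim_sd must be >= 0")

    @property
    def half_range(self) -> float:
        return (self.high - self.low) / 2.0

    def to_actual(self, coded):
        """Map coded level(s) to actual units: actual = mid + coded*(high-low)/2."""
        return self.mid + np.asarray(coded, dtype=float) * self.half_range

    def to_coded(self, actual):
        """Inverse of :meth:`to_actual`."""
        return (np.asarray(actual, dtype=float) - self.mid) / self.half_range


@dataclass
class DesignMatrix:
    """A run x factor table in coded units.

    ``family`` records the construction ("PB", "BB", "LHS" or "custom");
    ``n_center`` is the number of trailing all-zero center rows.
    """

    family: str
    coded: np.ndarray
    factor_names: list[str]
    n_center: int = 0

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded, dtype=float)
        if self.coded.ndim != 2:
            raise ShapeError("coded design must be a 2-D run x factor array")
        if self.coded.shape[1] != len(self.factor_names):
            raise ShapeError(
                f"{self.coded.shape[1]} columns but {len(self.factor_names)} factor names"
            )
        if np.abs(self.coded).max(initial=0.0) > 1.0 + 1e-12:
            raise ConfigurationError("coded entries must lie in [-1, +1]")

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def n_factors(self) -> int:
        return self.coded.shape[1]

    @property
    def base(self) -> np.ndarray:
        """The non-center block (first n_runs - n_center rows)."""
        return self.coded[: self.n_runs - self.n_center]

    def shuffled(self, seed: int) -> "DesignMatrix":
        """Return a copy with a seeded random run order (center rows included)."""
        rng = np.random.default_rng(seed)
        perm = rng.permutation(self.n_runs)
        return DesignMatrix(self.family, self.coded[perm], list(self.factor_names), 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.coded, columns=self.factor_names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, family: str = "custom", n_center: int = 0) -> "DesignMatrix":
        df = pd.read_csv(path)
        return cls(family, df.to_numpy(dtype=float), list(df.columns), n_center)


def _default_names(n_factors: int) -> list[str]:
    return [f"X{i + 1}" for i in range(n_factors)]


def generate_pb(
    n_factors: int,
    base_runs: int = 12,
    n_center: int = 0,
    factor_names: list[str] | None = None,
) -> DesignMatrix:
    """Plackett-Burman screening design from the 12-run cyclic generator.

    The base block cycles the canonical generator row through ``base_runs - 1``
    rows and appends the all-minus row; the first ``n_factors`` columns are
    kept.  Columns of the base block are mutually orthogonal, so up to
    ``base_runs - 1`` main effects can be estimated.  ``n_center`` all-zero
    rows are appended for a pure-error / curvature check.
    """
    if base_runs != 12:
        raise ConfigurationError(
            f"only the canonical 12-run PB construction is provided, got base_runs={base_runs}"
        )
    if n_factors < 1:
        raise ConfigurationError("n_factors must be >= 1")
    if n_factors > base_runs - 1:
        raise CapacityError(
            f"a {base_runs}-run PB design holds at most {base_runs - 1} factors, "
            f"got {n_factors}"
        )
    if n_center < 0:
        raise ConfigurationError("n_center must be >= 0")

    rows = [np.roll(_PB12_GENERATOR, shift) for shift in range(base_runs - 1)]
    rows.append(-np.ones(base_runs - 1, dtype=int))
    base = np.array(rows, dtype=float)[:, :n_factors]
    coded = np.vstack([base, np.zeros((n_center, n_factors))])
    names = factor_names or _default_names(n_factors)
    return DesignMatrix("PB", coded, names, n_center)


def generate_bb(
    n_factors: int,
    n_center: int = 0,
    factor_names: list[str] | None = None,
) -> DesignMatrix:
    """Box-Behnken design: edge midpoints of the factor cube plus center points.

    For each pair of factors the four (+-1, +-1) combinations are run with
    every other factor held at 0; for 3 factors this gives the classical
    12-run block, to which ``n_center`` all-zero rows are appended.
    """
    if n_factors < 3:
        raise ConfigurationError(
            f"Box-Behnken designs need at least 3 factors, got {n_factors}"
        )
    if n_center < 0:
        raise ConfigurationError("n_center must be >= 0")

    rows = []
    for i, j in combinations(range(n_factors), 2):
        for si in (-1.0, 1.0):
            for sj in (-1.0, 1.0):
                row = np.zeros(n_factors)
                row[i], row[j] = si, sj
                rows.append(row)
    coded = np.vstack(rows + [np.zeros((n_center, n_factors))])
    names = factor_names or _default_names(n_factors)
    return DesignMatrix("BB", coded, names, n_center)


def coded_to_actual(design: DesignMatrix, specs: list[FactorSpec]) -> np.ndarray:
    """Map a coded design to actual instrument units, one FactorSpec per column."""
    if len(specs) != design.n_factors:
        raise ShapeError(
            f"design has {design.n_factors} factors but {len(specs)} specs given"
        )
    mids = np.array([s.mid for s in specs])
    halves = np.array([s.half_range for s in specs])
    return mids + design.coded * halves


def actual_to_coded(actual: np.ndarray, specs: list[FactorSpec]) -> np.ndarray:
    """Inverse of :func:`coded_to_actual` on a plain run x factor array."""
    actual = np.asarray(actual, dtype=float)
    if actual.shape[-1] != len(specs):
        raise ShapeError(
            f"array has {actual.shape[-1]} columns but {len(specs)} specs given"
        )
    mids = np.array([s.mid for s in specs])
    halves = np.array([s.half_range for s in specs])
    return (actual - mids) / halves
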