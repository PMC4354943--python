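import numpy as np
import pytest

from chromdoe import designs, rsm


@pytest.fixture
def flow_spec():
    return designs.FactorSpec("flow", "mL/min", 0.6, 0.8, 1.0, sim_sd=0.1 / 3)


@pytest.fixture
def table1_specs():
    """The five screening factors of the fixture assay."""
    return [
        designs.FactorSpec("flow", "mL/min", 0.6, 0.8, 1.0, sim_sd=0.1 / 3),
        designs.FactorSpec("volume", "uL", 10.0, 15.0, 20.0, sim_sd=0.5),
        designs.FactorSpec("wavelength", "nm", 265.0, 270.0, 275.0, sim_sd=2.0 / 3),
        designs.FactorSpec("organic_init", "% v/v", 60.0, 70.0, 80.0, sim_sd=2.0 / 3),
        designs.FactorSpec("organic_late", "% v/v", 85.0, 90.0, 95.0, sim_sd=2.0 / 3),
    ]


def make_constant_model(
    intercept: float,
    rmse: float,
    factor_names=("x1",),
    form=rsm.MAIN_EFFECTS,
    residual_df: int = 5,
    coefficients: dict | None = None,
) -> rsm.FittedModel:
    """Hand-built response model for simulator oracle tests.

    ``coefficients`` maps term label -> value for any non-intercept terms;
    standard errors are set to 1 so t-ratios equal the coefficients.
    """
    terms = rsm.term_labels(list(factor_names), form)
    coef = np.zeros(len(terms))
    coef[0] = intercept
    for term, value in (coefficients or {}).items():
        coef[terms.index(term)] = value
    return rsm.FittedModel(
        form=form,
        factor_names=list(factor_names),
        terms=terms,
        coefficients=coef,
        standard_errors=np.ones(len(terms)),
        residual_df=residual_df,
        rmse=rmse,
        r2=1.0,
    )


@pytest.fixture
def unit_factor_specs():
    """Two coded-identity factors (actual == coded) with no random variation."""
    return [
        designs.FactorSpec("x1", "", -1.0, 0.0, 1.0, sim_sd=0.0),
        designs.FactorSpec("x2", "", -1.0, 0.0, 1.0, sim_sd=0.0),
    ]
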