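import numpy as np
import pytest
from scipy import special

from intelligrowth.betareg import BetaGrowthModel
from intelligrowth.splines import NaturalSplineBasis
from intelligrowth.synthetic import (
    NSMI_TRUTH,
    SMI_TRUTH,
    TD_TRUTH,
    generate_cp_cohort,
    generate_td_cohort,
)
from intelligrowth.betareg import fit_beta_growth


def constant_model(mu: float, phi: float) -> BetaGrowthModel:
    """A growth model whose distribution is the same Beta(mu*phi, (1-mu)*phi)
    at every age in [30, 96] (all spline weights zero)."""
    mean_basis = NaturalSplineBasis(df=3, interior_knots=(52.0, 74.0),
                                    boundary_knots=(30.0, 96.0))
    prec_basis = NaturalSplineBasis(df=2, interior_knots=(63.0,),
                                    boundary_knots=(30.0, 96.0))
    return BetaGrowthModel(
        mean_basis=mean_basis,
        precision_basis=prec_basis,
        mean_coefs=np.array([special.logit(mu), 0.0, 0.0, 0.0]),
        precision_coefs=np.array([np.log(phi), 0.0, 0.0]),
        loglik=0.0,
        n_obs=0,
        converged=True,
    )


@pytest.fixture(scope="session")
def td_cohort():
    return generate_td_cohort(505, TD_TRUTH, seed=1)


@pytest.fixture(scope="session")
def cp_cohort():
    return generate_cp_cohort(21, 44, NSMI_TRUTH, SMI_TRUTH, seed=2)


@pytest.fixture(scope="session")
def td_model(td_cohort):
    return fit_beta_growth(td_cohort)


@pytest.fixture(scope="session")
def nsmi_model(cp_cohort):
    return fit_beta_growth(cp_cohort.subset("NSMI"))


@pytest.fixture(scope="session")
def smi_model(cp_cohort):
    return fit_beta_growth(cp_cohort.subset("SMI"))


@pytest.fixture(scope="session")
def td_cohort_large():
    return generate_td_cohort(2000, TD_TRUTH, seed=1)


@pytest.fixture(scope="session")
def td_model_large(td_cohort_large):
    return fit_beta_growth(td_cohort_large)
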