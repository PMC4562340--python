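import numpy as np
import pandas as pd
import pytest

import adipometh as am
from adipometh.diffmeth import beta_to_m


def exact_stats_samples(mean: float, sd: float, n: int) -> np.ndarray:
    """n values with exactly the given mean and (ddof=1) SD."""
    z = np.linspace(-1.0, 1.0, n)
    z = (z - z.mean()) / z.std(ddof=1)
    return mean + sd * z


@pytest.fixture(scope="session")
def default_cohort() -> am.SimulatedCohort:
    return am.simulate_cohort(am.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def fitted_cohort(default_cohort):
    """Default cohort with the methylation and expression fits run once."""
    c = default_cohort
    m = pd.DataFrame(
        beta_to_m(c.betas.to_numpy()), index=c.betas.index, columns=c.betas.columns
    )
    meth = am.fit_moderated(m, c.sheet)
    gene_matrix, chosen = am.collapse_probesets(c.expression, c.probeset_map)
    expr = am.fit_de(gene_matrix, c.sheet, chosen=chosen)
    return c, meth, expr


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
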