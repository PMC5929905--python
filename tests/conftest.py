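import numpy as np
import pytest

from ascnet.covariance import StateCovariance, StateSeries, TwoStateSummary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_summary(rho_a, rho_b, var_a=1.0, var_b=1.44, dof=200.0, n=230):
    """Two-state summary with equal variances per state and explicit dof."""
    dof = min(dof, n)
    sa = StateCovariance(var_a, var_a, rho_a * var_a, n, dof)
    sb = StateCovariance(var_b, var_b, rho_b * var_b, n, dof)
    return TwoStateSummary(state_a=sa, state_b=sb, pair_labels=("x", "y"))


def bivariate_series(rho, n, rng, labels=("x", "y"), scale=(1.0, 1.0)):
    z = rng.normal(size=(n, 2))
    z[:, 1] = rho * z[:, 0] + np.sqrt(1 - rho ** 2) * z[:, 1]
    return StateSeries(values=z * np.asarray(scale), node_labels=labels)
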