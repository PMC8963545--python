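import numpy as np
import pytest

from mrselect.gwas import TwoSampleSummary
from mrselect.popgen import calibrate_alpha_scale


def make_summary(beta_x, beta_y, se_x=None, se_y=None) -> TwoSampleSummary:
    """Summary container from plain lists with default unit-ish SEs."""
    beta_x = np.asarray(beta_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    J = beta_x.size
    se_x = np.full(J, 0.01) if se_x is None else np.asarray(se_x, dtype=float)
    se_y = np.full(J, 0.1) if se_y is None else np.asarray(se_y, dtype=float)
    return TwoSampleSummary(
        snp_ids=np.array([f"snp_{j}" for j in range(J)]),
        beta_x=beta_x,
        beta_y=beta_y,
        se_x=se_x,
        se_y=se_y,
    )


def simulate_summary(
    rng: np.random.Generator,
    J: int = 50,
    theta: float = 0.0,
    n: int = 2000,
) -> TwoSampleSummary:
    """Summary-level emulation of one two-sample GWAS replicate: true SNP
    effects alpha ~ U(0, a) at the calibrated scale, association estimates
    drawn from normals with the sampling SEs implied by marginal regression
    at sample size ``n`` (genotype variance 0.42, residual variances from
    the structural model with unit confounder effects)."""
    a = calibrate_alpha_scale(J, 0.10)
    alpha = rng.uniform(0.0, a, J)
    var_g = 0.42
    var_x = 2.0 / 0.9  # (b^2 + 1) / (1 - r2)
    var_y = theta**2 * var_x + 1.0 + 1.0 + 2.0 * theta  # c^2 Var(U)+Var(eps)+2 theta c Cov(X,U)
    se_x = np.full(J, np.sqrt(var_x / (n * var_g)))
    se_y = np.full(J, np.sqrt(var_y / (n * var_g)))
    beta_x = rng.normal(alpha, se_x)
    beta_y = rng.normal(theta * alpha, se_y)
    return make_summary(beta_x, beta_y, se_x, se_y)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
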