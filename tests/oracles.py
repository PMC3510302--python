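"""Independent oracles used by the unit and acceptance tests.

These never call the package's Laplace/Newton code path.
"""

import numpy as np
from scipy.stats import multivariate_normal


def exact_gp_probit_probability(
    X: np.ndarray,
    y: np.ndarray,
    x_test: np.ndarray,
    amplitude: float = 1.0,
    bias: float = 0.0,
) -> float:
    """Exact predictive class-1 probability of a probit-likelihood GP.

    For f ~ N(0, K) and probit likelihood, E[prod_i Phi(y_i f_i)] equals
    a Gaussian orthant probability: introducing iid e_i ~ N(0,1),
    Phi(y_i f_i) = P(e_i < y_i f_i), so the expectation is the CDF at 0
    of N(0, I + D K D) with D = diag(y).  The exact predictive is the
    ratio of the joint (training + test, test label +1) orthant
    probability to the training-only one.  Equivalent to brute-force
    quadrature over the latent posterior, computed via scipy's
    multivariate-normal CDF (Genz's algorithm).
    """

    def orthant(K, labels):
        D = np.diag(labels)
        cov = np.eye(len(labels)) + D @ K @ D
        dist = multivariate_normal(mean=np.zeros(len(labels)), cov=cov, allow_singular=True)
        return dist.cdf(np.zeros(len(labels)))

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    XJ = np.vstack([X, np.atleast_2d(x_test)])
    K_joint = amplitude * (XJ @ XJ.T) + bias
    K_train = amplitude * (X @ X.T) + bias
    return orthant(K_joint, np.append(y, 1.0)) / orthant(K_train, y)


def ols_residual_columns(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Per-column OLS residuals of X on C (lstsq route, no projector)."""
    out = np.empty_like(X, dtype=float)
    for j in range(X.shape[1]):
        coef, *_ = np.linalg.lstsq(C, X[:, j], rcond=None)
        out[:, j] = X[:, j] - C @ coef
    return out


def anova_f_by_sums_of_squares(groups) -> tuple[float, int, int]:
    """Hand computation of the one-way ANOVA F statistic."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw
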