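"""Binary Gaussian process classification with the Laplace approximation.

Linear kernel (optionally trace-normalized), probit likelihood, and a
Newton-iteration Laplace approximation to the latent posterior using the
numerically stable ``B = I + W^{1/2} K W^{1/2}`` factorization.  The
probit link is the default because its predictive integral has a closed
form under a Gaussian latent: ``p = Phi(mu / sqrt(1 + var))``.

The classifier is purely probabilistic: it returns the predictive
probability of class 1 (the +1 label) and never applies a decision
threshold itself.  For linear kernels the dual solution maps back to a
primal voxel-weight vector, which is the discriminating map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import log_ndtr, ndtr

from mvgpc.errors import (
    ConvergenceError,
    InvalidLabelError,
    ShapeError,
    UnsupportedKernelError,
)
from mvgpc.first_level import FeatureMatrix

#: Evidence grid for the kernel amplitude hyperparameter.
AMPLITUDE_GRID = tuple(2.0**k for k in range(-6, 7))

_NORM_CONST = -0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class KernelOptions:
    """Linear-kernel settings.

    ``amplitude`` may be a positive scalar or the string ``"grid"`` to
    select it by maximizing the Laplace-approximate log marginal
    likelihood over :data:`AMPLITUDE_GRID`.  ``normalize`` rescales the
    raw Gram matrix by ``n_train / trace`` before applying the
    amplitude, making the amplitude scale-free across feature counts.
    """

    amplitude: float | str = "grid"
    bias: float = 0.0
    normalize: bool = False
    name: str = "linear"

    def __post_init__(self):
        if isinstance(self.amplitude, str):
            if self.amplitude != "grid":
                raise UnsupportedKernelError(f"unknown amplitude {self.amplitude!r}")
        elif self.amplitude <= 0:
            raise InvalidLabelError("amplitude must be > 0")
        if self.bias < 0:
            raise InvalidLabelError("bias must be >= 0")


def _probit_moments(f: np.ndarray, y: np.ndarray):
    """Log-likelihood, gradient, and negative Hessian diag for probit."""
    z = y * f
    log_lik = log_ndtr(z).sum()
    # phi(z)/Phi(z), computed in log space for stability at z << 0
    ratio = np.exp(_NORM_CONST - 0.5 * z * z - log_ndtr(z))
    grad = y * ratio
    w = ratio * (z + ratio)
    return log_lik, grad, np.maximum(w, 1e-12)


@dataclass
class _LaplaceFit:
    """Laplace posterior state for one Gram matrix + labels."""

    latent_mode: np.ndarray
    alpha: np.ndarray  # gradient of the log likelihood at the mode
    sqrt_w: np.ndarray
    cho: tuple  # Cholesky of B = I + sqrtW K sqrtW
    log_marginal_likelihood: float
    n_iterations: int


def laplace_fit_gram(
    K: np.ndarray, y: np.ndarray, tol: float = 1e-6, max_iter: int = 100
) -> _LaplaceFit:
    """Newton iteration to the posterior mode (stable parameterization)."""
    n = y.size
    f = np.zeros(n)
    obj_prev = -np.inf
    for iteration in range(1, max_iter + 1):
        _, grad, w = _probit_moments(f, y)
        sw = np.sqrt(w)
        B = np.eye(n) + sw[:, None] * K * sw[None, :]
        cho = cho_factor(B, lower=True)
        b = w * f + grad
        a = b - sw * cho_solve(cho, sw * (K @ b))
        f = K @ a
        log_lik, _, _ = _probit_moments(f, y)
        obj = -0.5 * float(a @ f) + log_lik
        if abs(obj - obj_prev) < tol:
            log_lik, grad, w = _probit_moments(f, y)
            sw = np.sqrt(w)
            B = np.eye(n) + sw[:, None] * K * sw[None, :]
            cho = cho_factor(B, lower=True)
            lml = obj - float(np.log(np.diag(cho[0])).sum())
            return _LaplaceFit(
                latent_mode=f,
                alpha=grad,
                sqrt_w=sw,
                cho=cho,
                log_marginal_likelihood=lml,
                n_iterations=iteration,
            )
        obj_prev = obj
    raise ConvergenceError(
        f"Laplace mode finding did not converge in {max_iter} iterations",
        n_iterations=max_iter,
    )


def laplace_predict_gram(
    fit: _LaplaceFit, k_cross: np.ndarray, k_diag: np.ndarray
) -> np.ndarray:
    """Predictive class-1 probabilities from cached training state.

    ``k_cross`` is (n_test, n_train); ``k_diag`` the test self-kernels.
    """
    mu = k_cross @ fit.alpha
    v = cho_solve(fit.cho, (fit.sqrt_w[:, None] * k_cross.T))
    var = np.maximum(k_diag - np.einsum("ij,ij->j", fit.sqrt_w[:, None] * k_cross.T, v), 0.0)
    p = ndtr(mu / np.sqrt(1.0 + var))
    return np.clip(p, 1e-15, 1.0 - 1e-15)


@dataclass
class GpcModel:
    """Trained GP classifier state for a linear kernel."""

    train_features: np.ndarray
    labels: np.ndarray
    kernel: KernelOptions
    amplitude: float  # selected amplitude (post grid search)
    scale: float  # effective multiplier on X X' (amplitude x normalization)
    fit: _LaplaceFit = field(repr=False)

    @property
    def latent_mode(self) -> np.ndarray:
        return self.fit.latent_mode

    @property
    def dual_coefficients(self) -> np.ndarray:
        return self.fit.alpha

    @property
    def log_marginal_likelihood(self) -> float:
        return self.fit.log_marginal_likelihood


def _validate_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float).ravel()
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise InvalidLabelError("labels must be +1/-1")
    if np.unique(y).size < 2:
        raise InvalidLabelError("need both classes present in training labels")
    return y


def gpc_train(
    X: np.ndarray | FeatureMatrix,
    y: np.ndarray,
    kernel_opts: KernelOptions | None = None,
) -> GpcModel:
    """Train on examples-by-features X with +/-1 labels."""
    opts = kernel_opts or KernelOptions()
    if opts.name != "linear":
        raise UnsupportedKernelError(f"unsupported kernel {opts.name!r}")
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if Xv.ndim != 2:
        raise ShapeError("X must be 2-D (examples x features)")
    y = _validate_labels(y)
    if Xv.shape[0] != y.size:
        raise ShapeError("X rows must equal label count")

    K0 = Xv @ Xv.T
    norm = Xv.shape[0] / np.trace(K0) if (opts.normalize and np.trace(K0) > 0) else 1.0

    if opts.amplitude == "grid":
        best = None
        for amp in AMPLITUDE_GRID:
            fit = laplace_fit_gram(amp * norm * K0 + opts.bias, y)
            if best is None or fit.log_marginal_likelihood > best[1].log_marginal_likelihood:
                best = (amp, fit)
        amplitude, fit = best
    else:
        amplitude = float(opts.amplitude)
        fit = laplace_fit_gram(amplitude * norm * K0 + opts.bias, y)

    return GpcModel(
        train_features=Xv,
        labels=y,
        kernel=opts,
        amplitude=amplitude,
        scale=amplitude * norm,
        fit=fit,
    )


def gpc_predict(model: GpcModel, x: np.ndarray) -> float | np.ndarray:
    """Predictive probability of class 1 for one or more test vectors."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xt = np.atleast_2d(x)
    if xt.shape[1] != model.train_features.shape[1]:
        raise ShapeError(
            f"test feature length {xt.shape[1]} != training "
            f"{model.train_features.shape[1]}"
        )
    k_cross = model.scale * (xt @ model.train_features.T) + model.kernel.bias
    k_diag = model.scale * np.einsum("ij,ij->i", xt, xt) + model.kernel.bias
    p = laplace_predict_gram(model.fit, k_cross, k_diag)
    return float(p[0]) if single else p


def latent_mean(model: GpcModel, x: np.ndarray) -> float | np.ndarray:
    """Latent predictive mean (the decision value before the probit link)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    xt = np.atleast_2d(x)
    k_cross = model.scale * (xt @ model.train_features.T) + model.kernel.bias
    mu = k_cross @ model.fit.alpha
    return float(mu[0]) if single else mu


def primal_weights(model: GpcModel) -> np.ndarray:
    """w = scale * X' alpha; latent mean is w.x + bias * sum(alpha)."""
    if model.kernel.name != "linear":
        raise UnsupportedKernelError("primal weights require a linear kernel")
    return model.scale * (model.train_features.T @ model.fit.alpha)


def weight_map(model: GpcModel, features: FeatureMatrix) -> np.ndarray:
    """Discriminating map: primal weights scattered into volume space.

    Positive voxels carry evidence for class 1 (+1 label), negative for
    class 2.
    """
    w = primal_weights(model)
    if w.size != features.n_voxels:
        raise ShapeError("model was not trained on this feature space")
    return features.scatter(w)
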