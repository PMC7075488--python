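"""Population two-factor measurement models and a small ML CFA fitter.

The population model is a two-factor confirmatory model with standardized
indicators: indicator i of factor X has loading lambda_x.i, unique variance
1 - lambda_x.i**2, and the two factors correlate phi.  The implied
correlation matrix is Lambda Phi Lambda' + Theta with a unit diagonal.

The fitter minimises the normal-theory maximum-likelihood discrepancy

    F(theta) = log|Sigma(theta)| + tr(S Sigma(theta)^-1) - log|S| - p

over loadings, the latent correlation and unique variances, with factor
variances fixed at 1 (all loadings free).  AVE is computed on the completely
standardized solution, lambda_i / sqrt(lambda_i**2 + theta_i).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

from .criteria import LoadingSet
from .errors import DegenerateInputError, InvalidInputError, InvalidModelError

__all__ = [
    "FactorModel",
    "CfaFit",
    "implied_correlation_matrix",
    "population_composite_correlation",
    "sample_dataset",
    "fit_cfa",
]

_UNIQUENESS_FLOOR = 1e-6  # lower bound on unique variances (Heywood handling)
_PHI_BOUND = 1.0 - 1e-6


@dataclass(frozen=True)
class FactorModel:
    """Population two-factor model with standardized indicators."""

    loadings_x: LoadingSet
    loadings_y: LoadingSet
    phi: float

    def __post_init__(self):
        if not np.isfinite(self.phi) or abs(self.phi) > 1.0:
            raise InvalidInputError(f"|phi| must be <= 1, got {self.phi}")
        for label, ls in (("x", self.loadings_x), ("y", self.loadings_y)):
            if np.any(ls.loadings == 0.0):
                raise InvalidInputError(f"factor {label}: zero loadings are not allowed")

    @property
    def error_variances(self) -> np.ndarray:
        lam = np.concatenate([self.loadings_x.loadings, self.loadings_y.loadings])
        return 1.0 - lam**2

    @property
    def n_indicators(self) -> tuple[int, int]:
        return (len(self.loadings_x), len(self.loadings_y))


@dataclass(frozen=True)
class CfaFit:
    """Result of one confirmatory factor analysis fit.

    Loadings and unique variances are reported on the completely
    standardized scale; ``discrepancy`` is the ML fit function value at the
    solution (0 when the sample matrix is reproduced exactly).
    """

    loadings_hat: tuple[LoadingSet, LoadingSet]
    phi_hat: float
    error_variances_hat: np.ndarray
    discrepancy: float
    converged: bool
    n_restarts_used: int
    heywood: bool


def implied_correlation_matrix(model: FactorModel) -> np.ndarray:
    """Model-implied correlation matrix Lambda Phi Lambda' + Theta."""
    lx = model.loadings_x.loadings
    ly = model.loadings_y.loadings
    kx = lx.size
    p = kx + ly.size
    lam = np.zeros((p, 2))
    lam[:kx, 0] = lx
    lam[kx:, 1] = ly
    phi_m = np.array([[1.0, model.phi], [model.phi, 1.0]])
    sigma = lam @ phi_m @ lam.T
    np.fill_diagonal(sigma, 1.0)
    if np.linalg.eigvalsh(sigma).min() < -1e-10:
        raise InvalidModelError("implied correlation matrix is not positive semi-definite")
    return sigma


def population_composite_correlation(model: FactorModel) -> float:
    """Correlation between the two unweighted mean composites.

    Closed form: phi * (sum lam_x)(sum lam_y) / sqrt((K_x + sum_{i!=j}
    lam_x.i lam_x.j) * (K_y + ...)).
    """
    lx = model.loadings_x.loadings
    ly = model.loadings_y.loadings
    sx, sy = lx.sum(), ly.sum()
    varx = lx.size + sx**2 - np.sum(lx**2)
    vary = ly.size + sy**2 - np.sum(ly**2)
    return float(model.phi * sx * sy / np.sqrt(varx * vary))


def sample_dataset(model: FactorModel, n: int, seed) -> np.ndarray:
    """Draw n observations from the model-implied multivariate normal.

    ``seed`` may be anything :func:`numpy.random.default_rng` accepts.
    Deterministic given the seed.
    """
    if n < 10:
        raise InvalidInputError(f"n must be >= 10, got {n}")
    sigma = implied_correlation_matrix(model)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        # PSD but singular (e.g. a loading of exactly 1); fall back to an
        # eigendecomposition square root.
        w, v = np.linalg.eigh(sigma)
        chol = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, sigma.shape[0]))
    return z @ chol.T


def _pack(loadings: np.ndarray, phi: float, uniq: np.ndarray) -> np.ndarray:
    return np.concatenate([loadings, [phi], uniq])


def _discrepancy_and_grad(theta, s_mat, logdet_s, kx, p):
    lam_vec = theta[:p]
    phi = theta[p]
    uniq = theta[p + 1 :]

    lam = np.zeros((p, 2))
    lam[:kx, 0] = lam_vec[:kx]
    lam[kx:, 1] = lam_vec[kx:]
    phi_m = np.array([[1.0, phi], [phi, 1.0]])
    sigma = lam @ phi_m @ lam.T + np.diag(uniq)

    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return 1e12, np.zeros_like(theta)
    sigma_inv = np.linalg.inv(sigma)
    f = logdet + np.trace(s_mat @ sigma_inv) - logdet_s - p

    # dF = tr(A dSigma) with A = Sigma^-1 - Sigma^-1 S Sigma^-1
    a_mat = sigma_inv - sigma_inv @ s_mat @ sigma_inv
    # loading k on factor f: dSigma = e_k (Phi Lam')_f + transpose
    lam_phi = lam @ phi_m  # p x 2
    factor_of = np.concatenate([np.zeros(kx, dtype=int), np.ones(p - kx, dtype=int)])
    grad_lam = 2.0 * (a_mat @ lam_phi)[np.arange(p), factor_of]
    grad_phi = 2.0 * (lam.T @ a_mat @ lam)[0, 1]
    grad_uniq = np.diag(a_mat).copy()
    return f, np.concatenate([grad_lam, [grad_phi], grad_uniq])


def fit_cfa(
    data: np.ndarray | None = None,
    assignment: tuple[Sequence[int], Sequence[int]] | None = None,
    *,
    corr: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    max_restarts: int = 5,
) -> CfaFit:
    """Fit the two-factor CFA to a data matrix or a correlation matrix.

    Parameters
    ----------
    data : ndarray of shape (n, p), optional
        Raw observations; the sample correlation matrix is fitted.
    assignment : pair of index sequences, optional
        Indicator columns of factor X and factor Y.  Defaults to an even
        front/back split.
    corr : ndarray of shape (p, p), optional
        Fit this correlation matrix directly instead of ``data`` (used for
        population-level fits).
    tol, max_iter, max_restarts
        Convergence tolerance on the discrepancy, iteration cap, and number
        of jittered restarts tried after a failed fit.

    Notes
    -----
    Start values: loadings 0.7, phi 0.3, uniquenesses 0.5.  Unique variances
    are bounded below at 1e-6; a solution on that bound is a Heywood case,
    flagged but retained.  Each factor's loading signs are normalised so the
    loading sum is positive, with phi flipped accordingly.
    """
    if (data is None) == (corr is None):
        raise InvalidInputError("provide exactly one of data or corr")
    if corr is None:
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[0] <= data.shape[1]:
            raise InvalidInputError(f"data must be n x p with n > p, got {data.shape}")
        s_mat = np.corrcoef(data, rowvar=False)
    else:
        s_mat = np.asarray(corr, dtype=float)
        if s_mat.ndim != 2 or s_mat.shape[0] != s_mat.shape[1]:
            raise InvalidInputError("corr must be square")
    p = s_mat.shape[0]

    if assignment is None:
        assignment = (tuple(range(p // 2)), tuple(range(p // 2, p)))
    idx_x, idx_y = (np.asarray(a, dtype=int) for a in assignment)
    if idx_x.size < 2 or idx_y.size < 2:
        raise InvalidInputError("each factor needs at least 2 indicators")
    order = np.concatenate([idx_x, idx_y])
    if sorted(order.tolist()) != list(range(p)):
        raise InvalidInputError("assignment must partition the indicator columns")
    s_mat = s_mat[np.ix_(order, order)]
    kx = idx_x.size

    sign_s, logdet_s = np.linalg.slogdet(s_mat)
    if sign_s <= 0 or not np.isfinite(logdet_s):
        raise DegenerateInputError("sample correlation matrix is singular")

    bounds = (
        [(-2.0, 2.0)] * p
        + [(-_PHI_BOUND, _PHI_BOUND)]
        + [(_UNIQUENESS_FLOOR, 10.0)] * p
    )
    start = _pack(np.full(p, 0.7), 0.3, np.full(p, 0.5))
    rng = np.random.default_rng(12345)  # fixed: restarts deterministic given data

    best = None
    n_restarts_used = 0
    for attempt in range(max_restarts + 1):
        x0 = start if attempt == 0 else start + rng.uniform(-0.15, 0.15, start.size)
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            _discrepancy_and_grad,
            x0,
            args=(s_mat, logdet_s, kx, p),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": tol},
        )
        if best is None or res.fun < best.fun:
            best = res
            n_restarts_used = attempt
        if res.success and np.isfinite(res.fun):
            best = res
            n_restarts_used = attempt
            break

    theta = best.x
    lam_vec = theta[:p].copy()
    phi_hat = float(theta[p])
    uniq = theta[p + 1 :].copy()

    # canonical sign: positive loading sum per factor
    for sl in (slice(0, kx), slice(kx, p)):
        if lam_vec[sl].sum() < 0:
            lam_vec[sl] = -lam_vec[sl]
            phi_hat = -phi_hat

    total_var = lam_vec**2 + uniq
    lam_std = lam_vec / np.sqrt(total_var)
    uniq_std = 1.0 - lam_std**2
    heywood = bool(np.any(uniq <= _UNIQUENESS_FLOOR * (1 + 1e-9)))

    return CfaFit(
        loadings_hat=(LoadingSet(lam_std[:kx]), LoadingSet(lam_std[kx:])),
        phi_hat=phi_hat,
        error_variances_hat=uniq_std,
        discrepancy=float(max(best.fun, 0.0)),
        converged=bool(best.success and np.isfinite(best.fun)),
        n_restarts_used=n_restarts_used,
        heywood=heywood,
    )
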