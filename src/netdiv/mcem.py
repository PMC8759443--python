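"""Monte-Carlo EM fitting of the logistic-normal multinomial model.

Model: latent log-ratios Y_i ~ N(X_i' gamma, Sigma) against a fixed base
taxon, counts W_i ~ Multinomial(M_i, phi_inverse(Y_i)).  The off-diagonal
structure of Sigma encodes the taxon co-occurrence network that a plain
multinomial model forbids.

Fitting alternates a Metropolis-Hastings E-step (a Gaussian random walk over
each sample's latent log-ratio vector, run independently per sample) with a
closed-form M-step (multivariate least squares for gamma, a Monte-Carlo
residual covariance for Sigma).  Three inverse-covariance estimates are
available for the E-step Gaussian term: the Moore-Penrose generalized
inverse (default), the diagonal-restricted MLE, and an L1-penalized
(graphical lasso) estimate with stability-based penalty selection.

Reproducibility contract: every stochastic routine takes an explicit seed;
per-sample chain seeds are derived from (master seed, EM iteration, sample
index) so results do not depend on chain execution order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .logratio import phi

__all__ = [
    "ModelParams",
    "MHConfig",
    "EMConfig",
    "LatentDraws",
    "multinomial_loglik_y",
    "gaussian_loglik",
    "mh_sample",
    "e_step",
    "m_step",
    "estimate_precision",
    "fit",
]

PRECISION_METHODS = ("naive", "diagonal", "glasso")


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------

@dataclass
class ModelParams:
    """Regression coefficients gamma (p x Q-1) and log-ratio covariance Sigma."""

    gamma: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim != 2 or self.sigma.shape[0] != self.sigma.shape[1]:
            raise ValueError("sigma must be a square matrix")
        if self.gamma.shape[1] != self.sigma.shape[0]:
            raise ValueError("gamma and sigma disagree on the number of log-ratios")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric (tolerance 1e-10)")
        evals = np.linalg.eigvalsh(self.sigma)
        if evals.size and evals.min() < -1e-10 * max(1.0, abs(evals.max())):
            raise ValueError("sigma must be positive semi-definite")


@dataclass
class MHConfig:
    """Metropolis-Hastings settings.

    ``v`` is the per-coordinate standard deviation of the Gaussian
    random-walk proposal (the step size); ``burn`` draws are discarded and
    ``r_draws`` retained per sample.
    """

    v: float = 0.01
    burn: int = 500
    r_draws: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v <= 0:
            raise ValueError("proposal step size v must be positive")
        if self.burn < 0 or self.r_draws < 1:
            raise ValueError("need burn >= 0 and r_draws >= 1")


@dataclass
class EMConfig:
    """EM settings: number of iterations and the inverse-covariance method."""

    n_iter: int = 6
    precision_method: str = "naive"
    center_at_updated_mean: bool = False

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("need at least one EM iteration")
        if self.precision_method not in PRECISION_METHODS:
            raise ValueError(f"precision_method must be one of {PRECISION_METHODS}")


@dataclass
class LatentDraws:
    """Retained MH draws, shape (n, R, Q-1), plus post-burn-in acceptance rates."""

    draws: np.ndarray
    acceptance_rate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim == 2:  # single sample
            self.draws = self.draws[None]
        self.acceptance_rate = np.atleast_1d(
            np.asarray(self.acceptance_rate, dtype=float)
        )
        if np.any(self.acceptance_rate < 0) or np.any(self.acceptance_rate > 1):
            raise ValueError("acceptance rates must lie in [0, 1]")


# ---------------------------------------------------------------------------
# log-densities
# ---------------------------------------------------------------------------

def _split_counts(w, d: int) -> tuple[np.ndarray, float]:
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("counts must be nonnegative")
    return np.delete(w, d), float(w.sum())


def multinomial_loglik_y(w, y, d: int) -> float:
    """Multinomial log-likelihood of counts ``w`` at log-ratios ``y``.

    ``sum_{q != d} w_q y_q - m log(sum_{q != d} exp(y_q) + 1)``, with the
    normalizer computed by a shifted log-sum-exp (the implicit baseline
    coordinate contributes exp(0)).  The multinomial coefficient is dropped:
    it cancels in MH ratios and does not affect maximization.
    """
    y = np.asarray(y, dtype=float)
    wq, m = _split_counts(w, d)
    if wq.shape != y.shape:
        raise ValueError(f"dimension mismatch: {wq.shape} counts vs {y.shape} log-ratios")
    shift = max(float(y.max(initial=0.0)), 0.0)
    lse = shift + np.log(np.exp(y - shift).sum() + np.exp(-shift))
    return float(wq @ y - m * lse)


def gaussian_loglik(y, mu, sigma) -> float:
    """Gaussian log-density of log-ratios up to the -k/2 log(2 pi) constant.

    Returns ``-0.5 log|Sigma| - 0.5 (y-mu)' Sigma^-1 (y-mu)``.  Singular
    covariances are handled through the eigendecomposition: eigenvalues
    below tolerance are dropped, giving the pseudo-determinant and the
    generalized-inverse quadratic form (components of ``y - mu`` in the null
    space are ignored).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if y.shape != mu.shape or sigma.shape != (y.size, y.size):
        raise ValueError("dimension mismatch between y, mu and sigma")
    evals, evecs = np.linalg.eigh(sigma)
    tol = sigma.shape[0] * np.finfo(float).eps * max(float(evals.max(initial=0.0)), 0.0)
    keep = evals > tol
    r = evecs.T @ (y - mu)
    logpdet = float(np.log(evals[keep]).sum())
    quad = float((r[keep] ** 2 / evals[keep]).sum())
    return -0.5 * logpdet - 0.5 * quad


# ---------------------------------------------------------------------------
# Metropolis-Hastings kernel
# ---------------------------------------------------------------------------

def _mh_chain_py(wq, m, y0, mu, omega, step_sd, n_burn, n_keep, normals, log_u):
    """Random-walk Metropolis over one sample's log-ratio vector.

    ``omega`` is the precision matrix used in the Gaussian term; log target
    is the multinomial log-likelihood plus the Gaussian log-prior up to
    constants.  Written so that numba can compile it unchanged.
    """
    k = y0.shape[0]
    draws = np.empty((n_keep, k))
    y = y0.copy()

    def logpost(yv):
        shift = 0.0
        for j in range(k):
            if yv[j] > shift:
                shift = yv[j]
        s = np.exp(-shift)
        wy = 0.0
        for j in range(k):
            s += np.exp(yv[j] - shift)
            wy += wq[j] * yv[j]
        r = yv - mu
        quad = r @ (omega @ r)
        return wy - m * (shift + np.log(s)) - 0.5 * quad

    lp = logpost(y)
    n_acc = 0
    for t in range(n_burn + n_keep):
        ystar = y + step_sd * normals[t]
        lps = logpost(ystar)
        if log_u[t] <= lps - lp:
            y = ystar
            lp = lps
            if t >= n_burn:
                n_acc += 1
        if t >= n_burn:
            draws[t - n_burn] = y
    return draws, n_acc


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _mh_chain = njit(cache=True)(_mh_chain_py)
except ImportError:  # pragma: no cover
    _mh_chain = _mh_chain_py


def mh_sample(w, mu, sigma_inv, cfg: MHConfig, rng, d: int, y0=None) -> LatentDraws:
    """Run one sample's MH chain and return the retained draws.

    The chain starts at the observed log-ratios ``phi(w / m)`` (so ``w``
    must be strictly positive, i.e. perturbed) unless ``y0`` is given.
    Proposals are ``y + v * eps`` with iid standard-normal ``eps``; the
    acceptance probability is min{1, exp(delta log posterior)}.
    """
    w = np.asarray(w, dtype=float)
    mu = np.asarray(mu, dtype=float)
    sigma_inv = np.ascontiguousarray(np.asarray(sigma_inv, dtype=float))
    m = float(w.sum())
    if m <= 0:
        raise ValueError("counts must have positive total")
    if y0 is None:
        y0 = phi(w / m, d)
    y0 = np.asarray(y0, dtype=float)
    wq = np.ascontiguousarray(np.delete(w, d))
    if not np.isfinite(
        multinomial_loglik_y(w, y0, d) - 0.5 * (y0 - mu) @ sigma_inv @ (y0 - mu)
    ):
        raise ValueError("non-finite log-density at chain initialization")
    n_steps = cfg.burn + cfg.r_draws
    normals = rng.standard_normal((n_steps, y0.size))
    log_u = np.log(rng.random(n_steps))
    draws, n_acc = _mh_chain(
        wq,
        m,
        np.ascontiguousarray(y0),
        np.ascontiguousarray(mu),
        sigma_inv,
        float(cfg.v),
        int(cfg.burn),
        int(cfg.r_draws),
        normals,
        log_u,
    )
    return LatentDraws(draws=draws, acceptance_rate=n_acc / cfg.r_draws)


def _chain_rng(master_seed: int, em_iter: int, stream: int):
    """Derived RNG: stream 0 is the precision estimator, i+1 is sample i's chain."""
    ss = np.random.SeedSequence(
        entropy=int(master_seed) & 0x7FFFFFFF, spawn_key=(em_iter, stream)
    )
    return np.random.default_rng(ss)


def e_step(
    W,
    X,
    params: ModelParams,
    d: int,
    cfg: MHConfig,
    precision_method: str = "naive",
    em_iter: int = 0,
    sigma_inv=None,
) -> LatentDraws:
    """MH draws of the latent log-ratios for every sample.

    Chains are mutually independent with per-sample seeds derived from
    ``cfg.seed``, so the output is identical regardless of execution order.
    ``W`` must be strictly positive (perturbed counts).
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if W.shape[0] != X.shape[0]:
        raise ValueError("W and X must have the same number of rows")
    if sigma_inv is None:
        sigma_inv = estimate_precision(
            params.sigma,
            precision_method,
            rng=_chain_rng(cfg.seed, em_iter, 0),
        )
    mu = X @ params.gamma
    n = W.shape[0]
    all_draws = np.empty((n, cfg.r_draws, params.sigma.shape[0]))
    rates = np.empty(n)
    for i in range(n):
        one = mh_sample(
            W[i], mu[i], sigma_inv, cfg, _chain_rng(cfg.seed, em_iter, i + 1), d
        )
        all_draws[i] = one.draws[0]
        rates[i] = one.acceptance_rate[0]
    return LatentDraws(draws=all_draws, acceptance_rate=rates)


# ---------------------------------------------------------------------------
# M-step and precision estimation
# ---------------------------------------------------------------------------

def m_step(
    draws: LatentDraws,
    X,
    mu_t,
    center_at_updated_mean: bool = False,
) -> ModelParams:
    """Closed-form M-step from the retained draws.

    gamma update: average over draws of the least-squares solution (equal,
    by linearity, to least squares on the draw mean).  Sigma update: the
    Monte-Carlo residual covariance, centered by default at the previous
    iteration's mean ``mu_t`` (set ``center_at_updated_mean`` for the
    freshly updated mean instead).  Rank-deficient ``X`` is handled through
    the generalized inverse.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = draws.draws  # (n, R, k)
    n, R, k = Y.shape
    ybar = Y.mean(axis=1)
    gamma = np.linalg.pinv(X.T @ X) @ X.T @ ybar
    center = X @ gamma if center_at_updated_mean else np.atleast_2d(np.asarray(mu_t, float))
    resid = Y - center[:, None, :]
    sigma = np.einsum("nrk,nrl->kl", resid, resid) / (n * R)
    sigma = 0.5 * (sigma + sigma.T)
    return ModelParams(gamma=gamma, sigma=sigma)


def _glasso_stability(sigma, rng, n_pseudo=200, n_subsamples=12, n_alphas=10,
                      instability_threshold=0.05):
    """Graphical-lasso precision with StARS-style stability selection.

    Gaussian pseudo-observations are drawn from ``sigma``; the penalty is
    the smallest value on a log-spaced grid whose monotonized average edge
    instability over subsamples stays below the threshold.
    """
    from sklearn.covariance import graphical_lasso

    k = sigma.shape[0]
    jitter = 1e-8 * max(np.trace(sigma) / k, 1.0)
    evals, evecs = np.linalg.eigh(sigma)
    root = evecs * np.sqrt(np.clip(evals, 0.0, None) + jitter)
    data = rng.standard_normal((n_pseudo, k)) @ root.T

    offdiag = np.abs(sigma - np.diag(np.diag(sigma)))
    alpha_max = max(float(offdiag.max()), 1e-3)
    alphas = np.geomspace(alpha_max, alpha_max * 1e-2, n_alphas)

    b = max(k + 1, int(0.75 * n_pseudo))
    edge_freq = np.zeros((n_alphas, k, k))
    for _ in range(n_subsamples):
        idx = rng.choice(n_pseudo, size=b, replace=False)
        sub = data[idx]
        emp = np.cov(sub, rowvar=False)
        emp = 0.5 * (emp + emp.T) + jitter * np.eye(k)
        for a, alpha in enumerate(alphas):
            try:
                _, prec = graphical_lasso(emp, alpha=alpha, max_iter=200)
            except FloatingPointError:  # pragma: no cover - rare non-convergence
                prec = np.linalg.pinv(emp)
            edge_freq[a] += np.abs(prec) > 1e-8
    theta = edge_freq / n_subsamples
    iu = np.triu_indices(k, 1)
    instability = np.array([np.mean(2 * t[iu] * (1 - t[iu])) for t in theta])
    # monotonize from the sparsest (largest alpha) end, then take the
    # smallest alpha still below threshold
    mono = np.maximum.accumulate(instability)
    ok = np.where(mono <= instability_threshold)[0]
    alpha_star = alphas[ok[-1]] if ok.size else alphas[0]

    emp = np.cov(data, rowvar=False)
    emp = 0.5 * (emp + emp.T) + jitter * np.eye(k)
    try:
        _, prec = graphical_lasso(emp, alpha=float(alpha_star), max_iter=200)
    except FloatingPointError:  # pragma: no cover
        prec = np.linalg.pinv(emp)
    return 0.5 * (prec + prec.T)


def estimate_precision(sigma, method: str = "naive", rng=None) -> np.ndarray:
    """Inverse-covariance estimate used in the E-step Gaussian term.

    naive
        Moore-Penrose generalized inverse (singular values below
        ``k * eps * s_max`` treated as zero).
    diagonal
        Inverse of diag(sigma); zero variances contribute zero precision.
    glasso
        L1-penalized precision with stability-based penalty selection
        (deterministic given ``rng``).
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("sigma must be square")
    if not np.allclose(sigma, sigma.T, atol=1e-8 * max(1.0, np.abs(sigma).max())):
        raise ValueError("sigma must be symmetric")
    if method == "naive":
        return np.linalg.pinv(sigma, hermitian=True)
    if method == "diagonal":
        dg = np.diag(sigma).copy()
        inv = np.where(dg > 0, 1.0 / np.where(dg > 0, dg, 1.0), 0.0)
        return np.diag(inv)
    if method == "glasso":
        if rng is None:
            rng = np.random.default_rng(0)
        return _glasso_stability(sigma, rng)
    raise ValueError(f"unknown precision method {method!r}")


# ---------------------------------------------------------------------------
# full fit
# ---------------------------------------------------------------------------

def fit(
    W,
    X,
    d: int | None = None,
    rho: float = 0.5,
    mh_cfg: MHConfig | None = None,
    em_cfg: EMConfig | None = None,
) -> tuple[ModelParams, dict]:
    """Fit the logistic-normal multinomial model by Monte-Carlo EM.

    Parameters
    ----------
    W
        n x Q count table (samples as rows); zeros are allowed and removed
        by adding ``rho`` to every entry before transforming.
    X
        n x p design matrix.
    d
        Base-taxon column index; default picks the most abundant taxon
        observed in every sample.
    rho
        Zero-perturbation constant, default 0.5.
    mh_cfg, em_cfg
        Sampler and EM settings (defaults: v=0.01, burn=500, R=500, 6 EM
        iterations, naive precision).

    Returns
    -------
    (ModelParams, dict)
        Final parameter estimates and a diagnostics dict with the base
        taxon, rho, and per-iteration traces (mean acceptance rate, gamma
        and sigma Frobenius norms) for convergence inspection.

    Initialization: gamma^(0) is the least-squares fit of the perturbed
    observed log-ratios on X and Sigma^(0) their residual covariance
    (divisor n), matching the sampler's initialization at the observed
    log-ratios.
    """
    from .logratio import choose_base_taxon, perturb

    W = np.atleast_2d(np.asarray(W, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, q = W.shape
    if X.shape[0] != n:
        raise ValueError("W and X must have the same number of rows")
    p = X.shape[1]
    if n == 1 and p > 1:
        raise ValueError("cannot fit p > 1 covariates to a single sample")
    if p > n:
        warnings.warn(
            f"more covariates (p={p}) than samples (n={n}); estimates are unstable",
            UserWarning,
            stacklevel=2,
        )
    if np.any(np.all(X == 0, axis=0)):
        warnings.warn("design matrix has an all-zero column", UserWarning, stacklevel=2)
    mh_cfg = mh_cfg or MHConfig()
    em_cfg = em_cfg or EMConfig()
    if d is None:
        d = choose_base_taxon(W)

    Wp = perturb(W, rho) if rho > 0 else W
    if np.any(Wp <= 0):
        raise ValueError("counts contain zeros; use a positive rho")
    P = Wp / Wp.sum(axis=1, keepdims=True)
    Y0 = phi(P, d)
    gamma = np.linalg.pinv(X.T @ X) @ X.T @ Y0
    resid = Y0 - X @ gamma
    sigma = resid.T @ resid / n
    sigma = 0.5 * (sigma + sigma.T)
    params = ModelParams(gamma=gamma, sigma=sigma)

    trace: dict = {
        "acceptance_rate": [],
        "gamma_norm": [],
        "sigma_norm": [],
        "base_taxon": int(d),
        "rho": float(rho),
    }
    for t in range(em_cfg.n_iter):
        draws = e_step(
            Wp, X, params, d, mh_cfg,
            precision_method=em_cfg.precision_method, em_iter=t,
        )
        mu_t = X @ params.gamma
        params = m_step(
            draws, X, mu_t, center_at_updated_mean=em_cfg.center_at_updated_mean
        )
        trace["acceptance_rate"].append(float(draws.acceptance_rate.mean()))
        trace["gamma_norm"].append(float(np.linalg.norm(params.gamma)))
        trace["sigma_norm"].append(float(np.linalg.norm(params.sigma)))
    return params, trace
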