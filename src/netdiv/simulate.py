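"""Synthetic data from the logistic-normal multinomial model.

The generative recipe: draw latent log-ratios ``Y_i ~ N(X_i' gamma, Sigma)``,
map to compositions ``Z_i = phi_inverse(Y_i)`` (last taxon as the implicit
baseline), and draw counts ``W_i ~ Multinomial(M_i, Z_i)``.  The generator
returns W, Z and Y so tests can check each stage against the latent truth.

``design_from_template`` builds the canonical two-group benchmark design —
an intercept plus a binary group indicator for the final third of samples,
n = 12 by default — with random regression coefficients and a factor-model
covariance whose off-diagonal scale (the strength of the taxon co-occurrence
network) is a single knob, ``network_strength``.

Default scales emulate 16S amplicon surveys: log-abundance spread of about
two natural-log units across taxa, per-log-ratio variance 1, and sequencing
depths drawn log-uniformly between 1e4 and 1e5 reads per sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .logratio import phi_inverse
from .mcem import ModelParams

__all__ = [
    "SimulationDesign",
    "simulate_dataset",
    "design_from_template",
    "design_from_counts",
]


@dataclass
class SimulationDesign:
    """Everything needed to draw one dataset: (X, gamma, Sigma, M)."""

    X: np.ndarray
    gamma: np.ndarray
    sigma: np.ndarray
    M: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.M = np.asarray(self.M, dtype=int)
        n, p = self.X.shape
        if self.gamma.shape[0] != p:
            raise ValueError("gamma rows must match design columns")
        k = self.gamma.shape[1]
        if self.sigma.shape != (k, k):
            raise ValueError("sigma must be (Q-1) x (Q-1)")
        if self.M.shape != (n,):
            raise ValueError("M must give one total per sample")
        if np.any(self.M < 1):
            raise ValueError("per-sample totals must be >= 1")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def q(self) -> int:
        return self.gamma.shape[1] + 1

    @property
    def base_taxon(self) -> int:
        """The generator's implicit baseline: the last taxon."""
        return self.q - 1


def _sigma_root(sigma: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(sigma)
    if evals.size and evals.min() < -1e-8 * max(1.0, float(evals.max())):
        raise ValueError("sigma must be positive semi-definite")
    return evecs * np.sqrt(np.clip(evals, 0.0, None))


def simulate_dataset(design: SimulationDesign, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (W, Z, Y) from the model; deterministic given ``rng``."""
    root = _sigma_root(design.sigma)
    mu = design.X @ design.gamma
    Y = mu + rng.standard_normal(mu.shape) @ root.T
    Z = phi_inverse(Y, design.base_taxon)
    W = np.empty((design.n, design.q), dtype=np.int64)
    for i in range(design.n):
        W[i] = rng.multinomial(int(design.M[i]), Z[i])
    return W, Z, Y


def design_from_template(
    n: int = 12,
    q: int = 200,
    group_fraction: float = 1 / 3,
    gamma=None,
    sigma=None,
    M=None,
    network_strength: float = 0.5,
    sigma_diag: float = 1.0,
    n_factors: int | None = None,
    intercept_scale: float = 2.0,
    effect_scale: float = 0.5,
    depth_range: tuple[float, float] = (1e4, 1e5),
    seed: int = 0,
) -> SimulationDesign:
    """Two-group benchmark design: intercept + binary indicator on the last block.

    ``n * group_fraction`` must be an integer; ``group_fraction = 0`` gives an
    intercept-only design.  Unless supplied, gamma rows are drawn
    ``N(0, intercept_scale^2)`` / ``N(0, effect_scale^2)``, Sigma is
    ``sigma_diag * [(1 - w) I + w R]`` with ``w = network_strength`` and R a
    random-factor correlation matrix (w = 0: no network), and depths are
    log-uniform over ``depth_range``.
    """
    rng = np.random.default_rng(seed)
    n_group = n * group_fraction
    if abs(n_group - round(n_group)) > 1e-9:
        raise ValueError(f"n * group_fraction = {n_group} is not an integer")
    n_group = int(round(n_group))
    if group_fraction == 0:
        X = np.ones((n, 1))
    else:
        indicator = np.zeros(n)
        indicator[n - n_group:] = 1.0
        X = np.column_stack([np.ones(n), indicator])
    p = X.shape[1]
    k = q - 1
    if gamma is None:
        scales = np.array([intercept_scale] + [effect_scale] * (p - 1))
        gamma = rng.normal(0.0, 1.0, (p, k)) * scales[:, None]
    if sigma is None:
        if not 0 <= network_strength < 1:
            raise ValueError("network_strength must lie in [0, 1)")
        if network_strength == 0:
            sigma = sigma_diag * np.eye(k)
        else:
            nf = n_factors if n_factors is not None else max(2, k // 20)
            A = rng.standard_normal((k, nf))
            R = A @ A.T / nf
            dg = np.sqrt(np.diag(R))
            R = R / np.outer(dg, dg)
            sigma = sigma_diag * ((1 - network_strength) * np.eye(k)
                                  + network_strength * R)
    if M is None:
        lo, hi = depth_range
        M = np.exp(rng.uniform(np.log(lo), np.log(hi), n)).astype(int)
    return SimulationDesign(X=X, gamma=gamma, sigma=sigma, M=M)


def design_from_counts(W, X, rho: float = 0.5) -> SimulationDesign:
    """Simulation design mimicking an observed count table.

    The benchmark construction: gamma is the least-squares fit of the
    (perturbed) observed log-ratios on X, Sigma the empirical covariance of
    the residual columns (rank at most n - p), and the per-sample totals are
    the observed sequencing depths.  The last taxon is moved to the
    baseline position of the generator, so pass counts whose final column
    is the intended base taxon.
    """
    from .logratio import perturb, phi

    W = np.atleast_2d(np.asarray(W, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Wp = perturb(W, rho) if rho > 0 else W
    P = Wp / Wp.sum(axis=1, keepdims=True)
    Y = phi(P, W.shape[1] - 1)
    gamma = np.linalg.pinv(X.T @ X) @ X.T @ Y
    resid = Y - X @ gamma
    sigma = resid.T @ resid / W.shape[0]
    sigma = 0.5 * (sigma + sigma.T)
    return SimulationDesign(
        X=X, gamma=gamma, sigma=sigma, M=W.sum(axis=1).astype(int)
    )


def params_from_design(design: SimulationDesign) -> ModelParams:
    """The design's (gamma, Sigma) as ModelParams, for oracle comparisons."""
    return ModelParams(gamma=design.gamma, sigma=design.sigma)
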