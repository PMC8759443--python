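"""Diversity estimates from fitted model parameters.

Fitted compositions are the inverse log-ratio transform of the linear
predictor, ``z_hat = phi_inverse(x' gamma_hat)``.  Because the model links
the latent log-ratio mean to covariates, estimates are computed per unique
covariate PROFILE (identical covariate rows share a fitted composition,
including profiles never observed in training) and mapped back to samples.

Alpha-diversity applies a within-community index (Shannon, Simpson) to each
fitted composition; beta-diversity applies a pairwise index (Bray-Curtis,
Euclidean) to every profile pair.  ``sensitivity_scan`` re-runs the full fit
across candidate base taxa or zero-perturbation values to reproduce
base-taxon / perturbation sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import indices as _idx
from .logratio import phi_inverse
from .mcem import EMConfig, MHConfig, ModelParams

__all__ = [
    "FittedCompositions",
    "DiversityEstimate",
    "fitted_compositions",
    "alpha_estimates",
    "beta_estimates",
    "sensitivity_scan",
    "ALPHA_INDICES",
    "BETA_INDICES",
]

ALPHA_INDICES = {"shannon": _idx.shannon, "simpson": _idx.simpson}
BETA_INDICES = {"bray_curtis": _idx.bray_curtis, "euclidean": _idx.euclidean}


@dataclass
class FittedCompositions:
    """Fitted compositions per unique covariate profile.

    ``z_hat`` has one row (a composition over the Q taxa) per profile;
    ``profiles`` holds the unique covariate rows and ``profile_index`` maps
    each requested covariate row to its profile.
    """

    z_hat: np.ndarray
    profiles: np.ndarray
    profile_index: np.ndarray


@dataclass
class DiversityEstimate:
    """Index values per profile (alpha) or per profile pair (beta)."""

    index_name: str
    values: np.ndarray
    profile_index: np.ndarray
    is_beta: bool = False
    variance: np.ndarray | None = None

    @property
    def per_sample(self) -> np.ndarray:
        """Alpha values mapped back to the requested covariate rows."""
        if self.is_beta:
            raise ValueError("per_sample applies to alpha estimates only")
        return self.values[self.profile_index]


def fitted_compositions(params: ModelParams, X_rows, d: int) -> FittedCompositions:
    """Compositions phi_inverse(x' gamma_hat) for each unique covariate row.

    Works equally for covariate profiles absent from training: the model
    predicts the latent log-ratio mean for any covariate vector.
    """
    X_rows = np.atleast_2d(np.asarray(X_rows, dtype=float))
    if X_rows.shape[1] != params.gamma.shape[0]:
        raise ValueError(
            f"covariate rows have {X_rows.shape[1]} columns but gamma expects "
            f"{params.gamma.shape[0]}"
        )
    profiles, inverse = np.unique(X_rows, axis=0, return_inverse=True)
    y_hat = profiles @ params.gamma
    z_hat = phi_inverse(y_hat, d)
    return FittedCompositions(
        z_hat=z_hat, profiles=profiles, profile_index=inverse.ravel()
    )


def alpha_estimates(fc: FittedCompositions, index: str) -> DiversityEstimate:
    """Apply a within-community index to every fitted composition."""
    try:
        f = ALPHA_INDICES[index]
    except KeyError:
        raise ValueError(
            f"unknown alpha index {index!r}; choose from {sorted(ALPHA_INDICES)}"
        ) from None
    values = np.array([f(z) for z in fc.z_hat])
    return DiversityEstimate(index, values, fc.profile_index)


def beta_estimates(fc: FittedCompositions, index: str) -> DiversityEstimate:
    """Pairwise index over fitted profiles: symmetric matrix, zero diagonal."""
    try:
        g = BETA_INDICES[index]
    except KeyError:
        raise ValueError(
            f"unknown beta index {index!r}; choose from {sorted(BETA_INDICES)}"
        ) from None
    k = fc.z_hat.shape[0]
    mat = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            mat[i, j] = mat[j, i] = g(fc.z_hat[i], fc.z_hat[j])
    return DiversityEstimate(index, mat, fc.profile_index, is_beta=True)


def sensitivity_scan(
    W,
    X,
    base_candidates=None,
    rho_candidates=None,
    index: str = "shannon",
    rho: float = 0.5,
    d: int | None = None,
    mh_cfg: MHConfig | None = None,
    em_cfg: EMConfig | None = None,
) -> pd.DataFrame:
    """Refit the model per candidate base taxon or per candidate rho.

    Exactly one of ``base_candidates`` / ``rho_candidates`` must be given.
    Each candidate triggers a full refit (no shortcuts) so the scan reflects
    the entire estimation pipeline.  Returns a long-format table with one
    row per (candidate, profile).
    """
    from .mcem import fit as _fit

    if (base_candidates is None) == (rho_candidates is None):
        raise ValueError("provide exactly one of base_candidates or rho_candidates")
    W = np.atleast_2d(np.asarray(W, dtype=float))
    rows = []
    if base_candidates is not None:
        if len(base_candidates) == 0:
            raise ValueError("base_candidates is empty")
        for cand in base_candidates:
            cand = int(cand)
            if not 0 <= cand < W.shape[1] or W[:, cand].sum() == 0:
                raise ValueError(f"candidate base taxon {cand} absent from the table")
            params, _ = _fit(W, X, d=cand, rho=rho, mh_cfg=mh_cfg, em_cfg=em_cfg)
            rows.extend(_scan_rows("base_taxon", cand, params, X, cand, index))
    else:
        if len(rho_candidates) == 0:
            raise ValueError("rho_candidates is empty")
        for cand in rho_candidates:
            params, diag = _fit(W, X, d=d, rho=float(cand), mh_cfg=mh_cfg, em_cfg=em_cfg)
            rows.extend(
                _scan_rows("rho", float(cand), params, X, diag["base_taxon"], index)
            )
    return pd.DataFrame(rows)


def _scan_rows(scan_name, cand, params, X, d, index):
    fc = fitted_compositions(params, X, d)
    if index in ALPHA_INDICES:
        est = alpha_estimates(fc, index)
        return [
            {scan_name: cand, "profile": int(k), "index": index, "estimate": v}
            for k, v in enumerate(est.values)
        ]
    est = beta_estimates(fc, index)
    k = est.values.shape[0]
    return [
        {scan_name: cand, "profile": f"{i},{j}", "index": index,
         "estimate": est.values[i, j]}
        for i in range(k) for j in range(i + 1, k)
    ]
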