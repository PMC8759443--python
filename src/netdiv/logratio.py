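"""Additive log-ratio (ALR) transform, zero perturbation, base-taxon choice.

The ALR transform ``phi`` maps a strictly positive composition of Q taxa to
the Q-1 log-ratios against a fixed baseline taxon ``d``; ``phi_inverse`` is
its inverse (a softmax with an implicit zero for the baseline).  Because the
transform is undefined at zero counts, observed tables are first perturbed
by adding a constant ``rho`` (default 0.5) to every entry.

Base-taxon indices are 0-based throughout the Python API.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["phi", "phi_inverse", "perturb", "choose_base_taxon"]


def _check_base(d: int, q: int) -> int:
    d = int(d)
    if not 0 <= d < q:
        raise IndexError(f"base taxon index {d} out of range for {q} taxa")
    return d


def phi(z, d: int) -> np.ndarray:
    """Log-ratios log(z_q / z_d) for q != d, in original taxon order.

    ``z`` must be strictly positive (perturb zero counts first); rows of a
    2-D array are transformed independently.
    """
    z = np.asarray(z, dtype=float)
    d = _check_base(d, z.shape[-1])
    if np.any(z <= 0):
        raise ValueError(
            "log-ratio transform requires strictly positive abundances; "
            "perturb zero counts first"
        )
    y = np.log(z / z[..., d : d + 1])
    return np.delete(y, d, axis=-1)


def phi_inverse(y, d: int) -> np.ndarray:
    """Map log-ratios back to the simplex: softmax with a 0 inserted at ``d``.

    Computed with a max-shift so large ``|y|`` cannot overflow; the result is
    normalized last, so each output row sums to 1 exactly.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("log-ratio vector must be finite")
    d = _check_base(d, y.shape[-1] + 1)
    full = np.insert(y, d, 0.0, axis=-1)
    full -= full.max(axis=-1, keepdims=True)
    ez = np.exp(full)
    return ez / ez.sum(axis=-1, keepdims=True)


def perturb(W, rho: float = 0.5) -> np.ndarray:
    """Add the perturbation constant ``rho`` to every count.

    ``rho`` must be positive; the conventional range is (0, 1) and values of
    1 or above are accepted with a warning.  Returns a float array with all
    entries strictly positive.
    """
    if rho <= 0:
        raise ValueError(f"perturbation rho must be positive, got {rho}")
    if rho >= 1:
        warnings.warn(
            f"perturbation rho={rho} is outside the conventional (0, 1) range",
            UserWarning,
            stacklevel=2,
        )
    W = np.asarray(W, dtype=float)
    return W + rho


def choose_base_taxon(W) -> int:
    """Pick the reference taxon: most abundant among taxa present in every sample.

    If no taxon is observed in all samples, falls back to the taxon with the
    largest total count.  Ties are broken by the lowest taxon index.  Returns
    a 0-based column index of ``W`` (samples as rows).
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    totals = W.sum(axis=0)
    if W.size == 0 or totals.sum() == 0:
        raise ValueError("count table is empty or all-zero")
    everywhere = np.all(W > 0, axis=0)
    if everywhere.any():
        masked = np.where(everywhere, totals, -np.inf)
        return int(np.argmax(masked))
    return int(np.argmax(totals))
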