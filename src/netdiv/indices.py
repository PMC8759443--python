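"""Diversity indices and classical count-based estimators.

Alpha-diversity indices (Shannon entropy, Simpson index) are functions of a
relative-abundance vector ``z`` on the simplex; beta-diversity indices
(Bray-Curtis dissimilarity, Euclidean distance) are functions of two such
vectors.  Alongside the index definitions this module provides the standard
count-based estimators used throughout ecology: the multinomial plug-in
estimates, the Miller-Maddow bias correction, the Chao-Shen coverage-adjusted
Shannon estimator, the zero-replace composition, and the finite-sample
Simpson correction.

All entropies are in nats (natural logarithm).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "InvalidCompositionError",
    "DegenerateCoverageError",
    "shannon",
    "simpson",
    "bray_curtis",
    "euclidean",
    "plugin_shannon",
    "miller_maddow_shannon",
    "chao_shen_shannon",
    "zero_replace_composition",
    "plugin_simpson",
    "plugin_bray_curtis",
    "plugin_euclidean",
]

#: absolute tolerance on |sum(z) - 1| for simplex membership
SIMPLEX_TOL = 1e-10


class InvalidCompositionError(ValueError):
    """Raised when a vector is not a valid point on the simplex."""


class DegenerateCoverageError(ValueError):
    """Raised when the Good-Turing coverage estimate is not positive."""


def _as_composition(z) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.ndim != 1 or z.size == 0:
        raise InvalidCompositionError("composition must be a nonempty 1-D vector")
    if np.any(z < -SIMPLEX_TOL) or np.any(z > 1 + SIMPLEX_TOL):
        raise InvalidCompositionError("composition entries must lie in [0, 1]")
    total = z.sum()
    if abs(total - 1.0) > SIMPLEX_TOL:
        raise InvalidCompositionError(
            f"composition entries sum to {total!r}, not 1 (tolerance {SIMPLEX_TOL})"
        )
    return z


def _as_counts(w, *, min_total: int = 1) -> tuple[np.ndarray, float]:
    w = np.asarray(w, dtype=float)
    if w.ndim != 1 or w.size == 0:
        raise ValueError("count vector must be a nonempty 1-D vector")
    if np.any(w < 0):
        raise ValueError("count vector entries must be nonnegative")
    if np.any(w != np.round(w)):
        raise ValueError("count vector entries must be integer-valued")
    m = float(w.sum())
    if m < min_total:
        raise ValueError(f"count vector total {m} below required minimum {min_total}")
    return w, m


def _check_same_length(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")


# ---------------------------------------------------------------------------
# indices on compositions
# ---------------------------------------------------------------------------

def shannon(z) -> float:
    """Shannon entropy -sum(z log z) of a composition, in nats.

    Terms with ``z_q == 0`` contribute zero (the limit x log x -> 0).
    Maximized at ``log Q`` by the uniform composition.
    """
    z = _as_composition(z)
    pos = z[z > 0]
    return float(-(pos * np.log(pos)).sum())


def simpson(z) -> float:
    """Simpson index sum(z^2): probability two random individuals match."""
    z = _as_composition(z)
    return float((z ** 2).sum())


def bray_curtis(z1, z2) -> float:
    """Bray-Curtis dissimilarity 1 - sum(min(z1, z2)) between compositions."""
    z1, z2 = _as_composition(z1), _as_composition(z2)
    _check_same_length(z1, z2)
    return float(1.0 - np.minimum(z1, z2).sum())


def euclidean(z1, z2) -> float:
    """Euclidean distance between two relative-abundance vectors."""
    z1, z2 = _as_composition(z1), _as_composition(z2)
    _check_same_length(z1, z2)
    return float(np.sqrt(((z1 - z2) ** 2).sum()))


# ---------------------------------------------------------------------------
# classical count-based estimators
# ---------------------------------------------------------------------------

def plugin_shannon(w) -> float:
    """Multinomial MLE (plug-in) of Shannon entropy from counts."""
    w, m = _as_counts(w)
    p = w[w > 0] / m
    return float(-(p * np.log(p)).sum())


def miller_maddow_shannon(w) -> float:
    """Plug-in Shannon entropy plus the (c-1)/(2m) bias correction.

    ``c`` is the observed richness (number of strictly positive counts); the
    true richness is unknown, so this is the only computable choice.
    """
    w, m = _as_counts(w)
    c = int((w > 0).sum())
    return plugin_shannon(w) + (c - 1) / (2.0 * m)


def chao_shen_shannon(w) -> float:
    """Coverage-adjusted Shannon estimator of Chao & Shen.

    Uses the Good-Turing coverage estimate ``Chat = 1 - f1/m`` (f1 = number
    of singletons) and a Horvitz-Thompson correction for unseen taxa:
    ``-sum Chat*p*log(Chat*p) / (1 - (1 - Chat*p)^m)`` over observed taxa.

    Raises
    ------
    DegenerateCoverageError
        If every observed count is a singleton (estimated coverage zero).
    """
    w, m = _as_counts(w)
    f1 = int((w == 1).sum())
    coverage = 1.0 - f1 / m
    if coverage <= 0:
        raise DegenerateCoverageError(
            "all observed counts are singletons: estimated sample coverage is 0, "
            "the coverage-adjusted Shannon estimator is undefined"
        )
    p = coverage * w[w > 0] / m
    return float(-(p * np.log(p) / (1.0 - (1.0 - p) ** m)).sum())


def zero_replace_composition(w) -> np.ndarray:
    """Replace zero counts by 0.5 and renormalize to a strictly positive composition."""
    w, _ = _as_counts(w)
    repl = np.maximum(w, 0.5)
    return repl / repl.sum()


def plugin_simpson(w, corrected: bool = False) -> float:
    """Plug-in Simpson index sum((w/m)^2), optionally scaled by m/(m-1).

    The corrected form applies the finite-sample ``m/(m-1)`` factor; for the
    sequencing depths typical of microbiome data the two differ negligibly.
    """
    w, m = _as_counts(w, min_total=2 if corrected else 1)
    value = float(((w / m) ** 2).sum())
    if corrected:
        value *= m / (m - 1.0)
    return value


def plugin_bray_curtis(w1, w2) -> float:
    """Plug-in Bray-Curtis: 1 - 2 sum(min(w1, w2)) / (m1 + m2)."""
    w1, m1 = _as_counts(w1)
    w2, m2 = _as_counts(w2)
    _check_same_length(w1, w2)
    return float(1.0 - 2.0 * np.minimum(w1, w2).sum() / (m1 + m2))


def plugin_euclidean(w1, w2) -> float:
    """Plug-in Euclidean distance between the two proportion vectors."""
    w1, m1 = _as_counts(w1)
    w2, m2 = _as_counts(w2)
    _check_same_length(w1, w2)
    return float(np.sqrt(((w1 / m1 - w2 / m2) ** 2).sum()))
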