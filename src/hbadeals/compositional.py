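"""Aitchison simplex algebra for isoform-proportion vectors.

Isoform usage of a gene with ``T`` isoforms lives on the open simplex:
``T`` strictly positive fractions summing to one.  Changes in usage between
two conditions are modelled multiplicatively with the Aitchison perturbation,
the group operation of the simplex: the elementwise product of two
composition vectors, renormalized to unit sum.  The uniform vector
``(1/T, ..., 1/T)`` is the identity element, so "no change in splicing"
corresponds exactly to a uniform perturbation vector.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "SIMPLEX_ATOL",
    "as_simplex",
    "aitchison_perturb",
    "aitchison_inverse",
    "uniform_alpha",
]

#: Tolerance on the unit-sum constraint for inputs claimed to be on the simplex.
SIMPLEX_ATOL = 1e-12

#: Floor applied to degenerate (zero or negative) entries before renormalizing.
ENTRY_FLOOR = 1e-12


def as_simplex(v, floor: float = ENTRY_FLOOR) -> np.ndarray:
    """Project ``v`` onto the open simplex by flooring and renormalizing.

    Entries below ``floor`` (including exact zeros, where the perturbation is
    undefined) are raised to ``floor`` and the vector is rescaled to unit sum.

    Raises
    ------
    ValueError
        If ``v`` has fewer than 2 entries or a non-finite entry.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError(f"simplex vector needs >= 2 entries, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("simplex vector has non-finite entries")
    v = np.maximum(v, floor)
    return v / v.sum()


def _check_simplex(v, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError(f"{name} needs >= 2 entries, got shape {v.shape}")
    if np.any(v <= 0.0):
        raise ValueError(f"{name} has non-positive entries; floor them with as_simplex()")
    if abs(v.sum() - 1.0) > 1e-8:
        raise ValueError(f"{name} does not sum to 1 (sum={v.sum()!r})")
    return v


def aitchison_perturb(p, alpha) -> np.ndarray:
    """Perturb composition ``p`` by ``alpha``: normalized elementwise product.

    ``out_i = p_i * alpha_i / sum_j p_j * alpha_j``.  Both arguments must be
    strictly positive vectors of equal length ``T >= 2`` summing to one.  The
    operation is commutative and closed on the simplex.
    """
    p = _check_simplex(p, "p")
    alpha = _check_simplex(alpha, "alpha")
    if p.size != alpha.size:
        raise ValueError(f"length mismatch: p has {p.size} entries, alpha has {alpha.size}")
    prod = p * alpha
    return prod / prod.sum()


def aitchison_inverse(alpha) -> np.ndarray:
    """Group inverse of ``alpha``: normalized entrywise reciprocal.

    ``perturb(perturb(p, alpha), aitchison_inverse(alpha)) == p``.
    """
    alpha = _check_simplex(alpha, "alpha")
    inv = 1.0 / alpha
    return inv / inv.sum()


def uniform_alpha(T: int) -> np.ndarray:
    """Identity element of the simplex group: ``(1/T, ..., 1/T)``."""
    T = int(T)
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")
    return np.full(T, 1.0 / T)
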