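"""Restricted (natural) cubic splines in the truncated-power form.

For knots k_1 < ... < k_K the basis is x plus, for j = 1..K-2,

    B_j(x) = (x-k_j)+^3 - (x-k_{K-1})+^3 (k_K-k_j)/(k_K-k_{K-1})
                        + (x-k_K)+^3   (k_{K-1}-k_j)/(k_K-k_{K-1})

which is twice continuously differentiable and exactly linear beyond the
boundary knots.  No intercept column is included.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rcs_basis", "rcs_basis_deriv", "knots_from_quantiles"]


def _validate_knots(knots) -> np.ndarray:
    knots = np.asarray(knots, dtype=float)
    if knots.size < 2:
        raise ValueError("need at least 2 knots")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    return knots


def _cube(x):
    return np.where(x > 0, x, 0.0) ** 3


def rcs_basis(x, knots) -> np.ndarray:
    """Design columns [x, B_1(x), ..., B_{K-2}(x)] for the given knots."""
    knots = _validate_knots(knots)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    K = knots.size
    cols = [x]
    if K > 2:
        kmax, ksub = knots[-1], knots[-2]
        denom = kmax - ksub
        for kj in knots[:-2]:
            cols.append(_cube(x - kj)
                        - _cube(x - ksub) * (kmax - kj) / denom
                        + _cube(x - kmax) * (ksub - kj) / denom)
    return np.column_stack(cols)


def rcs_basis_deriv(x, knots) -> np.ndarray:
    """Elementwise derivative d/dx of each rcs_basis column."""
    knots = _validate_knots(knots)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    K = knots.size
    cols = [np.ones_like(x)]
    if K > 2:
        kmax, ksub = knots[-1], knots[-2]
        denom = kmax - ksub

        def dcube(z):
            return 3.0 * np.where(z > 0, z, 0.0) ** 2

        for kj in knots[:-2]:
            cols.append(dcube(x - kj)
                        - dcube(x - ksub) * (kmax - kj) / denom
                        + dcube(x - kmax) * (ksub - kj) / denom)
    return np.column_stack(cols)


def knots_from_quantiles(values, interior_q, dedupe: bool = True) -> np.ndarray:
    """Boundary knots at min/max of ``values``, interior at the given
    quantiles; coincident knots are dropped (with the boundaries kept)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2 or values.min() == values.max():
        raise ValueError("need at least 2 distinct values to place knots")
    interior = np.quantile(values, interior_q)
    knots = np.concatenate([[values.min()], np.atleast_1d(interior),
                            [values.max()]])
    knots = np.sort(knots)
    if dedupe:
        keep = np.concatenate([[True], np.diff(knots) > 1e-12])
        knots = knots[keep]
    if np.any(np.diff(knots) <= 0):
        raise ValueError("coincident knots")
    return knots
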