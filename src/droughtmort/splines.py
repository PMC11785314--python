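"""Natural cubic spline basis (R ``ns()``-style contract).

``df`` columns; boundary knots at the data range, ``df - 1`` interior
knots at quantiles; the fitted curve is linear beyond the boundary knots
and has continuous second derivatives everywhere.  Built from the
classic reduced truncated-power representation: with knots
``xi_1 < ... < xi_K`` (K = df + 1),

    d_k(x) = [ (x - xi_k)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_k)

and basis ``{ x, d_1 - d_{K-1}, ..., d_{K-2} - d_{K-1} }`` — every
element is a natural cubic spline, and together with the intercept they
span the whole natural-spline space on those knots.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

__all__ = ["natural_spline_basis", "spline_basis"]


def _knots_from_quantiles(x, df):
    probs = np.linspace(0, 100, df + 1)
    knots = np.percentile(x, probs)
    if np.unique(knots).size != knots.size:
        raise ValidationError(
            f"cannot place {df + 1} distinct knots: need more distinct values"
        )
    return knots


def natural_spline_basis(x, df: int = 3, knots=None):
    """Evaluate the natural cubic spline basis.

    Parameters
    ----------
    x : array
        Points to evaluate at.
    df : int
        Number of basis columns (>= 1); ``df = 1`` is the linear column.
    knots : array, optional
        Full knot sequence (boundary + interior, ascending).  Default:
        ``df + 1`` knots at equally spaced quantiles of ``x``.

    Returns
    -------
    (basis, knots) : (ndarray of shape (n, df), ndarray)
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValidationError("df must be >= 1")
    if np.unique(x).size < df + 1 and knots is None:
        raise ValidationError(
            f"need >= {df + 1} distinct values for df={df}, got {np.unique(x).size}"
        )
    if knots is None:
        knots = _knots_from_quantiles(x, df)
    knots = np.asarray(knots, dtype=float)
    scale = knots[-1] - knots[0]
    if scale <= 0:
        raise ValidationError("degenerate knot range")
    z = (x - knots[0]) / scale
    kz = (knots - knots[0]) / scale
    cols = [z]

    def d(k):
        return (np.maximum(z - kz[k], 0.0) ** 3 - np.maximum(z - kz[-1], 0.0) ** 3) / (
            kz[-1] - kz[k]
        )

    d_last = d(len(kz) - 2)
    for k in range(len(kz) - 2):
        cols.append(d(k) - d_last)
    return np.column_stack(cols), knots


def spline_basis(x, df: int = 3, knots=None):
    """Natural cubic spline basis columns (convenience: basis only)."""
    return natural_spline_basis(x, df=df, knots=knots)[0]
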