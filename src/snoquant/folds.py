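"""Signed fold-change convention.

2D-GE software reports ratios in a signed "fold" convention: a positive
linear ratio r >= 1 is printed as +r, and r < 1 is printed as -1/r, so that
every fold value f satisfies |f| >= 1 and the sign encodes direction.  A
2.0 means doubled, a -2.0 means halved; 1.0 is the neutral value.  The
mapping is a monotone bijection between (0, inf) and (-inf,-1] u [1, inf).

These helpers convert losslessly between the two representations and are
vectorised over numpy arrays.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

__all__ = ["linear_to_fold", "fold_to_linear"]


def linear_to_fold(r):
    """Convert a positive linear ratio to the signed fold convention.

    Parameters
    ----------
    r : float or array-like
        Positive linear ratio(s).

    Returns
    -------
    float or ndarray
        ``r`` where ``r >= 1``, else ``-1/r``.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValidationError("linear ratio must be positive and finite")
    out = np.where(arr >= 1.0, arr, -1.0 / arr)
    return float(out) if np.isscalar(r) or arr.ndim == 0 else out


def fold_to_linear(f):
    """Invert :func:`linear_to_fold`.

    Parameters
    ----------
    f : float or array-like
        Signed fold value(s) with ``|f| >= 1``.

    Returns
    -------
    float or ndarray
        ``f`` where ``f >= 1``, else ``-1/f``.
    """
    arr = np.asarray(f, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(np.abs(arr) < 1.0):
        raise ValidationError("fold value must satisfy |fold| >= 1")
    out = np.where(arr >= 1.0, arr, -1.0 / arr)
    return float(out) if np.isscalar(f) or arr.ndim == 0 else out
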