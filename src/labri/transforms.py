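"""Box-Cox forward and inverse transforms.

The one-parameter family ``y = (x**lam - 1)/lam`` (``ln x`` at ``lam = 0``)
maps strictly positive concentrations onto an unbounded scale where the
central component is modeled as (truncated) normal.
"""

from __future__ import annotations

import numpy as np

from .errors import InverseDomainError

__all__ = ["box_cox", "inverse_box_cox"]


def box_cox(x, lam: float):
    """Transform positive value(s) ``x`` with exponent ``lam``.

    Parameters
    ----------
    x : float or array_like
        Strictly positive input(s).
    lam : float
        Box-Cox exponent.

    Returns
    -------
    float or ndarray
        ``(x**lam - 1)/lam`` for ``lam != 0``, ``ln x`` for ``lam == 0``.
    """
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("box_cox requires strictly positive finite input")
    if lam == 0.0:
        out = np.log(arr)
    else:
        out = (np.power(arr, lam) - 1.0) / lam
    return out if out.ndim else float(out)


def inverse_box_cox(y, lam: float):
    """Invert :func:`box_cox`; exact round trip on the transform's domain."""
    arr = np.asarray(y, dtype=float)
    if lam == 0.0:
        out = np.exp(arr)
    else:
        base = 1.0 + lam * arr
        if np.any(base <= 0):
            raise InverseDomainError(
                f"inverse Box-Cox undefined: 1 + {lam}*y <= 0 for some y"
            )
        out = np.power(base, 1.0 / lam)
    return out if out.ndim else float(out)
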