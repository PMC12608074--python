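"""Numerical helpers for (near-)singular PSD matrices."""
from __future__ import annotations

import numpy as np
from scipy import linalg

#: relative eigenvalue cutoff below which a PSD matrix is treated as singular
PSD_RTOL = 1e-10


def psd_pinv(a: np.ndarray, rtol: float = PSD_RTOL):
    """Moore-Penrose pseudo-inverse of a symmetric PSD matrix.

    Eigenvalues below ``rtol * max(eigenvalue)`` are treated as exact zeros;
    this is required because shared-time matrices of redundant path sets are
    exactly singular and those of short recombination loops are nearly so.

    Returns
    -------
    ginv : ndarray
        The pseudo-inverse.
    rank : int
        Number of retained (nonzero) eigenvalues.
    logpdet : float
        Log pseudo-determinant (sum of logs of retained eigenvalues).
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("expected a square matrix")
    if a.shape[0] == 0:
        return a.copy(), 0, 0.0
    w, u = linalg.eigh((a + a.T) / 2.0)
    wmax = max(float(w[-1]), 0.0)
    keep = w > rtol * wmax if wmax > 0 else np.zeros_like(w, dtype=bool)
    uk = u[:, keep]
    wk = w[keep]
    ginv = (uk / wk) @ uk.T
    return ginv, int(keep.sum()), float(np.log(wk).sum())


def solve_spd(a: np.ndarray, b: np.ndarray, what: str = "matrix") -> np.ndarray:
    """Solve a @ x = b for symmetric positive-definite ``a`` with a clear error."""
    try:
        c = linalg.cho_factor((a + a.T) / 2.0)
        return linalg.cho_solve(c, b)
    except linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"{what} is singular or not positive definite; "
            "this usually signals a redundant or insufficient path basis, "
            "or a root with no informative path"
        ) from err
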