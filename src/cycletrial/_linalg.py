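"""Batched matrix-exponential propagators for small dense rate matrices.

The cell-cycle model is a linear constant-coefficient ODE dX/dt = A·X with
3m ≤ 30 states, so trajectories are matrix exponentials. Time-varying runs
and vectorised likelihood evaluations need thousands of small expm calls;
this module computes them in one shot through batched eigendecomposition,
falling back to ``scipy.linalg.expm`` for (near-)defective matrices.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

# Condition-number threshold on the eigenvector matrix beyond which the
# spectral reconstruction of expm is not trusted (defective / near-defective
# matrices, e.g. equal chain rates producing Jordan blocks).
_COND_MAX = 1e8


def expm_batch(mats: np.ndarray) -> np.ndarray:
    """Matrix exponentials of a stack of square matrices.

    Parameters
    ----------
    mats : ndarray, shape (..., k, k)
        Real matrices (already multiplied by the time step).

    Returns
    -------
    ndarray of the same shape, exp(mats[i]) for each leading index.
    """
    mats = np.asarray(mats, dtype=float)
    if mats.ndim == 2:
        return expm(mats)
    lead = mats.shape[:-2]
    flat = mats.reshape((-1,) + mats.shape[-2:])
    out = np.empty_like(flat)
    w, v = np.linalg.eig(flat)
    ok = np.isfinite(w).all(axis=1)
    try:
        vinv = np.linalg.inv(v)
        # 1-norm condition estimate of the eigenvector matrix
        cond = np.abs(v).sum(axis=-2).max(axis=-1) * np.abs(vinv).sum(axis=-2).max(axis=-1)
        ok &= np.isfinite(cond) & (cond < _COND_MAX)
    except np.linalg.LinAlgError:
        ok[:] = False
        vinv = None
    if ok.any():
        idx = np.where(ok)[0]
        ew = np.exp(w[idx])
        rec = (v[idx] * ew[:, None, :]) @ vinv[idx]
        out[idx] = rec.real
    for i in np.where(~ok)[0]:
        out[i] = expm(flat[i])
    return out.reshape(lead + mats.shape[-2:])
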