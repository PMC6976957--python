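"""Genetic differentiation versus larval-drift connectivity.

Directional transport-probability matrices are symmetrized by averaging the
two directions, then compared to a pairwise FST matrix with a Mantel
permutation test (simultaneous row/column relabelling).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["symmetrize", "mantel", "align_matrices"]


def symmetrize(conn: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Mean of the two directions: out[i,j] = (c[i,j] + c[j,i]) / 2."""
    arr = conn.to_numpy(float) if isinstance(conn, pd.DataFrame) else np.asarray(conn, float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("connectivity matrix must be square")
    sym = (arr + arr.T) / 2.0
    if isinstance(conn, pd.DataFrame):
        return pd.DataFrame(sym, index=conn.index, columns=conn.columns)
    return sym


def align_matrices(
    m1: pd.DataFrame, m2: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both labeled matrices to their shared sites, same order.

    Alignment is by label, never by position; unmatched sites are dropped
    with a warning.
    """
    shared = [s for s in m1.index if s in set(m2.index)]
    dropped = sorted(set(m1.index).symmetric_difference(m2.index))
    if dropped:
        warnings.warn(f"sites present in only one matrix dropped: {dropped}")
    if len(shared) < 4:
        raise ValueError("need at least 4 shared sites for a Mantel test")
    return m1.loc[shared, shared], m2.loc[shared, shared]


def mantel(
    m1: pd.DataFrame | np.ndarray,
    m2: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    tail: str = "greater",
) -> tuple[float, float]:
    """Mantel test between two symmetric site x site matrices.

    Pearson correlation over strict upper triangles; the permutation null
    relabels the rows and columns of the second matrix simultaneously.
    One-tailed p with the add-one estimator; ``tail`` is "greater" or
    "less".  Returns ``(r, p)``.
    """
    if isinstance(m1, pd.DataFrame) and isinstance(m2, pd.DataFrame):
        m1, m2 = align_matrices(m1, m2)
        a = m1.to_numpy(float)
        b = m2.to_numpy(float)
    else:
        a = np.asarray(m1, float)
        b = np.asarray(m2, float)
    if a.shape != b.shape or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square with matching shapes")
    n = a.shape[0]
    if n < 4:
        raise ValueError("need at least 4 sites")
    if not (np.allclose(a, a.T, equal_nan=True) and np.allclose(b, b.T, equal_nan=True)):
        raise ValueError("matrices must be symmetric; symmetrize() first")
    if tail not in ("greater", "less"):
        raise ValueError("tail must be 'greater' or 'less'")
    iu = np.triu_indices(n, k=1)
    va, vb = a[iu], b[iu]
    if va.std() == 0 or vb.std() == 0:
        raise ValueError("zero variance in an upper triangle: r undefined")
    r_obs = float(np.corrcoef(va, vb)[0, 1])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        vp = b[np.ix_(perm, perm)][iu]
        r_p = float(np.corrcoef(va, vp)[0, 1])
        if (tail == "greater" and r_p >= r_obs) or (tail == "less" and r_p <= r_obs):
            count += 1
    p = (1 + count) / (n_perm + 1)
    return r_obs, p
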