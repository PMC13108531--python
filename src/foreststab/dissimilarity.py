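"""Bray-Curtis beta diversity with the Baselga balanced-variation /
abundance-gradient decomposition, Mantel tests, and PERMANOVA along a
continuous stability gradient.

Permutation p-values use the add-one convention p = (1 + #{perm >= obs}) / (1 + n_perm).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata


def bray_curtis_decompose(x, y) -> tuple[float, float, float]:
    """Decompose Bray-Curtis dissimilarity into balanced-variation and
    abundance-gradient components.

    With A = sum min(x_i, y_i), B = sum(x_i - min), C = sum(y_i - min):

        d_total    = (B + C) / (2A + B + C)
        d_balanced = min(B, C) / (A + min(B, C))
        d_gradient = d_total - d_balanced

    The two components are additive by construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("abundance vectors must have equal length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be non-negative")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError("both abundance vectors are all-zero")
    m = np.minimum(x, y)
    A = m.sum()
    B = (x - m).sum()
    C = (y - m).sum()
    d_total = (B + C) / (2 * A + B + C)
    mbc = min(B, C)
    d_balanced = mbc / (A + mbc) if (A + mbc) > 0 else 0.0
    return float(d_total), float(d_balanced), float(d_total - d_balanced)


def pairwise_decomposition(table: np.ndarray) -> dict[str, np.ndarray]:
    """All pairwise Bray-Curtis distances and their two Baselga components.

    ``table`` is (sites x species).  Returns square matrices under keys
    'total', 'balanced', 'gradient'.
    """
    table = np.asarray(table, dtype=float)
    n = table.shape[0]
    out = {k: np.zeros((n, n)) for k in ("total", "balanced", "gradient")}
    for i in range(n):
        for j in range(i + 1, n):
            t, b, g = bray_curtis_decompose(table[i], table[j])
            for k, v in zip(("total", "balanced", "gradient"), (t, b, g)):
                out[k][i, j] = out[k][j, i] = v
    return out


def gradient_distance(values) -> np.ndarray:
    """|delta| distance matrix of a 1-D gradient (e.g. ln community stability)."""
    v = np.asarray(values, dtype=float)[:, None]
    return squareform(pdist(v, metric="euclidean"))


def _check_square(D):
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    return D


def mantel_test(D1, D2, n_perm: int = 999, seed: int = 0,
                method: str = "spearman") -> tuple[float, float]:
    """Mantel correlation between two distance matrices with a permutation test.

    Correlates the upper off-diagonal triangles (Spearman rho by default, the
    statistic the downstream reports quote; Pearson switchable) and permutes
    the rows/columns of the second matrix.  Delegates to scikit-bio when it is
    importable; otherwise runs an equivalent in-package permutation test.
    """
    D1 = _check_square(D1)
    D2 = _check_square(D2)
    if D1.shape != D2.shape or D1.shape[0] < 4:
        raise ValueError("need matching matrices with n >= 4")
    iu = np.triu_indices_from(D1, k=1)
    if np.ptp(D1[iu]) == 0 or np.ptp(D2[iu]) == 0:
        raise ValueError("constant distance matrix: Mantel statistic undefined")
    try:
        from skbio.stats.distance import DistanceMatrix, mantel as _skbio_mantel
        rho, p, _ = _skbio_mantel(DistanceMatrix(D1), DistanceMatrix(D2),
                                  method=method, permutations=n_perm,
                                  alternative="greater", seed=seed)
        return float(rho), float(p)
    except ImportError:
        pass
    rng = np.random.default_rng(seed)

    def corr(a, b):
        if method == "spearman":
            a, b = rankdata(a), rankdata(b)
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    obs = corr(D1[iu], D2[iu])
    count = 0
    n = D1.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Dp = D2[np.ix_(perm, perm)]
        if corr(D1[iu], Dp[iu]) >= obs:
            count += 1
    return obs, (1 + count) / (1 + n_perm)


def _gower_center(D: np.ndarray) -> np.ndarray:
    A = -0.5 * D ** 2
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return J @ A @ J


def permanova(D, predictor, n_perm: int = 999, seed: int = 0) -> dict:
    """PERMANOVA of a distance matrix against a continuous gradient or groups.

    The total sum of squares of the Gower-centred inner-product matrix is
    partitioned by the hat matrix of the predictor design (an intercept plus
    either group dummies or the continuous gradient); significance by
    row/column permutation of the distance matrix.

    Returns dict with pseudo-F, R2, p, df_model, df_resid.
    """
    D = _check_square(D)
    n = D.shape[0]
    pred = np.asarray(predictor)
    if pred.dtype.kind in "OUS":  # categorical groups
        levels, codes = np.unique(pred, return_inverse=True)
        X = np.zeros((n, len(levels)))
        X[np.arange(n), codes] = 1.0
    else:
        X = np.column_stack([np.ones(n), pred.astype(float)])
    rank = np.linalg.matrix_rank(X)
    df_model = rank - 1
    df_resid = n - rank
    if df_model < 1 or df_resid < 1:
        raise ValueError("rank-deficient or saturated predictor")
    H = X @ np.linalg.pinv(X)
    G = _gower_center(D)
    ss_total = float(np.trace(G))
    I = np.eye(n)

    def pseudo_f(Dm):
        Gm = _gower_center(Dm)
        ss_model = float(np.trace(H @ Gm @ H))
        ss_resid = float(np.trace((I - H) @ Gm @ (I - H)))
        return (ss_model / df_model) / (ss_resid / df_resid), ss_model

    f_obs, ss_model = pseudo_f(D)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_p, _ = pseudo_f(D[np.ix_(perm, perm)])
        if f_p >= f_obs:
            count += 1
    return {
        "pseudo_F": f_obs,
        "R2": ss_model / ss_total,
        "p": (1 + count) / (1 + n_perm),
        "df_model": df_model,
        "df_resid": df_resid,
    }
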