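"""Significance assessment for the regulation-probability statistic T.

Two engines are provided.

* **Asymptotic**: when both classes are normally distributed the
  cutoff-free statistic is asymptotically normal; under the null
  (equal class means) it follows N(0, (n^2 + m^2) / (2 n m (n + m)^2)).
  This variance derives from an independence approximation across the
  per-sample exceedance proportions and is noticeably smaller than the
  exact label-permutation variance of T, which for tie-free data equals
  (n + m + 1)/(3 n m); the asymptotic engine is therefore anti-conservative
  and the permutation engine is the default.
* **Permutation**: sample labels are shuffled B times (the same shuffles
  for every gene), the statistic is recomputed on each shuffle, and the
  two-sided p-value is (1 + #{|T_b| >= |T_obs|}) / (B + 1).

Benjamini-Hochberg FDR correction (via statsmodels) handles multiplicity.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import stats

from statsmodels.stats.multitest import multipletests

from .core import _EPS, _tri_state
from .data import ExpressionDataset

__all__ = [
    "q_from_normal",
    "sampling_distribution",
    "asymptotic_null_variance",
    "asymptotic_pvalue",
    "permutation_pvalues",
    "exact_permutation_pvalues",
    "permutation_null_variance",
    "bh_adjust",
]

_P_FLOOR = np.finfo(float).eps  # keep p > 0 for downstream log transforms


def q_from_normal(mu1: float, mu2: float, s1: float, s2: float) -> float:
    """P(Y1 >= Y2) for independent Y1 ~ N(mu1, s1^2), Y2 ~ N(mu2, s2^2).

    Equals Phi((mu1 - mu2) / sqrt(s1^2 + s2^2)).
    """
    if s1 <= 0 and s2 <= 0:
        raise ValueError("both distributions are degenerate (s1 = s2 = 0)")
    return float(stats.norm.cdf((mu1 - mu2) / np.hypot(s1, s2)))


def sampling_distribution(q: float, n: int, m: int) -> tuple[float, float]:
    """Normal approximation N(2q - 1, 2 (n^2 + m^2) q (1 - q) / (n m (n + m)^2))
    of the cutoff-free statistic when the per-pair exceedance probability is q.
    """
    if not 0 <= q <= 1:
        raise ValueError(f"q must lie in [0, 1], got {q}")
    if q in (0.0, 1.0):
        import warnings

        warnings.warn("degenerate q in {0, 1}: variance is 0", stacklevel=2)
    mean = 2.0 * q - 1.0
    var = 2.0 * (n**2 + m**2) * q * (1.0 - q) / (n * m * (n + m) ** 2)
    return mean, var


def asymptotic_null_variance(n: int, m: int) -> float:
    """Null variance (n^2 + m^2) / (2 n m (n + m)^2) of T under equal means."""
    return (n**2 + m**2) / (2.0 * n * m * (n + m) ** 2)


def permutation_null_variance(n: int, m: int) -> float:
    """Exact label-permutation variance of T for tie-free data, (n+m+1)/(3nm).

    Follows from T = 2 U/(n m) - 1 and Var(U) = n m (n + m + 1)/12 under
    random relabelling.  Kept for diagnostics / engine comparison.
    """
    return (n + m + 1) / (3.0 * n * m)


def asymptotic_pvalue(T, n: int, m: int):
    """Two-sided p-value of T under the asymptotic null N(0, sigma0^2)."""
    if n < 2 or m < 2:
        raise ValueError("need n, m >= 2 for the asymptotic null")
    sigma0 = np.sqrt(asymptotic_null_variance(n, m))
    p = 2.0 * stats.norm.sf(np.abs(np.asarray(T, dtype=float)) / sigma0)
    p = np.clip(p, _P_FLOOR, 1.0)
    return float(p) if np.isscalar(T) else p


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------


def _permuted_T(X: np.ndarray, Z: np.ndarray, n: int, method: str, tau: float | None):
    """Statistic T for every gene under every relabelling.

    Parameters
    ----------
    X : (G, S) float array of expression values, any column order.
    Z : (B, S) boolean array; row b marks which columns are "tumor"
        (each row sums to n).

    Returns a (G, B) array.

    For genes whose values are all distinct the within-class comparison
    term is a constant, so T follows from pre-sorted positions alone; genes
    with tied values fall back to exact pairwise counting per relabelling.
    Both paths implement the same >= / <= indicators exactly.
    """
    G, S = X.shape
    B = Z.shape[0]
    m = S - n
    order = np.argsort(X, axis=1, kind="stable")
    Xs = np.take_along_axis(X, order, axis=1)
    has_tie = (np.diff(Xs, axis=1) == 0).any(axis=1)
    out = np.empty((G, B))

    free = ~has_tie
    if free.any():
        if method == "agrp":
            # rank of each column within its row (1-based); tie-free so the
            # >=-pair count against the normal class is  sum(ranks of tumor)
            # minus the constant within-tumor term n(n+1)/2
            ranks = np.empty((free.sum(), S))
            np.put_along_axis(
                ranks, order[free], np.arange(1, S + 1, dtype=float)[None, :], axis=1
            )
            U = ranks @ Z.T.astype(float) - n * (n + 1) / 2.0
            out[free] = 2.0 * U / (n * m) - 1.0
        else:
            out[free] = _grp_permuted_sorted(order[free], Z, n, m, tau)

    if has_tie.any():
        out[has_tie] = _pairwise_permuted_T(X[has_tie], Z, n, method, tau)
    return out


def _grp_permuted_sorted(order, Z, n, m, tau):
    """GRP T per relabelling from sorted positions (tie-free rows only).

    Walking the row in ascending order, the number of tumor values at or
    below position a gives both exceedance counts in O(S) per gene and
    relabelling.
    """
    G, S = order.shape
    B = Z.shape[0]
    a = np.arange(1, S + 1)
    up_t = tau * m - _EPS          # l >= tau        (tumor +1)
    dn_t = (1.0 - tau) * m - _EPS  # l <  1 - tau    (tumor -1)
    up_n = tau * n - _EPS          # k >= tau        (normal +1)
    dn_n = (1.0 - tau) * n - _EPS  # k <  1 - tau    (normal -1)
    out = np.empty((G, B))
    Zi = Z.astype(np.int8)
    for b in range(B):
        zs = Zi[b][order]                      # (G, S) tumor indicator, sorted order
        ct = np.cumsum(zs, axis=1)             # tumor count at or below each position
        zb = zs.astype(bool)
        lcount = a[None, :] - ct               # normal values <= x   (tumor rows)
        kcount = n - ct                        # tumor values >= x    (normal rows)
        s_u = ((lcount >= up_t) & zb).sum(1) + ((kcount >= up_n) & ~zb).sum(1)
        s_d = ((lcount < dn_t) & zb).sum(1) + ((kcount < dn_n) & ~zb).sum(1)
        out[:, b] = (s_u - s_d) / S
    return out


def _pairwise_permuted_T(X, Z, n, method, tau):
    """Exact per-relabelling T via full pairwise comparison (handles ties)."""
    S = X.shape[1]
    m = S - n
    C = X[:, :, None] >= X[:, None, :]  # (g, S, S)
    out = np.empty((X.shape[0], Z.shape[0]))
    for b in range(Z.shape[0]):
        t = Z[b]
        block = C[:, t][:, :, ~t]  # (g, n, m): tumor >= normal
        if method == "agrp":
            out[:, b] = 2.0 * block.sum(axis=(1, 2)) / (n * m) - 1.0
        else:
            l = block.mean(axis=2)
            k = block.mean(axis=1)
            s_u = (_tri_state(l, tau) == 1).sum(1) + (_tri_state(k, tau) == 1).sum(1)
            s_d = (_tri_state(l, tau) == -1).sum(1) + (_tri_state(k, tau) == -1).sum(1)
            out[:, b] = (s_u - s_d) / S
    return out


def permutation_pvalues(
    ds: ExpressionDataset,
    method: str = "agrp",
    tau: float | None = None,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
    return_stats: bool = False,
):
    """Two-sided permutation p-values for every gene of a dataset.

    The B label shuffles are drawn once and shared across genes, and the
    p-value uses the add-one smoothing (1 + #{|T_b| >= |T_obs|}) / (B + 1),
    so p >= 1/(B + 1) always.  Deterministic given ``seed``.
    """
    if B < 10:
        raise ValueError(f"need at least 10 permutations, got B={B}")
    if method == "grp" and tau is None:
        raise ValueError("method='grp' requires a tau cutoff")
    ds.require_two_per_class()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    X = np.hstack([ds.tumor_values(), ds.normal_values()])
    n, m = ds.n, ds.m
    S = n + m
    base = np.zeros(S, dtype=bool)
    base[:n] = True
    Z = np.empty((B, S), dtype=bool)
    for b in range(B):
        Z[b] = base[rng.permutation(S)]

    from .core import statistics_frame

    T_obs = statistics_frame(ds, method=method, tau=tau)["T"].to_numpy()
    T_perm = _permuted_T(X, Z, n, method, tau)
    exceed = (np.abs(T_perm) >= np.abs(T_obs)[:, None] - _EPS).sum(axis=1)
    p = (1.0 + exceed) / (B + 1.0)
    if return_stats:
        return p, T_obs
    return p


def exact_permutation_pvalues(
    ds: ExpressionDataset, method: str = "agrp", tau: float | None = None
):
    """Exhaustive-enumeration permutation p-values (all C(n+m, n) labelings).

    Feasible for small designs (n + m <= ~12); serves as the exact reference
    for the Monte-Carlo engine.  The observed labeling is part of the
    enumeration, so p >= 1/C(n+m, n).
    """
    ds.require_two_per_class()
    n, m = ds.n, ds.m
    S = n + m
    combos = list(combinations(range(S), n))
    Z = np.zeros((len(combos), S), dtype=bool)
    for b, idx in enumerate(combos):
        Z[b, list(idx)] = True
    X = np.hstack([ds.tumor_values(), ds.normal_values()])

    from .core import statistics_frame

    T_obs = statistics_frame(ds, method=method, tau=tau)["T"].to_numpy()
    T_perm = _permuted_T(X, Z, n, method, tau)
    exceed = (np.abs(T_perm) >= np.abs(T_obs)[:, None] - _EPS).sum(axis=1)
    return exceed / len(combos)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, order-preserving."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
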