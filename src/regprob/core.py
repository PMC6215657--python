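"""Regulation-probability statistics for two-group differential expression.

A gene can be up-regulated (U) or down-regulated (D) in tumor relative to
normal tissue.  Writing P(U) and P(D) for the probabilities of the two
events, the statistic

    T = P(U) - P(D),     T in [-1, 1],

measures how likely, and in which direction, the gene is differentially
regulated.  Two estimators are provided:

* **GRP** -- discretize each sample into a tri-state regulation status
  (+1 / 0 / -1) using a hard confidence cutoff ``tau`` on the sample's
  exceedance proportion, then estimate P(U), P(D) as event frequencies.
* **aGRP** -- skip the discretization and average the exceedance
  proportions themselves.  This is cutoff-free and unbiased; algebraically
  it rescales the Mann-Whitney exceedance probability U/(n*m) to [-1, 1].

Ties are counted as exceedance in *both* directions (the indicators are
``>=`` and ``<=``), so a gene that is constant across all samples yields
T = 1.  Such genes carry no comparison information; the coefficient-of-
variation filter in :mod:`regprob.preprocess` removes them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionDataset

__all__ = [
    "ExceedanceProportions",
    "RegulationProfile",
    "RegulationProbabilities",
    "exceedance_proportions",
    "regulation_status_profile",
    "grp_statistic",
    "agrp_statistic",
    "compute_statistics",
    "statistics_frame",
]

# comparisons of count/m floats against tau need a guard against the last ulp
_EPS = 1e-9


@dataclass(frozen=True)
class ExceedanceProportions:
    """Per-sample exceedance proportions of one gene.

    ``l[i]`` is the fraction of normal samples whose value does not exceed
    the i-th tumor sample's value; ``k[j]`` is the fraction of tumor samples
    whose value is not below the j-th normal sample's value.  Each ``l[i]``
    is a multiple of 1/m and each ``k[j]`` a multiple of 1/n.
    """

    l: np.ndarray
    k: np.ndarray


@dataclass(frozen=True)
class RegulationProfile:
    """Tri-state regulation profile of one gene (tumor block then normal block)."""

    r: np.ndarray  # entries in {-1, 0, +1}, length n + m
    tau: float


@dataclass(frozen=True)
class RegulationProbabilities:
    """Estimated P(U), P(D) and T = P(U) - P(D) for one gene."""

    p_up: float
    p_down: float
    T: float
    method: str  # "grp" or "agrp"
    tau: float | None = None


def _check_classes(tumor_values: np.ndarray, normal_values: np.ndarray) -> None:
    if tumor_values.size == 0 or normal_values.size == 0:
        raise ValueError("both classes need at least one sample")


def exceedance_proportions(tumor_values, normal_values) -> ExceedanceProportions:
    """Exceedance proportions l (tumor side) and k (normal side) of one gene.

    l_i = (1/m) * sum_j I(a1_i >= a2_j);  k_j = (1/n) * sum_i I(a2_j <= a1_i).
    Ties count as exceedance on both sides.
    """
    t = np.asarray(tumor_values, dtype=float).ravel()
    s = np.asarray(normal_values, dtype=float).ravel()
    _check_classes(t, s)
    ge = t[:, None] >= s[None, :]  # (n, m)
    return ExceedanceProportions(l=ge.mean(axis=1), k=ge.mean(axis=0))


def _tri_state(props_vec: np.ndarray, tau: float) -> np.ndarray:
    r = np.zeros(props_vec.shape, dtype=np.int8)
    r[props_vec >= tau - _EPS] = 1
    # -1 when 1 - p > tau, i.e. p < 1 - tau (strict, as printed)
    r[props_vec < (1.0 - tau) - _EPS] = -1
    return r


def regulation_status_profile(props: ExceedanceProportions, tau: float) -> RegulationProfile:
    """Map exceedance proportions to {-1, 0, +1} with confidence cutoff tau.

    +1 when the proportion is >= tau, -1 when its complement strictly
    exceeds tau, 0 otherwise.  The >=/> asymmetry is what makes tau = 0.5
    zero-free.
    """
    if not 0.5 <= tau <= 1.0:
        raise ValueError(f"tau must lie in [0.5, 1], got {tau}")
    return RegulationProfile(
        r=np.concatenate([_tri_state(props.l, tau), _tri_state(props.k, tau)]),
        tau=tau,
    )


def grp_statistic(profile: RegulationProfile, n: int, m: int) -> RegulationProbabilities:
    """GRP estimate of P(U), P(D), T from a tri-state regulation profile.

    An up-regulation vote is a +1 in a tumor sample or a -1 in a normal
    sample; a down-regulation vote is the reverse.  The class priors are the
    empirical frequencies n/(n+m) and m/(n+m), which reduces the
    total-probability estimate to vote counting over all n + m samples.
    """
    r = np.asarray(profile.r)
    if r.size != n + m:
        raise ValueError(f"profile length {r.size} != n + m = {n + m}")
    # A +1 status is up-evidence on either side: both l_i and k_j measure how
    # far tumor expression sits above normal, so the total-probability
    # estimate counts +1 votes from both blocks toward s_u (and -1 votes
    # toward s_d).  This is the counting whose cutoff-free limit is the
    # adaptive estimator.
    s_u = int((r == 1).sum())
    s_d = int((r == -1).sum())
    tot = n + m
    return RegulationProbabilities(
        p_up=s_u / tot, p_down=s_d / tot, T=(s_u - s_d) / tot,
        method="grp", tau=profile.tau,
    )


def agrp_statistic(props: ExceedanceProportions, n: int, m: int) -> RegulationProbabilities:
    """Adaptive (cutoff-free) estimate: average the exceedance proportions.

    P(U) = (sum l + sum k)/(n+m), P(D) = 1 - P(U), T = 2 P(U) - 1.
    Equivalently T = 2 U/(n m) - 1 with U the >= pair count.
    """
    if props.l.size != n or props.k.size != m:
        raise ValueError("proportion vectors do not match the class sizes")
    p_up = (props.l.sum() + props.k.sum()) / (n + m)
    return RegulationProbabilities(
        p_up=p_up, p_down=1.0 - p_up, T=2.0 * p_up - 1.0, method="agrp"
    )


# ---------------------------------------------------------------------------
# matrix-wide vectorized kernels (used by the model and the permutation engine)
# ---------------------------------------------------------------------------

_CHUNK = 4096  # genes per pairwise-comparison block, bounds peak memory


def exceedance_matrices(X_t: np.ndarray, X_n: np.ndarray):
    """Per-gene exceedance proportions for a whole matrix.

    Parameters are (genes, n) and (genes, m) arrays; returns ``(l, k)`` of
    shapes (genes, n) and (genes, m).
    """
    G, n = X_t.shape
    m = X_n.shape[1]
    l = np.empty((G, n))
    k = np.empty((G, m))
    for lo in range(0, G, _CHUNK):
        hi = min(lo + _CHUNK, G)
        ge = X_t[lo:hi, :, None] >= X_n[lo:hi, None, :]
        l[lo:hi] = ge.mean(axis=2)
        k[lo:hi] = ge.mean(axis=1)
    return l, k


def _agrp_arrays(l: np.ndarray, k: np.ndarray):
    p_up = (l.sum(axis=1) + k.sum(axis=1)) / (l.shape[1] + k.shape[1])
    return p_up, 1.0 - p_up, 2.0 * p_up - 1.0


def _grp_arrays(l: np.ndarray, k: np.ndarray, tau: float):
    n, m = l.shape[1], k.shape[1]
    rl = _tri_state(l, tau)
    rk = _tri_state(k, tau)
    s_u = (rl == 1).sum(axis=1) + (rk == 1).sum(axis=1)
    s_d = (rl == -1).sum(axis=1) + (rk == -1).sum(axis=1)
    tot = n + m
    return s_u / tot, s_d / tot, (s_u - s_d) / tot


def statistics_frame(ds: ExpressionDataset, method: str = "agrp", tau: float | None = None):
    """Per-gene (p_up, p_down, T) arrays for a dataset; order matches gene_ids."""
    import pandas as pd

    if method not in {"grp", "agrp"}:
        raise ValueError(f"method must be 'grp' or 'agrp', got {method!r}")
    if method == "grp":
        if tau is None:
            raise ValueError("method='grp' requires a tau cutoff")
        if not 0.5 <= tau <= 1.0:
            raise ValueError(f"tau must lie in [0.5, 1], got {tau}")
    ds.require_two_per_class()
    l, k = exceedance_matrices(ds.tumor_values(), ds.normal_values())
    if method == "agrp":
        p_up, p_down, T = _agrp_arrays(l, k)
    else:
        p_up, p_down, T = _grp_arrays(l, k, tau)
    return pd.DataFrame(
        {"p_up": p_up, "p_down": p_down, "T": T}, index=ds.gene_ids
    )


def compute_statistics(
    ds: ExpressionDataset, method: str = "agrp", tau: float | None = None
) -> list[RegulationProbabilities]:
    """Per-gene regulation probabilities for every gene of a dataset."""
    frame = statistics_frame(ds, method=method, tau=tau)
    return [
        RegulationProbabilities(
            p_up=row.p_up, p_down=row.p_down, T=row.T,
            method=method, tau=tau if method == "grp" else None,
        )
        for row in frame.itertuples()
    ]
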