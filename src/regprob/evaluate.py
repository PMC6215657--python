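"""Benchmark metrics and the cross-dataset consistency analysis.

Scores per-gene calls against simulated ground truth (sensitivity,
specificity, accuracy, ROC AUC, type-I error, power) and measures how
reproducible the statistic's magnitude and sign are across independent
datasets profiling the same contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvaluationReport",
    "ConsistencyTable",
    "confusion_metrics",
    "type1_and_power",
    "roc_auc",
    "direction_split",
    "consistency_analysis",
    "summarize_replicates",
]

DE_LABELS = ("up", "down")


@dataclass
class EvaluationReport:
    """Confusion metrics of one replicate at a p-value threshold ``alpha``.

    A gene is called positive iff p < alpha.  Sensitivity is computed over
    truly differentially expressed genes, specificity over truly null
    genes, accuracy over all genes; a metric whose truth class is empty is
    ``None`` rather than 0.
    """

    alpha: float
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    auc: float | None = None
    type1_error: float | None = None
    power: float | None = None
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            k: getattr(self, k)
            for k in ("sensitivity", "specificity", "accuracy", "auc",
                      "type1_error", "power")
            if getattr(self, k) is not None
        }


@dataclass
class ConsistencyTable:
    """Per-interval cross-dataset agreement of the statistic.

    For each magnitude interval (eta, eta + width], ``prop_common`` is the
    fraction of the union of member genes present in *all* datasets and
    ``prop_same_direction`` the fraction of those common genes whose sign
    agrees everywhere.  Empty-union intervals report NaN.
    """

    eta: np.ndarray
    width: float
    prop_common: np.ndarray
    prop_same_direction: np.ndarray
    n_union: np.ndarray
    n_common: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "interval_low": self.eta,
                "interval_high": self.eta + self.width,
                "n_union": self.n_union,
                "n_common": self.n_common,
                "prop_common": self.prop_common,
                "prop_same_direction": self.prop_same_direction,
            }
        )


def _truth_arrays(truth) -> np.ndarray:
    truth = np.asarray(truth, dtype=object)
    known = set(DE_LABELS) | {"null"}
    bad = set(truth) - known
    if bad:
        raise ValueError(f"unknown truth labels {sorted(bad)!r}; use up/down/null")
    return truth


def confusion_metrics(p, truth, alpha: float = 0.05) -> EvaluationReport:
    """Sensitivity / specificity / accuracy of the calls p < alpha."""
    p = np.asarray(p, dtype=float)
    truth = _truth_arrays(truth)
    if p.shape != truth.shape:
        raise ValueError("p and truth must have equal length")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    called = p < alpha
    is_de = np.isin(truth, DE_LABELS)
    rep = EvaluationReport(alpha=alpha)
    if is_de.any():
        rep.sensitivity = float(called[is_de].mean())
    if (~is_de).any():
        rep.specificity = float((~called[~is_de]).mean())
    rep.accuracy = float((called == is_de).mean())
    return rep


def type1_and_power(p_null, p_de, alpha: float = 0.05) -> tuple[float, float]:
    """Fractions of null genes (type-I error) and DE genes (power) with p < alpha."""
    p_null = np.asarray(p_null, dtype=float)
    p_de = np.asarray(p_de, dtype=float)
    if p_null.size == 0 or p_de.size == 0:
        raise ValueError("both null and DE p-value sets must be non-empty")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return float((p_null < alpha).mean()), float((p_de < alpha).mean())


def roc_auc(scores, truth, p=None) -> float:
    """Area under the ROC curve of ranking genes by evidence of DE.

    ``scores`` is the direction-free evidence (|T| by convention); when
    ``p`` is given, tied scores rank the smaller p first.  Equals the
    Mann-Whitney probability that a random DE gene outranks a random null
    gene.
    """
    scores = np.asarray(scores, dtype=float)
    truth = _truth_arrays(truth)
    y = np.isin(truth, DE_LABELS)
    if y.all() or not y.any():
        raise ValueError("truth must contain both DE and null genes")
    if p is not None:
        p = np.asarray(p, dtype=float)
        # lexicographic rank: ascending score, ties broken by descending p
        idx = np.lexsort((-p, scores))
        rank = np.empty(len(scores))
        rank[idx] = np.arange(len(scores), dtype=float)
        scores = rank
    return float(roc_auc_score(y, scores))


def direction_split(T, calls) -> tuple[list, list, list]:
    """Partition significant genes by the sign of their statistic.

    ``T`` is a per-gene Series (index = gene ids); ``calls`` the ids deemed
    significant.  Returns (positive, negative, undirected) id lists; genes
    with T exactly 0 go to the undirected list.
    """
    T = pd.Series(T)
    unknown = [g for g in calls if g not in T.index]
    if unknown:
        raise ValueError(f"called genes absent from the statistic table: {unknown[:5]}")
    pos = [g for g in calls if T[g] > 0]
    neg = [g for g in calls if T[g] < 0]
    zero = [g for g in calls if T[g] == 0]
    return pos, neg, zero


def consistency_analysis(
    stat_tables, eta_grid=(0.5, 0.6, 0.7, 0.8, 0.9), width: float = 0.1
) -> ConsistencyTable:
    """Cross-dataset agreement of |T| interval membership and sign.

    ``stat_tables`` is a sequence (>= 2) of per-dataset gene -> T mappings
    over overlapping gene universes.  Per interval, membership in dataset d
    is {g : |T_d(g)| in (eta, eta + width]}; the lowest interval also
    includes its left endpoint, so a boundary value belongs to the lower
    interval only.
    """
    tables = [pd.Series(t, dtype=float) for t in stat_tables]
    if len(tables) < 2:
        raise ValueError("need at least two datasets for a consistency analysis")
    eta = np.asarray(eta_grid, dtype=float)
    prop_common = np.full(eta.shape, np.nan)
    prop_same = np.full(eta.shape, np.nan)
    n_union = np.zeros(eta.shape, dtype=int)
    n_common = np.zeros(eta.shape, dtype=int)

    for i, lo in enumerate(eta):
        hi = lo + width
        members = []
        for t in tables:
            a = t.abs()
            mask = (a > lo) & (a <= hi + 1e-12)
            if i == 0:
                mask |= a == lo
            members.append(set(t.index[mask]))
        union = set().union(*members)
        inter = set.intersection(*members)
        n_union[i], n_common[i] = len(union), len(inter)
        if union:
            prop_common[i] = len(inter) / len(union)
        if inter:
            same = sum(
                1 for g in inter
                if len({int(np.sign(t[g])) for t in tables}) == 1
            )
            prop_same[i] = same / len(inter)
    return ConsistencyTable(
        eta=eta, width=width, prop_common=prop_common,
        prop_same_direction=prop_same, n_union=n_union, n_common=n_common,
    )


def score_simulated(
    sim,
    method: str = "agrp",
    tau: float | None = None,
    B: int = 1000,
    seed=None,
    alpha: float = 0.05,
) -> EvaluationReport:
    """Fit one simulated dataset and score the calls against its truth.

    Runs the chosen estimator with permutation p-values and fills an
    EvaluationReport with confusion metrics, AUC (|T| ranking, ties broken
    by p) and, when both truth classes are present, type-I error and power
    at raw p < alpha.
    """
    from .model import GeneRegulationModel

    res = GeneRegulationModel.from_simulated(sim).fit(
        method=method, tau=tau, B=B, seed=seed, alpha=alpha
    )
    p = res.pvalues.to_numpy()
    truth = sim.truth.to_numpy()
    rep = confusion_metrics(p, truth, alpha=alpha)
    is_de = np.isin(truth, DE_LABELS)
    if is_de.any() and (~is_de).any():
        rep.type1_error, rep.power = type1_and_power(p[~is_de], p[is_de], alpha)
        rep.auc = roc_auc(np.abs(res.statistic.to_numpy()), truth, p=p)
    elif not is_de.any():
        rep.type1_error = float((p < alpha).mean())
    return rep


def summarize_replicates(reports, as_percent: bool = True) -> pd.DataFrame:
    """Mean +/- std of each metric over replicate EvaluationReports."""
    rows = [r.as_dict() for r in reports]
    df = pd.DataFrame(rows)
    scale = 100.0 if as_percent else 1.0
    out = pd.DataFrame(
        {
            "mean": df.mean() * scale,
            "std": df.std(ddof=1).fillna(0.0) * scale,
            "reps": df.count(),
        }
    )
    out.index.name = "metric"
    return out
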