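"""Model / Results interface tying the statistic, significance and output together.

Follows the familiar two-object pattern: build a
:class:`GeneRegulationModel` from a dataset, call :meth:`fit`, and work
with the returned :class:`RegulationResults` (per-gene statistics,
p-values, BH q-values, direction calls, summary table, file output).

Example
-------
>>> from regprob import simulate, GeneRegulationModel
>>> null, de = simulate.simulate_simple(G_null=50, G_de=50, n=10, seed=0)
>>> res = GeneRegulationModel.from_simulated(de).fit(B=200, seed=1)
>>> res.to_frame().columns.tolist()
['gene_id', 'T', 'p_up', 'p_down', 'p_raw', 'q_bh', 'direction']
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import core, significance
from .data import ExpressionDataset, read_expression

__all__ = ["GeneRegulationModel", "RegulationResults", "write_results"]


class GeneRegulationModel:
    """Two-group differential-regulation model for an expression matrix.

    Parameters
    ----------
    dataset
        An :class:`~regprob.data.ExpressionDataset` (genes x samples with a
        binary tumor/normal design, at least two samples per class).
    """

    def __init__(self, dataset: ExpressionDataset):
        dataset.require_two_per_class()
        self.dataset = dataset

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_dataframe(cls, values: pd.DataFrame, classes, tumor_label: str = "tumor"):
        return cls(ExpressionDataset(values, classes, tumor_label=tumor_label))

    @classmethod
    def from_files(cls, matrix_path, labels_path, tumor_label: str = "tumor"):
        return cls(read_expression(matrix_path, labels_path, tumor_label=tumor_label))

    @classmethod
    def from_simulated(cls, sim):
        return cls(sim.dataset)

    @property
    def n(self) -> int:
        return self.dataset.n

    @property
    def m(self) -> int:
        return self.dataset.m

    def fit(
        self,
        method: str = "agrp",
        tau: float | None = None,
        pvalue: str = "permutation",
        B: int = 1000,
        seed: int | None = None,
        alpha: float = 0.05,
    ) -> "RegulationResults":
        """Estimate per-gene regulation probabilities and their significance.

        Parameters
        ----------
        method
            ``"agrp"`` (cutoff-free, default) or ``"grp"`` (requires ``tau``).
        tau
            Regulation confidence cutoff in [0.5, 1]; only for ``"grp"``.
        pvalue
            ``"permutation"`` (default; B label shuffles, add-one smoothed,
            the only engine whose null is exactly calibrated),
            ``"asymptotic"`` (normal-approximation null), or
            ``"exact"`` (exhaustive enumeration; small designs only).
        B, seed
            Permutation count and RNG seed for the permutation engine.
        alpha
            Significance level used by the direction call in the output.
        """
        stats = core.statistics_frame(self.dataset, method=method, tau=tau)
        T = stats["T"].to_numpy()
        if pvalue == "asymptotic":
            p = significance.asymptotic_pvalue(T, self.n, self.m)
        elif pvalue == "permutation":
            p = significance.permutation_pvalues(
                self.dataset, method=method, tau=tau, B=B, seed=seed
            )
        elif pvalue == "exact":
            p = significance.exact_permutation_pvalues(
                self.dataset, method=method, tau=tau
            )
        else:
            raise ValueError(
                f"pvalue engine must be 'permutation', 'asymptotic' or 'exact', "
                f"got {pvalue!r}"
            )
        q = significance.bh_adjust(p)
        return RegulationResults(
            model=self,
            stats=stats.assign(p_raw=p, q_bh=q),
            method=method,
            tau=tau,
            engine=pvalue,
            B=B if pvalue == "permutation" else None,
            seed=seed if pvalue == "permutation" else None,
            alpha=alpha,
        )


class RegulationResults:
    """Fitted per-gene statistics with significance and direction calls."""

    def __init__(self, model, stats, method, tau, engine, B, seed, alpha):
        self.model = model
        self._stats = stats
        self.method = method
        self.tau = tau
        self.engine = engine
        self.B = B
        self.seed = seed
        self.alpha = alpha

    # -- per-gene vectors ------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self._stats.index

    @property
    def statistic(self) -> pd.Series:
        """Per-gene T = P(U) - P(D)."""
        return self._stats["T"]

    @property
    def p_up(self) -> pd.Series:
        return self._stats["p_up"]

    @property
    def p_down(self) -> pd.Series:
        return self._stats["p_down"]

    @property
    def pvalues(self) -> pd.Series:
        return self._stats["p_raw"]

    @property
    def qvalues(self) -> pd.Series:
        """Benjamini-Hochberg adjusted p-values."""
        return self._stats["q_bh"]

    def significant(self, alpha: float | None = None, adjusted: bool = True) -> pd.Index:
        """Gene ids significant at level alpha (on BH q by default)."""
        alpha = self.alpha if alpha is None else alpha
        col = "q_bh" if adjusted else "p_raw"
        return self._stats.index[self._stats[col] < alpha]

    @property
    def direction(self) -> pd.Series:
        """Per-gene call: 'up' / 'down' for significant genes by sign of T, else 'none'."""
        sig = self._stats["q_bh"] < self.alpha
        T = self._stats["T"]
        out = pd.Series("none", index=self._stats.index)
        out[sig & (T > 0)] = "up"
        out[sig & (T < 0)] = "down"
        return out

    def to_frame(self) -> pd.DataFrame:
        """Results table sorted by ascending q then descending |T|."""
        df = self._stats.copy()
        df["direction"] = self.direction
        df = df.sort_values(
            ["q_bh", "T"], key=lambda c: c.abs() if c.name == "T" else c,
            ascending=[True, False],
        )
        df.index.name = "gene_id"
        return df.reset_index()[
            ["gene_id", "T", "p_up", "p_down", "p_raw", "q_bh", "direction"]
        ]

    def write(self, path) -> None:
        write_results(self.to_frame(), path)

    def summary(self, top: int = 10) -> str:
        """Readable run summary with the strongest genes."""
        ds = self.model.dataset
        sig = self.significant()
        up = int((self.direction == "up").sum())
        down = int((self.direction == "down").sum())
        lines = [
            "Gene regulation probability results",
            "=" * 56,
            f"method:            {self.method}"
            + (f" (tau={self.tau})" if self.method == "grp" else ""),
            f"p-value engine:    {self.engine}"
            + (f" (B={self.B}, seed={self.seed})" if self.engine == "permutation" else ""),
            f"genes:             {ds.n_genes}",
            f"samples:           n={ds.n} ({ds.tumor_label}), m={ds.m} ({ds.normal_label})",
            f"significant (BH q < {self.alpha:g}): {len(sig)}  [{up} up, {down} down]",
            "-" * 56,
        ]
        head = self.to_frame().head(top)
        with pd.option_context("display.float_format", "{:.4g}".format):
            lines.append(head.to_string(index=False))
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<RegulationResults method={self.method!r} engine={self.engine!r} "
            f"genes={len(self._stats)}>"
        )


def write_results(frame: pd.DataFrame, path) -> None:
    """Write a results table as tab-delimited text (full-precision floats)."""
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
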