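"""Preprocessing: probe-to-gene collapsing and the coefficient-of-variation filter."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import DataError, ExpressionDataset

logger = logging.getLogger("regprob")

__all__ = ["collapse_probes", "cv_filter"]


def collapse_probes(ds: ExpressionDataset, probe_map: dict) -> ExpressionDataset:
    """Average probe rows mapping to the same gene identifier.

    Rows whose probe id is absent from ``probe_map`` are dropped (the count
    is logged).  The result has one row per gene, each sample value being
    the arithmetic mean over the gene's probes.
    """
    genes = pd.Series(
        [probe_map.get(p) for p in ds.values.index], index=ds.values.index
    )
    unmapped = genes.isna()
    if unmapped.any():
        logger.info("dropping %d unmapped probes of %d", unmapped.sum(), len(genes))
    kept = ds.values.loc[~unmapped]
    if kept.empty:
        raise DataError("no probes left after applying the probe map")
    collapsed = kept.groupby(genes.dropna(), sort=False).mean()
    collapsed.index.name = ds.values.index.name
    return ExpressionDataset(collapsed, ds.classes, tumor_label=ds.tumor_label)


def cv_filter(ds: ExpressionDataset, cutoff: float = 0.05) -> ExpressionDataset:
    """Remove low-variability genes: keep CV = std/|mean| >= cutoff.

    The CV is computed over all samples jointly (sample std, ddof 1).
    Genes with mean exactly 0 have no defined CV and are dropped.  Besides
    discarding uninformative near-constant genes, this removes the
    all-ties pathology in which a constant gene scores T = 1.
    """
    if cutoff < 0:
        raise ValueError(f"cutoff must be non-negative, got {cutoff}")
    X = ds.values.to_numpy(dtype=float)
    mean = X.mean(axis=1)
    std = X.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, std / np.abs(mean), np.nan)
    keep = np.nan_to_num(cv, nan=-1.0) >= cutoff
    dropped = int((~keep).sum())
    if dropped:
        logger.info("CV filter (cutoff %g) removed %d of %d genes",
                    cutoff, dropped, len(keep))
    if not keep.any():
        raise DataError(f"CV filter at cutoff {cutoff} removed every gene")
    return ExpressionDataset(
        ds.values.loc[keep], ds.classes, tumor_label=ds.tumor_label
    )
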