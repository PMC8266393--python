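"""Spike-in normalized quantification of nascent (4-thioU) RNA-seq.

The pipeline order is fixed: normalize raw counts by the per-sample
S. pombe spike total, filter to genes detectable in every sample,
average biological replicates within each condition, then take the
per-gene log2 change (IAA vs DMSO). An :class:`ExpressionTable` tracks
the state so operations can assert their position in that order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .samples import SampleMeta, by_condition

STATES = ("raw", "normalized", "averaged")


class QuantError(ValueError):
    """Pipeline-order or normalization error."""


@dataclass
class ExpressionTable:
    """Gene x sample matrix of nonnegative signal plus its pipeline state."""

    values: pd.DataFrame
    state: str = "raw"

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise QuantError(f"unknown state {self.state!r}")
        if (self.values.to_numpy() < 0).any():
            raise QuantError("expression values must be nonnegative")


def normalize_counts(
    raw: ExpressionTable,
    metas: Sequence[SampleMeta],
    scale: float = 10_000.0,
) -> ExpressionTable:
    """Divide each sample column by its spike-in read total and rescale.

    entry = raw_count / spike_reads * scale
    """
    if raw.state != "raw":
        raise QuantError(f"normalize_counts requires state 'raw', got {raw.state!r}")
    meta_by_id = {m.sample_id: m for m in metas}
    out = raw.values.astype(float).copy()
    for col in out.columns:
        m = meta_by_id.get(col)
        if m is None:
            raise QuantError(f"no sample metadata for column {col!r}")
        if m.spike_reads <= 0:
            raise QuantError(f"sample {col}: spike_reads must be > 0 for normalization")
        out[col] = out[col] / m.spike_reads * scale
    return ExpressionTable(out, state="normalized")


def average_replicates(
    tbl: ExpressionTable,
    metas: Sequence[SampleMeta],
) -> ExpressionTable:
    """Arithmetic mean over biological replicates within each condition."""
    if tbl.state != "normalized":
        raise QuantError(f"average_replicates requires state 'normalized', got {tbl.state!r}")
    groups = by_condition([m for m in metas if m.sample_id in tbl.values.columns])
    if not groups:
        raise QuantError("no samples to average")
    cols = {}
    for cond, ms in groups.items():
        if not ms:
            raise QuantError(f"condition {cond}: zero replicates")
        cols[cond] = tbl.values[[m.sample_id for m in ms]].mean(axis=1)
    return ExpressionTable(pd.DataFrame(cols), state="averaged")


def log2_change(
    iaa_mean: pd.Series,
    dmso_mean: pd.Series,
    pseudocount: float = 0.0,
) -> pd.Series:
    """Per-gene log2((IAA + p) / (DMSO + p)) on a shared gene set.

    The default pseudocount is 0 because the detectability filter
    guarantees strictly positive signal; a zero denominator then points
    at a missing filter step rather than being papered over.
    """
    if not iaa_mean.index.equals(dmso_mean.index):
        common = iaa_mean.index.intersection(dmso_mean.index)
        if len(common) != len(iaa_mean) or len(common) != len(dmso_mean):
            raise QuantError("log2_change: inputs must share one gene set")
        dmso_mean = dmso_mean.loc[iaa_mean.index]
    denom = dmso_mean.astype(float) + pseudocount
    numer = iaa_mean.astype(float) + pseudocount
    if (denom <= 0).any():
        raise QuantError(
            "log2_change: zero signal in denominator; apply filter_detectable "
            "or pass a pseudocount"
        )
    return pd.Series(np.log2(numer / denom), index=iaa_mean.index, name="log2fc")


def replicate_cv(
    tbl: ExpressionTable,
    metas: Sequence[SampleMeta],
) -> tuple[pd.DataFrame, dict]:
    """Per-gene, per-condition coefficient of variation across replicates.

    CV = sample standard deviation (ddof=1) / mean. Genes with zero mean
    in a condition have undefined CV (NaN) and are excluded from the
    summary, which reports the median CV per condition and overall.
    """
    if tbl.state != "normalized":
        raise QuantError(f"replicate_cv requires state 'normalized', got {tbl.state!r}")
    groups = by_condition([m for m in metas if m.sample_id in tbl.values.columns])
    cv = {}
    n_undefined = {}
    for cond, ms in groups.items():
        if len(ms) < 2:
            raise QuantError(f"condition {cond}: replicate_cv needs >= 2 replicates")
        sub = tbl.values[[m.sample_id for m in ms]]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            c = sd / mean
        c[mean == 0] = np.nan
        cv[cond] = c
        n_undefined[cond] = int((mean == 0).sum())
    cv_df = pd.DataFrame(cv)

    def _median(arr) -> float:
        arr = np.asarray(arr, dtype=float).ravel()
        arr = arr[~np.isnan(arr)]
        return float(np.median(arr)) if arr.size else float("nan")

    summary = {
        "median_cv": {cond: _median(cv_df[cond]) for cond in cv_df.columns},
        "median_cv_overall": _median(cv_df.to_numpy()),
        "n_undefined": n_undefined,
    }
    return cv_df, summary


def class_summary(
    log2fc: pd.Series,
    class_labels: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Per-class medians of the log2 change and the equivalent fold change.

    Because the median commutes with monotone transforms, the median fold
    equals 2 ** (median log2 change); both are reported, along with the
    median fold *decrease* (2 ** -median) used for depletion summaries.
    Empty classes are absent from the table, not reported as zero.
    """
    labels = pd.Series(class_labels)
    labels = labels.reindex(log2fc.index)
    rows = []
    for cls, vals in log2fc.groupby(labels):
        if len(vals) == 0:
            continue
        med = float(vals.median())
        rows.append(
            {
                "class": cls,
                "n_genes": int(len(vals)),
                "median_log2fc": med,
                "median_fold_change": float(2.0 ** med),
                "median_fold_decrease": float(2.0 ** -med),
            }
        )
    return pd.DataFrame(rows).set_index("class")
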