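"""RNA polymerase II elongation metrics: traveling ratio, TSS-anchored
metagene change profiles, phospho-CTD / kinase ratios, and
dependence quintiles.

The traveling ratio (TR) is the ratio of polymerase occupancy in a
100 bp window at the 5' end of the transcribed region to a 100 bp window
at its 3' end; an increase after depletion indicates polymerase
accumulating near the promoter (an elongation defect). Because TR is a
ratio within one track, it is invariant to the spike normalization
factor, and the log2 TR change is invariant to per-condition scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .coverage import CoverageTrack, window_signal
from .stats import spearman


class ElongationError(ValueError):
    pass


@dataclass(frozen=True)
class TravelingRatioRecord:
    gene_id: str
    tr_dmso: float
    tr_iaa: float
    log2_tr_change: float


def _tr_windows(gene: GeneModel, width: int = 100) -> tuple[tuple[int, int], tuple[int, int]]:
    """5' and 3' windows of the transcribed region, transcription-direction aware."""
    lo, hi = gene.transcribed_interval()
    if gene.strand == "+":
        five = (lo, lo + width)
        three = (hi - width, hi)
    else:
        five = (hi - width, hi)
        three = (lo, lo + width)
    return five, three


def traveling_ratio(
    track: CoverageTrack,
    gene: GeneModel,
    width: int = 100,
    min_length: int = 300,
) -> Optional[float]:
    """5' / 3' occupancy ratio for one gene; None when undefined.

    Genes must be longer than ``min_length`` with annotated TSS and PAS;
    a zero 3' signal leaves the ratio undefined (None), to be excluded
    and counted by the caller.
    """
    if gene.tss is None or gene.pas is None:
        raise ElongationError(f"{gene.gene_id}: traveling_ratio requires TSS and PAS")
    if gene.length <= min_length:
        raise ElongationError(
            f"{gene.gene_id}: gene length {gene.length} <= {min_length} bp minimum"
        )
    five, three = _tr_windows(gene, width)
    s5 = window_signal(track, gene.chrom, *five)
    s3 = window_signal(track, gene.chrom, *three)
    if s3 == 0:
        return None
    return s5 / s3


def traveling_ratio_table(
    track_dmso: CoverageTrack,
    track_iaa: CoverageTrack,
    genes: Sequence[GeneModel],
    width: int = 100,
    min_length: int = 300,
) -> pd.DataFrame:
    """TR in both conditions for every eligible gene; undefined TRs dropped."""
    rows = []
    for g in genes:
        if g.tss is None or g.pas is None or g.length <= min_length:
            continue
        tr_d = traveling_ratio(track_dmso, g, width=width, min_length=min_length)
        tr_i = traveling_ratio(track_iaa, g, width=width, min_length=min_length)
        if tr_d is None or tr_i is None or tr_d == 0:
            continue
        rows.append(
            {
                "gene_id": g.gene_id, "tr_dmso": tr_d, "tr_iaa": tr_i,
                "log2_tr_change": float(np.log2(tr_i / tr_d)),
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "tr_dmso", "tr_iaa", "log2_tr_change"]).set_index("gene_id")


def quintile_groups(log2fc: pd.Series, n_groups: int = 5) -> pd.Series:
    """Group genes into equal-size quantile bins of their log2 change.

    Orientation: Q5 holds the most depletion-dependent genes (most
    negative log2 change), Q1 the least dependent. Group sizes differ by
    at most one; ties are broken by stable gene-id order.
    """
    vals = log2fc.dropna()
    if len(vals) < n_groups:
        raise ElongationError(f"quintile_groups: need >= {n_groups} genes")
    ordered = vals.iloc[np.argsort(vals.to_numpy(), kind="stable")]
    chunks = np.array_split(np.arange(len(ordered)), n_groups)
    labels = pd.Series(index=ordered.index, dtype=object, name="quintile")
    for i, chunk in enumerate(chunks):
        # ascending value order: first chunk = most negative = Q{n_groups}
        labels.iloc[chunk] = f"Q{n_groups - i}"
    return labels.reindex(log2fc.index)


def tr_change_summary(
    tr_table: pd.DataFrame,
    log2fc: pd.Series,
    n_groups: int = 5,
) -> dict:
    """Correlate the TR change with the transcription change.

    Returns the Spearman r between per-gene log2 TR change and log2
    transcription change (NaN when undefined), plus per-quintile medians
    of the TR change (quintiles of the transcription change).
    """
    common = tr_table.index.intersection(log2fc.index)
    if len(common) == 0:
        raise ElongationError("tr_change_summary: no genes shared with log2fc")
    tr_change = tr_table.loc[common, "log2_tr_change"]
    fc = log2fc.loc[common]
    r = spearman(fc.to_numpy(), tr_change.to_numpy()) if len(common) >= 3 else float("nan")
    groups = quintile_groups(fc, n_groups=n_groups)
    medians = tr_change.groupby(groups).median().to_dict()
    return {"spearman_r": r, "n_genes": int(len(common)), "quintile_median_tr_change": medians}


def metagene_log2_profile(
    track_dmso: CoverageTrack,
    track_iaa: CoverageTrack,
    genes: Sequence[GeneModel],
    groups: Optional[pd.Series] = None,
    upstream: int = 200,
    downstream: int = 1000,
    min_length: int = 1000,
) -> pd.DataFrame:
    """Mean log2 occupancy change per TSS-relative offset and gene group.

    For each offset in [-upstream, downstream) the per-condition group
    mean coverage is computed (strand-resolved), then log2(IAA / DMSO)
    of the means — tolerant of per-gene zeros, unlike a mean of per-gene
    log2 values. Genes shorter than ``min_length`` are excluded; empty
    groups are omitted with a warning.
    """
    offsets = np.arange(-upstream, downstream)
    eligible = [
        g for g in genes
        if g.tss is not None and g.pas is not None and g.length > min_length
    ]
    if groups is None:
        groups = pd.Series("all", index=[g.gene_id for g in eligible])
    dense_d: dict[str, np.ndarray] = {}
    dense_i: dict[str, np.ndarray] = {}
    profiles: dict[str, np.ndarray] = {}
    for label in pd.unique(groups.dropna()):
        members = {gid for gid, lab in groups.items() if lab == label}
        sel = [g for g in eligible if g.gene_id in members]
        if not sel:
            import logging
            logging.getLogger(__name__).warning("metagene: group %s has no eligible genes", label)
            continue
        sums_d = np.zeros(offsets.size)
        sums_i = np.zeros(offsets.size)
        for g in sel:
            size = track_dmso.chrom_sizes[g.chrom]
            if g.chrom not in dense_d:
                dense_d[g.chrom] = track_dmso.dense(g.chrom)
                dense_i[g.chrom] = track_iaa.dense(g.chrom)
            if g.strand == "+":
                pos = g.tss + offsets
            else:
                pos = g.tss - 1 - offsets
            valid = (pos >= 0) & (pos < size)
            sums_d[valid] += dense_d[g.chrom][pos[valid]]
            sums_i[valid] += dense_i[g.chrom][pos[valid]]
        with np.errstate(divide="ignore", invalid="ignore"):
            profiles[str(label)] = np.log2(sums_i / sums_d)
    return pd.DataFrame(profiles, index=pd.Index(offsets, name="offset"))


def phospho_status_change(
    phospho_iaa: pd.Series,
    phospho_dmso: pd.Series,
    rpb1_iaa: pd.Series,
    rpb1_dmso: pd.Series,
) -> tuple[pd.Series, int]:
    """log2 change of the phospho (or kinase) to Rpb1 signal ratio.

    log2[(P_IAA / R_IAA) / (P_DMSO / R_DMSO)] per gene over the
    transcribed region. Genes with zero Rpb1 (or zero DMSO phospho
    signal) in either condition are excluded and counted. The same
    computation serves kinase/elongation-factor occupancy normalized to
    total polymerase.
    """
    common = phospho_iaa.index
    for s in (phospho_dmso, rpb1_iaa, rpb1_dmso):
        common = common.intersection(s.index)
    if len(common) == 0:
        raise ElongationError("phospho_status_change: disjoint gene sets")
    pi = phospho_iaa.loc[common].astype(float)
    pdm = phospho_dmso.loc[common].astype(float)
    ri = rpb1_iaa.loc[common].astype(float)
    rd = rpb1_dmso.loc[common].astype(float)
    ok = ((ri > 0) & (rd > 0) & (pdm > 0) & (pi > 0)).to_numpy()
    change = np.log2(
        (pi.to_numpy()[ok] / ri.to_numpy()[ok]) / (pdm.to_numpy()[ok] / rd.to_numpy()[ok])
    )
    return pd.Series(change, index=common[ok], name="log2_ratio_change"), int((~ok).sum())
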