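"""Per-base coverage tracks with spike-in normalization.

Tracks are stored run-length encoded per chromosome (sorted,
non-overlapping half-open runs with a constant value each); windowed
sums are computed directly on the runs, with dense materialization only
where a caller asks for per-base values. A ``norm_state`` flag tracks
whether the per-base values are raw read counts or spike-normalized
signal, so downstream quantification can assert its preconditions.

Normalization modes
-------------------
chec  : value / (spike reads) x scale           (D. melanogaster spike)
chip  : value / (spike reads of the IP) x (spike/experimental ratio of
        the paired input sample) x scale        (S. pombe spike)
rpm   : value / (experimental reads) x 1e6      (no spike; re-analysis
        of public datasets)
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .samples import SampleMeta

NORM_STATES = ("raw", "chec_normalized", "chip_normalized", "rpm_normalized")


class CoverageError(ValueError):
    """Invalid track data or normalization request."""


@dataclass
class _Runs:
    """Run-length encoding of one chromosome: values[i] on [starts[i], ends[i])."""

    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray

    def total(self) -> float:
        return float(np.sum(self.values * (self.ends - self.starts)))


class CoverageTrack:
    """Nonnegative per-base signal over a genome, run-length encoded."""

    def __init__(
        self,
        chrom_sizes: Mapping[str, int],
        norm_state: str = "raw",
    ) -> None:
        if norm_state not in NORM_STATES:
            raise CoverageError(f"unknown norm_state {norm_state!r}")
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        self.norm_state = norm_state
        self._runs: dict[str, _Runs] = {
            c: _Runs(np.empty(0, int), np.empty(0, int), np.empty(0, float))
            for c in self.chrom_sizes
        }

    # -- construction -------------------------------------------------

    @classmethod
    def from_dense(
        cls,
        arrays: Mapping[str, np.ndarray],
        norm_state: str = "raw",
    ) -> "CoverageTrack":
        track = cls({c: len(a) for c, a in arrays.items()}, norm_state=norm_state)
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=float)
            if np.any(arr < 0):
                raise CoverageError(f"{chrom}: negative coverage values")
            if arr.size == 0:
                continue
            change = np.flatnonzero(arr[1:] != arr[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [arr.size]))
            values = arr[starts]
            keep = values != 0
            track._runs[chrom] = _Runs(starts[keep], ends[keep], values[keep])
        return track

    @classmethod
    def from_bedgraph(
        cls,
        path: str | Path,
        chrom_sizes: Optional[Mapping[str, int]] = None,
        norm_state: str = "raw",
    ) -> "CoverageTrack":
        """Read a 0-based half-open bedGraph (# comments tolerated, no track lines)."""
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        if chrom_sizes is None:
            if df.empty:
                chrom_sizes = {}
            else:
                chrom_sizes = df.groupby("chrom")["end"].max().to_dict()
        track = cls(chrom_sizes, norm_state=norm_state)
        for chrom, sub in df.groupby("chrom", sort=True):
            sub = sub.sort_values("start", kind="mergesort")
            starts = sub["start"].to_numpy(int)
            ends = sub["end"].to_numpy(int)
            values = sub["value"].to_numpy(float)
            if np.any(starts[1:] < ends[:-1]):
                raise CoverageError(f"{path}: overlapping runs on {chrom}")
            if np.any(values < 0):
                raise CoverageError(f"{path}: negative coverage on {chrom}")
            keep = values != 0
            track._runs[str(chrom)] = _Runs(starts[keep], ends[keep], values[keep])
        return track

    def to_bedgraph(self, path: str | Path, precision: int = 6) -> None:
        """Write nonzero runs as bedGraph, chromosomes sorted by name."""
        with open(path, "w") as fh:
            for chrom in sorted(self._runs):
                r = self._runs[chrom]
                for s, e, v in zip(r.starts, r.ends, r.values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.{precision}g}\n")

    # -- inspection ---------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return list(self.chrom_sizes)

    def dense(self, chrom: str) -> np.ndarray:
        """Materialize one chromosome as a per-base array."""
        if chrom not in self._runs:
            raise CoverageError(f"unknown chromosome {chrom!r}")
        out = np.zeros(self.chrom_sizes[chrom], dtype=float)
        r = self._runs[chrom]
        if r.starts.size == 0:
            return out
        lengths = r.ends - r.starts
        total = int(lengths.sum())
        shift = r.starts - np.concatenate(([0], np.cumsum(lengths)[:-1]))
        idx = np.arange(total) + np.repeat(shift, lengths)
        out[idx] = np.repeat(r.values, lengths)
        return out

    def total_signal(self) -> float:
        return sum(r.total() for r in self._runs.values())

    def scaled(self, factor: float, norm_state: Optional[str] = None) -> "CoverageTrack":
        return self.transformed(lambda v: v * factor, norm_state=norm_state)

    def transformed(self, func, norm_state: Optional[str] = None) -> "CoverageTrack":
        """New track with ``func`` applied to the run values."""
        out = CoverageTrack(self.chrom_sizes, norm_state=norm_state or self.norm_state)
        for chrom, r in self._runs.items():
            out._runs[chrom] = _Runs(r.starts.copy(), r.ends.copy(), func(r.values))
        return out

    def window_sum(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base values over [start, end), clipped at chromosome edges."""
        if chrom not in self._runs:
            raise CoverageError(f"unknown chromosome {chrom!r}")
        start = max(int(start), 0)
        end = min(int(end), self.chrom_sizes[chrom])
        if end <= start:
            return 0.0
        r = self._runs[chrom]
        if r.starts.size == 0:
            return 0.0
        lo = np.searchsorted(r.ends, start, side="right")
        hi = np.searchsorted(r.starts, end, side="left")
        if hi <= lo:
            return 0.0
        s = np.maximum(r.starts[lo:hi], start)
        e = np.minimum(r.ends[lo:hi], end)
        return float(np.sum(r.values[lo:hi] * np.maximum(e - s, 0)))


# -- normalization ----------------------------------------------------


def normalize_chec(track: CoverageTrack, meta: SampleMeta, scale: float = 10_000.0) -> CoverageTrack:
    """Spike normalization for ChEC-seq: per-base reads / spike reads x scale."""
    if track.norm_state != "raw":
        raise CoverageError(f"normalize_chec requires a raw track, got {track.norm_state}")
    if meta.spike_reads <= 0:
        raise CoverageError(f"sample {meta.sample_id}: spike_reads must be > 0")
    return track.transformed(lambda v: v / meta.spike_reads * scale,
                             norm_state="chec_normalized")


def normalize_chip(
    track: CoverageTrack,
    meta_ip: SampleMeta,
    meta_input: SampleMeta,
    scale: float = 10_000.0,
) -> CoverageTrack:
    """Input-corrected spike normalization for ChIP-seq.

    value = raw / spike_reads(IP) x (spike_reads(input) / experimental_reads(input)) x scale
    """
    if track.norm_state != "raw":
        raise CoverageError(f"normalize_chip requires a raw track, got {track.norm_state}")
    if meta_ip.input_link is None:
        raise CoverageError(f"sample {meta_ip.sample_id}: no input_link for ChIP normalization")
    if meta_ip.input_link != meta_input.sample_id:
        raise CoverageError(
            f"sample {meta_ip.sample_id} links to input {meta_ip.input_link!r}, "
            f"got {meta_input.sample_id!r}"
        )
    if meta_ip.spike_reads <= 0:
        raise CoverageError(f"sample {meta_ip.sample_id}: spike_reads must be > 0")
    if meta_input.spike_reads <= 0 or meta_input.experimental_reads <= 0:
        raise CoverageError(f"input {meta_input.sample_id}: read totals must be > 0")
    ratio = meta_input.spike_reads / meta_input.experimental_reads
    return track.transformed(lambda v: v / meta_ip.spike_reads * ratio * scale,
                             norm_state="chip_normalized")


def normalize_rpm(track: CoverageTrack, meta: SampleMeta) -> CoverageTrack:
    """Reads-per-million normalization (public datasets without spike-in)."""
    if track.norm_state != "raw":
        raise CoverageError(f"normalize_rpm requires a raw track, got {track.norm_state}")
    if meta.experimental_reads <= 0:
        raise CoverageError(f"sample {meta.sample_id}: experimental_reads must be > 0")
    return track.transformed(lambda v: v / meta.experimental_reads * 1e6,
                             norm_state="rpm_normalized")


# -- windowed signal --------------------------------------------------


def window_signal(track: CoverageTrack, chrom: str, start: int, end: int) -> float:
    """Sum of normalized per-base signal over a half-open interval.

    Intervals extending past a chromosome edge are clipped; an unknown
    chromosome raises.
    """
    return track.window_sum(chrom, start, end)


def gene_body_signal(track: CoverageTrack, gene) -> float:
    """Signal over the whole transcribed region, TSS to PAS."""
    lo, hi = gene.transcribed_interval()
    return track.window_sum(gene.chrom, lo, hi)


def signal_ratio(
    numerator: pd.Series,
    denominator: pd.Series,
) -> tuple[pd.Series, int]:
    """Per-gene ratio after inner join; zero-denominator genes excluded.

    Returns (ratios, number of genes excluded for a zero denominator).
    """
    common = numerator.index.intersection(denominator.index)
    if len(common) == 0:
        raise CoverageError("signal_ratio: gene sets are disjoint")
    num = numerator.loc[common].astype(float)
    den = denominator.loc[common].astype(float)
    ok = den != 0
    return (num[ok] / den[ok]), int((~ok).sum())
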