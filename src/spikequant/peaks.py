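"""Enrichment peak calling against a control track, promoter assignment,
replicate consensus, and promoter occupancy change.

The caller implements the published enrichment criteria directly: a
window must be enriched at least twofold over the (depth-matched)
control track, twofold over its local background, and pass a
Benjamini-Hochberg FDR of 0.1% on a Poisson tail test. Overlapping
passing windows are merged into peaks; the peak summit is the mid-range
of the merged borders.

To make the calls invariant to joint rescaling of IP and control (spike
normalization must not change which peaks exist), both tracks are
rescaled internally to a fixed effective depth of pseudo-reads before
the Poisson scoring; fold criteria are scale-free by construction. The
Poisson tail at non-integer pseudo-counts uses the continuous
regularized-gamma extension P[X >= x] = Q-tail gammainc(x, lam), which
coincides with the discrete tail at integers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .annotation import PromoterWindow
from .coverage import CoverageTrack, window_signal


class PeakError(ValueError):
    pass


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    summit: int
    fold_vs_control: float
    fold_vs_local: float
    p_value: float
    q_value: float = float("nan")

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise PeakError("peak start must be < end")
        if not (self.start <= self.summit < self.end):
            raise PeakError("summit must lie inside the peak")


@dataclass
class PromoterBindingCall:
    gene_id: str
    bound: list[bool]
    consensus_bound: bool
    summit_used: Optional[int] = None
    summit_source: str = "fallback_max"  # or "peak"


def peak_summit(start: int, end: int) -> int:
    """Mid-range of the peak borders, floored to a base position."""
    if not start < end:
        raise PeakError("peak_summit: start must be < end")
    return (start + end) // 2


def _bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def call_peaks(
    ip: CoverageTrack,
    control: CoverageTrack,
    window: int = 200,
    step: int = 50,
    local_span: int = 10_000,
    fold_control: float = 2.0,
    fold_local: float = 2.0,
    fdr: float = 0.001,
    effective_depth: float = 1e6,
) -> list[Peak]:
    """Call enrichment peaks of the IP track over a control track.

    Sliding windows (width ``window``, stride ``step``) are kept when the
    IP signal is >= ``fold_control`` times the depth-matched control
    expectation, >= ``fold_local`` times the local IP background over
    ``local_span``, and significant under a Poisson tail test at
    Benjamini-Hochberg FDR ``fdr``. Both tracks must be in the same
    normalization state. Overlapping passing windows merge into one peak.
    """
    if ip.norm_state != control.norm_state:
        raise PeakError(
            f"IP ({ip.norm_state}) and control ({control.norm_state}) must be "
            "normalized identically"
        )
    ctrl_total = control.total_signal()
    if ctrl_total <= 0:
        raise PeakError("control track has zero total signal; a control is required")
    ip_total = ip.total_signal()
    if ip_total <= 0:
        return []

    # rescale both tracks to a fixed pseudo-read depth -> scale invariance
    ip_f = effective_depth / ip_total
    ct_f = effective_depth / ctrl_total
    genome_len = sum(ip.chrom_sizes.values())
    mean_window = effective_depth * window / genome_len  # genome-average window count

    per_chrom = []
    for chrom, size in ip.chrom_sizes.items():
        if size < window:
            continue
        dense_ip = ip.dense(chrom) * ip_f
        dense_ct = (control.dense(chrom) * ct_f) if chrom in control.chrom_sizes else np.zeros(size)
        cum_ip = np.concatenate(([0.0], np.cumsum(dense_ip)))
        cum_ct = np.concatenate(([0.0], np.cumsum(dense_ct)))
        starts = np.arange(0, size - window + 1, step)
        ends = starts + window
        ip_win = cum_ip[ends] - cum_ip[starts]
        ct_win = cum_ct[ends] - cum_ct[starts]
        # local background: IP mean over +/- local_span/2, window excluded
        half = local_span // 2
        lo = np.maximum(starts - half, 0)
        hi = np.minimum(ends + half, size)
        local_sum = (cum_ip[hi] - cum_ip[lo]) - ip_win
        local_len = (hi - lo) - window
        with np.errstate(divide="ignore", invalid="ignore"):
            local_exp = np.where(local_len > 0, local_sum / np.maximum(local_len, 1) * window, 0.0)
        # floors keep folds finite and the Poisson rate positive in empty regions
        floor = 0.25 * mean_window
        exp_ctrl = np.maximum(ct_win, floor)
        exp_local = np.maximum(local_exp, floor)
        f_ctrl = ip_win / exp_ctrl
        f_local = ip_win / exp_local
        # P[X >= x] for Poisson(lam), continuous in x (1 where ip_win == 0)
        with np.errstate(invalid="ignore"):
            p = np.where(ip_win > 0, special.gammainc(np.maximum(ip_win, 1e-12), exp_ctrl), 1.0)
        per_chrom.append((chrom, starts, ends, ip_win, f_ctrl, f_local, p))

    if not per_chrom:
        return []
    all_p = np.concatenate([t[6] for t in per_chrom])
    all_q = _bh_qvalues(all_p)
    passing = []
    offset = 0
    for chrom, starts, ends, ip_win, f_ctrl, f_local, p in per_chrom:
        q = all_q[offset:offset + p.size]
        offset += p.size
        keep = (
            (f_ctrl >= fold_control) & (f_local >= fold_local)
            & (ip_win > 0) & (q <= fdr)
        )
        for i in np.flatnonzero(keep):
            passing.append(
                (chrom, int(starts[i]), int(ends[i]), float(f_ctrl[i]),
                 float(f_local[i]), float(p[i]), float(q[i]))
            )
    if not passing:
        return []

    # merge overlapping windows per chromosome
    peaks: list[Peak] = []
    passing.sort(key=lambda t: (t[0], t[1]))
    cur = None
    for chrom, s, e, fc, fl, pv, qv in passing:
        if cur is not None and chrom == cur[0] and s <= cur[2]:
            cur = (chrom, cur[1], max(cur[2], e), max(cur[3], fc), max(cur[4], fl),
                   min(cur[5], pv), min(cur[6], qv))
        else:
            if cur is not None:
                peaks.append(_finalize_peak(cur))
            cur = (chrom, s, e, fc, fl, pv, qv)
    if cur is not None:
        peaks.append(_finalize_peak(cur))
    return peaks


def _finalize_peak(t) -> Peak:
    chrom, s, e, fc, fl, pv, qv = t
    return Peak(chrom=chrom, start=s, end=e, summit=peak_summit(s, e),
                fold_vs_control=fc, fold_vs_local=fl, p_value=pv, q_value=qv)


def assign_peaks_to_promoters(
    peaks: Sequence[Peak],
    promoters: Sequence[PromoterWindow],
) -> tuple[dict[str, Peak], list[Peak]]:
    """Assign peaks whose summit falls inside a promoter window.

    When several peaks land in one window, the one whose summit is
    closest to the TSS wins; an exact distance tie goes to the upstream
    peak (in the transcription direction), which is deterministic.
    Returns (gene_id -> peak, unassigned peaks).
    """
    assigned: dict[str, Peak] = {}
    used: set[int] = set()
    for w in promoters:
        best = None
        for i, p in enumerate(peaks):
            if p.chrom != w.chrom or not (w.start <= p.summit < w.end):
                continue
            dist = abs(p.summit - w.tss)
            # signed offset in transcription direction; upstream = negative
            offset = (p.summit - w.tss) if w.strand == "+" else (w.tss - p.summit)
            key = (dist, 0 if offset < 0 else 1, p.start)
            if best is None or key < best[0]:
                best = (key, i, p)
        if best is not None:
            assigned[w.gene_id] = best[2]
            used.add(best[1])
    unassigned = [p for i, p in enumerate(peaks) if i not in used]
    return assigned, unassigned


def consensus_bound(
    replicate_assignments: Sequence[Mapping[str, Peak] | set],
    promoters: Sequence[PromoterWindow],
    k: int,
    n: Optional[int] = None,
) -> dict[str, PromoterBindingCall]:
    """Call a promoter bound when it is bound in at least k of n replicates.

    Presets from the published designs: 4 of 6 for ChEC-seq, 1 of 2 for
    ChIP-seq. ``replicate_assignments`` holds, per replicate, either the
    gene->peak mapping from :func:`assign_peaks_to_promoters` or a bare
    set of bound gene ids.
    """
    n_reps = len(replicate_assignments) if n is None else n
    if k > n_reps:
        raise PeakError(f"consensus_bound: k={k} exceeds n={n_reps}")
    if len(replicate_assignments) != n_reps:
        raise PeakError("consensus_bound: number of assignments differs from n")
    calls = {}
    for w in promoters:
        flags = []
        for rep in replicate_assignments:
            bound_ids = rep.keys() if isinstance(rep, Mapping) else rep
            flags.append(w.gene_id in bound_ids)
        calls[w.gene_id] = PromoterBindingCall(
            gene_id=w.gene_id, bound=flags, consensus_bound=sum(flags) >= k,
        )
    return calls


def fallback_summit(
    track: CoverageTrack,
    window: PromoterWindow,
    smooth_bp: int = 21,
) -> Optional[int]:
    """Position of the strongest (smoothed) signal inside a promoter window.

    Used when no called peak was assigned to the promoter. Signal is
    smoothed with a centered moving average of ``smooth_bp``; ties go to
    the position closest to the TSS. Returns None when the window is
    empty (fully clipped off the chromosome).
    """
    size = track.chrom_sizes.get(window.chrom)
    if size is None:
        raise PeakError(f"unknown chromosome {window.chrom!r}")
    lo, hi = max(window.start, 0), min(window.end, size)
    if hi <= lo:
        return None
    pad = smooth_bp // 2
    plo, phi = max(lo - pad, 0), min(hi + pad, size)
    dense = track.dense(window.chrom)[plo:phi]
    kernel = np.ones(smooth_bp) / smooth_bp
    smooth = np.convolve(dense, kernel, mode="same")
    seg = smooth[lo - plo:hi - plo]
    best = seg.max()
    # tolerance absorbs summation-order jitter across the smoothing plateau
    positions = np.flatnonzero(seg >= best - 1e-9 * max(abs(best), 1.0)) + lo
    # smoothing creates plateaus around sharp maxima: break ties by the
    # raw per-base signal, then by distance to the TSS, then leftmost
    raw = dense[positions - plo]
    dists = np.abs(positions - window.tss)
    return int(positions[np.lexsort((positions, dists, -raw))[0]])


def promoter_occupancy(
    track: CoverageTrack,
    window: PromoterWindow,
    peak: Optional[Peak] = None,
    width: int = 200,
    smooth_bp: int = 21,
) -> tuple[Optional[float], Optional[int], str]:
    """Signal in a ``width`` bp window centered on the promoter's summit.

    The summit comes from the assigned peak when there is one, otherwise
    from :func:`fallback_summit`. Returns (occupancy, summit, source);
    occupancy is None when the promoter window lies entirely off the
    chromosome.
    """
    if peak is not None:
        summit, source = peak.summit, "peak"
    else:
        summit, source = fallback_summit(track, window, smooth_bp=smooth_bp), "fallback_max"
        if summit is None:
            return None, None, source
    occ = window_signal(track, window.chrom, summit - width // 2, summit + width // 2)
    return occ, summit, source


def occupancy_log2_change(
    occ_iaa: pd.DataFrame,
    occ_dmso: pd.DataFrame,
    pseudocount: Optional[float] = None,
) -> pd.Series:
    """Mean over replicate pairs of log2(IAA / DMSO) promoter occupancy.

    Columns are replicate indices; pairing is by column name. When any
    occupancy is zero, a pseudocount of half the smallest positive
    occupancy in the experiment is applied (scale-aware, avoids
    infinities) unless an explicit pseudocount is given.
    """
    if list(occ_iaa.columns) != list(occ_dmso.columns):
        raise PeakError(
            f"unpaired replicates: IAA {list(occ_iaa.columns)} vs DMSO {list(occ_dmso.columns)}"
        )
    if not occ_iaa.index.equals(occ_dmso.index):
        raise PeakError("occupancy tables must share one promoter universe")
    a = occ_iaa.to_numpy(float)
    d = occ_dmso.to_numpy(float)
    if pseudocount is None:
        both = np.concatenate([a.ravel(), d.ravel()])
        pos = both[both > 0]
        pseudocount = 0.5 * pos.min() if (a <= 0).any() or (d <= 0).any() else 0.0
        if pos.size == 0:
            raise PeakError("all occupancies are zero")
    lfc = np.log2((a + pseudocount) / (d + pseudocount))
    return pd.Series(lfc.mean(axis=1), index=occ_iaa.index, name="log2_occupancy_change")
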