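"""Piecewise-constant segmentation of the de-noised BAF and RDR tracks.

Each chromosome arm is segmented independently by minimising

    L(x) = sum_s sum_{i in s} w_i (x_i - xbar_s)^2 + lambda |S|

over partitions S of the arm's data points, where xbar_s is the
per-segment weighted mean and lambda (default 0.1) penalises the number
of segments.  Minimisation uses a restarted stochastic greedy search.
The genome is segmented first on the mirrored BAF data alone, then
further on the normalised RDR data with the BAF breakpoints held fixed:
BAF is the cleaner of the two signals.

Prior to segmentation BAF values are mirrored, b_mirr = 0.5 - |0.5 - b|,
and RDR values normalised, r_norm = r / (4 rbar), so the two tracks live
on comparable scales.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .welldata_io import GenomeTracks, WellDataError
from .rlf_rdr import RDRTrack

DEFAULT_LAMBDA = 0.1
DEFAULT_MIN_SPAN = 5_000_000
DEFAULT_RESTARTS = 10_000
STOP_AFTER_REJECTIONS = 100


def mirror_baf(b):
    """Fold BAF onto [0, 0.5]: b_mirr = 0.5 - |0.5 - b|."""
    return 0.5 - np.abs(0.5 - np.asarray(b, dtype=float))


def normalize_rdr(r, r_bar: float):
    """r_norm = r / (4 rbar); the genome-mean window maps to 0.25."""
    if r_bar <= 0:
        raise WellDataError("genome-wide mean RDR must be positive")
    return np.asarray(r, dtype=float) / (4.0 * r_bar)


class _SegmentCost:
    """Weighted within-segment SSE of index ranges, via prefix sums.

    ``form="standard"`` evaluates sum w_i (x_i - xbar)^2 with xbar the
    weighted mean; ``form="literal"`` evaluates sum (w_i x_i - xbar)^2,
    the loss exactly as printed.  Both are O(1) per range.
    """

    def __init__(self, x, w, form: str = "standard"):
        x = np.asarray(x, dtype=float)
        w = np.asarray(w, dtype=float)
        self.n = len(x)
        self.form = form
        self._W = np.concatenate([[0.0], np.cumsum(w)]).tolist()
        self._WX = np.concatenate([[0.0], np.cumsum(w * x)]).tolist()
        self._WX2 = np.concatenate([[0.0], np.cumsum(w * x * x)]).tolist()
        self._W2X2 = np.concatenate([[0.0], np.cumsum((w * x) ** 2)]).tolist()

    def sse(self, i: int, j: int) -> float:
        wt = self._W[j] - self._W[i]
        if wt <= 0:
            return 0.0
        wx = self._WX[j] - self._WX[i]
        xbar = wx / wt
        if self.form == "standard":
            return max((self._WX2[j] - self._WX2[i]) - wx * xbar, 0.0)
        # literal printed form: sum (w_i x_i - xbar)^2
        return max((self._W2X2[j] - self._W2X2[i])
                   - 2.0 * xbar * wx + (j - i) * xbar * xbar, 0.0)


@dataclass
class Segmentation:
    """Result of segmenting one arm: interior breakpoints in data-point
    index space, the per-segment index ranges, and the attained loss."""

    breakpoints: list[int]
    n_points: int
    loss: float
    lam: float

    @property
    def segments(self) -> list[tuple[int, int]]:
        bounds = [0] + list(self.breakpoints) + [self.n_points]
        return list(zip(bounds[:-1], bounds[1:]))


def segment_loss(x, w, breakpoints, lam: float = DEFAULT_LAMBDA,
                 form: str = "standard") -> float:
    """Evaluate L for an explicit breakpoint set (interior indices)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    bounds = [0] + sorted(breakpoints) + [n]
    for i, j in zip(bounds[:-1], bounds[1:]):
        if j <= i:
            raise WellDataError("empty segment in breakpoint set")
    cost = _SegmentCost(x, w, form=form)
    total = sum(cost.sse(i, j) for i, j in zip(bounds[:-1], bounds[1:]))
    return total + lam * (len(bounds) - 1)


def _admissible(positions, i: int, j: int, min_span: float) -> bool:
    """A segment [i, j) is admissible if its genomic span is >= min_span."""
    return positions[j - 1] - positions[i] >= min_span


def greedy_segment(x, w, positions, lam: float = DEFAULT_LAMBDA,
                   min_span: float = DEFAULT_MIN_SPAN,
                   restarts: int = DEFAULT_RESTARTS,
                   seed: int | random.Random = 0,
                   required_breakpoints: list[int] | None = None,
                   form: str = "standard",
                   stop_after: int = STOP_AFTER_REJECTIONS,
                   max_iter: int = 5000) -> Segmentation:
    """Minimise the segmentation loss by restarted stochastic greedy search.

    Each restart begins from the coarsest admissible solution (the
    single segment, plus any ``required_breakpoints``) and repeatedly
    proposes one of three random moves — add a breakpoint at a random
    position, remove a random optional breakpoint, or shift one by a
    single data point — accepting a move iff it strictly decreases L,
    and stops after ``stop_after`` consecutive rejections.  The best
    segmentation over all restarts is returned.  Weights are
    renormalised to mean 1 within the arm so that lambda is comparable
    across arms and tracks.  A segment must span >= ``min_span`` of
    genome unless the whole arm is shorter.

    ``required_breakpoints`` (used by the RDR pass to honour the BAF
    pass) are always present and never removed or shifted.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    positions = np.asarray(positions, dtype=float)
    n = len(x)
    if n == 0:
        return Segmentation(breakpoints=[], n_points=0, loss=0.0, lam=lam)
    w = w / w.mean()
    required = sorted(set(required_breakpoints or []))
    cost = _SegmentCost(x, w, form=form)
    pos = positions.tolist()
    arm_too_short = positions[-1] - positions[0] < min_span

    master = random.Random(seed) if isinstance(seed, int) else seed

    def total_loss(bps: list[int]) -> float:
        bounds = [0] + bps + [n]
        return (sum(cost.sse(i, j) for i, j in zip(bounds[:-1], bounds[1:]))
                + lam * (len(bounds) - 1))

    def spans_ok(i: int, p: int, j: int) -> bool:
        # splitting [i, j) at p keeps both parts admissible
        if arm_too_short:
            return False
        return (pos[p - 1] - pos[i] >= min_span
                and pos[j - 1] - pos[p] >= min_span)

    best_bps = list(required)
    best_loss = total_loss(best_bps)

    req_set = set(required)
    for _ in range(restarts):
        rng = random.Random(master.getrandbits(64))
        bps = list(required)
        cur = total_loss(bps)
        rejections = 0
        for _it in range(max_iter):
            if rejections >= stop_after:
                break
            optional = [b for b in bps if b not in req_set]
            move = rng.randrange(3)
            delta = None
            if move == 0 and n > 1:  # add
                p = rng.randrange(1, n)
                if p not in bps:
                    bounds = [0] + bps + [n]
                    k = 0
                    while bounds[k + 1] < p:
                        k += 1
                    i, j = bounds[k], bounds[k + 1]
                    if i < p < j and spans_ok(i, p, j):
                        delta = (cost.sse(i, p) + cost.sse(p, j)
                                 - cost.sse(i, j) + lam)
                        new_bps = sorted(bps + [p])
            elif move == 1 and optional:  # remove
                p = optional[rng.randrange(len(optional))]
                k = bps.index(p)
                bounds = [0] + bps + [n]
                i, j = bounds[k], bounds[k + 2]
                delta = cost.sse(i, j) - cost.sse(i, p) - cost.sse(p, j) - lam
                new_bps = bps[:k] + bps[k + 1:]
            elif move == 2 and optional:  # shift by one data point
                p = optional[rng.randrange(len(optional))]
                q = p + (1 if rng.random() < 0.5 else -1)
                k = bps.index(p)
                bounds = [0] + bps + [n]
                i, j = bounds[k], bounds[k + 2]
                if i < q < j and q not in bps and spans_ok(i, q, j):
                    delta = (cost.sse(i, q) + cost.sse(q, j)
                             - cost.sse(i, p) - cost.sse(p, j))
                    new_bps = bps[:k] + [q] + bps[k + 1:]
            if delta is not None and delta < -1e-12:
                bps = new_bps
                cur += delta
                rejections = 0
            else:
                rejections += 1
        if cur < best_loss - 1e-12:
            best_loss = cur
            best_bps = bps
    return Segmentation(breakpoints=sorted(best_bps), n_points=n,
                        loss=total_loss(sorted(best_bps)), lam=lam)


@dataclass
class SegmentData:
    """One final genome segment carrying both data tracks for fitting."""

    chrom: str
    start: int
    end: int
    arm: str
    r: np.ndarray          # corrected RDR values of unmasked windows
    b: np.ndarray          # mirrored BAF values
    b_weight: np.ndarray   # haplotype-group sizes of the BAF points

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def has_baf(self) -> bool:
        return len(self.b) > 0


def segment_genome(baf_points: pd.DataFrame, rdr: RDRTrack,
                   tracks: GenomeTracks, lam: float = DEFAULT_LAMBDA,
                   min_span: float = DEFAULT_MIN_SPAN,
                   restarts: int = DEFAULT_RESTARTS,
                   seed: int = 0) -> list[SegmentData]:
    """Two-pass segmentation of the whole genome, arm by arm.

    Pass 1 segments the mirrored BAF points (weights = haplotype-group
    sizes).  Pass 2 segments the normalised RDR windows with the BAF
    breakpoints fixed, so RDR may only subdivide BAF segments.  Returns
    the final segments with both data subsets attached, ready for
    copy-number fitting.
    """
    master = random.Random(seed)
    windows = rdr.windows
    arm_ids = tracks.window_arms()
    mids = ((windows["start"] + windows["end"]) // 2).to_numpy()
    r_norm = rdr.normalised
    out: list[SegmentData] = []
    if len(baf_points):
        baf_chrom = baf_points["chrom"].to_numpy()
        baf_pos = baf_points["pos"].to_numpy()
        baf_cen = np.array([tracks.centromeres.get(c, 0) for c in baf_chrom])
        baf_arm = np.where(baf_pos < baf_cen, "p", "q")
        baf_arm_ids = np.char.add(np.char.add(baf_chrom.astype(str), ":"), baf_arm)
    for arm in arm_ids.unique():
        in_arm = (arm_ids == arm).to_numpy()
        usable = in_arm & rdr.mask
        widx = np.flatnonzero(usable)
        if len(widx) == 0:
            continue
        chrom = arm.split(":")[0]
        # --- BAF pass
        genomic_bps: list[float] = []
        if len(baf_points):
            bsel = np.flatnonzero(baf_arm_ids == arm)
        else:
            bsel = np.array([], dtype=int)
        if len(bsel) > 0:
            b_arm = mirror_baf(baf_points["b"].to_numpy()[bsel])
            w_arm = baf_points["weight"].to_numpy()[bsel].astype(float)
            p_arm = baf_pos[bsel].astype(float)
            seg_b = greedy_segment(b_arm, w_arm, p_arm, lam=lam,
                                   min_span=min_span, restarts=restarts,
                                   seed=master)
            for bp in seg_b.breakpoints:
                genomic_bps.append(0.5 * (p_arm[bp - 1] + p_arm[bp]))
        # --- RDR pass with BAF breakpoints fixed
        arm_mids = mids[widx].astype(float)
        required = sorted({int(np.searchsorted(arm_mids, g))
                           for g in genomic_bps})
        required = [b for b in required if 0 < b < len(widx)]
        seg_r = greedy_segment(r_norm[widx], np.ones(len(widx)), arm_mids,
                               lam=lam, min_span=min_span, restarts=restarts,
                               seed=master, required_breakpoints=required)
        # --- assemble final segments
        starts = windows["start"].to_numpy()[widx]
        ends = windows["end"].to_numpy()[widx]
        for (i, j) in seg_r.segments:
            seg_start, seg_end = int(starts[i]), int(ends[j - 1])
            if len(bsel) > 0:
                in_seg = (baf_pos[bsel] >= seg_start) & (baf_pos[bsel] < seg_end)
                b_vals = mirror_baf(baf_points["b"].to_numpy()[bsel][in_seg])
                b_w = baf_points["weight"].to_numpy()[bsel][in_seg].astype(float)
            else:
                b_vals = np.array([])
                b_w = np.array([])
            out.append(SegmentData(
                chrom=chrom, start=seg_start, end=seg_end, arm=arm,
                r=rdr.corrected[widx[i:j]], b=b_vals, b_weight=b_w))
    return out
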