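"""Reconstructed large fragments (RLFs) and the read-depth ratio (RDR).

Short-read depth in well-barcoded linked-read data is dominated by
per-fragment amplification noise: every ~100 kb input fragment is
amplified at its own rate before sequencing.  Because each well holds at
most one fragment per locus, co-local read pairs within one well almost
surely derive from one input fragment.  Chaining them reconstructs that
fragment in silico, and counting *fragments* per window instead of reads
removes the amplification noise from the depth signal.

The RDR per 1 Mb window is ``r = 100 * mean RLF depth / germline reads``
and is corrected for GC content and mappability with a per-sample linear
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .welldata_io import GenomeTracks, WellDataError

DEFAULT_MAX_GAP = 100_000

RLF_COLUMNS = ["well", "chrom", "start", "end"]


def reconstruct_rlfs(reads: pd.DataFrame, max_gap: int = DEFAULT_MAX_GAP) -> pd.DataFrame:
    """Chain co-local read pairs within each well into large fragments.

    Within one well and chromosome, consecutive (position-sorted) reads
    belong to the same fragment when the gap between them
    (next.start - prev.end) is strictly less than ``max_gap``.  Each RLF
    spans from the start of its first read to the end of its last read.

    Returns a DataFrame with columns ``well, chrom, start, end``.
    """
    if len(reads) == 0:
        return pd.DataFrame(columns=RLF_COLUMNS)
    df = reads.sort_values(["well", "chrom", "start", "end"], kind="mergesort")
    start = df["start"].to_numpy(dtype=np.int64)
    # running max of end within each (well, chrom) run handles contained reads
    group_change = np.zeros(len(df), dtype=bool)
    group_change[0] = True
    for col in ("well", "chrom"):
        vals = df[col].to_numpy()
        group_change[1:] |= vals[1:] != vals[:-1]
    run_end = df.groupby(np.cumsum(group_change))["end"].cummax().to_numpy(dtype=np.int64)
    gap = np.empty(len(df), dtype=np.int64)
    gap[0] = max_gap  # force new chain
    gap[1:] = start[1:] - run_end[:-1]
    new_chain = group_change | (gap >= max_gap)
    chain_id = np.cumsum(new_chain)
    out = pd.DataFrame({
        "well": df["well"].to_numpy(),
        "chrom": df["chrom"].to_numpy(),
        "start": start, "end": run_end, "chain": chain_id,
    })
    rlfs = out.groupby("chain", sort=True).agg(
        well=("well", "first"), chrom=("chrom", "first"),
        start=("start", "min"), end=("end", "max")).reset_index(drop=True)
    return rlfs[RLF_COLUMNS]


def _window_interval_depth(intervals: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Mean per-base count of intervals overlapping each window."""
    depth = np.zeros(len(windows), dtype=float)
    widx = np.arange(len(windows))
    for chrom, wgrp in windows.groupby("chrom", sort=False):
        sel = intervals[intervals["chrom"] == chrom]
        if len(sel) == 0:
            continue
        wstart = wgrp["start"].to_numpy()
        wend = wgrp["end"].to_numpy()
        rows = widx[windows["chrom"] == chrom]
        istart = sel["start"].to_numpy(dtype=np.int64)
        iend = sel["end"].to_numpy(dtype=np.int64)
        # windows tile contiguously: locate first/last window each interval touches
        istart = np.clip(istart, wstart[0], wend[-1])
        iend = np.clip(iend, wstart[0], wend[-1])
        first = np.minimum(np.searchsorted(wend, istart, side="right"), len(wgrp) - 1)
        last = np.minimum(np.searchsorted(wstart, iend, side="left"), len(wgrp))  # exclusive
        base_sum = np.zeros(len(wgrp), dtype=float)
        single = last - first <= 1
        if single.any():
            np.add.at(base_sum, first[single],
                      (iend[single] - istart[single]).astype(float))
        for f, l, s, e in zip(first[~single], last[~single],
                              istart[~single], iend[~single]):
            ov = np.minimum(e, wend[f:l]) - np.maximum(s, wstart[f:l])
            np.add.at(base_sum, np.arange(f, l), np.maximum(ov, 0).astype(float))
        depth[rows] = base_sum / (wend - wstart)
    return depth


def window_rlf_depth(rlfs: pd.DataFrame, tracks: GenomeTracks) -> np.ndarray:
    """Average RLF depth per window: mean over the window's bases of the
    number of RLFs covering that base."""
    return _window_interval_depth(rlfs, tracks.windows)


def window_read_depth(reads: pd.DataFrame, tracks: GenomeTracks) -> np.ndarray:
    """Short-read coverage per window (mean per-base read count).

    The noisy alternative to :func:`window_rlf_depth`; retained for
    benchmarking the de-noising gain of fragment-level depth.
    """
    return _window_interval_depth(reads, tracks.windows)


@dataclass
class RDRTrack:
    """Per-window read-depth-ratio values with their mask and covariates.

    ``raw``/``corrected`` are the x100-scaled tumour/germline depth
    ratios; ``mask`` is True for assessable windows (non-zero germline
    coverage); ``r_bar`` is the genome-wide mean of the corrected values
    over unmasked windows.
    """

    windows: pd.DataFrame
    raw: np.ndarray
    corrected: np.ndarray
    mask: np.ndarray
    r_bar: float

    @property
    def normalised(self) -> np.ndarray:
        """r_norm = r / (4 r̄); the genome-average window maps to 0.25."""
        return self.corrected / (4.0 * self.r_bar)

    def to_frame(self) -> pd.DataFrame:
        out = self.windows[["chrom", "start", "end"]].copy()
        out["raw_r"] = self.raw
        out["corrected_r"] = self.corrected
        out["r_norm"] = self.normalised
        out["masked"] = ~self.mask
        return out


def compute_raw_rdr(rlf_depth: np.ndarray, germline_reads: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Raw RDR per window: r = 100 x RLF depth / germline reads.

    Windows with zero germline reads are masked (r set to NaN).
    Returns (r, mask) where mask is True for assessable windows.
    """
    germline = np.asarray(germline_reads, dtype=float)
    mask = germline > 0
    if not mask.any():
        raise WellDataError("no window has germline coverage; RDR undefined")
    r = np.full(len(germline), np.nan)
    r[mask] = 100.0 * np.asarray(rlf_depth, dtype=float)[mask] / germline[mask]
    return r, mask


def correct_rdr(raw_r: np.ndarray, mask: np.ndarray, tracks: GenomeTracks,
                min_windows: int = 50) -> tuple[np.ndarray, float]:
    """Correct raw RDR for GC content and mappability.

    Fits r ~ 1 + gc + mappability by ordinary least squares over unmasked
    windows and rescales each window by (mean fitted)/(fitted), keeping
    depth non-negative and preserving the genome-wide mean.  Degenerate
    designs (constant covariates) leave the data unchanged.

    Returns (corrected r, r_bar) with r_bar the mean of corrected r over
    unmasked windows.
    """
    r = np.asarray(raw_r, dtype=float)
    m = np.asarray(mask, dtype=bool)
    gc = tracks.windows["gc"].to_numpy(dtype=float)
    mp = tracks.windows["mappability"].to_numpy(dtype=float)
    if m.sum() < min_windows:
        raise WellDataError(
            f"need at least {min_windows} assessable windows to fit the "
            f"GC/mappability model, got {int(m.sum())}")
    X = np.column_stack([np.ones(int(m.sum())), gc[m], mp[m]])
    # drop constant covariate columns; with none left the correction is a no-op
    keep = [0] + [j for j in (1, 2) if np.ptp(X[:, j]) > 0]
    corrected = r.copy()
    if len(keep) > 1:
        Xk = X[:, keep]
        beta, *_ = np.linalg.lstsq(Xk, r[m], rcond=None)
        fitted = Xk @ beta
        fitted = np.maximum(fitted, 1e-9)
        corrected[m] = r[m] * (fitted.mean() / fitted)
        corrected[m] = np.maximum(corrected[m], 0.0)
        # multiplicative recentring: the correction redistributes depth
        # between windows but must not move the genome-wide mean
        if corrected[m].mean() > 0:
            corrected[m] *= r[m].mean() / corrected[m].mean()
    r_bar = float(corrected[m].mean())
    if r_bar <= 0:
        raise WellDataError("mean corrected RDR is non-positive")
    return corrected, r_bar


def build_rdr_track(rlfs: pd.DataFrame, germline_reads: np.ndarray,
                    tracks: GenomeTracks, min_windows: int = 50) -> RDRTrack:
    """Convenience pipeline: RLF depth -> raw RDR -> corrected RDR track."""
    depth = window_rlf_depth(rlfs, tracks)
    raw, mask = compute_raw_rdr(depth, germline_reads)
    corrected, r_bar = correct_rdr(raw, mask, tracks, min_windows=min_windows)
    return RDRTrack(windows=tracks.windows, raw=raw, corrected=corrected,
                    mask=mask, r_bar=r_bar)


def predict_biallelic_fraction(n_wells: int, input_pg: float,
                               pg_per_genome: float = 6.6) -> float:
    """Expected fraction of covered wells holding both parental alleles.

    With ``c = input_pg / pg_per_genome`` genome copies per parental
    allele at a locus and each fragment landing uniformly in one of
    ``n_wells`` wells, a given well holds a copy of one parental allele
    with probability ``q = 1 - (1 - 1/W)^c`` and holds any fragment with
    probability ``1 - (1 - 1/W)^(2c)``.  The returned value is
    P(both alleles | >= 1 fragment) = q^2 / (1 - (1 - 1/W)^(2c)),
    the predicted rate of mono-allelic-property violations.
    """
    if n_wells < 1:
        raise ValueError("n_wells must be >= 1")
    if input_pg <= 0:
        raise ValueError("input_pg must be positive")
    c = input_pg / pg_per_genome
    miss = (1.0 - 1.0 / n_wells) ** c
    q = 1.0 - miss
    p_any = 1.0 - miss ** 2
    if p_any == 0.0:
        return 0.0
    return q * q / p_any
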