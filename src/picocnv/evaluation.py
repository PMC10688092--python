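"""Benchmarking of copy-number calls against a known truth.

Events are defined on the total copy number relative to the sample's
genomic-length-weighted median total n_med:

* amplification — total copy number >= 2 * n_med;
* deletion — total copy number 0;
* LOH — n_B = 0 with n_A > 0 (so a homozygous deletion is *not* LOH).

Per event class, sensitivity = agreeing bases / truth-event bases and
``specificity_paper`` = agreeing bases / called-event bases.  The latter
is the quantity conventionally called precision, but it is retained
under the name used in the benchmarking scheme this module implements;
F1 = 2 * sens * spec / (sens + spec).  All metrics count bases on the
intersection of the two profiles' assessable genome.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .welldata_io import CopyNumberProfile, WellDataError

EVENT_CLASSES = ("amplification", "deletion", "loh")
SNR_CAP = 1e12


def _flatten(profiles: list[CopyNumberProfile]) -> pd.DataFrame:
    """Intersect profiles onto common sub-intervals.

    Returns a DataFrame with columns chrom, start, end and, per profile
    p, columns nA{p}, nB{p}; only bases covered by *every* profile
    (the jointly assessable genome) are retained.
    """
    chroms: set[str] = set()
    for p in profiles:
        chroms.update(p.segments["chrom"].unique())
    rows = []
    for chrom in sorted(chroms):
        bounds: set[int] = set()
        segsets = []
        for p in profiles:
            seg = p.segments[p.segments["chrom"] == chrom]
            segsets.append(seg)
            bounds.update(seg["start"])
            bounds.update(seg["end"])
        edges = sorted(bounds)
        for s, e in zip(edges[:-1], edges[1:]):
            mid = (s + e) // 2
            states = []
            for seg in segsets:
                hit = seg[(seg["start"] <= mid) & (seg["end"] > mid)]
                if len(hit) != 1:
                    states = None
                    break
                states.append((int(hit["n_A"].iloc[0]), int(hit["n_B"].iloc[0])))
            if states is None:
                continue
            row = {"chrom": chrom, "start": s, "end": e}
            for k, (na, nb) in enumerate(states):
                row[f"nA{k}"] = na
                row[f"nB{k}"] = nb
            rows.append(row)
    return pd.DataFrame(rows)


def median_total_copy(profile: CopyNumberProfile) -> int:
    """Genomic-length-weighted median total copy number (lower median)."""
    seg = profile.segments
    totals = (seg["n_A"] + seg["n_B"]).to_numpy()
    lengths = (seg["end"] - seg["start"]).to_numpy(dtype=float)
    order = np.argsort(totals, kind="mergesort")
    cum = np.cumsum(lengths[order])
    idx = int(np.searchsorted(cum, cum[-1] / 2.0, side="left"))
    return int(totals[order][idx])


@dataclass
class EventCallSet:
    """Per-segment boolean event masks plus the median total copy."""

    intervals: pd.DataFrame  # chrom, start, end, amplification, deletion, loh
    n_med: int


def call_events(profile: CopyNumberProfile) -> EventCallSet:
    seg = profile.segments
    total = (seg["n_A"] + seg["n_B"]).to_numpy()
    n_med = median_total_copy(profile)
    out = seg[["chrom", "start", "end"]].copy()
    out["amplification"] = total >= 2 * n_med
    out["deletion"] = total == 0
    out["loh"] = (seg["n_B"].to_numpy() == 0) & (seg["n_A"].to_numpy() > 0)
    return EventCallSet(intervals=out, n_med=n_med)


def _event_masks(flat: pd.DataFrame, suffix: str, n_med: int) -> dict[str, np.ndarray]:
    total = (flat[f"nA{suffix}"] + flat[f"nB{suffix}"]).to_numpy()
    return {
        "amplification": total >= 2 * n_med,
        "deletion": total == 0,
        "loh": (flat[f"nB{suffix}"].to_numpy() == 0)
               & (flat[f"nA{suffix}"].to_numpy() > 0),
    }


def event_metrics(calls: CopyNumberProfile, truth: CopyNumberProfile) -> pd.DataFrame:
    """Base-level sensitivity, specificity (precision) and F1 per event.

    Metrics are computed on the jointly assessable genome.  A class with
    no truth bases has undefined sensitivity (NaN); one with no called
    bases has undefined specificity; F1 is 0 whenever either input to it
    is undefined or zero.
    """
    flat = _flatten([calls, truth])
    if len(flat) == 0:
        raise WellDataError("profiles share no assessable bases")
    lengths = (flat["end"] - flat["start"]).to_numpy(dtype=float)
    call_masks = _event_masks(flat, "0", median_total_copy(calls))
    truth_masks = _event_masks(flat, "1", median_total_copy(truth))
    rows = []
    for ev in EVENT_CLASSES:
        c, t = call_masks[ev], truth_masks[ev]
        agree = float(lengths[c & t].sum())
        called = float(lengths[c].sum())
        truthy = float(lengths[t].sum())
        sens = agree / truthy if truthy > 0 else np.nan
        spec = agree / called if called > 0 else np.nan
        if np.isnan(sens) or np.isnan(spec) or (sens + spec) == 0:
            f1 = 0.0
        else:
            f1 = 2.0 * sens * spec / (sens + spec)
        rows.append((ev, sens, spec, f1, truthy, called, agree))
    return pd.DataFrame(rows, columns=["event", "sensitivity",
                                       "specificity_paper", "f1",
                                       "truth_bases", "called_bases",
                                       "agreeing_bases"])


def exact_match_fraction(calls: CopyNumberProfile, truth: CopyNumberProfile) -> float:
    """Fraction of jointly assessable bases with identical {n_A, n_B}."""
    flat = _flatten([calls, truth])
    if len(flat) == 0:
        raise WellDataError("profiles share no assessable bases")
    lengths = (flat["end"] - flat["start"]).to_numpy(dtype=float)
    same = ((flat["nA0"] == flat["nA1"]) & (flat["nB0"] == flat["nB1"])).to_numpy()
    return float(lengths[same].sum() / lengths.sum())


def ploidy_error(calls: CopyNumberProfile, truth: CopyNumberProfile) -> float:
    """Absolute difference of length-weighted mean total copy numbers."""
    psi_c = calls.ploidy if calls.ploidy is not None else calls.length_weighted_ploidy()
    psi_t = truth.ploidy if truth.ploidy is not None else truth.length_weighted_ploidy()
    return abs(float(psi_c) - float(psi_t))


def _lower_median(values: np.ndarray) -> int:
    v = np.sort(values)
    return int(v[(len(v) - 1) // 2])


def consensus_states(profiles: list[CopyNumberProfile]
                     ) -> tuple[CopyNumberProfile, pd.DataFrame]:
    """Combine >= 2 profiles into a consensus by per-base median states.

    Per sub-interval the consensus n_A and n_B are the medians of the
    inputs' values (lower median for even counts, keeping states
    integral).  The accompanying report flags profiles whose rounded
    ploidy disagrees with the majority ploidy; re-running those callers
    with a forced ploidy is their owner's job, not this function's.
    """
    if len(profiles) < 2:
        raise WellDataError("consensus requires at least two profiles")
    flat = _flatten(profiles)
    if len(flat) == 0:
        raise WellDataError("profiles share no assessable bases")
    k = len(profiles)
    nA = np.stack([flat[f"nA{i}"].to_numpy() for i in range(k)])
    nB = np.stack([flat[f"nB{i}"].to_numpy() for i in range(k)])
    cons_a = np.apply_along_axis(_lower_median, 0, nA)
    cons_b = np.apply_along_axis(_lower_median, 0, nB)
    seg = flat[["chrom", "start", "end"]].copy()
    seg["n_A"] = np.maximum(cons_a, cons_b)
    seg["n_B"] = np.minimum(cons_a, cons_b)
    seg["clonality"] = 1.0
    # merge adjacent sub-intervals with identical consensus state
    merged = []
    for _, row in seg.iterrows():
        if (merged and merged[-1]["chrom"] == row["chrom"]
                and merged[-1]["end"] == row["start"]
                and merged[-1]["n_A"] == row["n_A"]
                and merged[-1]["n_B"] == row["n_B"]):
            merged[-1]["end"] = row["end"]
        else:
            merged.append(row.to_dict())
    consensus = CopyNumberProfile(pd.DataFrame(merged))
    ploidies = np.array([p.ploidy if p.ploidy is not None
                         else p.length_weighted_ploidy() for p in profiles])
    rounded = np.round(ploidies).astype(int)
    counts = pd.Series(rounded).value_counts()
    majority = int(counts.idxmax())
    report = pd.DataFrame({
        "profile": np.arange(k),
        "ploidy": ploidies,
        "rounded_ploidy": rounded,
        "flagged": rounded != majority,
    })
    return consensus, report


def snr(values: np.ndarray, positions: np.ndarray, chroms: np.ndarray,
        truth: CopyNumberProfile) -> float:
    """Signal-to-noise ratio of a data track against truth states.

    SNR = (difference of the track means over truth-{1,1} and
    truth-{1,0} bases)^2 / (average within-truth-segment variance).
    Noise-free tracks (zero within-segment variance) return a capped
    sentinel; a missing state returns NaN.
    """
    values = np.asarray(values, dtype=float)
    positions = np.asarray(positions)
    chroms = np.asarray(chroms)
    seg = truth.segments
    state_vals = {s: [] for s in [(1, 1), (1, 0)]}
    seg_vars = []
    for _, row in seg.iterrows():
        sel = ((chroms == row["chrom"]) & (positions >= row["start"])
               & (positions < row["end"]))
        v = values[sel]
        if len(v) >= 2:
            seg_vars.append(float(v.var()))
        key = (int(row["n_A"]), int(row["n_B"]))
        if key in state_vals and len(v):
            state_vals[key].append(v)
    if not state_vals[(1, 1)] or not state_vals[(1, 0)]:
        return float("nan")
    m11 = float(np.concatenate(state_vals[(1, 1)]).mean())
    m10 = float(np.concatenate(state_vals[(1, 0)]).mean())
    noise = float(np.mean(seg_vars)) if seg_vars else 0.0
    if noise <= 0:
        return SNR_CAP
    return min((m11 - m10) ** 2 / noise, SNR_CAP)
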