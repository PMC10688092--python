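"""Synthetic well-barcoded linked-read data with known copy-number truth.

Two generators are provided.

``simulate_well_data`` emulates the sequencing platform itself: ~100 kb
input fragments drawn per haplotype in proportion to local copy number
(tumour mixed with diploid normal at 1 - phi), distributed uniformly
over wells, amplified at per-fragment log-normal rates, and tiled with
read pairs; SNP allele observations follow each fragment's haplotype.
It exercises fragment reconstruction, phasing and well-count BAF, and
realises the mono-allelic property with exactly the violation rate of
the binomial collision model.

``simulate_tracks`` draws the de-noised window-level RDR and BAF data
directly from the copy-number model with Gaussian noise.  It is the
whole-genome-scale generator for segmentation/fitting studies, where
simulating every fragment would be needlessly expensive; its noise
level can be calibrated from a small ``simulate_well_data`` run with
:func:`estimate_track_noise`.

Default platform parameters: 384 wells per plate, one plate, 100 pg of
input DNA at 6.6 pg per diploid genome (~15 cell equivalents), 100 kb
mean fragment length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import cn_fit
from .cn_fit import CopyNumberState
from .rlf_rdr import RDRTrack
from .segmentation import SegmentData, mirror_baf
from .welldata_io import CopyNumberProfile, GenomeTracks, make_windows, WellDataError

KARYOTYPE_COLUMNS = ["chrom", "start", "end", "n_A", "n_B", "chi"]


@dataclass
class SimConfig:
    """Parameters of the well-level simulator.

    ``karyotype`` lists tumour CNA intervals (chrom, start, end, n_A,
    n_B, chi); uncovered genome defaults to the diploid {1, 1} state.
    """

    chrom_lengths: dict[str, int]
    centromeres: dict[str, int]
    karyotype: pd.DataFrame
    purity: float = 1.0
    n_wells: int = 384
    input_pg: float = 100.0
    pg_per_genome: float = 6.6
    fragment_mean: int = 100_000
    fragment_min: int = 5_000
    reads_per_100kb: float = 150.0   # ~0.45x per-fragment read coverage
    amp_log_sigma: float = 0.8   # log-normal spread of per-fragment depth
    read_span: int = 300
    snp_spacing: int = 5_000
    germline_depth: float = 200.0
    window_size: int = 1_000_000
    seed: int = 0

    @property
    def cell_equivalents(self) -> int:
        return max(1, int(round(self.input_pg / self.pg_per_genome)))


def toy_genome(n_chrom: int = 2, chrom_length: int = 100_000_000,
               centromere_frac: float = 0.4) -> tuple[dict[str, int], dict[str, int]]:
    """Equal-length toy chromosomes with a centromere at a fixed fraction."""
    lengths = {f"chr{i + 1}": chrom_length for i in range(n_chrom)}
    cens = {c: int(chrom_length * centromere_frac) for c in lengths}
    return lengths, cens


def fill_karyotype(chrom_lengths: dict[str, int],
                   events: pd.DataFrame | list[tuple] | None) -> pd.DataFrame:
    """Expand CNA events into a gap-free karyotype (background {1,1})."""
    if events is None:
        events = []
    if not isinstance(events, pd.DataFrame):
        events = pd.DataFrame(events, columns=KARYOTYPE_COLUMNS)
    rows = []
    for chrom, length in chrom_lengths.items():
        ev = events[events["chrom"] == chrom].sort_values("start")
        cursor = 0
        for _, e in ev.iterrows():
            if e["start"] > cursor:
                rows.append((chrom, cursor, int(e["start"]), 1, 1, 1.0))
            rows.append((chrom, int(e["start"]), int(e["end"]),
                         int(e["n_A"]), int(e["n_B"]), float(e["chi"])))
            cursor = int(e["end"])
        if cursor < length:
            rows.append((chrom, cursor, length, 1, 1, 1.0))
    return pd.DataFrame(rows, columns=KARYOTYPE_COLUMNS)


def truth_profile(karyotype: pd.DataFrame, purity: float) -> CopyNumberProfile:
    """Truth profile with ploidy = length-weighted mean total copy."""
    seg = karyotype.rename(columns={"chi": "clonality"}).copy()
    lengths = (seg["end"] - seg["start"]).to_numpy(dtype=float)
    # clonality-weighted expected total per segment for the ploidy bookkeeping
    tot = (seg["clonality"] * (seg["n_A"] + seg["n_B"])
           + (1 - seg["clonality"]) * 2).to_numpy(dtype=float)
    ploidy = float((lengths * tot).sum() / lengths.sum())
    return CopyNumberProfile(seg[["chrom", "start", "end", "n_A", "n_B",
                                  "clonality"]],
                             purity=purity, ploidy=ploidy, mse=None)


@dataclass
class WellSimResult:
    reads: pd.DataFrame
    tracks: GenomeTracks
    germline_reads: np.ndarray
    snps: pd.DataFrame            # chrom, pos, ref, alt, depth, af
    G: np.ndarray                 # SNP x well genotype matrix
    wells: list[str]
    alt_reads: np.ndarray         # SNP x well read counts supporting alt
    ref_reads: np.ndarray
    truth_haplotype: np.ndarray   # +1 if the SNP's alt allele is on haplotype A
    truth: CopyNumberProfile
    biallelic_fraction: float     # observed collision rate at SNPs
    config: SimConfig


def _fragment_starts_lengths(rng, start: int, end: int, mean: int, min_len: int):
    """Chop [start, end) into consecutive exponential-length fragments."""
    span = end - start
    n_est = max(int(span / mean * 2) + 8, 8)
    lengths = np.maximum(rng.exponential(mean, size=n_est), min_len)
    while lengths.sum() < span:
        lengths = np.concatenate([lengths, np.maximum(
            rng.exponential(mean, size=n_est), min_len)])
    ends = np.cumsum(lengths)
    keep = np.searchsorted(ends, span, side="left") + 1
    lengths = lengths[:keep]
    starts = np.concatenate([[0.0], np.cumsum(lengths)[:-1]]) + start
    f_start = starts.astype(np.int64)
    f_end = np.minimum((starts + lengths).astype(np.int64), end)
    ok = f_end > f_start
    return f_start[ok], f_end[ok]


def simulate_well_data(config: SimConfig) -> WellSimResult:
    """Generate per-well reads, SNP observations and germline depths.

    Each cell equivalent contributes, per haplotype and karyotype
    interval, as many chromosome copies as its (tumour or diploid
    normal) copy number; sub-clonal intervals are carried by a tumour
    cell with probability chi.  Every fragment lands in a uniformly
    random well, receives a log-normal amplification rate and a Poisson
    read count, and its reads report the fragment's haplotype at any
    SNP they cover.
    """
    rng = np.random.default_rng(config.seed)
    karyo = fill_karyotype(config.chrom_lengths, config.karyotype)
    n_cells = config.cell_equivalents
    n_tumour = int(round(config.purity * n_cells))
    wells = [f"W{k:04d}" for k in range(config.n_wells)]

    # --- SNP scaffold
    snp_rows = []
    for chrom, length in config.chrom_lengths.items():
        pos = np.arange(config.snp_spacing // 2, length, config.snp_spacing)
        pos = pos + rng.integers(-config.snp_spacing // 4,
                                 config.snp_spacing // 4, size=len(pos))
        for p in pos:
            snp_rows.append((chrom, int(p)))
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos"])
    snps = snps.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    snps["ref"] = "A"
    snps["alt"] = "G"
    snps["depth"] = 40
    snps["af"] = 0.5
    h_truth = np.where(rng.random(len(snps)) < 0.5, 1, -1).astype(np.int8)

    snp_pos_by_chrom = {c: grp["pos"].to_numpy()
                        for c, grp in snps.groupby("chrom", sort=False)}
    snp_offset = {}
    off = 0
    for c, grp in snps.groupby("chrom", sort=False):
        snp_offset[c] = off
        off += len(grp)

    read_well, read_chrom, read_start, read_end = [], [], [], []
    n_snps = len(snps)
    alt_reads = np.zeros((n_snps, config.n_wells), dtype=np.int32)
    ref_reads = np.zeros((n_snps, config.n_wells), dtype=np.int32)
    # fragment-level haplotype coverage per (snp, well): records every
    # fragment overlapping a SNP locus, read-sampled or not — the basis
    # of the mono-allelic collision rate
    hapA_frag = np.zeros((n_snps, config.n_wells), dtype=bool)
    hapB_frag = np.zeros((n_snps, config.n_wells), dtype=bool)

    for chrom in config.chrom_lengths:
        karyo_c = karyo[karyo["chrom"] == chrom]
        spos = snp_pos_by_chrom.get(chrom, np.array([], dtype=np.int64))
        soff = snp_offset.get(chrom, 0)
        for cell in range(n_cells):
            tumour = cell < n_tumour
            for hap in (0, 1):  # 0 = A, 1 = B
                for _, reg in karyo_c.iterrows():
                    if tumour:
                        carries = reg["chi"] >= 1.0 or rng.random() < reg["chi"]
                        copies = int(reg["n_A"] if hap == 0 else reg["n_B"]) \
                            if carries else 1
                    else:
                        copies = 1
                    for _ in range(copies):
                        f_start, f_end = _fragment_starts_lengths(
                            rng, int(reg["start"]), int(reg["end"]),
                            config.fragment_mean, config.fragment_min)
                        f_well = rng.integers(0, config.n_wells,
                                              size=len(f_start))
                        rate = rng.lognormal(
                            -0.5 * config.amp_log_sigma ** 2,
                            config.amp_log_sigma, size=len(f_start))
                        lam = (config.reads_per_100kb * rate
                               * (f_end - f_start) / 1e5)
                        n_reads = rng.poisson(lam)
                        frag_cov = hapA_frag if hap == 0 else hapB_frag
                        for fs, fe, wl, nr in zip(f_start, f_end, f_well,
                                                  n_reads):
                            fa = np.searchsorted(spos, fs, side="left")
                            fb = np.searchsorted(spos, fe, side="left")
                            if fb > fa:
                                frag_cov[soff + fa:soff + fb, wl] = True
                            if nr == 0:
                                continue
                            rs = rng.integers(fs, max(fe - config.read_span,
                                                      fs + 1), size=nr)
                            re_ = np.minimum(rs + config.read_span, fe)
                            read_well.append(np.full(nr, wl, dtype=np.int32))
                            read_chrom.append(chrom)
                            read_start.append(rs)
                            read_end.append(re_)
                            # reads are far shorter than the SNP spacing,
                            # so each read covers at most one SNP
                            a = np.searchsorted(spos, rs, side="left")
                            b = np.searchsorted(spos, re_, side="left")
                            covered = np.flatnonzero(b > a)
                            if len(covered) == 0:
                                continue
                            snp_idx = soff + a[covered]
                            for si in snp_idx:
                                # alt allele sits on haplotype A iff h=+1
                                if (h_truth[si] == 1) == (hap == 0):
                                    alt_reads[si, wl] += 1
                                else:
                                    ref_reads[si, wl] += 1

    # --- assemble read table
    if read_well:
        well_idx = np.concatenate(read_well)
        reads = pd.DataFrame({
            "well": np.array(wells)[well_idx],
            "chrom": np.repeat(read_chrom,
                               [len(a) for a in read_start]),
            "start": np.concatenate(read_start).astype(np.int64),
            "end": np.concatenate(read_end).astype(np.int64),
        }).sort_values(["well", "chrom", "start"], kind="mergesort"
                       ).reset_index(drop=True)
    else:
        reads = pd.DataFrame(columns=["well", "chrom", "start", "end"])

    # --- genotype matrix: mono-allelic wells only, collisions zeroed
    G = np.zeros((n_snps, config.n_wells), dtype=np.int8)
    only_alt = (alt_reads > 0) & (ref_reads == 0)
    only_ref = (ref_reads > 0) & (alt_reads == 0)
    G[only_alt] = 1
    G[only_ref] = -1
    any_frag = hapA_frag | hapB_frag
    both_frag = hapA_frag & hapB_frag
    biallelic_fraction = float(both_frag.sum() / max(any_frag.sum(), 1))

    # --- genome tracks and germline depths
    windows = make_windows(config.chrom_lengths, config.window_size)
    windows["gc"] = 0.40 + 0.15 * rng.random(len(windows))
    windows["mappability"] = 0.9 + 0.1 * rng.random(len(windows))
    tracks = GenomeTracks(windows=windows, centromeres=config.centromeres,
                          chrom_lengths=config.chrom_lengths)
    germline_reads = rng.poisson(config.germline_depth, size=len(windows)
                                 ).astype(float)

    return WellSimResult(
        reads=reads, tracks=tracks, germline_reads=germline_reads,
        snps=snps, G=G, wells=wells, alt_reads=alt_reads,
        ref_reads=ref_reads, truth_haplotype=h_truth,
        truth=truth_profile(karyo, config.purity),
        biallelic_fraction=biallelic_fraction, config=config)


def simulate_phasing_block(n_snps: int, n_wells: int = 384,
                           cover_frac: float = 0.3,
                           flip_rate: float = 0.0, dropout: float = 0.0,
                           seed: int | np.random.Generator = 0
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Mono-allelic genotype matrix for one haplotype block, with truth.

    Each well draws one haplotype (A or B) and covers a random
    contiguous stretch of at least two of the block's SNPs, as a single
    ~100 kb fragment spanning several SNPs would; blocks emitted by the
    phasing stage are always well-connected, and the generator mirrors
    that.  ``flip_rate`` randomly inverts entries (well-label errors);
    ``dropout`` zeroes entries (missed coverage).  Returns (G, h_truth)
    with G of shape (n_snps, n_wells).
    """
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    h = np.where(rng.random(n_snps) < 0.5, 1, -1).astype(np.int8)
    h[0] = 1  # sign convention of the recovered haplotype vector
    G = np.zeros((n_snps, n_wells), dtype=np.int8)
    span_lo = min(2, n_snps)
    span_hi = max(span_lo + 1, int(n_snps * cover_frac) + 1)
    for k in range(n_wells):
        s = 1 if rng.random() < 0.5 else -1  # which haplotype the well holds
        span = int(rng.integers(span_lo, span_hi))
        a = int(rng.integers(0, n_snps - span + 1))
        G[a:a + span, k] = h[a:a + span] * s
    if flip_rate > 0:
        flips = (rng.random(G.shape) < flip_rate) & (G != 0)
        G[flips] = -G[flips]
    if dropout > 0:
        G[rng.random(G.shape) < dropout] = 0
    return G, h


# ---------------------------------------------------------------------------
# track-level simulation


@dataclass
class TrackSimResult:
    rdr: RDRTrack
    baf_points: pd.DataFrame
    tracks: GenomeTracks
    truth: CopyNumberProfile
    truth_window_states: pd.DataFrame  # chrom, start, end, n_A, n_B, chi


# bulk-like window-level noise: ~2% depth CV at 1 Mb and BAF standard
# error of aggregating ~1,000 phased SNPs of bulk coverage
BULK_SIGMA_R_REL = 0.02
BULK_SIGMA_B = 0.01


def simulate_tracks(chrom_lengths: dict[str, int], centromeres: dict[str, int],
                    karyotype: pd.DataFrame | list[tuple] | None,
                    purity: float, seed: int,
                    sigma_r_rel: float = BULK_SIGMA_R_REL,
                    sigma_b: float = BULK_SIGMA_B,
                    window_size: int = 1_000_000,
                    baf_weight_mean: float = 40.0,
                    r_scale: float = 2.0) -> TrackSimResult:
    """Draw window-level RDR and BAF data directly from the model.

    Per window in truth state {n_A, n_B, chi}, the corrected RDR is the
    model expectation (at genome scale ``r_scale``) plus Gaussian noise
    of standard deviation ``sigma_r_rel * r_scale``; one BAF point per
    window is drawn around the expected (unmirrored, randomly-signed)
    allele frequency with standard deviation ``sigma_b``.
    """
    rng = np.random.default_rng(seed)
    karyo = fill_karyotype(chrom_lengths, karyotype)
    truth = truth_profile(karyo, purity)
    psi = truth.ploidy
    windows = make_windows(chrom_lengths, window_size)
    windows["gc"] = 0.40 + 0.15 * rng.random(len(windows))
    windows["mappability"] = 0.9 + 0.1 * rng.random(len(windows))
    tracks = GenomeTracks(windows=windows, centromeres=centromeres,
                          chrom_lengths=chrom_lengths)

    mids = ((windows["start"] + windows["end"]) // 2).to_numpy()
    state_rows = []
    r_vals = np.empty(len(windows))
    b_rows = []
    for i, (chrom, mid, wstart, wend) in enumerate(zip(
            windows["chrom"], mids, windows["start"], windows["end"])):
        seg = karyo[(karyo["chrom"] == chrom) & (karyo["start"] <= mid)
                    & (karyo["end"] > mid)]
        na, nb, chi = (int(seg["n_A"].iloc[0]), int(seg["n_B"].iloc[0]),
                       float(seg["chi"].iloc[0]))
        state = CopyNumberState(na, nb, chi)
        modal = (1, 1)
        r_hat = cn_fit.expected_rdr(state, purity, psi, r_scale, modal)
        b_hat = cn_fit.expected_baf(state, purity, modal)
        r_vals[i] = rng.normal(r_hat, sigma_r_rel * r_scale)
        if np.isfinite(b_hat):
            b_raw = b_hat if rng.random() < 0.5 else 1.0 - b_hat
            b = float(np.clip(rng.normal(b_raw, sigma_b), 0.0, 1.0))
            weight = max(1, int(rng.poisson(baf_weight_mean)))
            b_rows.append((chrom, int(mid), b, weight, i))
        state_rows.append((chrom, int(wstart), int(wend), na, nb, chi))

    r_vals = np.maximum(r_vals, 0.0)
    rdr = RDRTrack(windows=windows, raw=r_vals, corrected=r_vals,
                   mask=np.ones(len(windows), dtype=bool),
                   r_bar=float(r_vals.mean()))
    baf = pd.DataFrame(b_rows, columns=["chrom", "pos", "b", "weight", "block"])
    states = pd.DataFrame(state_rows,
                          columns=["chrom", "start", "end", "n_A", "n_B", "chi"])
    return TrackSimResult(rdr=rdr, baf_points=baf, tracks=tracks, truth=truth,
                          truth_window_states=states)


def estimate_track_noise(rdr: RDRTrack, baf_points: pd.DataFrame,
                         truth: CopyNumberProfile) -> tuple[float, float]:
    """Within-truth-segment noise of a pipeline's RDR/BAF tracks.

    Returns (sigma_r_rel, sigma_b): the RDR standard deviation relative
    to the genome mean, and the mirrored-BAF standard deviation, both
    pooled over truth segments.  Used to calibrate
    :func:`simulate_tracks` against well-level simulator output.
    """
    mids = ((rdr.windows["start"] + rdr.windows["end"]) // 2).to_numpy()
    chroms = rdr.windows["chrom"].to_numpy()
    ss_r = n_r = ss_b = n_b = 0.0
    for _, seg in truth.segments.iterrows():
        sel = ((chroms == seg["chrom"]) & (mids >= seg["start"])
               & (mids < seg["end"]) & rdr.mask)
        v = rdr.corrected[sel]
        if len(v) >= 2:
            ss_r += float(((v - v.mean()) ** 2).sum())
            n_r += len(v)
        if len(baf_points):
            bsel = ((baf_points["chrom"] == seg["chrom"])
                    & (baf_points["pos"] >= seg["start"])
                    & (baf_points["pos"] < seg["end"]))
            bv = mirror_baf(baf_points["b"].to_numpy()[bsel.to_numpy()])
            if len(bv) >= 2:
                ss_b += float(((bv - bv.mean()) ** 2).sum())
                n_b += len(bv)
    sigma_r = np.sqrt(ss_r / n_r) if n_r else 0.0
    sigma_b_est = np.sqrt(ss_b / n_b) if n_b else 0.0
    return float(sigma_r / rdr.r_bar), float(sigma_b_est)


# ---------------------------------------------------------------------------
# sub-clonal spike-in


@dataclass
class StateStats:
    """Per-copy-number-state track statistics from a fully-clonal fit."""

    stats: dict[tuple[int, int], tuple[float, float, float, float]]
    # state -> (mean_r, var_r, mean_b, var_b)

    def states(self) -> list[tuple[int, int]]:
        return list(self.stats)


def state_stats_from_fit(segments: list[SegmentData],
                         states: list[CopyNumberState]) -> StateStats:
    """Pool segment data per fitted clonal state into means/variances."""
    pools: dict[tuple[int, int], list] = {}
    for seg, st in zip(segments, states):
        pools.setdefault((st.n_A, st.n_B), []).append(seg)
    out = {}
    for key, segs in pools.items():
        r = np.concatenate([s.r for s in segs if len(s.r)]) \
            if any(len(s.r) for s in segs) else np.array([])
        b = np.concatenate([s.b for s in segs if s.has_baf]) \
            if any(s.has_baf for s in segs) else np.array([])
        out[key] = (float(r.mean()) if len(r) else np.nan,
                    float(r.var()) if len(r) > 1 else 0.0,
                    float(b.mean()) if len(b) else np.nan,
                    float(b.var()) if len(b) > 1 else 0.0)
    return StateStats(out)


def spike_in_subclonal(segments: list[SegmentData], stats: StateStats,
                       state: tuple[int, int], chi: float,
                       modal: tuple[int, int], seed,
                       min_points: int = 5,
                       mixture: bool = False
                       ) -> tuple[list[SegmentData], int, dict]:
    """Overwrite a random segment with a simulated sub-clonal CNA.

    RDR draws follow r = chi * N(mean_CNA, var_CNA) + (1 - chi) *
    N(mean_modal, var_modal) with independent normals (the sum of the
    two scaled variables; set ``mixture=True`` to instead draw each
    point from one component with probability chi).  BAF is spiked with
    the same construction from the per-state BAF statistics.

    Returns (new segment list, spiked index, truth record).
    """
    rng = np.random.default_rng(seed) if isinstance(seed, int) else seed
    eligible = [i for i, s in enumerate(segments) if len(s.r) >= min_points]
    if not eligible:
        raise WellDataError("no segment long enough to spike")
    idx = int(rng.choice(eligible))
    seg = segments[idx]
    mr1, vr1, mb1, vb1 = stats.stats[state]
    mr0, vr0, mb0, vb0 = stats.stats[modal]

    def draw(n, m1, v1, m0, v0):
        if mixture:
            pick = rng.random(n) < chi
            return np.where(pick, rng.normal(m1, np.sqrt(v1), n),
                            rng.normal(m0, np.sqrt(v0), n))
        return (chi * rng.normal(m1, np.sqrt(v1), n)
                + (1 - chi) * rng.normal(m0, np.sqrt(v0), n))

    new_seg = replace(seg, r=draw(len(seg.r), mr1, vr1, mr0, vr0))
    if seg.has_baf and np.isfinite(mb1) and np.isfinite(mb0):
        new_seg = replace(new_seg,
                          b=np.clip(draw(len(seg.b), mb1, vb1, mb0, vb0),
                                    0.0, 0.5))
    out = list(segments)
    out[idx] = new_seg
    record = {"segment": idx, "state": state, "chi": chi}
    return out, idx, record


def subclonal_sensitivity(segments: list[SegmentData], phi: float, psi: float,
                          r_bar: float, sigma2: tuple[float, float],
                          modal: tuple[int, int], stats: StateStats,
                          chi_values=(0.5, 0.6, 0.7, 0.8, 0.9),
                          n_sims: int = 200, seed: int = 0,
                          spike_states: list[tuple[int, int]] | None = None
                          ) -> pd.DataFrame:
    """Detection rate of spiked-in sub-clonal CNAs, per clonality.

    A simulation succeeds when the spiked segment is re-fitted to
    exactly the spiked {n_A, n_B} with clonality < 1.  Returns per chi
    the success fraction with a 95% Wilson interval.
    """
    rng = np.random.default_rng(seed)
    if spike_states is None:
        spike_states = [s for s in stats.states() if s != modal]
    if not spike_states:
        raise WellDataError("no non-modal states available to spike")
    n_max = cn_fit.max_total_copy(segments, phi, psi, r_bar)
    rows = []
    for chi in chi_values:
        hits = 0
        for _ in range(n_sims):
            state = spike_states[int(rng.integers(len(spike_states)))]
            spiked, idx, _ = spike_in_subclonal(segments, stats, state, chi,
                                                modal, rng)
            fitted = cn_fit.fit_states([spiked[idx]], phi, psi, r_bar, sigma2,
                                       allow_subclonal=True, modal=modal,
                                       n_max=n_max)[0]
            if (fitted.n_A, fitted.n_B) == state and fitted.chi < 1.0:
                hits += 1
        if n_sims > 0:
            p = hits / n_sims
            lo, hi = _wilson_interval(hits, n_sims)
        else:
            p = lo = hi = np.nan
        rows.append((chi, p, lo, hi, n_sims))
    return pd.DataFrame(rows, columns=["chi", "sensitivity", "ci_low",
                                       "ci_high", "n_sims"])


def _wilson_interval(k: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)
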