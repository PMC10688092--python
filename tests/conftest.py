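import numpy as np
import pandas as pd
import pytest

from picocnv import simulation as sim


@pytest.fixture(scope="session")
def small_well_sim():
    """One small well-level simulation shared across tests.

    Two 50 Mb chromosomes, an LOH arm on chr1q and a gain on chr2p,
    pure tumour, default platform parameters, fixed seed.
    """
    lengths, cens = sim.toy_genome(n_chrom=2, chrom_length=50_000_000,
                                   centromere_frac=0.4)
    events = [("chr1", 25_000_000, 50_000_000, 1, 0, 1.0),
              ("chr2", 0, 20_000_000, 2, 1, 1.0)]
    cfg = sim.SimConfig(
        chrom_lengths=lengths, centromeres=cens,
        karyotype=pd.DataFrame(events, columns=sim.KARYOTYPE_COLUMNS),
        purity=1.0, seed=42)
    return sim.simulate_well_data(cfg)


@pytest.fixture(scope="session")
def clonal_track_sim():
    """Track-level genome (20 x 150 Mb) with six clonal CNAs, purity 0.7."""
    lengths, cens = sim.toy_genome(n_chrom=20, chrom_length=150_000_000)
    cnas = [("chr1", 10e6, 40e6, 2, 0), ("chr2", 60e6, 100e6, 3, 1),
            ("chr3", 0, 30e6, 1, 0), ("chr7", 20e6, 50e6, 4, 1),
            ("chr12", 0, 20e6, 3, 0), ("chr15", 90e6, 150e6, 2, 1)]
    events = [(c, int(s), int(e), na, nb, 1.0) for c, s, e, na, nb in cnas]
    return sim.simulate_tracks(lengths, cens, events, purity=0.7, seed=11)


def brute_force_rlf_merge(reads: pd.DataFrame, max_gap: int) -> pd.DataFrame:
    """Independent sort-and-scan interval-merge oracle for fragment
    reconstruction: per (well, chrom), chain reads whose gap to the
    running fragment end is < max_gap."""
    rows = []
    for (well, chrom), grp in reads.groupby(["well", "chrom"], sort=True):
        ivs = sorted(zip(grp["start"], grp["end"]))
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s - cur_e < max_gap:
                cur_e = max(cur_e, e)
            else:
                rows.append((well, chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        rows.append((well, chrom, cur_s, cur_e))
    out = pd.DataFrame(rows, columns=["well", "chrom", "start", "end"])
    return out.sort_values(["well", "chrom", "start"]).reset_index(drop=True)


def dp_optimal_loss(x, w, positions, lam, min_span) -> float:
    """Exhaustive dynamic-programming minimum of the segmentation loss,
    independent of the greedy search path."""
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    w = w / w.mean()
    positions = np.asarray(positions, float)
    n = len(x)

    def sse(i, j):
        xs, ws = x[i:j], w[i:j]
        m = (ws * xs).sum() / ws.sum()
        return float((ws * (xs - m) ** 2).sum())

    single = sse(0, n) + lam
    INF = float("inf")
    best = [0.0] + [INF] * n
    for j in range(1, n + 1):
        for i in range(j):
            if positions[j - 1] - positions[i] < min_span:
                continue
            if best[i] < INF:
                c = best[i] + sse(i, j) + lam
                if c < best[j]:
                    best[j] = c
    return min(single, best[n])
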