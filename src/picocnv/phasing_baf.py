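"""Haplotype phasing of heterozygous SNPs and de-noised BAF computation.

Because each well holds at most one input fragment per locus, all reads
in a well at a heterozygous SNP derive from a single parental allele.
Nearby SNPs covered by overlapping well sets are therefore phasable: the
SNP-SNP similarity matrix

    M_ij = sum_k G_ik G_jk / sum_l |G_il| |G_jl|

equals the haplotype outer product h_i h_j when the mono-allelic
property holds exactly, and the sign pattern of its first singular
vector recovers h.  The B-allele frequency is then computed per
haplotype group from counts of *wells* (not reads), which removes
per-fragment amplification noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csgraph, csr_matrix

DEFAULT_MAX_GAP = 500_000
DEFAULT_MAX_SNPS = 100


@dataclass
class HaplotypeBlock:
    """A contiguous run of jointly phasable heterozygous SNPs.

    ``snp_indices`` index rows of the genome-wide SNP table / G matrix;
    they are contiguous in position order but not necessarily as
    integers after connectivity splitting.
    """

    block_id: int
    chrom: str
    snp_indices: np.ndarray
    positions: np.ndarray
    G: np.ndarray  # SNPs-in-block x wells

    def __len__(self) -> int:
        return len(self.snp_indices)


def _chunk_sizes(n: int, max_size: int) -> list[int]:
    """Split n items into the fewest contiguous chunks of <= max_size,
    as equal as possible (larger chunks first)."""
    k = -(-n // max_size)
    base, extra = divmod(n, k)
    return [base + 1] * extra + [base] * (k - extra)


def _connected_components(G: np.ndarray) -> np.ndarray:
    """Component labels of the graph joining SNPs that share >= 1 covering well."""
    cov = csr_matrix((G != 0).astype(np.int8))
    adj = cov @ cov.T  # (i, j) nonzero iff some well covers both SNPs
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    return labels


def build_blocks(snps: pd.DataFrame, G: np.ndarray,
                 max_gap: int = DEFAULT_MAX_GAP,
                 max_snps: int = DEFAULT_MAX_SNPS) -> list[HaplotypeBlock]:
    """Partition SNPs into phasable haplotype blocks.

    Steps, per chromosome, on position-sorted SNPs:

    1. contiguous runs in which consecutive-SNP gaps are <= ``max_gap``;
    2. runs longer than ``max_snps`` are subdivided into contiguous,
       near-equal chunks of at most ``max_snps`` SNPs;
    3. each chunk is split into connected components of the graph whose
       edges join SNPs sharing at least one covering well — SNPs with
       no shared wells carry no mutual phasing information;
    4. singleton blocks (one SNP) are removed.
    """
    blocks: list[HaplotypeBlock] = []
    block_id = 0
    order = np.lexsort((snps["pos"].to_numpy(), snps["chrom"].to_numpy()))
    for chrom in pd.unique(snps["chrom"].to_numpy()[order]):
        idx = order[snps["chrom"].to_numpy()[order] == chrom]
        pos = snps["pos"].to_numpy()[idx]
        gaps = np.diff(pos)
        run_starts = np.concatenate([[0], np.flatnonzero(gaps > max_gap) + 1,
                                     [len(idx)]])
        for a, b in zip(run_starts[:-1], run_starts[1:]):
            if b - a == 0:
                continue
            offset = a
            for size in _chunk_sizes(b - a, max_snps):
                chunk = idx[offset:offset + size]
                offset += size
                sub_G = G[chunk]
                labels = _connected_components(sub_G)
                for comp in np.unique(labels):
                    members = chunk[labels == comp]
                    if len(members) < 2:
                        continue  # singleton: no phasing partner
                    blocks.append(HaplotypeBlock(
                        block_id=block_id, chrom=chrom,
                        snp_indices=members,
                        positions=snps["pos"].to_numpy()[members],
                        G=G[members]))
                    block_id += 1
    return blocks


def similarity_matrix(G: np.ndarray) -> np.ndarray:
    """SNP-SNP similarity M_ij = sum_k G_ik G_jk / sum_l |G_il||G_jl|.

    M is symmetric with entries in [-1, +1]; +1 means two SNPs always
    show the same status in co-covering wells, -1 always the opposite.
    Pairs with no co-covering well have an undefined ratio and are set
    to 0 (no phasing signal).  The diagonal is 1 wherever the SNP has
    any coverage.
    """
    Gf = G.astype(float)
    num = Gf @ Gf.T
    A = np.abs(Gf)
    den = A @ A.T
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return M


def assign_haplotypes(M: np.ndarray) -> np.ndarray:
    """Haplotype vector h = sgn(first singular vector of M), h[0] = +1.

    The first singular vector is the one belonging to the largest
    singular value; zero entries of the vector map to +1 so h is always
    in {-1, +1}^n.
    """
    U, s, _ = np.linalg.svd(M, hermitian=True)
    h_star = U[:, int(np.argmax(s))]
    h = np.where(h_star >= 0, 1, -1).astype(np.int8)
    if h[0] < 0:
        h = -h
    return h


@dataclass
class BAFPoint:
    chrom: str
    pos: int
    b: float
    weight: int
    block_id: int


BAF_COLUMNS = ["chrom", "pos", "b", "weight", "block"]


def compute_baf(block: HaplotypeBlock, h: np.ndarray) -> list[BAFPoint]:
    """Well-count BAF per haplotype group of a block.

    SNPs whose alternative allele sits on the same haplotype (same sign
    of h) are pooled:  b = (wells supporting alt, summed over the
    group's SNPs) / (wells covering, summed).  Each non-empty group
    emits one point located at the median genomic coordinate of its
    SNPs, weighted by the group size.
    """
    points = []
    alt_wells = (block.G == 1).sum(axis=1)
    cov_wells = (block.G != 0).sum(axis=1)
    for sign in (1, -1):
        sel = h == sign
        if not sel.any():
            continue
        cov = int(cov_wells[sel].sum())
        if cov == 0:
            continue
        b = float(alt_wells[sel].sum()) / cov
        pos = int(np.median(block.positions[sel]))
        points.append(BAFPoint(chrom=block.chrom, pos=pos, b=b,
                               weight=int(sel.sum()), block_id=block.block_id))
    return points


def compute_baf_read_counts(block: HaplotypeBlock, h: np.ndarray,
                            alt_reads: np.ndarray, ref_reads: np.ndarray
                            ) -> list[BAFPoint]:
    """Read-count BAF per haplotype group (the noisy alternative).

    ``alt_reads``/``ref_reads`` are genome-wide SNP x well read-count
    matrices; counting reads instead of wells re-introduces per-fragment
    amplification noise and serves as the benchmark baseline.
    """
    points = []
    alt = alt_reads[block.snp_indices].sum(axis=1)
    tot = alt + ref_reads[block.snp_indices].sum(axis=1)
    for sign in (1, -1):
        sel = h == sign
        if not sel.any() or tot[sel].sum() == 0:
            continue
        b = float(alt[sel].sum()) / float(tot[sel].sum())
        pos = int(np.median(block.positions[sel]))
        points.append(BAFPoint(chrom=block.chrom, pos=pos, b=b,
                               weight=int(sel.sum()), block_id=block.block_id))
    return points


def phase_and_baf(snps: pd.DataFrame, G: np.ndarray,
                  max_gap: int = DEFAULT_MAX_GAP,
                  max_snps: int = DEFAULT_MAX_SNPS) -> tuple[pd.DataFrame, list[HaplotypeBlock], list[np.ndarray]]:
    """Full phasing pipeline: blocks -> haplotypes -> BAF point table.

    Returns (baf_points, blocks, haplotypes) where baf_points has
    columns ``chrom, pos, b, weight, block`` sorted by (chrom, pos).
    """
    blocks = build_blocks(snps, G, max_gap=max_gap, max_snps=max_snps)
    haplotypes = []
    rows = []
    for block in blocks:
        h = assign_haplotypes(similarity_matrix(block.G))
        haplotypes.append(h)
        for pt in compute_baf(block, h):
            rows.append((pt.chrom, pt.pos, pt.b, pt.weight, pt.block_id))
    baf = pd.DataFrame(rows, columns=BAF_COLUMNS)
    if len(baf):
        baf = baf.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return baf, blocks, haplotypes
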