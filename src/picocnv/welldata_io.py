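"""Input/output for well-resolved sequencing data and copy-number profiles.

All genomic coordinates are 0-based half-open internally.  VCF input is
1-based (converted on read); BED-dialect output is 0-based half-open.

The central containers are plain pandas DataFrames with documented column
sets, mirroring how depth/variant tables are passed around in genomics
pipelines:

* well-read table: columns ``well, chrom, start, end`` — one row per read
  pair (mates merged to their union span), sorted by (well, chrom, start).
* heterozygous-SNP table: columns ``chrom, pos, ref, alt, depth, af``.
* well-genotype matrix G: int8 array of shape (n_snps, n_wells) with
  entries +1 (well shows only the alternative allele at the SNP),
  -1 (only the reference allele), 0 (no coverage, or conflicting
  alleles — see :func:`build_well_genotypes`).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WELL_READ_COLUMNS = ["well", "chrom", "start", "end"]

# read pairs farther apart than this cannot come from one ~100 kb input
# fragment, so a discordant pair is split rather than merged
MAX_PAIR_SPAN = 100_000

MIN_SNP_DEPTH = 20
MIN_SNP_AF = 0.25
MAX_SNP_AF = 0.75


class WellDataError(ValueError):
    """Malformed or contract-violating input data."""


# ---------------------------------------------------------------------------
# genome tracks


@dataclass
class GenomeTracks:
    """1 Mb window grid with GC/mappability covariates and arm boundaries.

    Parameters
    ----------
    windows
        DataFrame with columns ``chrom, start, end, gc, mappability``.
        Windows must tile each chromosome without overlap, in order.
    centromeres
        Mapping chromosome -> centromere position (bp); splits each
        chromosome into p and q arms.
    chrom_lengths
        Mapping chromosome -> length (bp).
    """

    windows: pd.DataFrame
    centromeres: dict[str, int]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        w = self.windows
        required = {"chrom", "start", "end", "gc", "mappability"}
        missing = required - set(w.columns)
        if missing:
            raise WellDataError(f"windows missing columns: {sorted(missing)}")
        for chrom, grp in w.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            if not np.all(starts[1:] == ends[:-1]):
                raise WellDataError(f"windows on {chrom} do not tile contiguously")
        if ((w["gc"] < 0) | (w["gc"] > 1)).any():
            raise WellDataError("gc fractions must lie in [0, 1]")
        if ((w["mappability"] < 0) | (w["mappability"] > 1)).any():
            raise WellDataError("mappability fractions must lie in [0, 1]")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def arm_of(self, chrom: str, pos) -> np.ndarray:
        """Arm label ('p' or 'q') for position(s) on a chromosome."""
        cen = self.centromeres.get(chrom, 0)
        return np.where(np.asarray(pos) < cen, "p", "q")

    def window_arms(self) -> pd.Series:
        """Per-window arm id of the form 'chr1:p'."""
        mids = (self.windows["start"] + self.windows["end"]) // 2
        cens = self.windows["chrom"].map(lambda c: self.centromeres.get(c, 0))
        side = np.where(mids.to_numpy() < cens.to_numpy(), "p", "q")
        return self.windows["chrom"].str.cat(pd.Series(side, index=self.windows.index), sep=":")


def make_windows(chrom_lengths: dict[str, int], size: int = 1_000_000) -> pd.DataFrame:
    """Tile chromosomes with non-overlapping fixed-size windows.

    The last window on a chromosome is truncated at the chromosome end.
    GC and mappability default to 0.5/1.0 and can be overwritten from
    tracks with :func:`read_track_tsv`.
    """
    rows = []
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, length, size)
        ends = np.minimum(starts + size, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    out = pd.concat(rows, ignore_index=True)
    out["gc"] = 0.5
    out["mappability"] = 1.0
    return out


def read_track_tsv(path: str | os.PathLike, value_column: str) -> pd.DataFrame:
    """Read a (chrom, start, end, value) TSV track, e.g. GC or mappability."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["chrom", "start", "end", value_column])
    return df


# ---------------------------------------------------------------------------
# well reads


def read_well_alignments(path: str | os.PathLike, dialect: str = "tsv") -> pd.DataFrame:
    """Read per-well aligned tumour read pairs into a well-read table.

    Parameters
    ----------
    path
        SAM/BAM file (``dialect="bam-rg"``, well id in the read group) or
        whitespace-separated text with columns well/chrom/start/end
        (``dialect="tsv"``).
    dialect
        ``"bam-rg"`` or ``"tsv"``.

    Returns
    -------
    DataFrame with columns ``well, chrom, start, end``, one row per read
    pair (mates merged to the union span of both mates), sorted by
    (well, chrom, start).  Pairs whose union span exceeds 100 kb are
    split into two single-mate entries: they cannot derive from a single
    input fragment.
    """
    if dialect == "tsv":
        df = pd.read_csv(path, sep=r"\s+", comment="#",
                         names=WELL_READ_COLUMNS,
                         dtype={"well": str, "chrom": str})
        if len(df) == 0:
            return _empty_well_reads()
    elif dialect == "bam-rg":
        df = _read_bam_rg(path)
    else:
        raise WellDataError(f"unknown dialect {dialect!r}")
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise WellDataError(f"degenerate interval {bad.chrom}:{bad.start}-{bad.end}")
    return sort_well_reads(df)


def _empty_well_reads() -> pd.DataFrame:
    return pd.DataFrame({"well": pd.Series(dtype=str),
                         "chrom": pd.Series(dtype=str),
                         "start": pd.Series(dtype=np.int64),
                         "end": pd.Series(dtype=np.int64)})


def _read_bam_rg(path) -> pd.DataFrame:
    import pysam

    mode = "rb" if str(path).endswith(".bam") else "r"
    wells, chroms, starts, ends = [], [], [], []
    # pair up mates by query name within a chromosome
    pending: dict[tuple[str, str], tuple[str, int, int]] = {}
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            try:
                well = rec.get_tag("RG")
            except KeyError:
                raise WellDataError(
                    f"read {rec.query_name!r} carries no RG well tag") from None
            key = (rec.query_name, rec.reference_name)
            if key in pending:
                pwell, pstart, pend = pending.pop(key)
                if pwell != well:
                    raise WellDataError(
                        f"mates of {rec.query_name!r} disagree on well")
                start = min(pstart, rec.reference_start)
                end = max(pend, rec.reference_end)
                if end - start > MAX_PAIR_SPAN:
                    # discordant pair: record the mates separately
                    wells += [well, well]
                    chroms += [rec.reference_name, rec.reference_name]
                    starts += [pstart, rec.reference_start]
                    ends += [pend, rec.reference_end]
                else:
                    wells.append(well)
                    chroms.append(rec.reference_name)
                    starts.append(start)
                    ends.append(end)
            else:
                pending[key] = (well, rec.reference_start, rec.reference_end)
    # unpaired leftovers become single-end entries
    for (name, chrom), (well, start, end) in pending.items():
        wells.append(well)
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
    if not wells:
        return _empty_well_reads()
    return pd.DataFrame({"well": wells, "chrom": chroms,
                         "start": np.asarray(starts, dtype=np.int64),
                         "end": np.asarray(ends, dtype=np.int64)})


def sort_well_reads(df: pd.DataFrame) -> pd.DataFrame:
    return (df.sort_values(["well", "chrom", "start", "end"], kind="mergesort")
              .reset_index(drop=True))


def write_well_reads(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False, header=False,
              columns=WELL_READ_COLUMNS)


# ---------------------------------------------------------------------------
# heterozygous SNPs


def filter_het_snps(df: pd.DataFrame,
                    min_depth: int = MIN_SNP_DEPTH,
                    min_af: float = MIN_SNP_AF,
                    max_af: float = MAX_SNP_AF) -> pd.DataFrame:
    """Apply the heterozygous-SNP retention filter.

    Keeps sites with germline depth >= 20 and alternative-allele
    fraction between 25% and 75% inclusive.  Idempotent and
    order-independent; output sorted by (chrom, pos).
    """
    keep = (df["depth"] >= min_depth) & (df["af"] >= min_af) & (df["af"] <= max_af)
    out = df[keep].sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return out


def read_het_snps(vcf_path: str | os.PathLike,
                  sample: str | None = None) -> pd.DataFrame:
    """Read candidate heterozygous SNPs from a VCF and apply the filter.

    Uses the FORMAT/AD allele depths of ``sample`` (first sample by
    default) to compute germline depth and allele fraction.  Multi-allelic
    records and non-SNV alleles are dropped.  Positions are converted to
    0-based.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    if not vcf.samples:
        raise WellDataError("VCF carries no samples (allele depths required)")
    sidx = 0 if sample is None else vcf.samples.index(sample)
    rows = []
    saw_ad = False
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
            continue
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        if ad is None:
            continue
        saw_ad = True
        ref_d, alt_d = int(ad[sidx][0]), int(ad[sidx][1])
        depth = ref_d + alt_d
        af = alt_d / depth if depth > 0 else 0.0
        rows.append((var.CHROM, var.POS - 1, ref, alt, depth, af))
    if rows:
        df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "depth", "af"])
    else:
        if not saw_ad:
            raise WellDataError(
                "VCF has no usable FORMAT/AD allele depths; cannot apply the "
                "heterozygous-SNP depth/allele-fraction filter")
        df = pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "depth", "af"])
    return filter_het_snps(df)


# ---------------------------------------------------------------------------
# well genotype matrix


def build_well_genotypes(snps: pd.DataFrame,
                         observations: pd.DataFrame,
                         wells: list[str] | None = None
                         ) -> tuple[np.ndarray, list[str]]:
    """Build the SNP x well genotype matrix G from per-well allele calls.

    Parameters
    ----------
    snps
        Filtered heterozygous-SNP table (defines the row order).
    observations
        DataFrame with columns ``well, chrom, pos, alt_reads, ref_reads``
        giving per-well read support at SNP positions.
    wells
        Optional explicit well order; defaults to sorted unique wells in
        the observations.

    Returns
    -------
    (G, wells) where G[i, k] is +1 if well k's reads at SNP i support
    only the alternative allele, -1 if only the reference allele, and 0
    if the well has no coverage there.  Wells observing *both* alleles
    at a SNP are set to 0 for that SNP: under the mono-allelic model a
    well holds at most one input fragment per locus, so a bi-allelic
    observation signals a fragment collision and carries no reliable
    haplotype information.
    """
    if wells is None:
        wells = sorted(observations["well"].unique())
    well_index = {w: k for k, w in enumerate(wells)}
    snp_index = {(c, p): i for i, (c, p) in
                 enumerate(zip(snps["chrom"], snps["pos"]))}
    G = np.zeros((len(snps), len(wells)), dtype=np.int8)
    obs_keys = list(zip(observations["chrom"], observations["pos"]))
    for (key, well, alt_r, ref_r) in zip(obs_keys, observations["well"],
                                         observations["alt_reads"],
                                         observations["ref_reads"]):
        i = snp_index.get(key)
        if i is None:
            continue
        k = well_index[well]
        if alt_r > 0 and ref_r > 0:
            G[i, k] = 0
        elif alt_r > 0:
            G[i, k] = 1
        elif ref_r > 0:
            G[i, k] = -1
    return G, wells


def write_genotype_matrix(G: np.ndarray, wells: list[str],
                          path: str | os.PathLike) -> None:
    """Write G as a sparse triplet TSV (snp_index, well_index, value)
    with the well order recorded in the header."""
    with open(path, "w") as fh:
        fh.write("#wells=" + ",".join(wells) + "\n")
        fh.write(f"#n_snps={G.shape[0]}\n")
        rows, cols = np.nonzero(G)
        for i, k in zip(rows, cols):
            fh.write(f"{i}\t{k}\t{int(G[i, k])}\n")


def read_genotype_matrix(path: str | os.PathLike) -> tuple[np.ndarray, list[str]]:
    wells: list[str] = []
    n_snps = 0
    triplets = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#wells="):
                wells = line.strip()[len("#wells="):].split(",")
            elif line.startswith("#n_snps="):
                n_snps = int(line.strip().split("=")[1])
            elif line.strip():
                i, k, v = line.split()
                triplets.append((int(i), int(k), int(v)))
    G = np.zeros((n_snps, len(wells)), dtype=np.int8)
    for i, k, v in triplets:
        G[i, k] = v
    return G, wells


# ---------------------------------------------------------------------------
# copy number profiles


@dataclass
class CopyNumberProfile:
    """Per-segment allele-specific copy-number calls.

    ``segments`` has columns ``chrom, start, end, n_A, n_B, clonality``
    with the canonical order n_A >= n_B; clonality is 1 for clonal
    segments.  ``purity``/``ploidy``/``mse`` summarise the fitted model.
    """

    segments: pd.DataFrame
    purity: float | None = None
    ploidy: float | None = None
    mse: float | None = None

    def __post_init__(self) -> None:
        seg = self.segments.reset_index(drop=True)
        if len(seg) and (seg["n_B"] > seg["n_A"]).any():
            raise WellDataError("profile violates canonical order n_A >= n_B")
        for chrom, grp in seg.groupby("chrom", sort=False):
            s = grp.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                raise WellDataError(f"overlapping segments on {chrom}")
        self.segments = seg

    @property
    def total_length(self) -> int:
        return int((self.segments["end"] - self.segments["start"]).sum())

    def length_weighted_ploidy(self) -> float:
        seg = self.segments
        lengths = (seg["end"] - seg["start"]).to_numpy(dtype=float)
        total = (seg["n_A"] + seg["n_B"]).to_numpy(dtype=float)
        return float((lengths * total).sum() / lengths.sum())


PROFILE_COLUMNS = ["chrom", "start", "end", "n_A", "n_B", "clonality"]


def write_profile(profile: CopyNumberProfile, path: str | os.PathLike) -> None:
    """Write a profile as BED-dialect TSV plus a JSON sidecar summary."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PROFILE_COLUMNS) + "\n")
        profile.segments.to_csv(fh, sep="\t", index=False, header=False,
                                columns=PROFILE_COLUMNS)
    summary = {"purity": profile.purity, "ploidy": profile.ploidy,
               "mse": profile.mse}
    with open(str(path) + ".summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
        fh.write("\n")


def read_profile(path: str | os.PathLike) -> CopyNumberProfile:
    seg = pd.read_csv(path, sep="\t", comment="#", names=PROFILE_COLUMNS,
                      dtype={"chrom": str})
    summary_path = str(path) + ".summary.json"
    purity = ploidy = mse = None
    if os.path.exists(summary_path):
        with open(summary_path) as fh:
            summary = json.load(fh)
        purity, ploidy, mse = summary.get("purity"), summary.get("ploidy"), summary.get("mse")
    return CopyNumberProfile(seg, purity=purity, ploidy=ploidy, mse=mse)
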