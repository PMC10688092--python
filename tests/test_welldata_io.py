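import numpy as np
import pandas as pd
import pytest

from picocnv import welldata_io as wio


# ---------------------------------------------------------------------------
# well reads


def test_tsv_reader_parses_rows(tmp_path):
    p = tmp_path / "reads.tsv"
    p.write_text("P1W001 chr1 1000 1150\nP1W001 chr1 500 650\n")
    df = wio.read_well_alignments(p, dialect="tsv")
    assert df.iloc[0].tolist() == ["P1W001", "chr1", 500, 650]
    assert df.iloc[1].tolist() == ["P1W001", "chr1", 1000, 1150]


def test_tsv_reader_empty_file(tmp_path):
    p = tmp_path / "empty.tsv"
    p.write_text("")
    df = wio.read_well_alignments(p, dialect="tsv")
    assert len(df) == 0
    assert list(df.columns) == wio.WELL_READ_COLUMNS


SAM_HEADER = ("@HD\tVN:1.6\tSO:coordinate\n"
              "@SQ\tSN:chr2\tLN:1000000\n"
              "@RG\tID:P1W002\tSM:tumour\n")


def _sam_pair(name, chrom, s1, s2, rg="P1W002", tlen=550):
    cigar = "150M"
    return (f"{name}\t99\t{chrom}\t{s1 + 1}\t60\t{cigar}\t=\t{s2 + 1}\t{tlen}\t"
            + "A" * 150 + "\t" + "I" * 150 + f"\tRG:Z:{rg}\n"
            + f"{name}\t147\t{chrom}\t{s2 + 1}\t60\t{cigar}\t=\t{s1 + 1}\t{-tlen}\t"
            + "A" * 150 + "\t" + "I" * 150 + f"\tRG:Z:{rg}\n")


def test_bam_dialect_merges_mates_to_union_span(tmp_path):
    # mates at chr2:500-650 and chr2:900-1050 -> one interval 500-1050
    p = tmp_path / "pair.sam"
    p.write_text(SAM_HEADER + _sam_pair("r1", "chr2", 500, 900))
    df = wio.read_well_alignments(p, dialect="bam-rg")
    assert len(df) == 1
    assert df.iloc[0].tolist() == ["P1W002", "chr2", 500, 1050]


def test_bam_and_tsv_dialects_agree(tmp_path):
    sam = tmp_path / "r.sam"
    sam.write_text(SAM_HEADER + _sam_pair("r1", "chr2", 500, 900)
                   + _sam_pair("r2", "chr2", 2000, 2100))
    tsv = tmp_path / "r.tsv"
    tsv.write_text("P1W002 chr2 500 1050\nP1W002 chr2 2000 2250\n")
    a = wio.read_well_alignments(sam, dialect="bam-rg")
    b = wio.read_well_alignments(tsv, dialect="tsv")
    pd.testing.assert_frame_equal(a, b)


def test_missing_read_group_is_reported(tmp_path):
    p = tmp_path / "norg.sam"
    body = _sam_pair("r9", "chr2", 500, 900)
    body = "\n".join(t.rsplit("\tRG:Z:P1W002", 1)[0] for t in body.splitlines())
    p.write_text(SAM_HEADER + body + "\n")
    with pytest.raises(wio.WellDataError, match="r9"):
        wio.read_well_alignments(p, dialect="bam-rg")


def test_discordant_pair_split_beyond_fragment_scale(tmp_path):
    # union span > 100 kb cannot be one input fragment: keep mates separate
    p = tmp_path / "disc.sam"
    p.write_text(SAM_HEADER + _sam_pair("r1", "chr2", 500, 200_500))
    df = wio.read_well_alignments(p, dialect="bam-rg")
    assert len(df) == 2
    assert df["start"].tolist() == [500, 200_500]


# ---------------------------------------------------------------------------
# SNP filter


def _vcf(tmp_path, records):
    p = tmp_path / "snps.vcf"
    header = ("##fileformat=VCFv4.2\n"
              '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="AD">\n'
              '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
              "##contig=<ID=chr1,length=10000000>\n"
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tgermline\n")
    p.write_text(header + "".join(records))
    return p


def _rec(pos, ref, alt, ref_d, alt_d):
    return (f"chr1\t{pos}\t.\t{ref}\t{alt}\t50\tPASS\t.\t"
            f"GT:AD\t0/1:{ref_d},{alt_d}\n")


def test_het_snp_filter_depth_and_af_boundaries(tmp_path):
    vcf = _vcf(tmp_path, [
        _rec(100, "A", "G", 10, 9),    # depth 19 -> dropped
        _rec(200, "A", "G", 20, 20),   # depth 40, AF .5 -> kept
        _rec(300, "A", "G", 76, 24),   # AF .24 -> dropped
        _rec(400, "A", "G", 75, 25),   # AF .25 -> kept (boundary)
        _rec(500, "A", "G", 25, 75),   # AF .75 -> kept (boundary)
        _rec(600, "A", "G", 24, 76),   # AF .76 -> dropped
        _rec(700, "AT", "A", 20, 20),  # indel -> dropped
    ])
    snps = wio.read_het_snps(vcf)
    assert snps["pos"].tolist() == [199, 399, 499]  # 0-based


def test_vcf_without_allele_depths_is_fatal(tmp_path):
    p = tmp_path / "noad.vcf"
    p.write_text("##fileformat=VCFv4.2\n"
                 '##FORMAT=<ID=GT,Number=1,Type=String,Description="GT">\n'
                 "##contig=<ID=chr1,length=10000>\n"
                 "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tg\n"
                 "chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0/1\n")
    with pytest.raises(wio.WellDataError, match="allele depth"):
        wio.read_het_snps(p)


def test_filter_idempotent_and_order_independent():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "chrom": "chr1", "pos": rng.permutation(np.arange(100)) * 1000,
        "ref": "A", "alt": "G",
        "depth": rng.integers(5, 60, 100),
        "af": rng.random(100),
    })
    once = wio.filter_het_snps(df)
    twice = wio.filter_het_snps(once)
    shuffled = wio.filter_het_snps(df.sample(frac=1, random_state=1))
    pd.testing.assert_frame_equal(once, twice)
    pd.testing.assert_frame_equal(once, shuffled)


# ---------------------------------------------------------------------------
# genotype matrix


def test_build_well_genotypes_rules():
    snps = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 200],
                         "ref": "A", "alt": "G", "depth": 40, "af": 0.5})
    obs = pd.DataFrame({
        "well": ["w1", "w2", "w1"],
        "chrom": ["chr1", "chr1", "chr1"],
        "pos": [100, 100, 200],
        "alt_reads": [3, 2, 0],
        "ref_reads": [0, 1, 4],
    })
    G, wells = wio.build_well_genotypes(snps, obs)
    assert wells == ["w1", "w2"]
    assert G[0, 0] == 1          # alt only
    assert G[0, 1] == 0          # bi-allelic well zeroed (fragment collision)
    assert G[1, 0] == -1         # ref only
    assert G[1, 1] == 0          # no coverage


def test_genotype_matrix_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    G = rng.integers(-1, 2, size=(20, 8)).astype(np.int8)
    wells = [f"W{i}" for i in range(8)]
    p = tmp_path / "g.tsv"
    wio.write_genotype_matrix(G, wells, p)
    G2, wells2 = wio.read_genotype_matrix(p)
    assert wells2 == wells
    np.testing.assert_array_equal(G, G2)


# ---------------------------------------------------------------------------
# profiles


def _profile():
    seg = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [0, 30_000_000, 0],
        "end": [30_000_000, 60_000_000, 50_000_000],
        "n_A": [1, 2, 3], "n_B": [1, 0, 1],
        "clonality": [1.0, 1.0, 0.7],
    })
    return wio.CopyNumberProfile(seg, purity=0.8, ploidy=2.4, mse=1.5)


def test_profile_roundtrip(tmp_path):
    prof = _profile()
    path = tmp_path / "profile.bed"
    wio.write_profile(prof, path)
    back = wio.read_profile(path)
    pd.testing.assert_frame_equal(prof.segments, back.segments,
                                  check_dtype=False)
    assert back.purity == prof.purity
    assert back.ploidy == prof.ploidy
    assert back.mse == prof.mse


def test_profile_rejects_minor_above_major(tmp_path):
    path = tmp_path / "bad.bed"
    path.write_text("#chrom\tstart\tend\tn_A\tn_B\tclonality\n"
                    "chr1\t0\t1000\t1\t2\t1.0\n")
    with pytest.raises(wio.WellDataError, match="canonical"):
        wio.read_profile(path)


def test_profile_rejects_overlapping_segments(tmp_path):
    path = tmp_path / "ov.bed"
    path.write_text("#chrom\tstart\tend\tn_A\tn_B\tclonality\n"
                    "chr1\t0\t2000\t1\t1\t1.0\n"
                    "chr1\t1000\t3000\t2\t1\t1.0\n")
    with pytest.raises(wio.WellDataError, match="overlap"):
        wio.read_profile(path)


def test_empty_profile_roundtrip(tmp_path):
    prof = wio.CopyNumberProfile(
        pd.DataFrame(columns=wio.PROFILE_COLUMNS))
    path = tmp_path / "empty.bed"
    wio.write_profile(prof, path)
    back = wio.read_profile(path)
    assert len(back.segments) == 0


# ---------------------------------------------------------------------------
# genome tracks


def test_windows_tile_and_validate():
    w = wio.make_windows({"chr1": 2_500_000}, size=1_000_000)
    assert w["end"].tolist() == [1_000_000, 2_000_000, 2_500_000]
    tracks = wio.GenomeTracks(windows=w, centromeres={"chr1": 1_200_000},
                              chrom_lengths={"chr1": 2_500_000})
    # arm assignment is by window midpoint relative to the centromere
    assert tracks.window_arms().tolist() == ["chr1:p", "chr1:q", "chr1:q"]


def test_non_tiling_windows_rejected():
    w = wio.make_windows({"chr1": 3_000_000})
    w = w.drop(index=1).reset_index(drop=True)
    with pytest.raises(wio.WellDataError, match="tile"):
        wio.GenomeTracks(windows=w, centromeres={}, chrom_lengths={"chr1": 3_000_000})
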