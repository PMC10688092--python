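# picocnv

Allele-specific somatic copy-number calling for **well-barcoded
linked-read sequencing** of microscopic tumour samples (hundreds of
cells, picograms of DNA).

At such input amounts, whole-genome amplification is unavoidable and
its per-fragment rate variation drowns the read-depth signal that
conventional copy-number callers rely on. On a well-barcoded platform,
however, ~100 kb input DNA fragments are distributed across a 384-well
plate before amplification, so that almost every well holds **at most
one parental allele per locus** (the *mono-allelic property*). picocnv
exploits this twice:

* **Read depth** — co-local read pairs within one well are chained
  (gap < 100 kb) into *reconstructed large fragments* (RLFs); counting
  fragments instead of reads removes per-fragment amplification noise
  from the depth track.
* **Allele frequency** — nearby heterozygous SNPs covered by shared
  wells are phased per block from the SNP–SNP similarity matrix
  `M_ij = Σ_k G_ik G_jk / Σ_l |G_il||G_jl|` (sign pattern of the first
  singular vector of `M`), and the B-allele frequency is computed from
  counts of *wells*, aggregated per haplotype, rather than reads.

Downstream the caller is ASCAT-like. Per 1 Mb window the read-depth
ratio `r = 100 × (mean RLF depth)/(germline reads)` is corrected for GC
and mappability; tracks are transformed (`b_mirr = 0.5 − |0.5 − b|`,
`r_norm = r/4r̄`) and each chromosome arm is segmented by minimising

```
L(x) = Σ_s Σ_{i∈s} w_i (x_i − x̄_s)² + λ|S|,   λ = 0.1
```

with a restarted stochastic greedy search (BAF pass first, then RDR).
For purity φ and tumour ploidy ψ the per-segment model expectations are

```
r̂_s = r̄ (φ(n_A+n_B) + 2(1−φ)) / (φψ + 2(1−φ))
b̂_s = (φ n_B + (1−φ)) / (φ(n_A+n_B) + 2(1−φ))
```

(φ, ψ) is found by grid search over a variance-normalised, length-
weighted genome MSE, taking the **lowest-ploidy pronounced local
minimum** to avoid spuriously tetraploid solutions. Finally each
segment gets the MSE-minimal state, optionally over sub-clonal states
with clonality χ ∈ {0.5,…,0.9} (mixture with the modal state, flat
penalty π = 1). A full synthetic-data generator (fragments → wells →
reads, plus a faster track-level variant), spike-in machinery and
benchmarking metrics (per-event sensitivity/precision/F1, exact-match
fraction, SNR, multi-caller consensus) are included.

## Worked example

Simulate a small two-chromosome sample (pure tumour, an LOH arm on
chr1q and a single-copy gain on chr2p) and call it end to end:

```python
import pandas as pd
from picocnv import simulation as sim, rlf_rdr, phasing_baf, segmentation, cn_fit, evaluation

lengths, cens = sim.toy_genome(n_chrom=2, chrom_length=50_000_000, centromere_frac=0.4)
events = [("chr1", 25_000_000, 50_000_000, 1, 0, 1.0),   # LOH on chr1q
          ("chr2", 0, 20_000_000, 2, 1, 1.0)]            # gain on chr2p
config = sim.SimConfig(chrom_lengths=lengths, centromeres=cens,
                       karyotype=pd.DataFrame(events, columns=sim.KARYOTYPE_COLUMNS),
                       purity=1.0, seed=42)
data = sim.simulate_well_data(config)

rlfs = rlf_rdr.reconstruct_rlfs(data.reads)
rdr = rlf_rdr.build_rdr_track(rlfs, data.germline_reads, data.tracks)
baf, _, _ = phasing_baf.phase_and_baf(data.snps, data.G)
segments = segmentation.segment_genome(baf, rdr, data.tracks, restarts=200, seed=1)
profile, solution = cn_fit.fit_profile(segments, rdr.r_bar)

print(f"purity = {solution.purity:.2f}   ploidy = {solution.ploidy:.2f}")
print(profile.segments.to_string(index=False))
print("exact match vs truth:", f"{evaluation.exact_match_fraction(profile, data.truth):.3f}")
```

Output:

```
purity = 1.00   ploidy = 1.95
chrom    start      end  n_A  n_B  clonality
 chr1        0 20000000    1    1        1.0
 chr1 20000000 26000000    1    1        1.0
 chr1 26000000 50000000    1    0        1.0
 chr2        0 20000000    2    1        1.0
 chr2 20000000 50000000    1    1        1.0
exact match vs truth: 0.990
```

The recovered purity is exact, ploidy 1.95 matches the truth (the
simulated karyotype averages 1.95 copies), and 99% of the genome gets
the exactly correct allele-specific state; the only discrepancy is the
LOH breakpoint placed one window off. `n_A`/`n_B` are major/minor
parental copy numbers — `{1,0}` is copy-neutral-adjacent LOH, `{2,1}` a
single-copy gain; clonality 1.0 means every tumour cell carries the
state.

The same stages are available from the shell (`picocnv simulate`,
`rdr`, `phase`, `segment`, `fit`, `evaluate`, `spike`, `run-all`); every
stage writes plain TSV/JSON artifacts with parameters and seeds echoed
into the headers.

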