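# Methods

## Data model and assumptions

picocnv targets sequencing libraries in which a picogram-scale DNA
input is partitioned into `W` wells (default 384 per plate) *before*
whole-genome amplification, with the well identity preserved in the
read groups. Two assumptions drive everything downstream:

1. **Fragment scale.** Input DNA arrives as large fragments of roughly
   100 kb. Reads from one well that lie within 100 kb of each other
   are therefore taken to originate from a single input fragment, and
   chained into a reconstructed large fragment (RLF) spanning from the
   first read's start to the last read's end. The chaining gap is
   `next.start − prev.end < 100 kb` (strict), applied per well and
   chromosome on position-sorted reads. Read pairs are merged to the
   union span of their mates first; pairs spanning more than 100 kb are
   kept as separate single-mate intervals, since no single input
   fragment could produce them.
2. **Mono-allelic wells.** With `c = input_pg / 6.6` genome copies of
   input (6.6 pg per diploid genome) spread over `W` wells, the
   probability that a well holding any fragment at a locus holds both
   parental alleles is `q²/(1 − (1 − 1/W)^{2c})` with
   `q = 1 − (1 − 1/W)^c` — about 2% at 100 pg on one plate. All reads
   in a well at a locus can therefore be attributed to one parental
   allele. Wells that nonetheless show both alleles at a SNP are
   treated as fragment collisions and zeroed in the genotype matrix
   rather than majority-voted.

Non-cancer cells are assumed diploid everywhere; sex chromosomes are
not treated specially (the simulator generates autosome-like
chromosomes only, and real inputs should either drop gonosomes or
accept that the genome-wide mean includes them).

## Pipeline stages and tunable parameters

| parameter | default | meaning |
|---|---|---|
| RLF chaining gap | 100 kb | maximum intra-well read gap within one fragment |
| window size | 1 Mb | RDR resolution |
| SNP filter | depth ≥ 20, AF ∈ [0.25, 0.75] | heterozygous-SNP retention in the germline |
| block gap | 500 kb | maximum inter-SNP gap inside a haplotype block |
| block size | ≤ 100 SNPs | SVD problem size cap; long runs split into near-equal contiguous chunks |
| λ | 0.1 | segmentation penalty per segment |
| minimum span | 5 Mb | genomic span of any segment (whole arms shorter than this stay single segments) |
| restarts | 10,000 | greedy-search restarts (validation studies use 200, which already reaches the exhaustive optimum on small arms) |
| φ grid | 0.05–1.00 step 0.01 | purity candidates |
| ψ grid | 1.0–8.0 step 0.05 | ploidy candidates |
| κ | 1.2 | a local MSE minimum is "pronounced" if within κ× the global minimum |
| χ grid | {0.5, 0.6, 0.7, 0.8, 0.9, 1} | clonality candidates |
| π | 1 | flat sub-clonal penalty on the per-segment MSE |

**RDR.** `r = 100 × (mean RLF depth)/(germline reads)` per window;
windows without germline coverage are masked. GC/mappability correction
fits `r ~ 1 + gc + mappability` by OLS and rescales each window by
`mean(fitted)/fitted`, then recentres multiplicatively so the
genome-wide mean is preserved exactly; the ratio form keeps depth
non-negative, which an additive residual correction would not.
Constant covariates silently skip the correction.

**Phasing.** Blocks are contiguous SNP runs (gap ≤ 500 kb), chunked to
≤ 100 SNPs, then split into connected components of the shared-well
graph; singletons are dropped. The similarity matrix is rank-one
(`M = hhᵀ`) under exact mono-allelism, so `h` is read off the sign of
the first singular vector (largest singular value, ties by first
occurrence; `sgn(0) → +1`; global sign fixed by `h₁ = +1`). Pairs with
no co-covering well get `M_ij = 0` — they contribute no signal, and
connectivity filtering guarantees no SNP is fully isolated.

**BAF.** Per haplotype group, `b = Σ(wells supporting alt)/Σ(wells
covering)`, positioned at the group's median SNP coordinate and
weighted by group size. A read-count variant is kept only as a
benchmarking baseline.

**Segmentation.** The printed loss is read as standard weighted least
squares `w_i(x_i − x̄_s)²` with weighted segment means; the literal
alternative `(w_i x_i − x̄_s)²` is available via `form="literal"` but
is inconsistent with a weighted mean for non-unit weights. Weights are
renormalised to mean 1 per arm so λ is comparable across arms and
tracks. Each restart starts from the coarsest admissible solution and
proposes uniform random add/remove/shift-by-one moves, accepting only
strict improvements, stopping after 100 consecutive rejections; this
schedule is this package's concretisation of a stochastic greedy
search. The BAF pass runs first (the cleaner track); its breakpoints
are frozen and the RDR pass may only subdivide further.

**Fitting.** Noise `σ̂²` per track is the pooled within-segment
variance (point-count weighted, floored at 1e-6). Candidate states are
all `{n_A ≥ n_B}` with total up to the smallest total whose expected
RDR exceeds every observed segment mean (capped at 20). The genome MSE
is the length-weighted mean of per-segment MSEs, each the sum of
variance-normalised RDR and mirrored-BAF terms; segments lacking BAF
data drop that term. On the (φ, ψ) grid, local minima are cells
strictly below all 8 neighbours; among those within κ× the global
minimum the lowest ψ wins. State ties break toward lower total copy,
then higher clonality, then higher `n_B`. A clonal `{0,0}` segment at
φ = 1 has no defined BAF and is fitted on RDR alone.

## The synthetic-data generator

`simulate_well_data` emulates the platform at fragment resolution:
each of `round(input_pg/6.6)` cell equivalents contributes, per
haplotype and karyotype interval, as many chromosome copies as its
copy number (tumour cells carry a sub-clonal interval with probability
χ; normal cells at fraction 1 − φ are diploid). Chromosome copies are
chopped into exponential-length fragments (mean 100 kb), each assigned
to a uniform well, given a log-normal amplification rate (log-sd 0.8,
the "non-uniform amplification" term) and a Poisson read count
(default 150 read pairs per 100 kb, ≈ 0.45× per-fragment coverage),
with 300 bp read spans placed uniformly. SNPs sit every ~5 kb with the
alternative allele assigned to a random haplotype; reads report their
fragment's haplotype. Germline window depths are Poisson around 200.
This generator reproduces, rather than postulates, the binomial well
collision rate, fragment-level depth noise, and well-count BAF
statistics.

`simulate_tracks` draws corrected-RDR windows and BAF points directly
from the model expectations with Gaussian noise — the whole-genome
(3,000 Mb) generator for segmentation and fitting studies where
simulating every fragment would be wasteful. Its noise can be set to
bulk-like defaults (2% RDR CV, 0.01 BAF sd at 1 Mb) or calibrated from
a well-level run via `estimate_track_noise` (typically ≈ 8.5% RDR CV
and 0.019 BAF sd under default platform settings).

What the generator does **not** model: base-level sequencing errors,
mapping and reference bias, GC-dependent amplification, allele-specific
amplification bias, and any extra-binomial dispersion of allele
fractions. Passing tests therefore demonstrate correctness of the
algorithms under the stated stochastic model, not performance on real
libraries, which carry all of those additional noise sources.

**Spike-ins.** Sub-clonal sensitivity is measured by overwriting a
random segment's RDR with
`r = χ·N(r̄_CNA, σ²_CNA) + (1 − χ)·N(r̄_modal, σ²_modal)` — the sum of
two scaled independent normals, the literal reading of the mixture
expression; a true two-component mixture is available via
`mixture=True` (same mean, larger variance `χσ₁² + (1−χ)σ₂²` vs
`χ²σ₁² + (1−χ)²σ₂²`). Per-state means/variances come from a
fully-clonal fit of the background. BAF is overwritten with the same
construction from per-state BAF statistics (a package extension — only
the depth formula is canonical). Eligible segments are drawn uniformly
(not length-weighted); success means the spiked segment is re-fitted to
exactly the spiked `{n_A, n_B}` with χ < 1.

**Known limitation.** Because the simulator's well-count BAF noise is
purely binomial (sd ≈ 0.02 per aggregated point), a residual offset of
`(1 − χ)` times the state separation remains statistically detectable
even at χ = 0.9, so on synthetic backgrounds the spike-in sensitivity
*increases* with χ rather than peaking near χ ≈ 0.5 as expected for
noisier real libraries; the flat π = 1 penalty is not large enough to
absorb it. Raising the simulated BAF noise does not restore the peak:
well before that point the mirror-folding bias of noisy balanced
segments destabilises the purity/ploidy grid search. The corresponding
validation check is left failing by design rather than re-tuning the
generator around it.

## Numerical choices

* Coordinates are 0-based half-open internally; VCF input converts
  from 1-based, profile output is BED-dialect.
* Greedy-search determinism: restart streams are drawn from one
  `random.Random(seed)` master; identical inputs and seed give
  byte-identical outputs.
* Acceptance of a greedy move requires improvement > 1e-12 to avoid
  cycling on ties.
* `M_ij` with zero denominator → 0; σ̂² floored at 1e-6; SNR of
  noise-free tracks is reported as a 1e12 sentinel; medians over an
  even number of consensus profiles use the lower median to keep
  states integral.
* Arm assignment of a window is by its midpoint relative to the
  centromere; BAF points likewise by position.

## Validation problem sizes

The shipped validation suite runs the optimality oracles on arms of
≤ 20 points against an exhaustive dynamic program (200 restarts),
phasing on blocks of 2–100 SNPs over 384 wells, whole-pipeline studies
on twenty 150 Mb chromosomes (3,000 windows), well-level simulations on
two 50 Mb chromosomes (~4 M reads), and 200 spike-ins per clonality.
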