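# Methods

## Model of the data-generating process

The simulator treats an EdU XR-seq library as a weighted sample of excision
events over a reference genome.

**Lesion landscape.** Each thymidine — `T` on the plus strand, `A` on the
plus strand for the minus strand — independently carries EdU with
probability `p_edu` (default 0.2; a heavy 24-h labeling regime, during which
replication passes every locus, so both strands are labeled independently).
EdU-flagged sites within 40 bp of a chromosome end are excluded so products
never run off the sequence.

**Excision sampling.** Reads are drawn from flagged sites *with
replacement*, with per-site weight

    w(site) = alpha_eff(site) * state_multiplier(state at site)

where `alpha_eff = alpha` (the TCR factor) for sites on the transcribed
strand — the strand opposite the gene annotation — inside an expressed gene
body, and 1 elsewhere. Sampling with replacement reflects that a sequencing
library pools lesions from millions of cells, so one genomic coordinate
yields many independent excision events; without-replacement sampling would
saturate high-weight sites and flatten the very strand asymmetry the
analysis measures. An optional 5′-weighted decay
(`alpha_eff = 1 + (alpha-1) * exp(-decay * x)`, `x` the fractional position
from the TSS) reproduces promoter-proximal TCR excess. If a gene carries an
antisense promoter unit, the α weight is also applied to that interval on
the gene's own strand (its antisense transcript's template), which inverts
the preferred strand upstream of the TSS.

**Dual-incision geometry.** The 5′ incision leaves the lesion `d`
nucleotides from the product's 5′ end (1-based; pmf over {19, 20, 21} with
probabilities {0.25, 0.5, 0.25}); the 3′ incision leaves a `k`-nucleotide
tail (pmf over {3..9} peaked at 6), so product length `L = d + k` spans
exactly 22–30 nt. The analytic convolution of the two pmfs has mode
P(L=26) = 0.2175 > P(27) = 0.1975 > P(25) = 0.1675, matching the nominal
26-mer with a 25–27 shoulder. One mechanism therefore produces both the
length distribution and the positional thymine peak near 20 observed in the
composition matrices. `d` and `k` are independent of the site, so geometry
statistics are unbiased by TCR or chromatin weighting.

**Library artifacts.** The 5′ adapter is consumed by the sequencing primer
(small-RNA-style library) and never appears in reads; the full 3′ adapter
(TruSeq small-RNA, `TGGAATTCTCGGGTGCCAAGG`) is appended to every insert.
Each read is PCR-duplicated with probability `duplication_rate` (default
0.1), qualities are constant Phred-33 `I`, and the output order is a
seed-deterministic shuffle.

**Genome and annotation.** Chromosomes are i.i.d. bases at a configurable
GC fraction (default 0.41, human-like). Genes are packed with lengths
sampled in [5001, 10002] bp and pairwise gaps ≥ 5000 bp (largest-remainder
apportionment across chromosomes; slack distributed multinomially), so
every generated gene passes the analysis-gene filter by construction.
Chromatin is tiled with 200–4000-bp segments over a 15-label vocabulary in
the style of the ChromHMM core model; the tile containing each expressed
TSS is relabeled `Active_Promoter` and tiles fully inside expressed bodies
get transcription labels. DNase peaks sit at expressed promoters (±150 bp
around the TSS, summit on the TSS) plus random 300-bp intergenic sites.

## Analysis conventions

- All intervals are 0-based half-open (BED); lesion offsets are 1-based
  from the product 5′ end, so "T at 19" is the 19th base.
- Fragment-to-feature assignment uses the fragment midpoint everywhere
  (gene bodies, metaprofile bins, chromatin states, peak windows): short
  fragments get exactly one unambiguous assignment.
- TS/NTS: a fragment is TS for a gene when its strand differs from the
  gene's annotated strand. The TCR analysis is defined over *expressed*
  (RNA Pol II-transcribed) genes; including silent genes dilutes the
  genome-wide ratio toward 1 by construction.
- The genome-wide TS:NTS ratio sums TS and NTS RPKM over gene-body bins
  only; flanks are displayed in metaprofiles but never summed.
- The lesion-signature filter (26-mers with T at 19, 27-mers with T at 20)
  is applied before the TCR analyses by default; every entry point takes an
  unfiltered escape hatch. Positional base composition for the signature
  diagnostics is computed on all aligned fragments of the requested length,
  *before* filtering (the filter would pin T at the probed position).
- RPKM = count / (feature kb) / (mapped reads / 1e6); browser tracks use a
  per-1e7 variant. Scale invariance (duplicate every fragment and double
  the total) is exact in floating point because the scaling factor is a
  power of two.

## Preprocessing

Trimming removes the longest read suffix matching a prefix of the 3′
adapter with ≥ 3 bases of overlap and a mismatch rate ≤ 0.1; inserts
shorter than 10 nt or longer than 50 nt are discarded (brackets the 22–30
nt biology with margin). Deduplication keeps the first occurrence of each
exact sequence and runs *before* alignment, mirroring the usual
cutadapt → fastx → aligner tool order. The aligner seeds with 12-mers from
a sorted-array index over the plus strand, queries both the read and its
reverse complement, and verifies candidates by exact string comparison;
only reads with exactly one genomic locus become fragments (a perfect
palindrome hits both strands at one locus and is deliberately counted as
multimapped — its strand is unknowable). A mismatch allowance exists
(multi-seed, Hamming verification) but defaults to 0. Each stage's counts
are recorded in a ledger whose identities (input = kept + discards, etc.)
are asserted after every run.

## Numerical choices and degenerate inputs

- `modal_length` breaks ties toward the smaller length.
- Unit-gene body bins use `bin = floor(rel * n_bins / length)`. Exact
  per-bin mirror symmetry under gene-strand reversal is impossible for
  general (length, bin-count) pairs — the positions cannot be partitioned
  into equal symmetric groups — so reversal symmetry is exact at the level
  of per-gene TS/NTS counts, flank bins and body totals, and only
  approximate per body bin.
- Empty inputs: an empty composition matrix is flagged, not an exception;
  an empty time-course sample gets a NaN-flagged row without affecting
  others; zero NTS signal yields a NaN ratio ("undefined" flag).
- A gene packing that cannot fit raises a capacity error naming the
  achievable count; `p_edu = 0` or a T-free genome raises an explicit
  no-eligible-sites error rather than writing an empty file.
- `SimulationConfig.validate()` enforces pmf normalization (1e-9), positive
  multipliers and length support within [20, 35]. Point-mass geometries
  (e.g. d ≡ 20, k ≡ 6) are valid configurations used by tests, so coverage
  of the full 22–30 range is a property of the defaults, not a hard
  invariant.

## What the simulator does and does not emulate

Emulated: per-thymidine lesion placement, dual-incision geometry,
transcription-coupled strand asymmetry with optional 5′ decay, antisense
promoter units, chromatin-state rate modulation, promoter-centered DNase
peaks, 3′-adapter read-through and PCR duplication.

Not emulated: sequencing errors and quality variation, paired-end reads,
repetitive or low-complexity genome structure (so multimapping is
vanishingly rare here, unlike in a real genome), replication dynamics and
EdU strand-of-incorporation structure, excision kinetics over time (time
points are metadata; supply per-timepoint α and depth), and UV-type damage
spectra. Passing recovery tests therefore demonstrates correctness of the
counting and normalization machinery under the modeled structure, not
robustness to real-genome mappability or error artifacts.

## Problem sizes

The standard study conditions used by the test-suite and the reproduction
script are a 2-Mb genome (2 × 1 Mb, 41% GC) with 40 genes (70% expressed):
50k reads for geometry/composition statistics and 100k reads for TS:NTS
(α ∈ {2.5, 1.2}) and chromatin-state recovery. At these depths the TS:NTS
estimator's sampling error is a few percent and per-state densities carry
~2–3% noise, comfortably inside the 10%/15% recovery tolerances.

## Known limitations

- The exact aligner is built for megabase-scale synthetic references; it
  does not aim at hg38-scale performance (externally aligned BED6 can be
  consumed instead).
- Exact-sequence deduplication cannot distinguish PCR duplicates from
  genuinely recurrent excision events at the same coordinates with the same
  geometry; at the default depths this removes ~1–3% of true events and
  biases the TS:NTS estimate downward by well under the test tolerances.
- State-enrichment densities are reported raw (as a browser or bedtools
  workflow would); the thymidine-density correction is applied only inside
  recovery tests, since observed repair density legitimately scales with
  local substrate density.
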