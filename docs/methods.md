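# Methods

## Model and rationale

Microprocessor cleavage of pri-miRNA hairpins is co-transcriptional, so in
the chromatin fraction an efficiently processed hairpin is covered by fewer
reads than the nascent sequence around it. The MPI scores that depletion:

    MPI_sample = -log2((hairpin_RD + 1) / (flank_RD + 1))

where both read depths (RD) are mean per-nucleotide depths over scoring
regions on the locus's transcribed strand, and the +1 pseudocounts keep the
ratio defined at zero coverage (an all-zero locus scores exactly 0). MPI is
a within-sample ratio, so no library-size or cross-sample normalisation is
applied anywhere. Condition-level MPI is the arithmetic mean of sample
MPIs — the mean of ratios, not the ratio of pooled means; the two differ
and the former is the definition honoured. ΔMPI = MPI_mutant −
MPI_reference, so negative values mean reduced processing in the mutant.

## Scoring-region geometry

From a hairpin [start, end) with parameters `flank_len` (default 100 nt)
and `trim` (default 5 nt):

- hairpin core: [start+trim, end−trim)
- left flank core: [start−flank_len, start−trim)
- right flank core: [end+trim, end+flank_len)

The 2·trim = 10 nt gaps on each side give leeway for alternative Drosha
cleavage positions; each flank core scores flank_len − trim = 95 nt. The
geometry depends only on hairpin start/end, so MPI is orientation-symmetric
between strands. Both parameters are configurable; the gap is emergent, not
hard-coded. A locus whose hairpin is shorter than 2·trim+1 or whose left
flank would underflow the chromosome start is a hard error carrying the
locus ID, never a silent truncation — a truncated flank would bias the
flank mean. Overlapping clustered loci (a neighbour hairpin inside a flank)
are surfaced by an optional overlap report but never auto-filtered; the
flank-ratio filter partially guards against the resulting imbalance.

MPI uses the pooled per-nucleotide mean over both flank cores (equal to the
average of the two flank means, since the cores have equal length); the
flank-ratio filter uses the two per-flank means separately.

## Inclusion filters

Applied in fixed order; the audit table records the first and all failing
filters per excluded locus, and survivors + distinct excluded loci always
partition the input.

1. **mirtron** — mirtrons and tailed mirtrons bypass the Microprocessor via
   splicing; membership comes from a curated ID list (or a GFF-level flag),
   not from structure inference.
2. **detected** — the locus must produce a mature miRNA present in the
   small-RNA-seq detected list. GFF3 loci match on mature IDs; BED6 loci
   carry no mature IDs, so the list is then matched against the locus ID
   itself (this is what lets the BED6-emitting simulator exercise the
   filter). When no detected list is supplied to the `run_mpi` entry point
   the filter is skipped.
3. **ref_flank_depth** — mean pooled flank depth across reference-condition
   samples must be ≥ 2 (inclusive: exactly 2.0 passes). Guards against
   MPI ≈ 0 artifacts from untranscribed loci.
4. **flank_ratio** — (max(left, right)+1)/(min(left, right)+1) ≤ 4. The
   pseudocounts keep the ratio defined when one flank is zero; with filter
   3 in force this rarely changes outcomes. The rule is applied per sample
   in every sample (the strictest reading), configurable to
   reference-condition means only.

`processed_in_ref` flags loci whose *minimum* MPI across reference-condition
samples exceeds 0.3 (so every reference replicate shows processing). It
feeds distribution summaries only and never removes records.

## Basal UG motif

The UG dinucleotide is called present when it occupies positions −14/−13
upstream of the 5' end of the 5p mature miRNA (counting −1 as the
nucleotide immediately upstream), the standard basal-UG convention.
Sequences are taken sense-orientation; T≡U, case-insensitive; an N inside
the window yields an indeterminate call, which is excluded from group
counts and reported separately. A ±1 nt slack window is available (off by
default) because Drosha cleavage-site annotations vary by one nucleotide
across databases. Group comparisons use the exact two-sided 2×2 test.

## Enrichment

Category over-representation uses the exact upper-tail hypergeometric
probability P(X ≥ k) for a universe of N with K category members and a
selected set of n containing k. The universe must be supplied by the
caller (the miRNAs actually included in the upstream analysis); no default
universe is baked in. ID-list inputs are clipped to the universe before
counting. The tail computation is delegated to scipy.stats and is verified
in the test suite against an exact rational-arithmetic enumeration for all
N ≤ 20.

## Coverage extraction

From alignments: primary, non-supplementary, non-duplicate-flagged records
with MAPQ ≥ `min_mapq` (default 0) are counted; existing duplicate flags
are respected but never set. Reads are assigned to the transcribed strand
by library chemistry — default `reverse_stranded` (dUTP-style, the common
chemistry for rRNA-depleted kits): first-in-pair and unpaired reads map
antisense to the transcript, second-in-pair sense; `forward_stranded`
inverts this. Match/mismatch and deletion-spanned reference bases count as
covered; spliced gaps (N), insertions and soft clips do not — standard
depth semantics. From bedGraph pairs: 0-based half-open, non-overlapping
intervals per file, uncovered positions zero. Both routes produce
identical region means on identical data (tested).

## Synthetic data generator

Emulates the coverage signature the pipeline is built to read out: each
locus has flat flank transcription at per-locus rate λ and a
hairpin-depleted interior, with independent per-nucleotide Poisson counts:

    depth_flank   ~ Poisson(λ)
    depth_hairpin ~ Poisson(λ·(1 − p))

where p ∈ [0, 1] is the per-condition processing efficiency. The expected
MPI is then the closed form −log2((λ(1−p)+1)/(λ+1)), inverted by
`estimate_efficiency` for parameter-recovery tests:

    p̂ = 1 − (2^(−MPI)·(flank_mean + 1) − 1)/flank_mean, clipped to [0, 1]

Defaults: 200 loci of 85 nt hairpins (typical human pre-miRNA, so trimmed
cores are 75 nt and flank cores 95 nt, matching real scale), λ drawn
uniformly from 50–200 reads/nt, conditions WT/HET/KO at efficiencies
0.8/0.5/0.1 with 4 replicates each — a wild-type > heterozygote > knockout
processing ordering. 5% of loci are flagged mirtrons (simulated with p = 0
in every condition, since mirtrons bypass the Microprocessor) and a
disjoint 5% are omitted from the detected list, so filters 1–2 are
exercised with known truth. Loci alternate strands, are spaced so flanks
never overlap, and everything (BED6, bedGraph pairs, manifest, ID lists,
truth table) is byte-deterministic given the seed.

What the generator does **not** emulate: read-level sampling (counts are
per-nucleotide, so fragment-length autocorrelation is absent — region-mean
standard errors on real data will be larger than Poisson), transcription
gradients, splicing, mappability or GC bias, partial hairpin retention
(available via `residual_retention`, default 0), and overlapping clustered
loci. Passing recovery tests therefore demonstrate the estimator and
pipeline plumbing are correct under the stated model, not that real
chromatin RNA-seq attains that precision.

## Numerical and design choices

- Internal coordinates are 0-based half-open throughout; GFF3 (1-based
  inclusive) is converted at the parse boundary.
- Filter thresholds are inclusive at the stated bounds (≥ 2 passes, ≤
  4-fold passes).
- Region means are exact arithmetic means over all interval nucleotides;
  unseen chromosomes query as zero rather than erroring, so sparse
  coverage files are valid.
- No per-locus significance testing of ΔMPI is provided: the intended
  output is the per-locus index and its distributions, and the replicate
  counts involved do not support stable per-locus inference.
- Validation problem sizes (200 loci, λ = 100, 3 replicates) were chosen so
  that Poisson error puts closed-form checks comfortably within ±0.05
  tolerances at sub-minute runtimes.

## Limitations

- MPI conflates processing with any other process that depletes hairpin
  coverage on chromatin (e.g. faster release of cleaved products is the
  intended signal, but structured-region mappability loss would mimic it).
- The detected-miRNA filter inherits the upstream small-RNA-seq analysis's
  inclusion choices.
- The flank-ratio filter assumes roughly uniform local transcription;
  loci at sharp transcription boundaries (TSS-proximal hairpins) may be
  excluded or biased.
- The basal-UG caller trusts the supplied 5p 5'-end offsets; a one-off
  annotation shifts the window (mitigated by the optional slack).
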