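# mpindex

Quantify co-transcriptional pri-miRNA processing from chromatin-associated
RNA-seq.

The Microprocessor complex (DGCR8 + Drosha) excises pre-miRNA hairpins from
primary miRNA transcripts while they are still attached to chromatin. In
chromatin RNA-seq coverage this leaves a footprint: a hairpin that is
efficiently cleaved is depleted of reads relative to the transcribed
sequence flanking it. `mpindex` turns that footprint into a per-locus
statistic, the **Microprocessor Processing Index (MPI)**, and contrasts it
between genotypes — for example wild-type cells against cells carrying one
or zero functional copies of *DGCR8*. It is written for people analysing
stranded chromatin (or nascent) RNA-seq who want a processing readout per
pri-miRNA without any cross-sample normalisation.

## The statistic

For each pri-miRNA hairpin, three scoring regions are derived: the hairpin
trimmed by 5 nt at each end, and two 95 nt flank cores (100 nt flanks minus
the 5 nt adjacent to the hairpin), leaving 10 nt gaps that absorb
alternative Drosha cleavage positions. With mean per-nucleotide read depths
RD over those regions,

```
MPI_sample    = -log2( (hairpin_RD + 1) / (flank_RD + 1) )
MPI_condition = mean of MPI_sample over replicates
ΔMPI          = MPI_mutant - MPI_reference
```

A high positive MPI indicates efficient processing; values near zero or
negative indicate inefficient or absent processing, and a negative ΔMPI
means the locus is less processed in the mutant. Loci are excluded if they
(1) are mirtrons or tailed mirtrons (Microprocessor-independent), (2) have
no mature miRNA detected by small RNA-seq, (3) have mean reference-sample
flank depth < 2, or (4) show a > 4-fold imbalance between the two flanks.

The package also ships the two helper analyses used to interpret MPI
shifts: presence of the basal UG motif at position −14 upstream of the 5p
miRNA, and upper-tail hypergeometric enrichment of miRNA categories (e.g.
primate-specific miRNAs among dysregulated ones), plus a synthetic-data
generator with known per-locus processing efficiency for validation.

## Worked example

Simulate a wild-type vs heterozygote experiment (processing efficiency 0.8
vs 0.5, mean coverage 100 reads/nt), run the full pipeline, and check that
the efficiencies are recovered from the MPI values alone:

```sh
mpindex recover --n-loci 50 --replicates 3 --seed 7 --lam 100 100 \
    --efficiency WT=0.8 --efficiency HET=0.5 --out demo
cat demo/recovery_summary.json
```

```json
{
  "n_loci": 50,
  "n_surviving": 46,
  "per_condition": {
    "HET": {"bias": 0.000422, "mean_abs_error": 0.004034},
    "WT":  {"bias": -0.0001,  "mean_abs_error": 0.002399}
  }
}
```

46 of the 50 simulated loci pass the four inclusion filters (the other 4
are the simulated mirtron/undetected loci, attributed in `demo/audit.tsv`),
and the per-locus efficiency estimates `p_hat` in `demo/recovery.tsv` land
within ~0.004 of the true 0.8/0.5 on average — the MPI faithfully encodes
the simulated processing efficiency. The same `compute` subcommand runs on
real manifests:

```sh
mpindex compute --manifest manifest.tsv --annotations hairpins.gff3 \
    --reference WT --detected detected.txt --mirtrons mirtrons.txt --out out/
```

producing `out/mpi.tsv` (per-sample and per-condition MPI, ΔMPI per
contrast, filter flags, the processed-in-reference flag) and
`out/audit.tsv` (first and all failing filters per excluded locus). A
category enrichment check is one call:

```sh
$ mpindex enrich 10 5 4 4     # N K n k
0.0238095
```

the exact probability of drawing ≥ 4 category members in 4 picks from a
universe of 10 containing 5.

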