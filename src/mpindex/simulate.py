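"""Synthetic chromatin-coverage datasets with known processing efficiency.

The generative model mirrors what chromatin-associated RNA-seq sees at a
pri-miRNA locus: nascent transcription covers the hairpin and its flanks
uniformly, and co-transcriptional Microprocessor cleavage removes the
hairpin from chromatin, depleting hairpin coverage in proportion to the
processing efficiency p.  Per nucleotide,

    depth_flank   ~ Poisson(lambda)
    depth_hairpin ~ Poisson(lambda * (1 - p))

so the expected MPI of a locus is -log2((lambda*(1-p) + 1) / (lambda + 1)),
which inverts to an efficiency estimator for parameter-recovery tests.

The generator emits exactly the formats the pipeline reads (BED6 loci,
per-sample plus/minus bedGraph pairs, a manifest TSV, mirtron and detected
ID lists) plus a truth table, and is byte-deterministic given a seed.
Simulated mirtron loci are Microprocessor-independent (p = 0 in every
condition); loci flagged undetected are omitted from the detected list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import GenomicInterval, PreMirnaLocus, write_loci_bed
from .coverage import StrandedCoverage
from .mpi import MpiResult

__all__ = [
    "SimConfig",
    "SimOutput",
    "simulate_dataset",
    "estimate_efficiency",
    "recovery_report",
]

# minimum spacing so neighbouring flanks never overlap
_LOCUS_GAP_PAD = 20


@dataclass(frozen=True)
class SimConfig:
    """Study design of a simulated chromatin RNA-seq experiment.

    Defaults emulate a wild-type / heterozygous / knockout comparison with
    four replicates each, efficiencies ordered WT > HET > KO, and realistic
    desk-scale chromatin coverage (mean depth 50-200 reads/nt).
    ``efficiency_by_condition`` values may be scalars (shared by all loci)
    or per-locus sequences of length ``n_loci``.
    """

    n_loci: int = 200
    genome: tuple | None = None  # ((chrom, length), ...); auto-sized if None
    hairpin_len: int = 85
    flank_len: int = 100
    trim: int = 5
    lambda_range: tuple = (50.0, 200.0)
    efficiency_by_condition: Mapping[str, object] = field(
        default_factory=lambda: {"WT": 0.8, "HET": 0.5, "KO": 0.1}
    )
    replicates_per_condition: int = 4
    seed: int = 0
    mirtron_fraction: float = 0.05
    undetected_fraction: float = 0.05
    residual_retention: float = 0.0  # hairpin coverage kept by processed transcripts
    reference_condition: str = "WT"

    def __post_init__(self):
        if self.n_loci < 1 or self.replicates_per_condition < 1:
            raise ValueError("n_loci and replicates_per_condition must be >= 1")
        lo, hi = self.lambda_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid lambda_range {self.lambda_range}")
        for cond, p in self.efficiency_by_condition.items():
            arr = np.atleast_1d(np.asarray(p, dtype=float))
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError(f"efficiency for {cond!r} outside [0, 1]")
        if self.reference_condition not in self.efficiency_by_condition:
            raise ValueError(
                f"reference condition {self.reference_condition!r} missing "
                "from efficiency_by_condition"
            )
        if not (0 <= self.mirtron_fraction < 1 and 0 <= self.undetected_fraction < 1):
            raise ValueError("fractions must be in [0, 1)")
        if self.hairpin_len <= 2 * self.trim or self.flank_len <= self.trim:
            raise ValueError("lengths insufficient for region derivation")

    @property
    def footprint(self) -> int:
        """Genomic span of one locus including both flanks."""
        return self.hairpin_len + 2 * self.flank_len


@dataclass
class SimOutput:
    """Paths and truth table of one simulated dataset."""

    outdir: Path
    annotations_bed: Path
    manifest_tsv: Path
    mirtrons_txt: Path
    detected_txt: Path
    truth_tsv: Path
    truth: pd.DataFrame
    loci: list  # PreMirnaLocus, in genomic order
    conditions: list


def _place_loci(cfg: SimConfig) -> list[PreMirnaLocus]:
    """Lay loci along the genome, alternating strands, flanks never
    overlapping a neighbour or a chromosome edge."""
    step = cfg.footprint + _LOCUS_GAP_PAD
    if cfg.genome is None:
        genome = (("chrSim", cfg.n_loci * step + cfg.flank_len),)
    else:
        genome = tuple(cfg.genome)
    width = len(str(cfg.n_loci))
    loci = []
    i = 0
    for chrom, length in genome:
        hp_start = cfg.flank_len
        while i < cfg.n_loci:
            hp_end = hp_start + cfg.hairpin_len
            if hp_end + cfg.flank_len > length:
                break
            strand = "+" if i % 2 == 0 else "-"
            loci.append(
                PreMirnaLocus(
                    locus_id=f"sim-mir-{i + 1:0{width}d}",
                    hairpin=GenomicInterval(chrom, hp_start, hp_end, strand),
                )
            )
            hp_start += step
            i += 1
        if i >= cfg.n_loci:
            break
    if i < cfg.n_loci:
        raise ValueError(
            f"genome too small: placed {i} of {cfg.n_loci} loci "
            f"(need ~{cfg.n_loci * step} bp plus margins)"
        )
    return loci


def simulate_dataset(cfg: SimConfig, outdir) -> SimOutput:
    """Generate a full dataset under ``outdir``; deterministic given seed."""
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    loci = _place_loci(cfg)
    n = cfg.n_loci
    conditions = list(cfg.efficiency_by_condition)

    lam = rng.uniform(cfg.lambda_range[0], cfg.lambda_range[1], size=n)

    # flag loci that exercise filters 1-2; the two sets are kept disjoint
    n_mirtron = int(round(cfg.mirtron_fraction * n))
    n_undet = int(round(cfg.undetected_fraction * n))
    order = rng.permutation(n)
    mirtron_idx = set(order[:n_mirtron].tolist())
    undet_idx = set(order[n_mirtron : n_mirtron + n_undet].tolist())

    eff = {}
    for cond in conditions:
        p = np.asarray(cfg.efficiency_by_condition[cond], dtype=float)
        p = np.broadcast_to(p, (n,)).copy()
        p[list(mirtron_idx)] = 0.0  # mirtrons bypass the Microprocessor
        eff[cond] = p

    # truth table
    rows = []
    for j, locus in enumerate(loci):
        hp = locus.hairpin
        row = {
            "locus_id": locus.locus_id,
            "chrom": hp.chrom,
            "start": hp.start,
            "end": hp.end,
            "strand": hp.strand,
            "lam": lam[j],
            "is_mirtron": j in mirtron_idx,
            "is_detected": j not in undet_idx,
        }
        for cond in conditions:
            row[f"p_{cond}"] = eff[cond][j]
        rows.append(row)
    truth = pd.DataFrame(rows)

    # annotations + ID lists
    annotations_bed = outdir / "loci.bed"
    write_loci_bed(loci, annotations_bed)
    mirtrons_txt = outdir / "mirtrons.txt"
    with open(mirtrons_txt, "w") as fh:
        for j in sorted(mirtron_idx):
            fh.write(loci[j].locus_id + "\n")
    detected_txt = outdir / "detected.txt"
    with open(detected_txt, "w") as fh:
        for j in range(n):
            if j not in undet_idx:
                fh.write(loci[j].locus_id + "\n")

    # per-sample coverage
    manifest_rows = []
    retain = cfg.residual_retention
    for cond in conditions:
        for rep in range(1, cfg.replicates_per_condition + 1):
            sample_id = f"{cond}_rep{rep}"
            cov = StrandedCoverage(sample_id=sample_id)
            for j, locus in enumerate(loci):
                hp = locus.hairpin
                lam_hp = lam[j] * ((1.0 - eff[cond][j]) + eff[cond][j] * retain)
                arr = cov._array(hp.chrom, hp.strand, hp.end + cfg.flank_len)
                arr[hp.start - cfg.flank_len : hp.start] += rng.poisson(
                    lam[j], cfg.flank_len
                )
                arr[hp.start : hp.end] += rng.poisson(lam_hp, cfg.hairpin_len)
                arr[hp.end : hp.end + cfg.flank_len] += rng.poisson(
                    lam[j], cfg.flank_len
                )
            plus = outdir / f"{sample_id}.plus.bedgraph"
            minus = outdir / f"{sample_id}.minus.bedgraph"
            cov.to_bedgraph(plus, minus)
            manifest_rows.append(
                (sample_id, cond, "bedgraph_pair", plus.name, minus.name)
            )

    manifest_tsv = outdir / "manifest.tsv"
    with open(manifest_tsv, "w") as fh:
        fh.write("sample_id\tcondition\tkind\tpath_plus\tpath_minus\n")
        for row in manifest_rows:
            fh.write("\t".join(row) + "\n")

    truth_tsv = outdir / "truth.tsv"
    truth.to_csv(truth_tsv, sep="\t", index=False)

    return SimOutput(
        outdir=outdir,
        annotations_bed=annotations_bed,
        manifest_tsv=manifest_tsv,
        mirtrons_txt=mirtrons_txt,
        detected_txt=detected_txt,
        truth_tsv=truth_tsv,
        truth=truth,
        loci=loci,
        conditions=conditions,
    )


def estimate_efficiency(mpi: float, flank_mean: float) -> float:
    """Invert the expected-MPI closed form to an efficiency estimate.

    p_hat = 1 - (2**(-mpi) * (flank_mean + 1) - 1) / flank_mean,
    clipped to [0, 1].  At mpi = 0 the estimate is exactly 0, and very
    large MPIs clip to 1.
    """
    if not flank_mean > 0:
        raise ValueError(f"flank_mean must be positive, got {flank_mean}")
    p_hat = 1.0 - (2.0 ** (-mpi) * (flank_mean + 1.0) - 1.0) / flank_mean
    return float(np.clip(p_hat, 0.0, 1.0))


def recovery_report(truth: pd.DataFrame, result: MpiResult) -> pd.DataFrame:
    """Per-locus, per-condition efficiency estimates against the truth.

    Uses each surviving locus's per-condition mean MPI and mean pooled
    flank depth.  Columns: locus_id, condition, p_true, p_hat, error.
    """
    truth_idx = truth.set_index("locus_id")
    by_condition: dict[str, list[str]] = {}
    for sid, cond in result.sample_conditions.items():
        by_condition.setdefault(cond, []).append(sid)
    rows = []
    for rec in result.survivors:
        for cond in rec.per_condition_mpi:
            samples = by_condition[cond]
            flank = float(
                np.mean([rec.per_sample[s].flank_mean for s in samples])
            )
            p_hat = estimate_efficiency(rec.per_condition_mpi[cond], flank)
            p_true = float(truth_idx.loc[rec.locus_id, f"p_{cond}"])
            rows.append(
                {
                    "locus_id": rec.locus_id,
                    "condition": cond,
                    "p_true": p_true,
                    "p_hat": p_hat,
                    "error": p_hat - p_true,
                }
            )
    return pd.DataFrame(rows, columns=["locus_id", "condition", "p_true", "p_hat", "error"])
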