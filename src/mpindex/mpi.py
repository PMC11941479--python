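"""Microprocessor Processing Index (MPI), ΔMPI, and locus-inclusion filters.

The MPI of one locus in one sample is the pseudocounted negative log2 ratio
of mean hairpin read depth to mean flank read depth::

    MPI_sample = -log2((hairpin_RD + 1) / (flank_RD + 1))

where ``hairpin_RD`` is the mean per-nucleotide depth over the trimmed
hairpin core and ``flank_RD`` the pooled mean over both flank cores.  A
hairpin that the Microprocessor cleaves co-transcriptionally is depleted of
chromatin-associated reads relative to its flanks, so a high positive MPI
indicates efficient processing and an MPI near zero or negative indicates
inefficient or absent processing.  Per-condition MPI is the arithmetic mean
of sample MPIs, and ΔMPI = MPI_mutant - MPI_reference, so negative ΔMPI
means the locus is less processed in the mutant.

Four inclusion filters remove Microprocessor-independent loci and coverage
artifacts: (1) no mirtrons or tailed mirtrons; (2) the locus's mature
miRNAs were detected by small RNA-seq; (3) mean flank depth across
reference-condition samples >= 2; (4) the two flank means never differ by
more than 4-fold (pseudocounted) in any sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import (
    PreMirnaLocus,
    RegionDerivationError,
    RegionSet,
    derive_regions,
)
from .coverage import SampleManifest, StrandedCoverage, load_sample_coverage

__all__ = [
    "mpi_sample",
    "mpi_condition",
    "delta_mpi",
    "FilterConfig",
    "SampleRegionStats",
    "MpiRecord",
    "MpiResult",
    "compute_records",
    "apply_filters",
    "run_mpi",
    "records_to_frame",
]

FILTER_NAMES = ("mirtron", "detected", "ref_flank_depth", "flank_ratio")
FILTER_INDEX = {name: i + 1 for i, name in enumerate(FILTER_NAMES)}


def mpi_sample(hairpin_mean: float, flank_mean: float) -> float:
    """-log2((hairpin_mean + 1) / (flank_mean + 1))."""
    if not (math.isfinite(hairpin_mean) and math.isfinite(flank_mean)):
        raise ValueError("region means must be finite")
    if hairpin_mean < 0 or flank_mean < 0:
        raise ValueError(
            f"region means must be non-negative, got "
            f"({hairpin_mean}, {flank_mean})"
        )
    return -math.log2((hairpin_mean + 1.0) / (flank_mean + 1.0))


def mpi_condition(sample_mpis: Sequence[float]) -> float:
    """Arithmetic mean of per-sample MPIs within one condition."""
    if len(sample_mpis) == 0:
        raise ValueError("condition has no sample MPIs")
    return float(np.mean(sample_mpis))


def delta_mpi(mutant_mpi: float, reference_mpi: float) -> float:
    """Mutant minus reference condition MPI."""
    return mutant_mpi - reference_mpi


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for the four inclusion filters and the processed flag.

    ``flank_ratio_scope``: "per_sample" applies filter 4 in every sample
    (strictest reading); "reference_mean" applies it to the reference-
    condition mean of each flank only.
    """

    min_ref_flank_depth: float = 2.0
    max_flank_ratio: float = 4.0
    require_detected: bool = True
    exclude_mirtrons: bool = True
    ref_processed_threshold: float = 0.3
    flank_ratio_scope: str = "per_sample"

    def __post_init__(self):
        if self.min_ref_flank_depth <= 0 or self.max_flank_ratio <= 0:
            raise ValueError("filter thresholds must be positive")
        if self.ref_processed_threshold <= 0:
            raise ValueError("ref_processed_threshold must be positive")
        if self.flank_ratio_scope not in ("per_sample", "reference_mean"):
            raise ValueError(
                f"unknown flank_ratio_scope {self.flank_ratio_scope!r}"
            )


@dataclass(frozen=True)
class SampleRegionStats:
    hairpin_mean: float
    left_flank_mean: float
    right_flank_mean: float
    flank_mean: float  # pooled per-nucleotide mean over both flank cores
    mpi: float


@dataclass
class MpiRecord:
    """Per-locus ledger of region means, MPIs, ΔMPIs, and filter outcomes."""

    locus_id: str
    per_sample: dict[str, SampleRegionStats]
    per_condition_mpi: dict[str, float]
    delta_mpi: dict[str, float]
    filters: dict[str, tuple[bool, str]] = field(default_factory=dict)
    processed_in_ref: bool | None = None

    @property
    def passed(self) -> bool:
        return all(ok for ok, _ in self.filters.values()) if self.filters else True

    def failing_filters(self) -> list[str]:
        return [name for name, (ok, _) in self.filters.items() if not ok]


def _pooled_flank_mean(cov: StrandedCoverage, regions: RegionSet) -> tuple[float, float, float]:
    left = cov.region_mean(regions.left_flank_core)
    right = cov.region_mean(regions.right_flank_core)
    n_l = regions.left_flank_core.length
    n_r = regions.right_flank_core.length
    pooled = (left * n_l + right * n_r) / (n_l + n_r)
    return left, right, pooled


def compute_records(
    loci: Sequence[PreMirnaLocus],
    coverages: Mapping[str, StrandedCoverage],
    sample_conditions: Mapping[str, str],
    reference: str,
    flank_len: int = 100,
    trim: int = 5,
) -> tuple[list[MpiRecord], list[tuple[str, str]]]:
    """Compute per-sample/per-condition MPI and ΔMPI for every locus.

    Returns ``(records, failures)`` where ``failures`` lists
    ``(locus_id, reason)`` for loci whose scoring regions cannot be derived;
    such loci are reported, never silently dropped.
    """
    if reference not in set(sample_conditions.values()):
        raise ValueError(f"unknown reference condition {reference!r}")
    by_condition: dict[str, list[str]] = {}
    for sid, cond in sample_conditions.items():
        by_condition.setdefault(cond, []).append(sid)

    records, failures = [], []
    for locus in sorted(loci, key=lambda l: l.locus_id):
        try:
            regions = derive_regions(locus, flank_len=flank_len, trim=trim)
        except RegionDerivationError as exc:
            failures.append((locus.locus_id, str(exc)))
            continue
        per_sample = {}
        for sid, cov in coverages.items():
            hp = cov.region_mean(regions.hairpin_core)
            left, right, pooled = _pooled_flank_mean(cov, regions)
            per_sample[sid] = SampleRegionStats(
                hairpin_mean=hp,
                left_flank_mean=left,
                right_flank_mean=right,
                flank_mean=pooled,
                mpi=mpi_sample(hp, pooled),
            )
        per_condition = {
            cond: mpi_condition([per_sample[sid].mpi for sid in sids])
            for cond, sids in by_condition.items()
        }
        deltas = {
            cond: delta_mpi(per_condition[cond], per_condition[reference])
            for cond in per_condition
            if cond != reference
        }
        records.append(
            MpiRecord(
                locus_id=locus.locus_id,
                per_sample=per_sample,
                per_condition_mpi=per_condition,
                delta_mpi=deltas,
            )
        )
    return records, failures


def _locus_detected(locus: PreMirnaLocus, detected: set) -> bool:
    # GFF3 loci carry mature IDs; BED6 loci do not, so the detected list is
    # then matched against the locus ID itself.
    if locus.mature_ids:
        return bool(set(locus.mature_ids) & detected)
    return locus.locus_id in detected


def apply_filters(
    records: Iterable[MpiRecord],
    loci: Sequence[PreMirnaLocus],
    detected: set,
    mirtrons: set,
    cfg: FilterConfig,
    reference: str,
    sample_conditions: Mapping[str, str],
) -> tuple[list[MpiRecord], pd.DataFrame]:
    """Annotate records with filter outcomes; return survivors and an audit.

    The audit table has one row per excluded locus with the first failing
    filter and all failing filters.  ``processed_in_ref`` (minimum MPI over
    reference-condition samples above ``ref_processed_threshold``) is a flag
    used for distribution summaries, never a removal criterion.
    """
    loci_by_id = {l.locus_id: l for l in loci}
    ref_samples = [s for s, c in sample_conditions.items() if c == reference]
    if not ref_samples:
        raise ValueError(f"unknown reference condition {reference!r}")

    survivors, audit_rows = [], []
    for rec in records:
        locus = loci_by_id.get(rec.locus_id)
        if locus is None:
            raise ValueError(f"record {rec.locus_id!r} has no matching locus")
        filters: dict[str, tuple[bool, str]] = {}

        if cfg.exclude_mirtrons and (locus.is_mirtron or rec.locus_id in mirtrons):
            filters["mirtron"] = (False, "mirtron or tailed mirtron")
        else:
            filters["mirtron"] = (True, "")

        if cfg.require_detected and not _locus_detected(locus, detected):
            filters["detected"] = (False, "no mature miRNA detected by small RNA-seq")
        else:
            filters["detected"] = (True, "")

        ref_flank = float(
            np.mean([rec.per_sample[s].flank_mean for s in ref_samples])
        )
        if ref_flank >= cfg.min_ref_flank_depth:
            filters["ref_flank_depth"] = (True, "")
        else:
            filters["ref_flank_depth"] = (
                False,
                f"reference flank depth {ref_flank:.4g} < "
                f"{cfg.min_ref_flank_depth:g}",
            )

        if cfg.flank_ratio_scope == "per_sample":
            ratio_inputs = [
                (s.left_flank_mean, s.right_flank_mean)
                for s in rec.per_sample.values()
            ]
        else:
            ratio_inputs = [
                (
                    float(np.mean([rec.per_sample[s].left_flank_mean for s in ref_samples])),
                    float(np.mean([rec.per_sample[s].right_flank_mean for s in ref_samples])),
                )
            ]
        worst = max(
            (max(l, r) + 1.0) / (min(l, r) + 1.0) for l, r in ratio_inputs
        )
        if worst <= cfg.max_flank_ratio:
            filters["flank_ratio"] = (True, "")
        else:
            filters["flank_ratio"] = (
                False,
                f"flank ratio {worst:.4g} exceeds {cfg.max_flank_ratio:g}-fold",
            )

        rec.filters = filters
        ref_min_mpi = min(rec.per_sample[s].mpi for s in ref_samples)
        rec.processed_in_ref = ref_min_mpi > cfg.ref_processed_threshold

        failing = rec.failing_filters()
        if failing:
            audit_rows.append(
                {
                    "locus_id": rec.locus_id,
                    "first_failing_filter": failing[0],
                    "first_failing_index": FILTER_INDEX[failing[0]],
                    "all_failing_filters": ",".join(failing),
                    "reasons": "; ".join(
                        rec.filters[name][1] for name in failing
                    ),
                }
            )
        else:
            survivors.append(rec)

    audit = pd.DataFrame(
        audit_rows,
        columns=[
            "locus_id",
            "first_failing_filter",
            "first_failing_index",
            "all_failing_filters",
            "reasons",
        ],
    )
    return survivors, audit


def records_to_frame(
    records: Sequence[MpiRecord], reference: str | None = None
) -> pd.DataFrame:
    """Flatten records to one row per locus (deterministic column order)."""
    sample_ids = sorted({s for r in records for s in r.per_sample})
    conditions = sorted({c for r in records for c in r.per_condition_mpi})
    rows = []
    for rec in sorted(records, key=lambda r: r.locus_id):
        row: dict = {"locus_id": rec.locus_id}
        for sid in sample_ids:
            st = rec.per_sample.get(sid)
            if st is None:
                continue
            row[f"{sid}.hairpin_mean"] = st.hairpin_mean
            row[f"{sid}.flank_mean"] = st.flank_mean
            row[f"{sid}.mpi"] = st.mpi
        for cond in conditions:
            row[f"mpi.{cond}"] = rec.per_condition_mpi.get(cond)
        for cond, d in sorted(rec.delta_mpi.items()):
            row[f"delta_mpi.{cond}"] = d
        for name in FILTER_NAMES:
            if name in rec.filters:
                row[f"filter.{name}"] = "pass" if rec.filters[name][0] else "fail"
        row["passed_all_filters"] = rec.passed
        row["processed_in_ref"] = rec.processed_in_ref
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class MpiResult:
    """Output bundle of a full MPI run."""

    records: list[MpiRecord]  # all loci with computed MPIs
    survivors: list[MpiRecord]  # records passing all four filters
    table: pd.DataFrame  # one row per locus (records_to_frame)
    audit: pd.DataFrame  # one row per excluded locus
    failures: list[tuple[str, str]]  # loci whose regions could not be derived
    reference: str
    sample_conditions: dict[str, str] = field(default_factory=dict)

    def write(self, mpi_tsv, audit_tsv) -> None:
        self.table.to_csv(mpi_tsv, sep="\t", index=False)
        self.audit.to_csv(audit_tsv, sep="\t", index=False)


def run_mpi(
    manifest: SampleManifest,
    loci: Sequence[PreMirnaLocus],
    cfg: FilterConfig | None = None,
    flank_len: int = 100,
    trim: int = 5,
    detected: set | None = None,
    mirtrons: set | None = None,
    orientation: str = "reverse_stranded",
    min_mapq: int = 0,
) -> MpiResult:
    """Full pipeline: load coverage, compute MPI/ΔMPI, apply filters.

    When no ``detected`` list is supplied the detection filter is skipped
    (there is nothing to check against); pass an empty set to fail all loci
    instead.
    """
    cfg = cfg or FilterConfig()
    if detected is None and cfg.require_detected:
        from dataclasses import replace

        cfg = replace(cfg, require_detected=False)
    coverages = {
        e.sample_id: load_sample_coverage(e, orientation=orientation, min_mapq=min_mapq)
        for e in manifest.entries
    }
    sample_conditions = manifest.sample_conditions()
    records, failures = compute_records(
        loci,
        coverages,
        sample_conditions,
        manifest.reference_condition,
        flank_len=flank_len,
        trim=trim,
    )
    survivors, audit = apply_filters(
        records,
        loci,
        detected if detected is not None else set(),
        mirtrons if mirtrons is not None else set(),
        cfg,
        manifest.reference_condition,
        sample_conditions,
    )
    table = records_to_frame(records, reference=manifest.reference_condition)
    return MpiResult(
        records=records,
        survivors=survivors,
        table=table,
        audit=audit,
        failures=failures,
        reference=manifest.reference_condition,
        sample_conditions=sample_conditions,
    )
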