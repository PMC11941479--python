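"""Strand-resolved per-nucleotide read depth.

Depth can come from a coordinate-sorted indexed alignment file (BAM/CRAM,
via pysam) or from a pair of plus/minus bedGraph files.  Depth is stored
per (chromosome, strand) as a dense array; querying an unseen chromosome or
positions beyond the stored length returns zero, so coverage objects behave
as if defined over the whole genome.

MPI is a within-sample ratio, so no cross-sample normalisation is applied
anywhere in this module.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .annotations import GenomicInterval

__all__ = [
    "StrandedCoverage",
    "SampleManifest",
    "ManifestEntry",
    "CoverageError",
    "depth_from_alignment",
    "depth_from_bedgraph",
    "region_mean",
    "read_manifest",
    "load_sample_coverage",
]

ORIENTATIONS = ("reverse_stranded", "forward_stranded")


class CoverageError(ValueError):
    pass


class StrandedCoverage:
    """Per-chromosome, per-strand, per-nucleotide depth for one sample."""

    def __init__(
        self,
        sample_id: str = "",
        library_orientation: str = "reverse_stranded",
    ):
        if library_orientation not in ORIENTATIONS:
            raise CoverageError(
                f"unknown library orientation {library_orientation!r}; "
                f"expected one of {ORIENTATIONS}"
            )
        self.sample_id = sample_id
        self.library_orientation = library_orientation
        self._depth: dict[tuple[str, str], np.ndarray] = {}

    def _array(self, chrom: str, strand: str, min_len: int = 0) -> np.ndarray:
        key = (chrom, strand)
        arr = self._depth.get(key)
        if arr is None:
            arr = np.zeros(min_len, dtype=np.float64)
            self._depth[key] = arr
        elif arr.size < min_len:
            arr = np.concatenate([arr, np.zeros(min_len - arr.size)])
            self._depth[key] = arr
        return arr

    def add_interval(
        self, chrom: str, strand: str, start: int, end: int, depth: float
    ) -> None:
        if depth < 0:
            raise CoverageError(f"negative depth {depth} at {chrom}:{start}-{end}")
        self._array(chrom, strand, end)[start:end] += depth

    def depth_slice(
        self, chrom: str, strand: str, start: int, end: int
    ) -> np.ndarray:
        """Depth over [start, end); positions outside stored data are zero."""
        if start < 0 or end < start:
            raise CoverageError(f"invalid query [{start}, {end})")
        arr = self._depth.get((chrom, strand))
        out = np.zeros(end - start, dtype=np.float64)
        if arr is not None and start < arr.size:
            stop = min(end, arr.size)
            out[: stop - start] = arr[start:stop]
        return out

    def region_mean(self, iv: GenomicInterval) -> float:
        return float(
            self.depth_slice(iv.chrom, iv.strand, iv.start, iv.end).mean()
        )

    def to_bedgraph(self, plus_path, minus_path) -> None:
        """Write step-function bedGraph files (zero runs omitted)."""
        for strand, path in (("+", plus_path), ("-", minus_path)):
            with open(path, "w") as fh:
                for (chrom, s), arr in sorted(self._depth.items()):
                    if s != strand:
                        continue
                    for start, end, val in _runs(arr):
                        if val != 0:
                            fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(val)}\n")


def _runs(arr: np.ndarray):
    """Yield maximal constant runs (start, end, value) of a 1-D array."""
    if arr.size == 0:
        return
    change = np.flatnonzero(np.diff(arr)) + 1
    bounds = np.concatenate([[0], change, [arr.size]])
    for s, e in zip(bounds[:-1], bounds[1:]):
        yield int(s), int(e), float(arr[s])


def _fmt(val: float) -> str:
    return str(int(val)) if float(val).is_integer() else repr(val)


def region_mean(cov: StrandedCoverage, iv: GenomicInterval) -> float:
    """Arithmetic mean depth over the interval on its strand."""
    return cov.region_mean(iv)


# ---------------------------------------------------------------------------
# bedGraph input


def depth_from_bedgraph(
    plus_path, minus_path, sample_id: str = ""
) -> StrandedCoverage:
    """Build coverage from a plus/minus bedGraph pair.

    Intervals must be 0-based half-open and non-overlapping within a file;
    uncovered positions are zero.
    """
    cov = StrandedCoverage(sample_id=sample_id)
    for strand, path in (("+", plus_path), ("-", minus_path)):
        last_end: dict[str, int] = {}
        intervals: dict[str, list] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split()
                if len(fields) < 4:
                    raise CoverageError(
                        f"{path}:{lineno}: expected 4 bedGraph fields"
                    )
                chrom, start, end, val = fields[0], int(fields[1]), int(fields[2]), float(fields[3])
                if val < 0:
                    raise CoverageError(f"{path}:{lineno}: negative value {val}")
                if start < 0 or end <= start:
                    raise CoverageError(
                        f"{path}:{lineno}: invalid interval [{start}, {end})"
                    )
                intervals.setdefault(chrom, []).append((start, end, val))
        for chrom, ivs in intervals.items():
            ivs.sort()
            prev_end = -1
            for start, end, val in ivs:
                if start < prev_end:
                    raise CoverageError(
                        f"{path}: overlapping intervals on {chrom} at {start}"
                    )
                prev_end = end
            arr = cov._array(chrom, strand, max(e for _, e, _ in ivs))
            for start, end, val in ivs:
                arr[start:end] = val
    return cov


# ---------------------------------------------------------------------------
# alignment input


def depth_from_alignment(
    path,
    orientation: str = "reverse_stranded",
    min_mapq: int = 0,
    sample_id: str = "",
) -> StrandedCoverage:
    """Extract stranded depth from a coordinate-sorted indexed BAM/CRAM.

    Counts primary, non-supplementary, non-duplicate alignments with
    MAPQ >= ``min_mapq``.  Each counted read increments depth by 1 over its
    aligned reference positions: match/mismatch and deletion-spanned bases
    are covered, skipped regions (spliced introns), insertions and soft
    clips are not.

    Strand assignment follows the library chemistry: with a
    ``reverse_stranded`` (dUTP-style) library the first-in-pair read maps
    antisense to the transcript, so its mapped strand is flipped (as is an
    unpaired read's); with ``forward_stranded`` the second-in-pair flips.
    """
    import pysam

    if orientation not in ORIENTATIONS:
        raise CoverageError(f"unknown library orientation {orientation!r}")
    cov = StrandedCoverage(sample_id=sample_id, library_orientation=orientation)
    with pysam.AlignmentFile(str(path)) as af:
        try:
            af.check_index()
        except (ValueError, AttributeError) as exc:
            raise CoverageError(f"{path}: missing index ({exc})") from exc
        lengths = dict(zip(af.references, af.lengths))
        for chrom in af.references:
            plus = cov._array(chrom, "+", lengths[chrom])
            minus = cov._array(chrom, "-", lengths[chrom])
            for read in af.fetch(chrom):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                    or read.is_qcfail
                    or read.mapping_quality < min_mapq
                ):
                    continue
                read_strand = "-" if read.is_reverse else "+"
                if orientation == "reverse_stranded":
                    flip = (not read.is_paired) or read.is_read1
                else:
                    flip = read.is_paired and read.is_read2
                strand = _flip(read_strand) if flip else read_strand
                arr = plus if strand == "+" else minus
                for start, end in _covered_blocks(read):
                    arr[start:end] += 1
    return cov


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _covered_blocks(read):
    """Reference blocks covered by a read: CIGAR M/=/X and D advance and
    cover; N advances without covering; I/S/H/P neither."""
    pos = read.reference_start
    start = None
    for op, length in read.cigartuples or ():
        if op in (0, 2, 7, 8):  # M, D, =, X: covered
            if start is None:
                start = pos
            pos += length
        elif op == 3:  # N: splice gap
            if start is not None:
                yield start, pos
                start = None
            pos += length
        # I (1), S (4), H (5), P (6): no reference advance
    if start is not None:
        yield start, pos


# ---------------------------------------------------------------------------
# sample manifest


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    condition: str
    kind: str  # "alignment" or "bedgraph_pair"
    path_plus: str  # BAM path for kind == "alignment"
    path_minus: str | None = None


@dataclass(frozen=True)
class SampleManifest:
    entries: tuple[ManifestEntry, ...]
    reference_condition: str

    def __post_init__(self):
        ids = [e.sample_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise CoverageError("duplicate sample_id in manifest")
        conditions = {e.condition for e in self.entries}
        if self.reference_condition not in conditions:
            raise CoverageError(
                f"reference condition {self.reference_condition!r} has no samples "
                f"(conditions present: {sorted(conditions)})"
            )

    @property
    def conditions(self) -> list[str]:
        seen = []
        for e in self.entries:
            if e.condition not in seen:
                seen.append(e.condition)
        return seen

    def sample_conditions(self) -> dict[str, str]:
        return {e.sample_id: e.condition for e in self.entries}


def read_manifest(path, reference_condition: str) -> SampleManifest:
    """Read a TSV manifest: sample_id, condition, kind, path_plus, [path_minus].

    Relative paths are resolved against the manifest's directory.
    """
    base = Path(path).parent
    entries = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "condition", "kind", "path_plus"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise CoverageError(
                f"{path}: manifest needs columns {sorted(required)}"
            )
        for row in reader:
            kind = row["kind"]
            if kind not in ("alignment", "bedgraph_pair"):
                raise CoverageError(f"{path}: unknown source kind {kind!r}")
            minus = row.get("path_minus") or None
            if kind == "bedgraph_pair" and minus is None:
                raise CoverageError(
                    f"{path}: bedgraph_pair sample {row['sample_id']} "
                    "needs path_minus"
                )
            entries.append(
                ManifestEntry(
                    sample_id=row["sample_id"],
                    condition=row["condition"],
                    kind=kind,
                    path_plus=str(base / row["path_plus"]),
                    path_minus=str(base / minus) if minus else None,
                )
            )
    return SampleManifest(tuple(entries), reference_condition)


def load_sample_coverage(
    entry: ManifestEntry,
    orientation: str = "reverse_stranded",
    min_mapq: int = 0,
) -> StrandedCoverage:
    if entry.kind == "alignment":
        return depth_from_alignment(
            entry.path_plus,
            orientation=orientation,
            min_mapq=min_mapq,
            sample_id=entry.sample_id,
        )
    return depth_from_bedgraph(
        entry.path_plus, entry.path_minus, sample_id=entry.sample_id
    )
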