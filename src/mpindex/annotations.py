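"""Pri-miRNA locus annotations and derivation of the MPI scoring regions.

A pri-miRNA locus is scored over three intervals derived from its hairpin
(pre-miRNA) coordinates: the hairpin core (hairpin minus ``trim`` nt at each
end) and two flank cores (``flank_len`` nt on each side, with the ``trim`` nt
adjacent to the hairpin excluded).  With the defaults ``flank_len=100`` and
``trim=5`` this leaves a 10 nt gap between the hairpin core and each flank
core, absorbing alternative Drosha cleavage positions, and 95 nt of scored
flank on each side.

All internal coordinates are 0-based half-open (BED convention); GFF3 input
is converted at the boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "PreMirnaLocus",
    "RegionSet",
    "AnnotationError",
    "RegionDerivationError",
    "load_annotations",
    "load_id_list",
    "derive_regions",
    "write_loci_bed",
    "write_regions_bed",
    "overlap_report",
]

_STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


class RegionDerivationError(ValueError):
    """Scoring regions cannot be derived for a locus (too short, or the
    left flank would run off the chromosome start)."""

    def __init__(self, locus_id: str, message: str):
        self.locus_id = locus_id
        super().__init__(f"{locus_id}: {message}")


@dataclass(frozen=True)
class GenomicInterval:
    """Strand-aware genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __len__(self) -> int:
        return self.length


@dataclass(frozen=True)
class PreMirnaLocus:
    """An annotated pre-miRNA hairpin with its mature products."""

    locus_id: str
    hairpin: GenomicInterval
    mature_ids: frozenset = field(default_factory=frozenset)
    is_mirtron: bool = False


@dataclass(frozen=True)
class RegionSet:
    """The three trimmed scoring intervals of one locus."""

    locus_id: str
    hairpin_core: GenomicInterval
    left_flank_core: GenomicInterval
    right_flank_core: GenomicInterval

    def flank_cores(self) -> tuple[GenomicInterval, GenomicInterval]:
        return (self.left_flank_core, self.right_flank_core)


def derive_regions(
    locus: PreMirnaLocus, flank_len: int = 100, trim: int = 5
) -> RegionSet:
    """Derive the hairpin core and the two flank cores of a locus.

    ``hairpin_core = [start+trim, end-trim)``;
    ``left_flank_core = [start-flank_len, start-trim)``;
    ``right_flank_core = [end+trim, end+flank_len)``.

    The construction depends only on the hairpin start/end: a minus-strand
    hairpin yields the same coordinates as its plus-strand mirror (the MPI
    is orientation-symmetric), only the upstream/downstream labelling of the
    flanks differs.
    """
    if flank_len <= trim:
        raise ValueError(f"flank_len ({flank_len}) must exceed trim ({trim})")
    hp = locus.hairpin
    if hp.length <= 2 * trim:
        raise RegionDerivationError(
            locus.locus_id,
            f"hairpin length {hp.length} too short for trim {trim} "
            f"(need length > {2 * trim})",
        )
    if hp.start < flank_len:
        raise RegionDerivationError(
            locus.locus_id,
            f"left flank would underflow chromosome start "
            f"(hairpin start {hp.start} < flank_len {flank_len})",
        )
    mk = lambda s, e: GenomicInterval(hp.chrom, s, e, hp.strand)
    return RegionSet(
        locus_id=locus.locus_id,
        hairpin_core=mk(hp.start + trim, hp.end - trim),
        left_flank_core=mk(hp.start - flank_len, hp.start - trim),
        right_flank_core=mk(hp.end + trim, hp.end + flank_len),
    )


# ---------------------------------------------------------------------------
# readers


def load_annotations(path, format: str | None = None) -> list[PreMirnaLocus]:
    """Read pri-miRNA loci from BED6 or miRBase-style GFF3.

    ``format`` is ``"bed6"`` or ``"gff3"``; when omitted it is inferred from
    the file extension.  GFF3 coordinates (1-based inclusive) are converted
    to the internal 0-based half-open convention, and ``mature_ids`` are
    populated from child ``miRNA`` features linked by ``Derives_from``.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix == ".bed":
            format = "bed6"
        elif suffix in (".gff", ".gff3"):
            format = "gff3"
        else:
            raise AnnotationError(
                f"cannot infer annotation format from extension {suffix!r}; "
                "pass format='bed6' or 'gff3'"
            )
    if format == "bed6":
        loci = _load_bed6(path)
    elif format == "gff3":
        loci = _load_gff3(path)
    else:
        raise AnnotationError(f"unknown annotation format {format!r}")
    seen = set()
    for locus in loci:
        if locus.locus_id in seen:
            raise AnnotationError(f"duplicate locus_id {locus.locus_id!r}")
        seen.add(locus.locus_id)
    return loci


def _load_bed6(path: Path) -> list[PreMirnaLocus]:
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(
                    f"{path}:{lineno}: expected >= 6 tab-separated BED fields, "
                    f"got {len(fields)}"
                )
            chrom, start, end, name, _score, strand = fields[:6]
            if strand not in _STRANDS:
                raise AnnotationError(
                    f"{path}:{lineno}: strand is required, got {strand!r}"
                )
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            loci.append(PreMirnaLocus(locus_id=name, hairpin=iv))
    return loci


def _load_gff3(path: Path) -> list[PreMirnaLocus]:
    import gffutils

    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises assorted parse errors
        raise AnnotationError(f"{path}: GFF3 parse failed: {exc}") from exc

    # map primary-transcript ID -> mature miRNA names (or IDs)
    matures: dict[str, set] = {}
    for feat in db.features_of_type("miRNA"):
        parents = feat.attributes.get("Derives_from", []) + feat.attributes.get(
            "Parent", []
        )
        label = (feat.attributes.get("Name") or feat.attributes.get("ID") or [feat.id])[0]
        for parent in parents:
            matures.setdefault(parent, set()).add(label)

    loci = []
    for feat in db.features_of_type("miRNA_primary_transcript"):
        if feat.strand not in _STRANDS:
            raise AnnotationError(
                f"{path}: feature {feat.id}: strand is required, got {feat.strand!r}"
            )
        name = (feat.attributes.get("Name") or [feat.id])[0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        loci.append(
            PreMirnaLocus(
                locus_id=name,
                hairpin=iv,
                mature_ids=frozenset(matures.get(feat.id, ())),
            )
        )
    return loci


def load_id_list(path) -> set:
    """Read a one-identifier-per-line list; '#' lines are comments."""
    ids = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            ids.add(line)
    return ids


# ---------------------------------------------------------------------------
# writers and reports


def write_loci_bed(loci: Iterable[PreMirnaLocus], path) -> None:
    """BED6 export of hairpin intervals (round-trips with the BED6 reader)."""
    with open(path, "w") as fh:
        for locus in loci:
            hp = locus.hairpin
            fh.write(
                f"{hp.chrom}\t{hp.start}\t{hp.end}\t{locus.locus_id}\t0\t{hp.strand}\n"
            )


def write_regions_bed(regions: Iterable[RegionSet], path) -> None:
    """BED6 export of derived scoring regions, three rows per locus."""
    with open(path, "w") as fh:
        for rs in regions:
            for iv, suffix in (
                (rs.hairpin_core, "hairpin"),
                (rs.left_flank_core, "flankL"),
                (rs.right_flank_core, "flankR"),
            ):
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"{rs.locus_id}.{suffix}\t0\t{iv.strand}\n"
                )


def overlap_report(
    loci: Sequence[PreMirnaLocus], flank_len: int = 100
) -> list[tuple[str, str]]:
    """Pairs of same-strand loci whose flank-extended footprints overlap.

    Clustered miRNAs can place a neighbouring hairpin inside a locus's flank;
    this report surfaces such pairs for inspection.  It is informational only
    and never filters loci.
    """
    pairs = []
    by_key: dict[tuple, list[PreMirnaLocus]] = {}
    for locus in loci:
        key = (locus.hairpin.chrom, locus.hairpin.strand)
        by_key.setdefault(key, []).append(locus)
    for group in by_key.values():
        group = sorted(group, key=lambda l: l.hairpin.start)
        for i, a in enumerate(group):
            a_end = a.hairpin.end + flank_len
            for b in group[i + 1 :]:
                if b.hairpin.start - flank_len >= a_end:
                    break
                pairs.append((a.locus_id, b.locus_id))
    return pairs
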