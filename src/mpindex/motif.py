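"""Basal UG motif detection in pri-miRNA precursor contexts.

The basal UG dinucleotide sits at the basal stem junction of a pri-miRNA
hairpin, anchored 14 nt upstream of the 5' end of the 5p mature miRNA
(positions -14/-13, counting -1 as the nucleotide immediately upstream).
It is associated with efficient Drosha recognition; precursors lacking it
are plausibly more sensitive to reduced Microprocessor levels.  Sequences
are taken in transcript (sense) orientation; T and U are equivalent and
case is ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .enrichment import two_sided_exact_2x2

__all__ = [
    "PrecursorContext",
    "MotifWindowError",
    "basal_ug_present",
    "load_contexts",
    "motif_depletion_report",
    "MotifReport",
]

_ALPHABET = set("ACGUN")
MOTIF_OFFSET = 14  # UG anchor: position -14 relative to the 5p 5' end


class MotifWindowError(ValueError):
    """The -14/-13 window does not exist in the supplied context."""


@dataclass(frozen=True)
class PrecursorContext:
    """Sense-orientation sequence covering a hairpin plus basal flank.

    ``fivep_offset`` is the 0-based index of the first nucleotide of the
    5p mature miRNA within ``sequence``.
    """

    locus_id: str
    sequence: str
    fivep_offset: int

    def __post_init__(self):
        norm = self.sequence.upper().replace("T", "U")
        bad = set(norm) - _ALPHABET
        if bad:
            raise ValueError(
                f"{self.locus_id}: invalid characters in sequence: {sorted(bad)}"
            )
        object.__setattr__(self, "_norm", norm)

    @property
    def normalized(self) -> str:
        return self._norm  # type: ignore[attr-defined]


def basal_ug_present(ctx: PrecursorContext, slack: int = 0) -> Optional[bool]:
    """True iff UG occupies positions -14/-13 upstream of the 5p 5' end.

    ``slack=1`` additionally accepts the dinucleotide shifted one position
    either way (annotation offsets of the Drosha cleavage site vary by one
    nucleotide across databases); default is the exact window.  Returns
    ``None`` (indeterminate) when an N falls inside the window.
    """
    if ctx.fivep_offset < MOTIF_OFFSET + slack:
        raise MotifWindowError(
            f"{ctx.locus_id}: fivep_offset {ctx.fivep_offset} leaves no "
            f"-{MOTIF_OFFSET + slack} window"
        )
    seq = ctx.normalized
    anchors = range(-slack, slack + 1)
    saw_n = False
    for shift in anchors:
        i = ctx.fivep_offset - MOTIF_OFFSET + shift
        window = seq[i : i + 2]
        if "N" in window:
            saw_n = True
            continue
        if window == "UG":
            return True
    return None if saw_n else False


def load_contexts(fasta_path, offsets_tsv) -> list[PrecursorContext]:
    """Read context sequences (FASTA) and 5p offsets (TSV locus_id, offset)."""
    from pyfaidx import Fasta

    offsets = {}
    with open(offsets_tsv) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            locus_id, off = line.split("\t")[:2]
            offsets[locus_id] = int(off)
    fasta = Fasta(str(fasta_path))
    contexts = []
    for name in fasta.keys():
        if name not in offsets:
            continue
        contexts.append(
            PrecursorContext(
                locus_id=name,
                sequence=str(fasta[name][:]),
                fivep_offset=offsets[name],
            )
        )
    return contexts


@dataclass
class MotifReport:
    """2x2 motif-by-group counts with a two-sided exact test."""

    table: list  # [[a_present, a_absent], [b_present, b_absent]]
    p_value: float
    indeterminate: list  # locus IDs excluded from the counts
    calls: pd.DataFrame  # locus_id, group, call


def motif_depletion_report(
    contexts: Iterable[PrecursorContext],
    group_a: set,
    group_b: set,
    slack: int = 0,
) -> MotifReport:
    """Compare basal-UG presence between two disjoint locus groups.

    Indeterminate contexts (N in the motif window) are excluded from the
    2x2 counts and listed separately.
    """
    group_a, group_b = set(group_a), set(group_b)
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if group_a & group_b:
        raise ValueError("groups must be disjoint")

    counts = {"a": [0, 0], "b": [0, 0]}
    indeterminate, rows = [], []
    for ctx in contexts:
        if ctx.locus_id in group_a:
            group = "a"
        elif ctx.locus_id in group_b:
            group = "b"
        else:
            continue
        call = basal_ug_present(ctx, slack=slack)
        if call is None:
            indeterminate.append(ctx.locus_id)
            label = "indeterminate"
        else:
            counts[group][0 if call else 1] += 1
            label = "present" if call else "absent"
        rows.append({"locus_id": ctx.locus_id, "group": group, "call": label})

    table = [counts["a"], counts["b"]]
    p = two_sided_exact_2x2(table)
    return MotifReport(
        table=table,
        p_value=p,
        indeterminate=indeterminate,
        calls=pd.DataFrame(rows, columns=["locus_id", "group", "call"]),
    )
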