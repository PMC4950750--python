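"""Genomic interval model shared by every pipeline stage.

Coordinates are 1-based and fully closed internally, matching how breakpoint
junctions are printed in the clinical-genomics literature (e.g. a deletion
written ``chr1:g.213396378-213592823`` spans end - start + 1 = 196,446 bp).
BED input/output converts to/from the on-disk 0-based half-open convention at
the boundary and nowhere else.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "GenomicInterval",
    "normalize_chrom",
    "parse_region",
    "interval_length",
    "overlap_bp",
    "contained_in",
    "read_bed",
    "write_bed",
]

_REGION_RE = re.compile(
    r"^(?P<chrom>[\w.]+?):(?:g\.)?(?P<start>[\d,]+)[-_](?P<end>[\d,]+)(?:\[[^\]]*\])?$"
)


def normalize_chrom(chrom: str) -> str:
    """Normalise a chromosome name to the ``chr``-prefixed dialect."""
    chrom = str(chrom).strip()
    if not chrom:
        raise ValueError("empty chromosome name")
    if chrom.lower().startswith("chr"):
        return "chr" + chrom[3:]
    return "chr" + chrom


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully closed genomic interval.

    Invariants: ``start >= 1`` and ``end >= start``; length is
    ``end - start + 1`` bp.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.start < 1:
            raise ValueError(f"interval start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} (end < start)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def parse_region(text: str) -> GenomicInterval:
    """Parse a printed region such as ``chr1:g.213,396,378-213,592,823[hg19]``.

    Accepts the plain ``chr4:94006145-94032105`` style as well; commas, the
    HGVS ``g.`` prefix and a trailing assembly tag are tolerated.
    """
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse region {text!r}")
    start = int(m.group("start").replace(",", ""))
    end = int(m.group("end").replace(",", ""))
    return GenomicInterval(m.group("chrom"), start, end)


def interval_length(iv: GenomicInterval) -> int:
    """Length of a closed interval in bp (``end - start + 1``)."""
    return iv.length


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of overlapping bp between two closed intervals (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    return max(0, hi - lo + 1)


def contained_in(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``a`` lies entirely within ``b`` (same chromosome)."""
    return a.chrom == b.chrom and b.start <= a.start and a.end <= b.end


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED4 into a frame of 1-based closed intervals.

    Columns: chrom, start, end (1-based closed) and name (empty string when the
    file has only three columns).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed BED line: {line!r}")
            chrom = normalize_chrom(parts[0])
            start0, end0 = int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else ""
            rows.append((chrom, start0 + 1, end0, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def write_bed(df: pd.DataFrame, path, name_col: str | None = "name") -> None:
    """Write a frame of 1-based closed intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            fields = [str(row.chrom), str(int(row.start) - 1), str(int(row.end))]
            if name_col and hasattr(row, name_col):
                fields.append(str(getattr(row, name_col)))
            fh.write("\t".join(fields) + "\n")
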