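"""Genomic intervals and window construction.

Internal convention is 0-based, half-open ``[start, end)``.  VCF positions
(1-based) and 1-based inclusive coordinates printed in reports are converted
at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np


@dataclass(frozen=True)
class GenomicInterval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval {self.chrom}:{self.start}-{self.end} has start >= end"
            )

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def contains_point(self, chrom: str, pos: int) -> bool:
        """Membership of a 0-based position."""
        return chrom == self.chrom and self.start <= pos < self.end

    def span_bp(self) -> int:
        return self.end - self.start


def span_bp_inclusive(start: int, end: int) -> int:
    """Span of a 1-based inclusive coordinate pair, in bp.

    Report-facing helper: printed genomic coordinates (e.g. browser-style
    ``chr7:30,297,170-30,364,571``) are 1-based inclusive, so the span is
    ``end - start + 1``.
    """
    if end < start:
        raise ValueError("end < start in 1-based inclusive coordinates")
    return end - start + 1


def span_kb_inclusive(start: int, end: int) -> float:
    """Span of a 1-based inclusive pair in kb, rounded to 2 decimals."""
    return round(span_bp_inclusive(start, end) / 1000.0, 2)


def make_windows(
    chrom_sizes: dict[str, int], size_bp: int, step_bp: int
) -> list[GenomicInterval]:
    """Tile sliding windows from position 0 of each chromosome.

    Windows are 0-based half-open; the last window of a chromosome is
    truncated at the chromosome end.  ``size_bp >= step_bp >= 1`` is
    required; equal size and step gives a non-overlapping tiling.
    """
    if not (size_bp >= step_bp >= 1):
        raise ValueError("require size_bp >= step_bp >= 1")
    out: list[GenomicInterval] = []
    for chrom, length in chrom_sizes.items():
        start = 0
        while start < length:
            out.append(GenomicInterval(chrom, start, min(start + size_bp, length)))
            start += step_bp
    return out


def windows_for_variants(
    chroms: np.ndarray, pos: np.ndarray, size_bp: int, step_bp: int
) -> list[GenomicInterval]:
    """Windows covering the extent of a variant list (1-based positions)."""
    sizes = {}
    for c in pd_unique(chroms):
        sizes[str(c)] = int(pos[chroms == c].max())  # 1-based max == 0-based end
    return make_windows(sizes, size_bp, step_bp)


def pd_unique(x: Iterable) -> list:
    """Order-preserving unique."""
    seen: dict = {}
    for v in x:
        seen.setdefault(v, None)
    return list(seen)


def assign_sites_to_windows(
    windows: list[GenomicInterval], chroms: np.ndarray, pos_1based: np.ndarray
) -> list[np.ndarray]:
    """Indices of variants falling in each window (half-open membership).

    Membership follows the windowing convention of the common VCF tools: the
    1-based position value is compared directly against the half-open window
    bounds, so a variant at 1-based 50,000 belongs to [25k, 75k) and
    [50k, 100k) but not [0, 50k).
    """
    p = np.asarray(pos_1based)
    chroms = np.asarray(chroms)
    out = []
    for w in windows:
        mask = (chroms == w.chrom) & (p >= w.start) & (p < w.end)
        out.append(np.flatnonzero(mask))
    return out


@dataclass
class WindowStatTrack:
    """Per-window scalar statistics.

    ``values`` maps a statistic name to one float per window; missing values
    are NaN, windows are never dropped.
    """

    windows: list[GenomicInterval]
    values: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if len(v) != len(self.windows):
                raise ValueError(f"track '{k}' length != number of windows")

    def add(self, name: str, vals: np.ndarray) -> None:
        vals = np.asarray(vals, dtype=float)
        if len(vals) != len(self.windows):
            raise ValueError("value length != number of windows")
        self.values[name] = vals

    def to_frame(self):
        import pandas as pd

        d = {
            "chrom": [w.chrom for w in self.windows],
            "start": [w.start for w in self.windows],
            "end": [w.end for w in self.windows],
        }
        d.update({k: v for k, v in self.values.items()})
        return pd.DataFrame(d)


def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3+ (0-based half-open); column 4 name, column 5 score."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), name, score))
    return out


def write_bed(intervals: list[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(f"{iv.score:g}")
            fh.write("\t".join(fields) + "\n")
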