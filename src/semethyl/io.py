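"""Readers/writers for CpG count data and genomic intervals.

All in-memory coordinates are 0-based half-open.  Conversion to/from
1-based file dialects (Bismark coverage) happens only at file boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "CpGSite",
    "GenomicInterval",
    "Methylome",
    "methylation_level",
    "merge_strand_counts",
    "read_bismark_coverage",
    "read_bedgraph",
    "write_coverage",
    "read_bed",
    "write_bed",
]


@dataclass(frozen=True)
class CpGSite:
    """Per-CpG read counts at a single genomic position (0-based)."""

    chrom: str
    pos: int
    meth: int
    unmeth: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")
        if self.meth < 0 or self.unmeth < 0:
            raise ValueError(f"negative read count at {self.chrom}:{self.pos}")

    @property
    def coverage(self) -> int:
        return self.meth + self.unmeth


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (start >= end)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def methylation_level(site: CpGSite) -> float:
    """Raw methylation level meth/(meth+unmeth); NaN when coverage is zero."""
    cov = site.meth + site.unmeth
    if cov == 0:
        return float("nan")
    return site.meth / cov


class Methylome:
    """Ordered per-CpG counts for one sample, stored as parallel arrays.

    Sites are kept strictly sorted by (chrom, pos); duplicate positions
    within a chromosome are rejected.
    """

    def __init__(
        self,
        chrom: Sequence[str] | np.ndarray,
        pos: Sequence[int] | np.ndarray,
        meth: Sequence[int] | np.ndarray,
        unmeth: Sequence[int] | np.ndarray,
        sample_id: str = "sample",
        tissue: str = "",
        condition: str = "normal",
    ) -> None:
        if condition not in ("normal", "cancer", "metastasis"):
            raise ValueError(f"unknown condition {condition!r}")
        self.sample_id = sample_id
        self.tissue = tissue
        self.condition = condition
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.meth = np.asarray(meth, dtype=np.int64)
        self.unmeth = np.asarray(unmeth, dtype=np.int64)
        n = len(self.pos)
        if not (len(self.chrom) == len(self.meth) == len(self.unmeth) == n):
            raise ValueError("column length mismatch")
        if n and (self.pos.min() < 0 or self.meth.min() < 0 or self.unmeth.min() < 0):
            raise ValueError("negative position or read count")
        self._sort()

    def _sort(self) -> None:
        if len(self.pos) == 0:
            return
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(len(order))):
            logger.warning("methylome %s not sorted; sorting on load", self.sample_id)
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.meth = self.meth[order]
            self.unmeth = self.unmeth[order]
        same = (self.chrom[1:] == self.chrom[:-1]) & (self.pos[1:] == self.pos[:-1])
        if same.any():
            i = int(np.flatnonzero(same)[0])
            raise ValueError(
                f"duplicate position {self.chrom[i]}:{self.pos[i]} in {self.sample_id}"
            )

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def coverage(self) -> np.ndarray:
        return self.meth + self.unmeth

    @property
    def levels(self) -> np.ndarray:
        """Raw per-site methylation levels; NaN at zero-coverage sites."""
        cov = self.coverage
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.meth / np.maximum(cov, 1), np.nan)

    @property
    def sites(self) -> Iterator[CpGSite]:
        for c, p, m, u in zip(self.chrom, self.pos, self.meth, self.unmeth):
            yield CpGSite(str(c), int(p), int(m), int(u))

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(str(c), None)
        return list(seen)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous slice of the arrays for each chromosome."""
        out: dict[str, slice] = {}
        if len(self) == 0:
            return out
        change = np.flatnonzero(self.chrom[1:] != self.chrom[:-1]) + 1
        bounds = [0, *change.tolist(), len(self)]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            out[str(self.chrom[lo])] = slice(lo, hi)
        return out

    def replace_counts(self, meth: np.ndarray, unmeth: np.ndarray) -> "Methylome":
        return Methylome(
            self.chrom, self.pos, meth, unmeth,
            sample_id=self.sample_id, tissue=self.tissue, condition=self.condition,
        )


def merge_strand_counts(m: Methylome) -> Methylome:
    """Pool counts of adjacent-position site pairs (p, p+1) onto position p.

    Greedy left-to-right: once a site is pooled into its left partner it
    cannot pair again.  Total meth/unmeth counts are conserved.
    """
    if len(m) == 0:
        return m
    chrom, pos = m.chrom, m.pos
    meth = m.meth.copy()
    unmeth = m.unmeth.copy()
    keep = np.ones(len(m), dtype=bool)
    i = 0
    n = len(m)
    while i < n - 1:
        if chrom[i] == chrom[i + 1] and pos[i + 1] == pos[i] + 1:
            meth[i] += meth[i + 1]
            unmeth[i] += unmeth[i + 1]
            keep[i + 1] = False
            i += 2
        else:
            i += 1
    return Methylome(
        chrom[keep], pos[keep], meth[keep], unmeth[keep],
        sample_id=m.sample_id, tissue=m.tissue, condition=m.condition,
    )


def read_bismark_coverage(path: str | Path, sample_id: str | None = None,
                          tissue: str = "", condition: str = "normal") -> Methylome:
    """Read a Bismark coverage file (1-based; converted to 0-based).

    Columns: chrom, start(1-based), end, percent methylation, meth count,
    unmeth count.  The percent column is ignored and recomputed from counts.
    """
    path = Path(path)
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[int] = []
    unmeths: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 tab-separated fields")
            try:
                start = int(parts[1])
                meth = int(parts[4])
                unmeth = int(parts[5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if start < 1 or meth < 0 or unmeth < 0:
                raise ValueError(f"{path}:{lineno}: negative count or position")
            chroms.append(parts[0])
            poss.append(start - 1)
            meths.append(meth)
            unmeths.append(unmeth)
    return Methylome(chroms, poss, meths, unmeths,
                     sample_id=sample_id or path.stem, tissue=tissue,
                     condition=condition)


def read_bedgraph(path: str | Path, sample_id: str | None = None) -> Methylome:
    """Read a 4-column bedGraph of methylation levels as pseudo-counts.

    The level is scaled to counts out of 100 reads so the data model is
    shared; use a real coverage file when counts matter.
    """
    path = Path(path)
    chroms: list[str] = []
    poss: list[int] = []
    meths: list[int] = []
    unmeths: list[int] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 tab-separated fields")
            level = float(parts[3])
            if not 0.0 <= level <= 1.0:
                raise ValueError(f"{path}:{lineno}: level {level} outside [0,1]")
            chroms.append(parts[0])
            poss.append(int(parts[1]))
            meths.append(round(level * 100))
            unmeths.append(100 - round(level * 100))
    return Methylome(chroms, poss, meths, unmeths, sample_id=sample_id or path.stem)


def write_coverage(m: Methylome, path: str | Path) -> None:
    """Write Bismark-style coverage (1-based, 6 columns)."""
    with open(path, "w") as fh:
        cov = m.coverage
        with np.errstate(invalid="ignore"):
            pct = np.where(cov > 0, 100.0 * m.meth / np.maximum(cov, 1), 0.0)
        for c, p, pc, mt, um in zip(m.chrom, m.pos, pct, m.meth, m.unmeth):
            fh.write(f"{c}\t{p + 1}\t{p + 1}\t{pc:g}\t{mt}\t{um}\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED4 intervals (0-based half-open)."""
    path = Path(path)
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start >= end")
            name = parts[3] if len(parts) > 3 else None
            out.append(GenomicInterval(parts[0], start, end, name))
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path,
              header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header is not None:
            fh.write(header.rstrip("\n") + "\n")
        for iv in intervals:
            if iv.name is not None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
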