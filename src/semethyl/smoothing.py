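"""Local-likelihood smoothing of CpG methylation levels.

The smoother is a degree-0 local likelihood fit for binomial counts: at
each CpG the smoothed level is the tricube-kernel- and coverage-weighted
mean of methylated reads over total reads within a window centered on the
site.  The window expands symmetrically until it holds at least
``min_cpgs`` covered sites, so sparse regions still receive estimates.
Chromosomes are never mixed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from .io import Methylome

logger = logging.getLogger(__name__)

__all__ = ["SmoothedMethylome", "smooth", "write_smoothed_bedgraph", "read_smoothed_bedgraph"]


class SmoothedMethylome(Methylome):
    """Methylome plus a per-site smoothed level in [0, 1]."""

    def __init__(self, *args, smoothed: np.ndarray, **kwargs) -> None:
        super().__init__(*args, **kwargs)
        self.smoothed = np.asarray(smoothed, dtype=float)
        if len(self.smoothed) != len(self):
            raise ValueError("smoothed column length mismatch")
        finite = self.smoothed[np.isfinite(self.smoothed)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("smoothed levels outside [0, 1]")

    @classmethod
    def from_methylome(cls, m: Methylome, smoothed: np.ndarray) -> "SmoothedMethylome":
        return cls(m.chrom, m.pos, m.meth, m.unmeth, smoothed=smoothed,
                   sample_id=m.sample_id, tissue=m.tissue, condition=m.condition)


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None) ** 3
    return w


def smooth(m: Methylome, half_window: int = 500, min_cpgs: int = 10) -> SmoothedMethylome:
    """Smooth per-CpG methylation levels along each chromosome.

    Parameters
    ----------
    m
        Input methylome (sorted).
    half_window
        Base half-width (bp) of the tricube kernel.
    min_cpgs
        Minimum number of covered CpGs per window; the window expands to
        one bp past the ``min_cpgs``-th nearest covered site when needed
        (tricube weight is zero exactly at the window edge).
    """
    if half_window <= 0:
        raise ValueError("half_window must be positive")
    if min_cpgs < 1:
        raise ValueError("min_cpgs must be >= 1")
    smoothed = np.full(len(m), np.nan)
    cov_all = m.coverage
    for chrom, sl in m.chrom_slices().items():
        pos = m.pos[sl].astype(float)
        meth = m.meth[sl].astype(float)
        cov = cov_all[sl].astype(float)
        n = len(pos)
        covered_idx = np.flatnonzero(cov > 0)
        if covered_idx.size == 0:
            logger.warning("chromosome %s has no covered CpGs; skipped", chrom)
            continue
        if n == 1:
            smoothed[sl] = meth[0] / cov[0] if cov[0] > 0 else 0.5
            if cov[0] == 0:
                logger.warning("single uncovered CpG on %s; smoothed set to 0.5", chrom)
            continue
        cpos = pos[covered_idx]
        out = np.empty(n)
        for i in range(n):
            p = pos[i]
            h = float(half_window)
            # strictly-inside window: tricube weight is 0 at |d| = h anyway
            lo = np.searchsorted(cpos, p - h, side="right")
            hi = np.searchsorted(cpos, p + h, side="left")
            if hi - lo < min_cpgs:
                d = np.abs(cpos - p)
                k = min(min_cpgs, len(cpos))
                h = max(h, float(np.partition(d, k - 1)[k - 1]) + 1.0)
                lo = np.searchsorted(cpos, p - h, side="right")
                hi = np.searchsorted(cpos, p + h, side="left")
            idx = covered_idx[lo:hi]
            k = _tricube((pos[idx] - p) / h)
            denom = float(np.dot(k, cov[idx]))
            if denom <= 0:
                # all in-window weight degenerate; fall back to nearest covered site
                j = covered_idx[np.argmin(np.abs(cpos - p))]
                out[i] = meth[j] / cov[j]
                continue
            out[i] = float(np.dot(k, meth[idx]) / denom)
        smoothed[sl] = np.clip(out, 0.0, 1.0)
    return SmoothedMethylome.from_methylome(m, smoothed)


def write_smoothed_bedgraph(sm: SmoothedMethylome, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, p, v in zip(sm.chrom, sm.pos, sm.smoothed):
            if np.isfinite(v):
                fh.write(f"{c}\t{p}\t{p + 1}\t{v:.6g}\n")


def read_smoothed_bedgraph(path: str | Path, sample_id: str | None = None) -> SmoothedMethylome:
    """Read a smoothed bedGraph back into a count-less SmoothedMethylome."""
    path = Path(path)
    chroms: list[str] = []
    poss: list[int] = []
    vals: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            chroms.append(parts[0])
            poss.append(int(parts[1]))
            vals.append(float(parts[3]))
    zeros = np.zeros(len(poss), dtype=np.int64)
    return SmoothedMethylome(chroms, poss, zeros, zeros, smoothed=np.array(vals),
                             sample_id=sample_id or path.stem)
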