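"""Detection of unusually large hypomethylated regions.

Candidate HMRs (mean smoothed methylation < 0.2) are sorted by genomic
size, size and rank are mapped onto (0, 1), the upper tail of the curve
is fitted as log(scaled size) ~ logit(scaled rank), and the size cutoff
is the point where the back-transformed curve has derivative 1.  Regions
above that point are "large" HMRs.  The procedure is per sample.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .hmm import HMR
from .smoothing import SmoothedMethylome

logger = logging.getLogger(__name__)

__all__ = [
    "RankedHMR",
    "ElbowFit",
    "select_candidates",
    "scale_rank",
    "fit_log_logit",
    "tangent_cutoff",
    "classify_large",
    "find_large_hmrs",
]


@dataclass(frozen=True)
class RankedHMR:
    hmr: HMR
    x: float  # scaled ascending-size rank, in (0, 1)
    y: float  # size / max size, in (0, 1]


@dataclass(frozen=True)
class ElbowFit:
    a: float       # intercept of log(y) on logit(x)
    b: float       # slope
    x_star: float  # tangent-slope-1 rank index
    size_cutoff: float  # bp, interpolated size at x_star


def _logit(x: np.ndarray | float) -> np.ndarray | float:
    return np.log(x) - np.log1p(-x)


def select_candidates(hmrs: Sequence[HMR], smoothed: SmoothedMethylome,
                      max_level: float = 0.2) -> list[HMR]:
    """Keep HMRs whose mean smoothed level over member CpGs is < max_level."""
    out: list[HMR] = []
    slices = smoothed.chrom_slices()
    for h in hmrs:
        sl = slices.get(h.interval.chrom)
        if sl is None:
            continue
        pos = smoothed.pos[sl]
        lo = np.searchsorted(pos, h.interval.start, side="left")
        hi = np.searchsorted(pos, h.interval.end, side="left")
        if hi <= lo:
            continue
        vals = smoothed.smoothed[sl][lo:hi]
        vals = vals[np.isfinite(vals)]
        if vals.size and float(vals.mean()) < max_level:
            out.append(h)
    return out


def scale_rank(candidates: Sequence[HMR]) -> list[RankedHMR]:
    """Ascending size sort; x_i = (i - 0.5)/n, y_i = size_i / max size.

    The half-rank offset keeps logit(x) finite at both ends.  Size ties
    are broken by (chrom, start).
    """
    n = len(candidates)
    if n < 2:
        raise ValueError("need at least 2 candidate HMRs to rank")
    ordered = sorted(candidates, key=lambda h: (h.size, h.interval.chrom, h.interval.start))
    ymax = ordered[-1].size
    return [RankedHMR(h, (i - 0.5) / n, h.size / ymax)
            for i, h in enumerate(ordered, start=1)]


def fit_log_logit(ranked: Sequence[RankedHMR], size_quantile: float = 0.90) -> ElbowFit:
    """OLS of log(y) on logit(x) over the upper size tail.

    The subset is regions with size strictly above the ``size_quantile``
    empirical quantile of sizes (on sorted data this is also the
    high-rank tail).  Returns the fit with the tangent point filled by
    :func:`tangent_cutoff`.
    """
    sizes = np.array([r.hmr.size for r in ranked], dtype=float)
    cut = np.quantile(sizes, size_quantile)
    subset = [r for r in ranked if r.hmr.size > cut]
    if len(subset) < 3:
        raise ValueError("fit subset has fewer than 3 points")
    x = np.array([r.x for r in subset])
    y = np.array([r.y for r in subset])
    if np.allclose(y, y[0]):
        raise ValueError("degenerate fit: all scaled sizes equal in subset")
    X = np.column_stack([np.ones_like(x), _logit(x)])
    coef, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    a, b = float(coef[0]), float(coef[1])
    x_star = tangent_cutoff(a, b)
    size_cutoff = math.exp(a + b * float(_logit(x_star))) * max(r.hmr.size for r in ranked)
    return ElbowFit(a=a, b=b, x_star=x_star, size_cutoff=size_cutoff)


def _slope(a: float, b: float, x: float) -> float:
    # d/dx exp(a + b*logit(x)) = exp(a + b*logit(x)) * b / (x(1-x))
    return math.exp(a + b * (math.log(x) - math.log1p(-x))) * b / (x * (1.0 - x))


def tangent_cutoff(a: float, b: float, lo: float = 0.5, hi: float = 1.0 - 1e-9,
                   tol: float = 1e-8) -> float:
    """Largest x in (lo, hi) where the fitted curve's derivative equals 1.

    A sign-scan over a fine grid locates bracketing intervals for
    g(x) = slope(x) - 1; bisection refines the largest root.  If the
    slope exceeds 1 on the whole interval the lower boundary is returned
    with a warning; if it never reaches 1 there are no large HMRs and
    1.0 is returned.
    """
    if b <= 0:
        raise ValueError("tangent cutoff requires a positive slope b")

    def g(x: float) -> float:
        return _slope(a, b, x) - 1.0

    grid = np.linspace(lo, hi, 4097)
    vals = np.array([g(x) for x in grid])
    sign_change = np.flatnonzero(np.sign(vals[:-1]) != np.sign(vals[1:]))
    if sign_change.size == 0:
        if vals[0] > 0:
            logger.warning("curve slope > 1 everywhere; cutoff at boundary %.3f", lo)
            return lo
        return 1.0
    i = int(sign_change[-1])
    xl, xr = float(grid[i]), float(grid[i + 1])
    fl = g(xl)
    while xr - xl > tol:
        xm = 0.5 * (xl + xr)
        fm = g(xm)
        if (fl <= 0) == (fm <= 0):
            xl, fl = xm, fm
        else:
            xr = xm
    return 0.5 * (xl + xr)


def classify_large(ranked: Sequence[RankedHMR], x_star: float) -> list[RankedHMR]:
    """Regions with scaled rank above the tangent point."""
    return [r for r in ranked if r.x > x_star]


def find_large_hmrs(hmrs: Sequence[HMR], smoothed: SmoothedMethylome,
                    max_level: float = 0.2, size_quantile: float = 0.90
                    ) -> tuple[list[RankedHMR], ElbowFit]:
    """End-to-end: candidate filter, scaling, fit, tangent classification."""
    candidates = select_candidates(hmrs, smoothed, max_level=max_level)
    ranked = scale_rank(candidates)
    fit = fit_log_logit(ranked, size_quantile=size_quantile)
    return classify_large(ranked, fit.x_star), fit
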