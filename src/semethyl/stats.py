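"""Association statistics: CpG class enrichment, windowed histone/
methylation summaries, target-gene assignment and expression models.

Exact-vs-approximate switchovers are fixed so results are reproducible:
the rank-sum test enumerates assignments when n1+n2 <= 12, Spearman's p
enumerates permutations when n <= 8; larger inputs use the standard
normal/t approximations (midrank tie handling throughout).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.stats import rankdata

from .io import GenomicInterval

__all__ = [
    "ContingencyTable2x2",
    "WindowRecord",
    "CorrelationResult",
    "classify_cpg",
    "fisher_exact",
    "window_stats",
    "rank_sum_test",
    "linear_model_signal",
    "spearman",
    "assign_target",
    "loglinear_expression",
    "bh_fdr",
]

HYPO_THRESHOLD = 0.33
HYPER_THRESHOLD = 0.66
RANKSUM_EXACT_N = 12
SPEARMAN_EXACT_N = 8


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


@dataclass(frozen=True)
class WindowRecord:
    interval: GenomicInterval
    mean_signal: float
    mean_meth: float      # NaN when the window has no CpG
    cpg_density: float    # CpGs per bp
    meth_class: str | None
    is_remainder: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    n: int


def classify_cpg(level: float) -> str:
    """hypo (< 0.33), hyper (> 0.66) or intermediate."""
    if not 0.0 <= level <= 1.0:
        raise ValueError(f"methylation level {level} outside [0, 1]")
    if level < HYPO_THRESHOLD:
        return "hypo"
    if level > HYPER_THRESHOLD:
        return "hyper"
    return "intermediate"


def fisher_exact(t: ContingencyTable2x2) -> tuple[float, float]:
    """Fisher's exact test for a 2x2 table.

    Odds ratio is the cross-product (a*d)/(b*c), Haldane-corrected
    (+0.5 to every cell) iff any cell is zero.  The two-sided p sums
    hypergeometric probabilities (margins fixed) of tables no more
    likely than the observed one.  A zero margin yields p = 1 and a
    NaN odds ratio.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return float("nan"), 1.0
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        oratio = (aa * dd) / (bb * cc)
    else:
        oratio = (a * d) / (b * c)
    n = r1 + r2
    lo = max(0, r1 - c2)
    hi = min(r1, c1)
    denom = (math.lgamma(r1 + 1) + math.lgamma(r2 + 1)
             + math.lgamma(c1 + 1) + math.lgamma(c2 + 1) - math.lgamma(n + 1))

    def logp(x: int) -> float:
        return (denom - math.lgamma(x + 1) - math.lgamma(r1 - x + 1)
                - math.lgamma(c1 - x + 1) - math.lgamma(r2 - c1 + x + 1))

    lp_obs = logp(a)
    p = 0.0
    for x in range(lo, hi + 1):
        lp = logp(x)
        if lp <= lp_obs + 1e-7:  # relative tolerance for float ties
            p += math.exp(lp)
    return oratio, min(p, 1.0)


def window_stats(signal_pos: np.ndarray, signal_val: np.ndarray,
                 sm_pos: np.ndarray, sm_level: np.ndarray,
                 region: GenomicInterval, width: int = 50) -> list[WindowRecord]:
    """Tile a region into fixed-width windows and average signal and methylation.

    ``signal_pos/val`` give a per-bp (or sparse per-position) signal
    track; ``sm_pos/level`` the smoothed CpG methylation.  Windows with
    no CpG carry NaN methylation and a None class.
    """
    signal_pos = np.asarray(signal_pos)
    signal_val = np.asarray(signal_val, dtype=float)
    sm_pos = np.asarray(sm_pos)
    sm_level = np.asarray(sm_level, dtype=float)
    out: list[WindowRecord] = []
    start = region.start
    while start < region.end:
        end = min(start + width, region.end)
        s_lo, s_hi = np.searchsorted(signal_pos, [start, end])
        m_lo, m_hi = np.searchsorted(sm_pos, [start, end])
        mean_signal = float(signal_val[s_lo:s_hi].mean()) if s_hi > s_lo else float("nan")
        n_cpg = m_hi - m_lo
        if n_cpg > 0:
            mean_meth = float(sm_level[m_lo:m_hi].mean())
            meth_class = classify_cpg(mean_meth)
        else:
            mean_meth = float("nan")
            meth_class = None
        out.append(WindowRecord(
            interval=GenomicInterval(region.chrom, start, end),
            mean_signal=mean_signal,
            mean_meth=mean_meth,
            cpg_density=n_cpg / (end - start),
            meth_class=meth_class,
            is_remainder=(end - start) != width,
        ))
        start = end
    return out


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Wilcoxon rank-sum test (midrank ties); exact when n1+n2 <= 12.

    Returns (W = rank sum of x, two-sided p).  The exact p enumerates
    all C(n1+n2, n1) assignments of the pooled values; otherwise a
    normal approximation with tie correction is used (no continuity
    correction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.allclose(pooled, pooled[0]):
        ranks = rankdata(pooled)
        return float(ranks[:x.size].sum()), 1.0
    ranks = rankdata(pooled)
    n1, n2 = x.size, y.size
    w = float(ranks[:n1].sum())
    if n1 + n2 <= RANKSUM_EXACT_N:
        total = 0
        lower = 0
        upper = 0
        for comb in itertools.combinations(range(n1 + n2), n1):
            ws = ranks[list(comb)].sum()
            total += 1
            if ws <= w + 1e-9:
                lower += 1
            if ws >= w - 1e-9:
                upper += 1
        p = min(1.0, 2.0 * min(lower / total, upper / total))
        return w, p
    n = n1 + n2
    mean = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return w, 1.0
    z = (w - mean) / math.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return w, min(p, 1.0)


def linear_model_signal(windows: Sequence[WindowRecord]) -> dict[str, float]:
    """OLS of window signal on methylation status (hyper=1) and CpG density.

    Windows without a hypo/hyper class or without signal are dropped.
    Returns intercept, status and density coefficients plus the t-based
    two-sided p of the status term.
    """
    usable = [w for w in windows
              if w.meth_class in ("hypo", "hyper") and np.isfinite(w.mean_signal)]
    if len(usable) < 3:
        raise ValueError("need >= 3 classified windows")
    status = np.array([1.0 if w.meth_class == "hyper" else 0.0 for w in usable])
    if status.min() == status.max():
        raise ValueError("both methylation statuses must be present")
    dens = np.array([w.cpg_density for w in usable])
    ysig = np.array([w.mean_signal for w in usable])
    X = np.column_stack([np.ones_like(status), status, dens])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design matrix")
    coef, _, _, _ = np.linalg.lstsq(X, ysig, rcond=None)
    resid = ysig - X @ coef
    dof = len(usable) - X.shape[1]
    if dof <= 0:
        raise ValueError("not enough windows for inference")
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = math.sqrt(cov[1, 1])
    if se == 0:
        p_status = 0.0 if coef[1] != 0 else 1.0
    else:
        tval = coef[1] / se
        p_status = float(2.0 * sps.t.sf(abs(tval), dof))
    return {"intercept": float(coef[0]), "status": float(coef[1]),
            "density": float(coef[2]), "p_status": p_status, "n": len(usable)}


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = rankdata(x)
    ry = rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        return float("nan")
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman correlation (midranks); exact permutation p when n <= 8."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    n = x.size
    rho = _spearman_rho(x, y)
    if not np.isfinite(rho):
        return CorrelationResult(rho=float("nan"), p=float("nan"), n=n)
    if n <= SPEARMAN_EXACT_N:
        ry = rankdata(y)
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = _spearman_rho(x, ry[list(perm)])
            total += 1
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        return CorrelationResult(rho=rho, p=count / total, n=n)
    if abs(rho) >= 1.0:
        return CorrelationResult(rho=rho, p=0.0, n=n)
    tval = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * sps.t.sf(abs(tval), n - 2))
    return CorrelationResult(rho=rho, p=p, n=n)


def assign_target(se: SuperEnhancer, tss_list: Sequence[tuple[str, str, int]],
                  max_distance: int = 1_000_000) -> str | None:
    """Closest-TSS target gene within max_distance of the SE boundary.

    ``tss_list`` holds (gene, chrom, tss_pos) records where tss_pos is
    the most upstream base across the gene's transcripts.  Distance is 0
    for a TSS inside the SE; ties break to the smaller coordinate.
    """
    iv = se.interval
    best: tuple[int, int, str] | None = None
    for gene, chrom, pos in tss_list:
        if chrom != iv.chrom:
            continue
        if iv.start <= pos < iv.end:
            dist = 0
        elif pos < iv.start:
            dist = iv.start - pos
        else:
            dist = pos - iv.end + 1
        key = (dist, pos, gene)
        if best is None or key < best:
            best = key
    if best is None or best[0] > max_distance:
        return None
    return best[2]


def loglinear_expression(expr: Sequence[float], meth: Sequence[float]
                         ) -> tuple[float, float]:
    """OLS of log(expr + 1) on average SE methylation; returns (slope, p)."""
    expr = np.asarray(expr, dtype=float)
    meth = np.asarray(meth, dtype=float)
    if expr.size != meth.size or expr.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if expr.min() < 0:
        raise ValueError("expression must be non-negative")
    if np.allclose(meth, meth[0]):
        raise ValueError("degenerate predictor: constant methylation")
    yv = np.log1p(expr)
    X = np.column_stack([np.ones_like(meth), meth])
    coef, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ coef
    dof = expr.size - 2
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(X.T @ X)
    se = math.sqrt(cov[1, 1])
    if se == 0:
        p = 0.0 if coef[1] != 0 else 1.0
    else:
        p = float(2.0 * sps.t.sf(abs(coef[1] / se), dof))
    return float(coef[1]), p


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(n)
    out[order] = adj
    return out
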