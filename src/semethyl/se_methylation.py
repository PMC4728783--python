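"""Super-enhancer DNA methylation quantification.

Covers flank extension with scaled coordinates, per-SE average
methylation and category assignment, base-pair HMR occupancy, delta
occupancy differential calls, tissue-specificity calls, the paired
flank-versus-inside reduction test, and array-based validation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io import GenomicInterval, Methylome
from .hmm import HMR
from .smoothing import SmoothedMethylome
from .stats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "SuperEnhancer",
    "ExtendedSE",
    "OccupancyRecord",
    "DeltaOccupancy",
    "extend_and_scale",
    "profile",
    "average_methylation",
    "categorize",
    "se_coverage_filter",
    "occupancy",
    "delta_occupancy",
    "call_tissue_specific",
    "flank_inside_reduction",
    "array_validate",
]

CATEGORY_EDGES = (0.25, 0.50, 0.75)  # Q1 < .25 <= Q2 < .50 <= Q3 < .75 <= Q4


@dataclass(frozen=True)
class SuperEnhancer:
    interval: GenomicInterval
    tissue: str = ""
    se_id: str = ""
    target_gene: str | None = None

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class ExtendedSE:
    """SE plus 50 % flanks and the linear scaled-coordinate map.

    scaled(center) = 0, scaled(SE edges) = -1/+1, scaled(extended edges)
    = -2/+2.  The map is anchored to the unclipped geometry even when
    the left extension is clipped at position 0.
    """

    se: SuperEnhancer
    extended: GenomicInterval

    @property
    def center(self) -> float:
        return 0.5 * (self.se.interval.start + self.se.interval.end)

    def scaled(self, pos: int | float | np.ndarray) -> float | np.ndarray:
        half = self.se.length / 2.0
        return (np.asarray(pos, dtype=float) - self.center) / half


def extend_and_scale(se: SuperEnhancer) -> ExtendedSE:
    """Extend by 50 % of the SE length on each side (floor left, ceil right)."""
    iv = se.interval
    length = len(iv)
    left = length // 2
    right = length - left  # ceil(L/2)
    start = iv.start - left
    if start < 0:
        logger.warning("extension of %s clipped at chromosome start", se.se_id or iv)
        start = 0
    return ExtendedSE(se=se, extended=GenomicInterval(iv.chrom, start, iv.end + right, iv.name))


def _sites_in(sm: SmoothedMethylome, iv: GenomicInterval) -> tuple[np.ndarray, np.ndarray]:
    """(positions, smoothed levels) of CpGs inside a half-open interval."""
    sl = sm.chrom_slices().get(iv.chrom)
    if sl is None:
        return np.empty(0, dtype=np.int64), np.empty(0)
    pos = sm.pos[sl]
    lo = np.searchsorted(pos, iv.start, side="left")
    hi = np.searchsorted(pos, iv.end, side="left")
    return pos[lo:hi], sm.smoothed[sl][lo:hi]


def profile(se: SuperEnhancer, sm: SmoothedMethylome) -> list[tuple[float, float]]:
    """Per-CpG (scaled position, smoothed level) over the extended SE."""
    ext = extend_and_scale(se)
    pos, vals = _sites_in(sm, ext.extended)
    ok = np.isfinite(vals)
    if not ok.any():
        logger.warning("no covered CpGs in extended SE %s", se.se_id or se.interval)
        return []
    scaled = ext.scaled(pos[ok])
    return list(zip(np.atleast_1d(scaled).tolist(), vals[ok].tolist()))


def average_methylation(se: SuperEnhancer, sm: SmoothedMethylome) -> float:
    """Unweighted mean smoothed level over CpGs strictly inside the SE; NaN if none."""
    _, vals = _sites_in(sm, se.interval)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def categorize(mean: float) -> str | None:
    """Q1..Q4 bin of an average methylation level (left-closed bins)."""
    if not np.isfinite(mean):
        return None
    if mean < CATEGORY_EDGES[0]:
        return "Q1"
    if mean < CATEGORY_EDGES[1]:
        return "Q2"
    if mean < CATEGORY_EDGES[2]:
        return "Q3"
    return "Q4"


def se_coverage_filter(se: SuperEnhancer, m: Methylome, min_frac: float = 0.5,
                       registry: Sequence[int] | None = None) -> bool:
    """True iff the fraction of SE CpGs with coverage >= 1 exceeds min_frac.

    ``registry`` optionally lists all CpG positions in the SE (e.g. from
    the reference); without it the observed sites are the denominator.
    """
    sl = m.chrom_slices().get(se.interval.chrom)
    if sl is None:
        return False
    pos = m.pos[sl]
    lo = np.searchsorted(pos, se.interval.start, side="left")
    hi = np.searchsorted(pos, se.interval.end, side="left")
    covered = set(pos[lo:hi][(m.coverage[sl][lo:hi] > 0)].tolist())
    if registry is not None:
        universe = [p for p in registry if se.interval.start <= p < se.interval.end]
    else:
        universe = pos[lo:hi].tolist()
    if not universe:
        logger.warning("no CpGs known for SE %s", se.se_id or se.interval)
        return False
    frac = sum(1 for p in universe if p in covered) / len(universe)
    return frac > min_frac


@dataclass(frozen=True)
class OccupancyRecord:
    se_id: str
    sample_id: str
    occupancy: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0 + 1e-12:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


@dataclass(frozen=True)
class DeltaOccupancy:
    se_id: str
    delta: float
    label: str  # hypomethylated | hypermethylated | unchanged


def _union_overlap(iv: GenomicInterval, hmrs: Sequence[HMR]) -> int:
    """Base pairs of iv covered by the union of HMR intervals."""
    segs = sorted((max(h.interval.start, iv.start), min(h.interval.end, iv.end))
                  for h in hmrs
                  if h.interval.chrom == iv.chrom
                  and h.interval.start < iv.end and h.interval.end > iv.start)
    total = 0
    cur_s: int | None = None
    cur_e = 0
    for s, e in segs:
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_s is not None:
        total += cur_e - cur_s
    return total


def occupancy(se: SuperEnhancer, hmrs: Sequence[HMR], sample_id: str = "") -> OccupancyRecord:
    """Fraction of the SE length covered by the union of HMRs (bp fraction)."""
    frac = _union_overlap(se.interval, hmrs) / se.length
    return OccupancyRecord(se_id=se.se_id or str(se.interval), sample_id=sample_id,
                           occupancy=frac)


def delta_occupancy(occ_cancer: OccupancyRecord, occ_normal: OccupancyRecord,
                    threshold: float = 0.25) -> DeltaOccupancy:
    """delta = cancer - normal; positive delta means methylation loss in cancer."""
    if occ_cancer.se_id != occ_normal.se_id:
        raise ValueError(f"se_id mismatch: {occ_cancer.se_id} vs {occ_normal.se_id}")
    delta = occ_cancer.occupancy - occ_normal.occupancy
    if delta > threshold:
        label = "hypomethylated"
    elif delta < -threshold:
        label = "hypermethylated"
    else:
        label = "unchanged"
    return DeltaOccupancy(se_id=occ_cancer.se_id, delta=delta, label=label)


def call_tissue_specific(occ_matrix: Mapping[str, Mapping[str, float]],
                         abs_thr: float = 0.20, diff_thr: float = 0.10,
                         other_agg: str = "mean") -> dict[str, list[str]]:
    """Tissue-specific SE sets from an SE x tissue occupancy matrix.

    ``occ_matrix`` maps se_id -> {tissue: occupancy}.  An SE is specific
    to tissue t iff occupancy(t) > abs_thr and occupancy(t) minus the
    aggregate (mean or max) of the other tissues' occupancies > diff_thr.
    """
    if other_agg not in ("mean", "max"):
        raise ValueError("other_agg must be 'mean' or 'max'")
    agg = np.mean if other_agg == "mean" else np.max
    tissues: set[str] = set()
    for occs in occ_matrix.values():
        tissues.update(occs)
    if len(tissues) < 2:
        raise ValueError("need occupancies for at least 2 tissues")
    out: dict[str, list[str]] = {t: [] for t in sorted(tissues)}
    for se_id, occs in occ_matrix.items():
        for t in sorted(tissues):
            if t not in occs:
                logger.info("SE %s missing occupancy for %s; skipped", se_id, t)
                continue
            others = [occs[o] for o in occs if o != t]
            if not others:
                continue
            if occs[t] > abs_thr and occs[t] - float(agg(others)) > diff_thr:
                out[t].append(se_id)
    return out


def flank_inside_reduction(sm_a: SmoothedMethylome, sm_b: SmoothedMethylome,
                           ses: Sequence[SuperEnhancer]) -> tuple[float, float, int]:
    """Paired t-test of the flank-minus-inside methylation reduction.

    For each SE and sample the reduction is mean smoothed level in the
    flanks minus mean level inside the SE; reductions are paired across
    SEs between the two samples.  Returns (t, two-sided p, n pairs).
    """
    r_a: list[float] = []
    r_b: list[float] = []
    for se in ses:
        vals = []
        for sm in (sm_a, sm_b):
            ext = extend_and_scale(se)
            pos, lv = _sites_in(sm, ext.extended)
            ok = np.isfinite(lv)
            pos, lv = pos[ok], lv[ok]
            inside = (pos >= se.interval.start) & (pos < se.interval.end)
            if inside.sum() == 0 or (~inside).sum() == 0:
                vals = []
                break
            vals.append(float(lv[~inside].mean()) - float(lv[inside].mean()))
        if vals:
            r_a.append(vals[0])
            r_b.append(vals[1])
    n = len(r_a)
    if n < 2:
        raise ValueError("need >= 2 SEs with flank and inside CpGs in both samples")
    diff = np.asarray(r_b) - np.asarray(r_a)
    if np.allclose(diff, diff[0]):
        if abs(diff[0]) < 1e-12:
            return 0.0, 1.0, n
        raise ValueError("zero variance of paired differences; t undefined")
    t, p = stats.ttest_rel(r_b, r_a)
    return float(t), float(p), n


def array_validate(beta_table: Mapping[str, np.ndarray],
                   probe_counts: Mapping[str, int],
                   group_labels: Sequence[int],
                   min_probes: int = 3,
                   beta_max: float = 0.33,
                   fdr_max: float = 0.05) -> dict[str, str]:
    """Array-based validation verdict per SE.

    ``beta_table`` maps se_id -> per-sample mean beta values (averaged
    over the SE's probes); ``probe_counts`` gives the number of probes
    behind each mean; ``group_labels`` marks target-group samples with 1.
    SEs with fewer than ``min_probes`` probes are 'not testable'; the
    rest are t-tested target vs other samples, BH-adjusted across SEs,
    and 'validated' iff target mean beta < beta_max and FDR < fdr_max.
    """
    labels = np.asarray(group_labels)
    verdicts: dict[str, str] = {}
    testable: list[str] = []
    pvals: list[float] = []
    for se_id, betas in beta_table.items():
        if probe_counts.get(se_id, 0) < min_probes:
            verdicts[se_id] = "not testable"
            continue
        betas = np.asarray(betas, dtype=float)
        a = betas[labels == 1]
        b = betas[labels == 0]
        if a.size < 2 or b.size < 2:
            verdicts[se_id] = "not testable"
            continue
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and math.isclose(a[0], b[0]):
            p = 1.0
        else:
            _, p = stats.ttest_ind(a, b)
            if not np.isfinite(p):
                p = 1.0
        testable.append(se_id)
        pvals.append(float(p))
    if testable:
        fdrs = bh_fdr(np.asarray(pvals))
        for se_id, fdr in zip(testable, fdrs):
            betas = np.asarray(beta_table[se_id], dtype=float)
            target_mean = float(betas[labels == 1].mean())
            verdicts[se_id] = ("validated"
                               if target_mean < beta_max and fdr < fdr_max
                               else "not validated")
    return verdicts
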