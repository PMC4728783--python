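"""Synthetic WGBS-like data with full ground truth.

Generates CpG positions (geometric gaps), two-state beta-binomial count
data over a hidden low/high segmentation, super-enhancers with
unmethylated edges and category structure, cancer methylomes with global
and focal shifts, correlated histone tracks and anti-correlated target
expression.  Every generator is deterministic given the config seed, and
the truth round-trips through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .hmm import HMR
from .io import GenomicInterval, Methylome
from .se_methylation import SuperEnhancer

__all__ = [
    "SimConfig",
    "TruthSet",
    "SimDataset",
    "simulate_positions",
    "simulate_methylome",
    "implant_background_hmrs",
    "implant_superenhancers",
    "apply_cancer_shift",
    "simulate_histone_track",
    "simulate_expression",
    "simulate_dataset",
    "simulate_large_hmr_mixture",
    "true_low_intervals_as_hmrs",
]

# category -> target mean methylation inside the SE; Q1 sits at the low-state
# mean because kernel smoothing bleeds flank methylation across SE edges
_CATEGORY_TARGET = {"Q1": 0.10, "Q2": 0.375, "Q3": 0.625, "Q4": 0.85}


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 1
    chrom_len: int = 2_000_000
    cpg_gap_mean: float = 100.0
    coverage_mean: float = 14.0        # Poisson reads per CpG
    background_mean: float = 0.75      # high-state beta-binomial mean
    hmr_mean: float = 0.10             # low-state mean
    concentration: float = 17.0        # alpha+beta of the within-state beta
    n_background_hmrs: int = 40
    background_hmr_len: int = 1500
    n_ses: int = 24
    se_len: int = 4000
    global_drop: float = 0.0           # additive drop of both state means in cancer
    focal_delta: float = 0.4           # |delta occupancy| of focally shifted SEs
    fraction_focal: float = 0.5        # fraction of SEs focally shifted in cancer
    focal_mode: str = "both"           # both | hypo | hyper
    categories: tuple[str, ...] = ("Q1", "Q2", "Q3", "Q4")
    histone_scale: float = 5.0
    histone_noise: float = 0.5
    expr_base: float = 2.0
    expr_slope: float = 3.0
    expr_noise: float = 0.3

    def __post_init__(self) -> None:
        for v in (self.background_mean, self.hmr_mean):
            if not 0.0 < v < 1.0:
                raise ValueError("state means must lie in (0, 1)")
        if self.hmr_mean >= self.background_mean:
            raise ValueError("hmr_mean must be below background_mean")


@dataclass
class TruthSet:
    """Ground truth for one simulated dataset."""

    low_intervals: dict[str, dict[str, list[tuple[int, int]]]] = field(default_factory=dict)
    se_records: list[dict] = field(default_factory=list)
    occupancy: dict[str, dict[str, float]] = field(default_factory=dict)
    delta_labels: dict[str, str] = field(default_factory=dict)
    expression: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def ses(self) -> list[SuperEnhancer]:
        return [SuperEnhancer(
            interval=GenomicInterval(r["chrom"], r["start"], r["end"], r["se_id"]),
            tissue=r.get("tissue", ""), se_id=r["se_id"],
            target_gene=r.get("target_gene")) for r in self.se_records]

    def category(self, se_id: str) -> str:
        for r in self.se_records:
            if r["se_id"] == se_id:
                return r["category"]
        raise KeyError(se_id)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        t = cls(**d)
        t.low_intervals = {
            s: {c: [tuple(iv) for iv in ivs] for c, ivs in per.items()}
            for s, per in t.low_intervals.items()}
        return t


@dataclass
class SimDataset:
    config: SimConfig
    normal: Methylome
    cancer: Methylome | None
    ses: list[SuperEnhancer]
    truth: TruthSet


def simulate_positions(cfg: SimConfig, rng: np.random.Generator | None = None
                       ) -> dict[str, np.ndarray]:
    """CpG positions per chromosome from cumulative geometric gaps."""
    rng = rng or np.random.default_rng(cfg.seed)
    out: dict[str, np.ndarray] = {}
    for i in range(cfg.n_chroms):
        chrom = f"chr{i + 1}"
        n_guess = int(cfg.chrom_len / cfg.cpg_gap_mean * 1.3) + 100
        gaps = rng.geometric(1.0 / cfg.cpg_gap_mean, size=n_guess)
        pos = np.cumsum(gaps)
        while pos[-1] < cfg.chrom_len:
            extra = rng.geometric(1.0 / cfg.cpg_gap_mean, size=n_guess)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra)])
        out[chrom] = pos[pos < cfg.chrom_len].astype(np.int64)
    return out


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _in_intervals(pos: np.ndarray, ivs: list[tuple[int, int]]) -> np.ndarray:
    if not ivs:
        return np.zeros(len(pos), dtype=bool)
    flat = np.array(_merge_intervals(ivs)).ravel()
    return np.searchsorted(flat, pos, side="right") % 2 == 1


def snap_intervals_to_sites(positions: dict[str, np.ndarray],
                            intervals: dict[str, list[tuple[int, int]]],
                            ) -> dict[str, list[tuple[int, int]]]:
    """Snap each interval to [first CpG inside, last CpG inside + 1].

    Matches the HMR extraction convention so truth and calls share a
    coordinate convention; intervals containing no CpG are dropped.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in intervals.items():
        pos = positions.get(chrom)
        snapped: list[tuple[int, int]] = []
        if pos is None:
            continue
        for s, e in _merge_intervals(list(ivs)):
            lo = int(np.searchsorted(pos, s, side="left"))
            hi = int(np.searchsorted(pos, e, side="left"))
            if hi > lo:
                snapped.append((int(pos[lo]), int(pos[hi - 1]) + 1))
        out[chrom] = snapped
    return out


def simulate_methylome(positions: dict[str, np.ndarray],
                       low_intervals: dict[str, list[tuple[int, int]]],
                       cfg: SimConfig,
                       rng: np.random.Generator,
                       sample_id: str = "normal",
                       condition: str = "normal",
                       global_drop: float = 0.0,
                       bg_overrides: dict[str, list[tuple[int, int, float]]] | None = None,
                       ) -> Methylome:
    """Beta-binomial counts over the hidden segmentation.

    ``global_drop`` lowers BOTH state means additively (clipped to
    [0.02, 0.98]) so that flank-minus-inside methylation differences are
    invariant under a purely global shift.  ``bg_overrides`` replaces
    the high-state mean inside specific intervals (used for Q4 SEs).
    """
    chroms: list[np.ndarray] = []
    poss: list[np.ndarray] = []
    meths: list[np.ndarray] = []
    unmeths: list[np.ndarray] = []
    for chrom in sorted(positions):
        pos = positions[chrom]
        n = len(pos)
        mean = np.full(n, cfg.background_mean)
        if bg_overrides:
            for s, e, m0 in bg_overrides.get(chrom, []):
                mean[(pos >= s) & (pos < e)] = m0
        low = _in_intervals(pos, low_intervals.get(chrom, []))
        mean[low] = cfg.hmr_mean
        mean = np.clip(mean - global_drop, 0.02, 0.98)
        a = mean * cfg.concentration
        b = (1.0 - mean) * cfg.concentration
        p = rng.beta(a, b)
        cov = rng.poisson(cfg.coverage_mean, size=n)
        meth = rng.binomial(cov, p)
        chroms.append(np.full(n, chrom, dtype=object))
        poss.append(pos)
        meths.append(meth)
        unmeths.append(cov - meth)
    return Methylome(np.concatenate(chroms), np.concatenate(poss),
                     np.concatenate(meths), np.concatenate(unmeths),
                     sample_id=sample_id, condition=condition)


def implant_background_hmrs(cfg: SimConfig, rng: np.random.Generator,
                            exclude: dict[str, list[tuple[int, int]]] | None = None,
                            ) -> dict[str, list[tuple[int, int]]]:
    """Random non-overlapping low intervals outside excluded regions."""
    exclude = exclude or {}
    out: dict[str, list[tuple[int, int]]] = {}
    per_chrom = max(1, cfg.n_background_hmrs // cfg.n_chroms)
    for i in range(cfg.n_chroms):
        chrom = f"chr{i + 1}"
        placed: list[tuple[int, int]] = []
        banned = _merge_intervals(list(exclude.get(chrom, [])))
        attempts = 0
        while len(placed) < per_chrom and attempts < per_chrom * 200:
            attempts += 1
            length = max(200, int(rng.normal(cfg.background_hmr_len,
                                             cfg.background_hmr_len / 4)))
            start = int(rng.integers(0, max(1, cfg.chrom_len - length)))
            cand = (start, start + length)
            clash = any(cand[0] < e and cand[1] > s for s, e in banned + placed)
            if not clash:
                placed.append(cand)
        out[chrom] = sorted(placed)
    return out


def implant_superenhancers(cfg: SimConfig, rng: np.random.Generator,
                           categories: Sequence[str] | None = None,
                           ) -> tuple[list[SuperEnhancer], dict[str, list[tuple[int, int]]],
                                      dict[str, list[tuple[int, int, float]]],
                                      dict[str, float], dict[str, str]]:
    """Place SEs with hypomethylated edges realizing the target categories.

    Returns (ses, low intervals, background overrides, true occupancy,
    category per SE).  Each SE occupies a regular slot (with jitter) so
    extended flanks never overlap; its low-state occupancy fraction f is
    chosen so the expected mean methylation hits the category target,
    implanted as two edge segments of length f*L/2.
    """
    per_chrom = max(1, cfg.n_ses // cfg.n_chroms)
    ses: list[SuperEnhancer] = []
    low: dict[str, list[tuple[int, int]]] = {}
    overrides: dict[str, list[tuple[int, int, float]]] = {}
    occ: dict[str, float] = {}
    cats: dict[str, str] = {}
    cat_cycle = categories or ("Q1", "Q2", "Q3", "Q4")
    k = 0
    for i in range(cfg.n_chroms):
        chrom = f"chr{i + 1}"
        slot = cfg.chrom_len // per_chrom
        if slot < 3 * cfg.se_len:
            raise ValueError("chromosome too short for requested SEs with flanks")
        low[chrom] = []
        overrides[chrom] = []
        for j in range(per_chrom):
            margin = cfg.se_len  # room for 50 % flanks plus slack
            lo_bound = j * slot + margin
            hi_bound = (j + 1) * slot - margin - cfg.se_len
            start = int(rng.integers(lo_bound, max(lo_bound + 1, hi_bound)))
            end = start + cfg.se_len
            se_id = f"SE{k + 1}"
            cat = cat_cycle[k % len(cat_cycle)]
            se = SuperEnhancer(GenomicInterval(chrom, start, end, se_id),
                               tissue="sim", se_id=se_id, target_gene=f"GENE{k + 1}")
            target = _CATEGORY_TARGET[cat]
            bg = cfg.background_mean
            if cat == "Q4":
                bg = 0.85
                overrides[chrom].append((start, end, bg))
                f = 0.0
            else:
                f = (bg - target) / (bg - cfg.hmr_mean)
            f = float(np.clip(f, 0.0, 0.98))
            if f > 0:
                edge = int(round(f * cfg.se_len / 2))
                low[chrom].append((start, start + edge))
                low[chrom].append((end - edge, end))
                occ[se_id] = 2 * edge / cfg.se_len
            else:
                occ[se_id] = 0.0
            cats[se_id] = cat
            ses.append(se)
            k += 1
    return ses, low, overrides, occ, cats


def apply_cancer_shift(ses: Sequence[SuperEnhancer],
                       normal_low: dict[str, list[tuple[int, int]]],
                       normal_occ: dict[str, float],
                       cats: dict[str, str],
                       cfg: SimConfig,
                       rng: np.random.Generator,
                       ) -> tuple[dict[str, list[tuple[int, int]]], dict[str, float],
                                  dict[str, str]]:
    """Cancer segmentation: focal occupancy shifts of ±focal_delta.

    Hypomethylated SEs gain a central low segment of delta*L; hyper-
    methylated SEs lose delta*L of their edge segments.  Eligible SEs
    (enough high/low space) are sampled to the configured focal
    fraction, split evenly between directions.  Returns (cancer low
    intervals, true cancer occupancy, delta label per SE).
    """
    delta = cfg.focal_delta
    cancer_low = {c: list(ivs) for c, ivs in normal_low.items()}
    cancer_occ = dict(normal_occ)
    labels = {se.se_id: "unchanged" for se in ses}
    hypo_ok = [se for se in ses if normal_occ[se.se_id] + delta <= 0.95]
    hyper_ok = [se for se in ses if normal_occ[se.se_id] - delta >= 0.02]
    n_focal = int(round(cfg.fraction_focal * len(ses)))
    if cfg.focal_mode == "hypo":
        n_hypo = min(len(hypo_ok), n_focal)
        n_hyper = 0
    elif cfg.focal_mode == "hyper":
        n_hypo = 0
        n_hyper = min(len(hyper_ok), n_focal)
    else:
        n_hypo = min(len(hypo_ok), (n_focal + 1) // 2)
        n_hyper = min(len(hyper_ok), n_focal - n_hypo)
    chosen_hypo = list(rng.choice(len(hypo_ok), size=n_hypo, replace=False)) if n_hypo else []
    pool = [se for se in hyper_ok if labels[se.se_id] == "unchanged"
            and se.se_id not in {hypo_ok[i].se_id for i in chosen_hypo}]
    chosen_hyper = list(rng.choice(len(pool), size=min(n_hyper, len(pool)),
                                   replace=False)) if n_hyper else []
    for i in chosen_hypo:
        se = hypo_ok[i]
        iv = se.interval
        length = len(iv)
        add = int(round(delta * length))
        center = (iv.start + iv.end) // 2
        seg = (center - add // 2, center - add // 2 + add)
        cancer_low[iv.chrom].append(seg)
        cancer_occ[se.se_id] = normal_occ[se.se_id] + add / length
        labels[se.se_id] = "hypomethylated"
    for i in chosen_hyper:
        se = pool[i]
        iv = se.interval
        length = len(iv)
        cut = int(round(delta * length / 2))  # per edge
        new_ivs = []
        for s, e in cancer_low[iv.chrom]:
            if s >= iv.start and e <= iv.end:  # an edge segment of this SE
                if s == iv.start:
                    s2, e2 = s, max(s, e - cut)
                else:
                    s2, e2 = min(e, s + cut), e
                if e2 > s2:
                    new_ivs.append((s2, e2))
            else:
                new_ivs.append((s, e))
        removed = sum(e - s for s, e in cancer_low[iv.chrom]) - \
            sum(e - s for s, e in new_ivs)
        cancer_low[iv.chrom] = new_ivs
        cancer_occ[se.se_id] = max(0.0, normal_occ[se.se_id] - removed / length)
        labels[se.se_id] = "hypermethylated"
    for c in cancer_low:
        cancer_low[c] = _merge_intervals(cancer_low[c])
    return cancer_low, cancer_occ, labels


def simulate_histone_track(low_intervals: dict[str, list[tuple[int, int]]],
                           cfg: SimConfig, rng: np.random.Generator,
                           chrom: str, start: int, end: int, width: int = 50,
                           noise: float | None = None,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """50-bp window signal anti-correlated with local methylation.

    signal = scale * (1 - expected local methylation) + Gaussian noise.
    Returns (window start positions, signal values).
    """
    noise = cfg.histone_noise if noise is None else noise
    ivs = _merge_intervals(low_intervals.get(chrom, []))
    starts = np.arange(start, end, width)
    vals = np.empty(len(starts))
    for i, ws in enumerate(starts):
        we = min(ws + width, end)
        low_bp = sum(max(0, min(we, e) - max(ws, s)) for s, e in ivs)
        frac_low = low_bp / (we - ws)
        local_meth = frac_low * cfg.hmr_mean + (1 - frac_low) * cfg.background_mean
        vals[i] = cfg.histone_scale * (1.0 - local_meth)
    if noise > 0:
        vals = vals + rng.normal(0.0, noise, size=len(vals))
    return starts, vals


def simulate_expression(ses: Sequence[SuperEnhancer], se_mean_meth: dict[str, float],
                        cfg: SimConfig, rng: np.random.Generator,
                        slope: float | None = None, noise: float | None = None,
                        ) -> dict[str, float]:
    """Target-gene expression anti-correlated with SE mean methylation."""
    slope = cfg.expr_slope if slope is None else slope
    noise = cfg.expr_noise if noise is None else noise
    out: dict[str, float] = {}
    for se in ses:
        if se.target_gene is None:
            continue
        mu = cfg.expr_base - slope * se_mean_meth[se.se_id]
        eps = rng.normal(0.0, noise) if noise > 0 else 0.0
        out[se.target_gene] = float(np.exp(mu + eps))
    return out


def simulate_dataset(cfg: SimConfig, with_cancer: bool = True) -> SimDataset:
    """Full closed-loop dataset: normal + cancer methylomes, SEs, truth."""
    rng = np.random.default_rng(cfg.seed)
    positions = simulate_positions(cfg, rng)
    ses, se_low, overrides, occ, cats = implant_superenhancers(
        cfg, rng, categories=cfg.categories)
    extended = {c: [] for c in positions}
    for se in ses:
        iv = se.interval
        half = len(iv) // 2
        extended[iv.chrom].append((max(0, iv.start - half), iv.end + len(iv) - half))
    bg_low = implant_background_hmrs(cfg, rng, exclude=extended)
    normal_low = {c: _merge_intervals(se_low.get(c, []) + bg_low.get(c, []))
                  for c in positions}
    normal = simulate_methylome(positions, normal_low, cfg, rng,
                                sample_id="sim_normal", condition="normal",
                                bg_overrides=overrides)
    truth = TruthSet(params={"config": asdict(cfg)})
    truth.se_records = [
        {"se_id": se.se_id, "chrom": se.interval.chrom, "start": se.interval.start,
         "end": se.interval.end, "tissue": se.tissue, "category": cats[se.se_id],
         "target_gene": se.target_gene} for se in ses]
    truth.low_intervals["sim_normal"] = snap_intervals_to_sites(positions, normal_low)
    truth.occupancy["sim_normal"] = occ

    cancer = None
    if with_cancer:
        cancer_low, cancer_occ, labels = apply_cancer_shift(
            ses, normal_low, occ, cats, cfg, rng)
        cancer = simulate_methylome(positions, cancer_low, cfg, rng,
                                    sample_id="sim_cancer", condition="cancer",
                                    global_drop=cfg.global_drop,
                                    bg_overrides=overrides)
        truth.low_intervals["sim_cancer"] = snap_intervals_to_sites(positions, cancer_low)
        truth.occupancy["sim_cancer"] = cancer_occ
        truth.delta_labels = labels

    se_mean = {se.se_id: occ[se.se_id] * cfg.hmr_mean
               + (1 - occ[se.se_id]) * (0.85 if cats[se.se_id] == "Q4"
                                        else cfg.background_mean)
               for se in ses}
    truth.expression = simulate_expression(ses, se_mean, cfg, rng)
    truth.params["se_mean_meth"] = se_mean
    return SimDataset(config=cfg, normal=normal, cancer=cancer, ses=ses, truth=truth)


def simulate_hmm_chain(n_sites: int = 50_000, low_mean: float = 0.10,
                       high_mean: float = 0.85, self_low: float = 0.99,
                       self_high: float = 0.995, concentration: float = 17.0,
                       coverage_mean: float = 14.0, gap_mean: float = 100.0,
                       seed: int = 0) -> tuple[Methylome, np.ndarray]:
    """Counts generated from an explicit two-state beta-binomial HMM.

    Returns the methylome and the hidden state sequence (0 = low).  Used
    for parameter-recovery checks against the known generative values.
    """
    rng = np.random.default_rng(seed)
    states = np.empty(n_sites, dtype=np.int64)
    # stationary initial distribution of the 2-state chain
    p_low = (1 - self_high) / ((1 - self_low) + (1 - self_high))
    states[0] = 0 if rng.random() < p_low else 1
    stay = np.array([self_low, self_high])
    u = rng.random(n_sites)
    for t in range(1, n_sites):
        s = states[t - 1]
        states[t] = s if u[t] < stay[s] else 1 - s
    gaps = rng.geometric(1.0 / gap_mean, size=n_sites)
    pos = np.cumsum(gaps)
    mean = np.where(states == 0, low_mean, high_mean)
    a = mean * concentration
    b = (1.0 - mean) * concentration
    p = rng.beta(a, b)
    cov = rng.poisson(coverage_mean, size=n_sites)
    meth = rng.binomial(cov, p)
    m = Methylome(np.full(n_sites, "chr1", dtype=object), pos, meth, cov - meth,
                  sample_id="hmm_chain")
    return m, states


def true_low_intervals_as_hmrs(truth: TruthSet, sample_id: str) -> list[HMR]:
    """Truth low segments as HMR records (for closed-loop occupancy checks)."""
    out: list[HMR] = []
    for chrom, ivs in truth.low_intervals[sample_id].items():
        for s, e in ivs:
            out.append(HMR(GenomicInterval(chrom, s, e), n_cpgs=1, score=0.0,
                           mean_meth=0.0))
    return out


def simulate_large_hmr_mixture(seed: int = 0, n_background: int = 1000,
                               n_implant: int = 20, factor: float = 10.0,
                               median_size: float = 1000.0, sigma: float = 0.08,
                               implant_sigma: float = 1.1,
                               ) -> tuple[list[HMR], list[bool]]:
    """HMR size mixture: lognormal background plus factor-times-larger implants.

    Implants are centered at ``factor`` times the background median with
    their own lognormal spread, giving the rank-size curve a rising
    blade rather than a flat step (a step defeats any tangent rule).
    """
    rng = np.random.default_rng(seed)
    bg = np.exp(rng.normal(np.log(median_size), sigma, size=n_background))
    im = factor * median_size * np.exp(rng.normal(0.0, implant_sigma, size=n_implant))
    hmrs: list[HMR] = []
    flags: list[bool] = []
    pos = 0
    for i, size in enumerate(np.concatenate([bg, im])):
        size = max(10, int(round(size)))
        hmrs.append(HMR(GenomicInterval("chr1", pos, pos + size, f"R{i}"),
                        n_cpgs=max(1, size // 100), score=float(size) / 100,
                        mean_meth=0.1))
        flags.append(i >= n_background)
        pos += size + 1000
    return hmrs, flags
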