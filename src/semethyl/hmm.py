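"""Two-state beta-binomial hidden Markov segmentation of a methylome.

Raw methylated/unmethylated read counts at covered CpGs are modeled with
per-state beta-binomial emissions; a two-state (low/high methylation)
HMM is fitted by Baum-Welch, sites are labeled by posterior decoding,
maximal low-state runs become hypomethylated regions (HMRs), each region
is scored as ``n_cpgs - sum(levels)``, and regions are filtered at the
99th percentile of scores obtained from permuted methylomes.

Observation chains restart at chromosome boundaries and at CpG gaps
larger than ``gap_bp``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, gammaln

from .io import GenomicInterval, Methylome

logger = logging.getLogger(__name__)

__all__ = [
    "EmissionParams",
    "HMMParams",
    "HMR",
    "HMRCallConfig",
    "DecodedMethylome",
    "fit_hmm",
    "posterior_decode",
    "extract_hmrs",
    "score_hmr",
    "permutation_threshold",
    "call_hmrs",
    "write_hmr_bed",
    "read_hmr_bed",
]


@dataclass(frozen=True)
class EmissionParams:
    """Beta-binomial shape parameters for one hidden state."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta-binomial shapes must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class HMMParams:
    """Initial/transition probabilities plus per-state emissions (low, high)."""

    initial: np.ndarray
    transition: np.ndarray
    emissions: tuple[EmissionParams, EmissionParams]

    def __post_init__(self) -> None:
        initial = np.asarray(self.initial, dtype=float)
        transition = np.asarray(self.transition, dtype=float)
        object.__setattr__(self, "initial", initial)
        object.__setattr__(self, "transition", transition)
        if initial.shape != (2,) or transition.shape != (2, 2):
            raise ValueError("expected 2-state parameters")
        if abs(initial.sum() - 1.0) > 1e-9:
            raise ValueError("initial probabilities must sum to 1")
        if np.abs(transition.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("transition matrix rows must sum to 1")
        if self.emissions[0].mean >= self.emissions[1].mean:
            raise ValueError("state 0 must be the low-methylation state")

    @property
    def low(self) -> EmissionParams:
        return self.emissions[0]

    @property
    def high(self) -> EmissionParams:
        return self.emissions[1]


@dataclass(frozen=True)
class HMR:
    """A hypomethylated region with its CpG count, score and mean level."""

    interval: GenomicInterval
    n_cpgs: int
    score: float
    mean_meth: float

    @property
    def size(self) -> int:
        return len(self.interval)


@dataclass
class HMRCallConfig:
    n_permutations: int = 20
    seed: int = 0
    max_iter: int = 100
    tol: float = 1e-4
    gap_bp: int = 5000
    decode: str = "posterior"  # or "viterbi"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.decode not in ("posterior", "viterbi"):
            raise ValueError("decode must be 'posterior' or 'viterbi'")


@dataclass
class DecodedMethylome:
    """Covered-site view of a methylome with state labels and posteriors."""

    chrom: np.ndarray
    pos: np.ndarray
    meth: np.ndarray
    unmeth: np.ndarray
    labels: np.ndarray          # 0 = low, 1 = high
    posterior: np.ndarray       # (n, 2)
    chain_bounds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def levels(self) -> np.ndarray:
        return self.meth / (self.meth + self.unmeth)


def score_hmr(levels: Sequence[float]) -> float:
    """Region score: number of CpG sites minus the sum of their levels."""
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("cannot score an empty region")
    if np.nanmin(levels) < -1e-12 or np.nanmax(levels) > 1 + 1e-12:
        raise ValueError("levels must lie in [0, 1]")
    return float(levels.size - levels.sum())


# ---------------------------------------------------------------------------
# internals

def _covered_view(m: Methylome) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    cov = m.coverage
    mask = cov > 0
    return m.chrom[mask], m.pos[mask], m.meth[mask], m.unmeth[mask]


def _chain_bounds(chrom: np.ndarray, pos: np.ndarray, gap_bp: int) -> list[tuple[int, int]]:
    n = len(pos)
    if n == 0:
        return []
    brk = (chrom[1:] != chrom[:-1]) | (pos[1:] - pos[:-1] > gap_bp)
    starts = [0, *(np.flatnonzero(brk) + 1).tolist()]
    bounds = [(s, e) for s, e in zip(starts, [*starts[1:], n])]
    return bounds


def _log_emission(k: np.ndarray, n: np.ndarray, params: tuple[EmissionParams, EmissionParams]) -> np.ndarray:
    """(T, 2) log beta-binomial pmf of each observation under each state."""
    logb = np.empty((len(k), 2))
    lchoose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    for s, e in enumerate(params):
        logb[:, s] = lchoose + betaln(k + e.alpha, n - k + e.beta) - betaln(e.alpha, e.beta)
    return logb


def _forward_backward(B0: list, B1: list, logscale: float, pi: np.ndarray,
                      A: np.ndarray, want_xi: bool) -> tuple[np.ndarray, np.ndarray | None, float]:
    """Scaled forward-backward on one chain.

    B0/B1 are per-site emission likelihoods already divided by the per-site
    maximum (logscale holds the discarded log mass).  Returns posteriors
    gamma (T, 2), summed transition posteriors xi (2, 2) or None, and the
    chain log-likelihood.
    """
    T = len(B0)
    a00 = float(A[0, 0]); a01 = float(A[0, 1])
    a10 = float(A[1, 0]); a11 = float(A[1, 1])
    al0 = [0.0] * T
    al1 = [0.0] * T
    cs = [0.0] * T
    f0 = float(pi[0]) * B0[0]
    f1 = float(pi[1]) * B1[0]
    c = f0 + f1
    f0 /= c; f1 /= c
    al0[0] = f0; al1[0] = f1; cs[0] = c
    for t in range(1, T):
        g0 = (f0 * a00 + f1 * a10) * B0[t]
        g1 = (f0 * a01 + f1 * a11) * B1[t]
        c = g0 + g1
        f0 = g0 / c; f1 = g1 / c
        al0[t] = f0; al1[t] = f1; cs[t] = c
    loglik = logscale + math.fsum(map(math.log, cs))

    g0arr = [0.0] * T
    g1arr = [0.0] * T
    g0arr[T - 1] = al0[T - 1]
    g1arr[T - 1] = al1[T - 1]
    be0 = 1.0; be1 = 1.0
    x00 = x01 = x10 = x11 = 0.0
    for t in range(T - 2, -1, -1):
        bb0 = B0[t + 1] * be0
        bb1 = B1[t + 1] * be1
        ct = cs[t + 1]
        f0 = al0[t]; f1 = al1[t]
        if want_xi:
            x00 += f0 * a00 * bb0 / ct
            x01 += f0 * a01 * bb1 / ct
            x10 += f1 * a10 * bb0 / ct
            x11 += f1 * a11 * bb1 / ct
        be0 = (a00 * bb0 + a01 * bb1) / ct
        be1 = (a10 * bb0 + a11 * bb1) / ct
        g0arr[t] = f0 * be0
        g1arr[t] = f1 * be1
    gamma = np.column_stack([g0arr, g1arr])
    xi = np.array([[x00, x01], [x10, x11]]) if want_xi else None
    return gamma, xi, loglik


def _run_forward_backward(logB: np.ndarray, pi: np.ndarray, A: np.ndarray,
                          bounds: list[tuple[int, int]], want_xi: bool
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """All chains; returns gamma, xi sums, chain-start gamma sums, loglik."""
    n = logB.shape[0]
    gamma = np.empty((n, 2))
    xi_sum = np.zeros((2, 2))
    start_sum = np.zeros(2)
    loglik = 0.0
    rowmax = logB.max(axis=1)
    B = np.exp(logB - rowmax[:, None])
    for s, e in bounds:
        if e - s == 1:
            w = pi * B[s]
            gamma[s] = w / w.sum()
            loglik += rowmax[s] + math.log(w.sum())
        else:
            g, xi, ll = _forward_backward(
                B[s:e, 0].tolist(), B[s:e, 1].tolist(),
                float(rowmax[s:e].sum()), pi, A, want_xi)
            gamma[s:e] = g
            if xi is not None:
                xi_sum += xi
            loglik += ll
        start_sum += gamma[s]
    return gamma, xi_sum, start_sum, loglik


def _weighted_bb_mle(k: np.ndarray, n: np.ndarray, w: np.ndarray,
                     init: EmissionParams) -> EmissionParams:
    """Maximize sum_i w_i * log BetaBinom(k_i; n_i, a, b) over (a, b)."""
    # collapse to unique (n, k) pairs for cheap objective evaluations
    pairs = n * 10007 + k
    uniq, inv = np.unique(pairs, return_inverse=True)
    wsum = np.bincount(inv, weights=w, minlength=len(uniq))
    first = np.full(len(uniq), -1, dtype=np.int64)
    first[inv[::-1]] = np.arange(len(k) - 1, -1, -1)
    ku = k[first].astype(float)
    nu = n[first].astype(float)
    lchoose = gammaln(nu + 1) - gammaln(ku + 1) - gammaln(nu - ku + 1)

    def neg(theta: np.ndarray) -> float:
        a, b = math.exp(theta[0]), math.exp(theta[1])
        ll = lchoose + betaln(ku + a, nu - ku + b) - betaln(a, b)
        return -float(np.dot(wsum, ll))

    x0 = np.log([init.alpha, init.beta])
    res = minimize(neg, x0, method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": 400})
    # guarantee EM monotonicity: never accept a worse objective
    if res.fun <= neg(x0):
        a, b = math.exp(res.x[0]), math.exp(res.x[1])
        a = min(max(a, 1e-4), 1e6)
        b = min(max(b, 1e-4), 1e6)
        return EmissionParams(a, b)
    return init


def fit_hmm(m: Methylome, cfg: HMRCallConfig | None = None) -> HMMParams:
    """Fit the two-state beta-binomial HMM by Baum-Welch EM.

    States are returned ordered so that state 0 has the lower emission
    mean.  The per-iteration log-likelihood is non-decreasing.
    """
    cfg = cfg or HMRCallConfig()
    chrom, pos, meth, unmeth = _covered_view(m)
    if len(pos) < 100:
        raise ValueError(f"need >= 100 covered CpGs, got {len(pos)}")
    k = meth.astype(float)
    n = (meth + unmeth).astype(float)
    if np.unique(k / n).size < 2:
        raise ValueError("two states unidentifiable: all methylation levels identical")
    bounds = _chain_bounds(chrom, pos, cfg.gap_bp)

    # init: state means 0.2 / 0.8, moderate concentration, sticky transitions
    conc = 10.0
    emissions = (EmissionParams(0.2 * conc, 0.8 * conc),
                 EmissionParams(0.8 * conc, 0.2 * conc))
    pi = np.array([0.5, 0.5])
    A = np.array([[0.99, 0.01], [0.01, 0.99]])

    prev_ll = -np.inf
    trace: list[float] = []
    for _ in range(cfg.max_iter):
        logB = _log_emission(k, n, emissions)
        gamma, xi_sum, start_sum, ll = _run_forward_backward(logB, pi, A, bounds, True)
        trace.append(ll)
        if np.isfinite(prev_ll):
            rel = (ll - prev_ll) / max(abs(prev_ll), 1.0)
            if rel < cfg.tol:
                prev_ll = ll
                break
        prev_ll = ll
        # M-step
        pi = start_sum / start_sum.sum()
        pi = np.clip(pi, 1e-12, None)
        pi /= pi.sum()
        rows = xi_sum.sum(axis=1, keepdims=True)
        if (rows > 0).all():
            A = xi_sum / rows
            A = np.clip(A, 1e-12, None)
            A /= A.sum(axis=1, keepdims=True)
        emissions = (
            _weighted_bb_mle(k, n, gamma[:, 0], emissions[0]),
            _weighted_bb_mle(k, n, gamma[:, 1], emissions[1]),
        )
    if emissions[0].mean > emissions[1].mean:
        emissions = (emissions[1], emissions[0])
        pi = pi[::-1].copy()
        A = A[::-1, ::-1].copy()
    if abs(emissions[0].mean - emissions[1].mean) < 1e-6:
        raise ValueError("two states unidentifiable: emission means collapsed")
    params = HMMParams(pi, A, emissions)
    object.__setattr__(params, "loglik_trace", trace)
    return params


def posterior_decode(m: Methylome, p: HMMParams, gap_bp: int = 5000,
                     method: str = "posterior") -> DecodedMethylome:
    """Label covered CpGs by forward-backward posterior (or Viterbi)."""
    chrom, pos, meth, unmeth = _covered_view(m)
    if len(pos) == 0:
        return DecodedMethylome(chrom, pos, meth, unmeth,
                                np.empty(0, dtype=np.int64), np.empty((0, 2)), [])
    k = meth.astype(float)
    n = (meth + unmeth).astype(float)
    bounds = _chain_bounds(chrom, pos, gap_bp)
    logB = _log_emission(k, n, p.emissions)
    gamma, _, _, _ = _run_forward_backward(logB, p.initial, p.transition, bounds, False)
    if method == "posterior":
        labels = (gamma[:, 1] > gamma[:, 0]).astype(np.int64)
    elif method == "viterbi":
        labels = _viterbi(logB, p.initial, p.transition, bounds)
    else:
        raise ValueError(f"unknown decode method {method!r}")
    return DecodedMethylome(chrom, pos, meth, unmeth, labels, gamma, bounds)


def _viterbi(logB: np.ndarray, pi: np.ndarray, A: np.ndarray,
             bounds: list[tuple[int, int]]) -> np.ndarray:
    logpi = np.log(pi)
    logA = np.log(A)
    labels = np.empty(logB.shape[0], dtype=np.int64)
    for s, e in bounds:
        T = e - s
        delta = np.empty((T, 2))
        back = np.empty((T, 2), dtype=np.int64)
        delta[0] = logpi + logB[s]
        for t in range(1, T):
            cand = delta[t - 1][:, None] + logA
            back[t] = cand.argmax(axis=0)
            delta[t] = cand.max(axis=0) + logB[s + t]
        lab = np.empty(T, dtype=np.int64)
        lab[-1] = delta[-1].argmax()
        for t in range(T - 2, -1, -1):
            lab[t] = back[t + 1, lab[t + 1]]
        labels[s:e] = lab
    return labels


def extract_hmrs(decoded: DecodedMethylome) -> list[HMR]:
    """Maximal low-state runs (within chains) as scored HMR records."""
    out: list[HMR] = []
    labels = decoded.labels
    for s, e in decoded.chain_bounds:
        i = s
        while i < e:
            if labels[i] == 0:
                j = i
                while j + 1 < e and labels[j + 1] == 0:
                    j += 1
                pos = decoded.pos[i:j + 1]
                levels = decoded.meth[i:j + 1] / (decoded.meth[i:j + 1] + decoded.unmeth[i:j + 1])
                out.append(HMR(
                    interval=GenomicInterval(str(decoded.chrom[i]), int(pos[0]), int(pos[-1]) + 1),
                    n_cpgs=j - i + 1,
                    score=score_hmr(levels),
                    mean_meth=float(levels.mean()),
                ))
                i = j + 1
            else:
                i += 1
    return out


def permutation_threshold(m: Methylome, p: HMMParams, cfg: HMRCallConfig) -> float:
    """99th-percentile score cutoff from permuted methylomes.

    Each permutation shuffles the (meth, unmeth) count pairs across site
    positions genome-wide, re-decodes and re-scores; all null scores are
    pooled and the cutoff is their empirical 99th percentile using the
    linear-interpolation quantile definition (numpy default).
    """
    rng = np.random.default_rng(cfg.seed)
    null_scores: list[float] = []
    for _ in range(cfg.n_permutations):
        perm = rng.permutation(len(m))
        pm = m.replace_counts(m.meth[perm], m.unmeth[perm])
        decoded = posterior_decode(pm, p, gap_bp=cfg.gap_bp, method=cfg.decode)
        null_scores.extend(h.score for h in extract_hmrs(decoded))
    if not null_scores:
        logger.warning("no null HMRs in any permutation; cutoff set to 0")
        return 0.0
    return float(np.percentile(np.asarray(null_scores), 99.0, method="linear"))


def call_hmrs(m: Methylome, cfg: HMRCallConfig | None = None) -> list[HMR]:
    """Full pipeline: fit, decode, extract, permutation-filter (score > cutoff)."""
    cfg = cfg or HMRCallConfig()
    params = fit_hmm(m, cfg)
    decoded = posterior_decode(m, params, gap_bp=cfg.gap_bp, method=cfg.decode)
    hmrs = extract_hmrs(decoded)
    cutoff = permutation_threshold(m, params, cfg)
    kept = [h for h in hmrs if h.score > cutoff]
    kept.sort(key=lambda h: (h.interval.chrom, h.interval.start))
    logger.info("called %d HMRs (%d before filtering, cutoff %.3f)",
                len(kept), len(hmrs), cutoff)
    return kept


def write_hmr_bed(hmrs: Sequence[HMR], path: str | Path) -> None:
    """BED4+ : chrom, start, end, name, score, n_cpgs, mean_meth."""
    with open(path, "w") as fh:
        for i, h in enumerate(hmrs, start=1):
            iv = h.interval
            name = iv.name or f"HMR{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t"
                     f"{h.score:.10g}\t{h.n_cpgs}\t{h.mean_meth:.10g}\n")


def read_hmr_bed(path: str | Path) -> list[HMR]:
    out: list[HMR] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith(("track", "#")):
                continue
            parts = line.split("\t")
            out.append(HMR(
                interval=GenomicInterval(parts[0], int(parts[1]), int(parts[2]),
                                         parts[3] if len(parts) > 3 else None),
                score=float(parts[4]) if len(parts) > 4 else 0.0,
                n_cpgs=int(parts[5]) if len(parts) > 5 else 1,
                mean_meth=float(parts[6]) if len(parts) > 6 else 0.0,
            ))
    return out
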