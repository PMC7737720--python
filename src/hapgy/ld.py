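"""Pairwise linkage disequilibrium statistics and LD decay.

Lines are advanced inbreds, so two-locus haplotypes are read directly from
homozygous calls: a line contributes one gamete per locus pair, and lines
that are heterozygous or missing at either locus are excluded.  No EM
phasing is performed.

The D' 95% confidence interval follows the Gabriel/Haploview convention: the
multinomial likelihood of the four haplotype counts is evaluated on a grid
of |D'| values with allele frequencies fixed at their sample estimates,
normalized to sum to one, and the one-sided 5% and 95% cumulative points are
reported.  Pairs are classified as strong LD (ci_low >= 0.6 and
ci_high >= 0.95), strong recombination (ci_high < 0.90), or inconclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from hapgy.io_genotypes import MISSING, GenotypeMatrix

STRONG_LD = "strong_LD"
STRONG_RECOMB = "strong_recombination"
INCONCLUSIVE = "inconclusive"

#: default Gabriel-method confidence-interval bounds
CI_LOW_BOUND = 0.6
CI_HIGH_BOUND = 0.95
RECOMB_HIGH_BOUND = 0.90


class InsufficientDataError(ValueError):
    pass


@dataclass
class LDPairStats:
    marker_i: str
    marker_j: str
    distance_bp: int
    hap_freqs: tuple  # (p_AB, p_Ab, p_aB, p_ab)
    D: float
    Dprime: float
    r2: float
    ci_low: float
    ci_high: float
    classification: str
    n_informative: int


@dataclass
class LDDecayCurve:
    """LOESS-smoothed r2 against physical distance.

    ``decay_distance_bp`` is the interpolated distance where the fitted
    curve first drops below the baseline (r2 = 0.1 by default); ``None``
    when the curve never crosses it.
    """

    distance_bp: np.ndarray
    r2_smooth: np.ndarray
    baseline: float
    decay_distance_bp: Optional[float]
    n_pairs: int


def _two_locus_hap_counts(ci: np.ndarray, cj: np.ndarray) -> np.ndarray:
    """4-vector of gamete counts (AB, Ab, aB, ab) from homozygous calls.

    A/B denote the major allele (call 0) at each locus, a/b the minor
    (call 2).  Heterozygous (1) or missing calls exclude the line.
    """
    hom = ((ci == 0) | (ci == 2)) & ((cj == 0) | (cj == 2))
    a = ci[hom] // 2  # 0 -> major, 1 -> minor
    b = cj[hom] // 2
    idx = a * 2 + b  # 0=AB, 1=Ab, 2=aB, 3=ab
    return np.bincount(idx, minlength=4).astype(np.int64)


def _d_stats(freqs: np.ndarray):
    """(D, Dprime, r2) from haplotype frequencies (p_AB, p_Ab, p_aB, p_ab)."""
    p_ab_, p_aB, p_Ab, p_AB = freqs[3], freqs[2], freqs[1], freqs[0]
    p_A = p_AB + p_Ab
    p_B = p_AB + p_aB
    p_a, p_b = 1.0 - p_A, 1.0 - p_B
    D = p_AB - p_A * p_B
    denom = p_A * p_a * p_B * p_b
    r2 = (D * D) / denom if denom > 0 else np.nan
    if D > 0:
        d_max = min(p_A * p_b, p_a * p_B)
    else:
        d_max = min(p_A * p_B, p_a * p_b)
    dprime = abs(D) / d_max if d_max > 0 else np.nan
    return D, dprime, r2


def dprime_ci(hap_counts, grid_step: float = 0.001) -> tuple:
    """Likelihood-based 95% confidence interval for |D'|.

    Parameters
    ----------
    hap_counts : sequence of 4 non-negative ints
        Gamete counts (n_AB, n_Ab, n_aB, n_ab); total must be >= 4.
    grid_step : float
        Spacing of the |D'| evaluation grid on [0, 1].

    Returns
    -------
    (ci_low, ci_high) : tuple of float
        Smallest grid values whose cumulative normalized likelihood reaches
        0.05 and 0.95 respectively.
    """
    n = np.asarray(hap_counts, dtype=np.float64)
    if n.shape != (4,) or (n < 0).any():
        raise ValueError("hap_counts must be 4 non-negative counts")
    total = n.sum()
    if total < 4:
        raise InsufficientDataError("fewer than 4 informative gametes")
    p_A = (n[0] + n[1]) / total
    p_B = (n[0] + n[2]) / total
    if p_A in (0.0, 1.0) or p_B in (0.0, 1.0):
        raise ValueError("degenerate allele margins: a locus is monomorphic")
    # orient so the MLE of D is non-negative (swap minor/major at locus B)
    d_mle = n[0] / total - p_A * p_B
    if d_mle < 0:
        n = n[[1, 0, 3, 2]]
        p_B = 1.0 - p_B
    p_a, p_b = 1.0 - p_A, 1.0 - p_B
    d_max = min(p_A * p_b, p_a * p_B)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    p_AB = p_A * p_B + grid * d_max
    p_Ab = p_A - p_AB
    p_aB = p_B - p_AB
    p_ab = 1.0 - p_AB - p_Ab - p_aB
    eps = 1e-12
    freqs = np.clip(np.stack([p_AB, p_Ab, p_aB, p_ab]), eps, None)
    loglik = (n[:, None] * np.log(freqs)).sum(axis=0)
    lik = np.exp(loglik - loglik.max())
    cum = np.cumsum(lik / lik.sum())
    ci_low = float(grid[np.searchsorted(cum, 0.05)])
    ci_high = float(grid[np.searchsorted(cum, 0.95)])
    return ci_low, ci_high


def classify_pair(
    ci_low: float,
    ci_high: float,
    ci_low_bound: float = CI_LOW_BOUND,
    ci_high_bound: float = CI_HIGH_BOUND,
    recomb_high_bound: float = RECOMB_HIGH_BOUND,
) -> str:
    """Gabriel-method pair classification from the D' confidence interval."""
    if not (0 <= ci_low <= ci_high <= 1):
        raise ValueError("require 0 <= ci_low <= ci_high <= 1")
    if ci_low >= ci_low_bound and ci_high >= ci_high_bound:
        return STRONG_LD
    if ci_high < recomb_high_bound:
        return STRONG_RECOMB
    return INCONCLUSIVE


def pair_ld(g: GenotypeMatrix, i: int, j: int, grid_step: float = 0.001) -> LDPairStats:
    """Full LD statistics for the marker pair (i, j).

    Raises
    ------
    InsufficientDataError
        When fewer than 4 lines are homozygous-called at both loci.
    """
    counts = _two_locus_hap_counts(g.calls[:, i], g.calls[:, j])
    total = int(counts.sum())
    if total < 4:
        raise InsufficientDataError(f"pair ({g.marker_ids[i]}, {g.marker_ids[j]}): insufficient data")
    freqs = counts / total
    D, dprime, r2 = _d_stats(freqs)
    if np.isnan(r2):
        ci_low, ci_high, label = np.nan, np.nan, INCONCLUSIVE
    else:
        ci_low, ci_high = dprime_ci(counts, grid_step=grid_step)
        label = classify_pair(ci_low, ci_high)
    dist = int(abs(int(g.pos_bp[j]) - int(g.pos_bp[i]))) if g.chrom[i] == g.chrom[j] else -1
    return LDPairStats(
        marker_i=g.marker_ids[i],
        marker_j=g.marker_ids[j],
        distance_bp=dist,
        hap_freqs=tuple(freqs),
        D=D,
        Dprime=dprime,
        r2=r2,
        ci_low=ci_low,
        ci_high=ci_high,
        classification=label,
        n_informative=total,
    )


def pair_r2(ci: np.ndarray, cj: np.ndarray) -> float:
    """r2 from homozygous two-locus calls; NaN when undefined."""
    counts = _two_locus_hap_counts(ci, cj)
    total = counts.sum()
    if total < 4:
        return np.nan
    _, _, r2 = _d_stats(counts / total)
    return r2


# ---------------------------------------------------------------------------
# LOESS LD decay


def _loess_quadratic(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, span: float) -> np.ndarray:
    """Second-degree locally weighted regression with tricube weights.

    For each evaluation point, the nearest ``ceil(span * n)`` data points
    are fitted with a weighted quadratic; the fit is evaluated at the point.
    """
    n = len(x)
    k = max(int(np.ceil(span * n)), 5)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    out = np.empty(len(x_eval))
    for m, x0 in enumerate(x_eval):
        lo = np.searchsorted(xs, x0)
        a, b = max(0, lo - k), min(n, lo + k)
        d = np.abs(xs[a:b] - x0)
        idx = np.argpartition(d, min(k - 1, len(d) - 1))[:k]
        xi, yi, di = xs[a:b][idx], ys[a:b][idx], d[idx]
        dmax = di.max()
        if dmax == 0:
            out[m] = yi.mean()
            continue
        w = (1 - (di / dmax) ** 3) ** 3
        w = np.maximum(w, 1e-9)
        # weighted quadratic fit centered at x0 for conditioning
        t = (xi - x0) / dmax
        X = np.stack([np.ones_like(t), t, t * t], axis=1)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], yi * sw, rcond=None)
        out[m] = beta[0]
    return out


def ld_decay(
    g: GenotypeMatrix,
    max_dist_bp: int = 50_000_000,
    sample_pairs: int = 50_000,
    seed: int = 0,
    baseline: float = 0.1,
    span: float = 0.5,
    n_grid: int = 512,
) -> LDDecayCurve:
    """LOESS LD-decay curve and baseline-crossing distance.

    Pools intrachromosomal (distance, r2) pairs genome-wide, subsamples to
    at most ``sample_pairs`` pairs, fits a second-degree LOESS (default span
    0.5) on a log-spaced distance grid, and reports the distance where the
    smoothed curve first crosses ``baseline`` (linearly interpolated).
    """
    pairs = []
    for chrom in g.chromosomes():
        idx = np.flatnonzero(g.chrom == chrom)
        if len(idx) < 2:
            continue
        pos = g.pos_bp[idx]
        ii, jj = np.triu_indices(len(idx), k=1)
        d = pos[jj] - pos[ii]
        ok = d <= max_dist_bp
        pairs.extend(zip(idx[ii[ok]], idx[jj[ok]], d[ok]))
    if len(pairs) < 100:
        raise InsufficientDataError(f"only {len(pairs)} intrachromosomal pairs within {max_dist_bp} bp")
    rng = np.random.default_rng(seed)
    if len(pairs) > sample_pairs:
        sel = rng.choice(len(pairs), size=sample_pairs, replace=False)
        pairs = [pairs[s] for s in sel]
    dist = np.empty(len(pairs))
    r2 = np.empty(len(pairs))
    for k, (i, j, d) in enumerate(pairs):
        dist[k] = d
        r2[k] = pair_r2(g.calls[:, i], g.calls[:, j])
    ok = np.isfinite(r2)
    return ld_decay_from_points(dist[ok], r2[ok], baseline=baseline, span=span, n_grid=n_grid)


def ld_decay_from_points(
    dist: np.ndarray,
    r2: np.ndarray,
    baseline: float = 0.1,
    span: float = 0.5,
    n_grid: int = 512,
) -> LDDecayCurve:
    """Fit the LOESS decay curve to a precomputed (distance, r2) scatter."""
    dist = np.asarray(dist, dtype=np.float64)
    r2 = np.asarray(r2, dtype=np.float64)
    lo = max(dist.min(), 1.0)
    grid = np.geomspace(lo, dist.max(), n_grid)
    smooth = np.clip(_loess_quadratic(dist, r2, grid, span), 0.0, 1.0)
    below = smooth < baseline
    decay = None
    if below.any():
        first = int(np.argmax(below))
        if first == 0:
            decay = float(grid[0])
        else:
            x0, x1 = grid[first - 1], grid[first]
            y0, y1 = smooth[first - 1], smooth[first]
            decay = float(x0 + (y0 - baseline) / (y0 - y1) * (x1 - x0))
    return LDDecayCurve(
        distance_bp=grid, r2_smooth=smooth, baseline=baseline, decay_distance_bp=decay, n_pairs=len(dist)
    )
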