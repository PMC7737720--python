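"""Favorable-haplotype stacking: per-line counts, heat-map matrices, and
the additive grain-yield trend over the number of favorable haplotypes.

The heat-map matrix codes, per line and stable block: 1 = carries the
primary favorable allele, 2 = carries a secondary favorable allele,
0 = carries another allele, -1 = haplotype missing.  A line's stack count
is the number of non-missing blocks where it carries any favorable allele;
lines with too many missing blocks can be dropped by a completeness filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from hapgy.io_genotypes import MISSING


@dataclass
class StackingProfile:
    line_ids: list
    block_ids: list
    indicator: np.ndarray  # lines x blocks, codes {1, 2, 0, -1}
    counts: np.ndarray  # favorable haplotypes carried per line (-1 = filtered out)

    def count_classes(self) -> dict:
        ok = self.counts >= 0
        vals, n = np.unique(self.counts[ok], return_counts=True)
        return dict(zip(vals.tolist(), n.tolist()))


@dataclass
class AdditiveTrend:
    class_means: dict  # count -> mean phenotype
    percent_increase: float  # lowest to highest populated class
    slope: float  # phenotype units per favorable haplotype
    slope_p: float
    n_classes: int


def favorable_matrix(haps, stable, min_completeness: float = 0.0) -> StackingProfile:
    """Lines x stable-blocks favorable-allele indicator matrix.

    Parameters
    ----------
    haps : HaplotypeGenotypes
    stable : list of StableAssociation
        Each must name its favorable allele(s); the first is primary, any
        further ones secondary.
    min_completeness : fraction
        Lines called at fewer than this fraction of the stable blocks get
        count -1 (excluded from count classes).
    """
    block_ids = [s.block_id for s in stable]
    id_to_col = {b.block_id: k for k, b in enumerate(haps.blocks)}
    n = len(haps.line_ids)
    ind = np.full((n, len(stable)), MISSING, dtype=np.int16)
    for k, s in enumerate(stable):
        if not s.favorable_alleles:
            raise ValueError(f"stable block {s.block_id} has no favorable allele")
        codes = haps.calls[:, id_to_col[s.block_id]]
        called = codes != MISSING
        ind[called, k] = 0
        primary = s.favorable_alleles[0]
        ind[codes == primary, k] = 1
        for sec in s.favorable_alleles[1:]:
            ind[codes == sec, k] = 2
    called = ind != MISSING
    counts = ((ind == 1) | (ind == 2)).sum(axis=1)
    if min_completeness > 0:
        frac = called.mean(axis=1) if ind.shape[1] else np.ones(n)
        counts = np.where(frac >= min_completeness, counts, -1)
    return StackingProfile(
        line_ids=list(haps.line_ids), block_ids=block_ids, indicator=ind, counts=counts
    )


def additive_trend(profile: StackingProfile, y: np.ndarray) -> AdditiveTrend:
    """Mean phenotype per stack-count class, percent gain, and linear slope.

    percent gain = 100 * (mean at the highest populated count class - mean
    at the lowest) / mean at the lowest.  The slope comes from an ordinary
    regression of phenotype on count.  With fewer than 3 populated classes
    the trend is undefined (NaN percent and slope).
    """
    y = np.asarray(y, dtype=np.float64)
    ok = (profile.counts >= 0) & np.isfinite(y)
    c, yy = profile.counts[ok], y[ok]
    classes = np.unique(c)
    class_means = {int(k): float(yy[c == k].mean()) for k in classes}
    if len(classes) < 3:
        return AdditiveTrend(class_means, np.nan, np.nan, np.nan, len(classes))
    lo, hi = classes.min(), classes.max()
    base = class_means[int(lo)]
    pct = 100.0 * (class_means[int(hi)] - base) / base if base != 0 else np.nan
    res = stats.linregress(c.astype(float), yy)
    return AdditiveTrend(class_means, pct, float(res.slope), float(res.pvalue), len(classes))


def haplotype_frequency_trajectory(
    haps, cohorts, stable, decline_delta: float = 0.10
) -> pd.DataFrame:
    """Favorable-allele frequency of each stable block per cohort (EYT).

    ``cohorts`` assigns each line a cohort label.  Frequencies are computed
    among non-missing calls.  A block is flagged ``declining`` when its
    frequency drops by more than ``decline_delta`` from the first to the
    last cohort with an overall downward trend (negative Kendall tau).
    """
    cohorts = np.asarray(cohorts)
    order = sorted(pd.unique(cohorts))
    id_to_col = {b.block_id: k for k, b in enumerate(haps.blocks)}
    rows = []
    for s in stable:
        codes = haps.calls[:, id_to_col[s.block_id]]
        fav = set(s.favorable_alleles)
        freqs = []
        for coh in order:
            sub = codes[cohorts == coh]
            called = sub != MISSING
            freqs.append(float(np.isin(sub[called], list(fav)).mean()) if called.any() else np.nan)
        f = np.asarray(freqs)
        finite = np.isfinite(f)
        declining = False
        if finite.sum() >= 2:
            ff = f[finite]
            drop = ff[0] - ff[-1]
            tau = stats.kendalltau(np.arange(len(ff)), ff).statistic if len(ff) >= 3 else -np.sign(ff[-1] - ff[0])
            declining = bool(drop > decline_delta and (tau is not None and tau < 0))
        rows.append({"block_id": s.block_id, **{str(c): v for c, v in zip(order, freqs)}, "declining": declining})
    return pd.DataFrame(rows)
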