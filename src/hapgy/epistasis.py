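"""Two- and three-locus haplotype interaction scans.

Each locus pair (or triple) is tested by comparing a main-effects linear
model (allele dummies of every involved block) against a full model that
adds the interaction dummies.  The reported p-value is the F-test of the
interaction group; the reported variance share is the partial R2

    (RSS_main - RSS_full) / TSS,

the incremental variance explained by the interactions beyond main effects.
Interaction cells carrying fewer than ``cell_floor`` lines are pooled with
the reference (their dummies are dropped).  The phenotype is the adjusted
grain yield per trial x environment, as in the association scan; no kinship
correction is applied by default (a plain linear regression, matching how
such scans are usually run).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
from scipy import stats

from hapgy.assoc import prepare_block_column
from hapgy.io_genotypes import MISSING


@dataclass
class EpistasisResult:
    loci: tuple  # block ids, in input order
    trial_id: str
    environment: str
    partial_r2: float  # fraction of total variance
    p_value: float
    n_lines: int

    @property
    def partial_r2_pct(self) -> float:
        return 100.0 * self.partial_r2


def _main_dummies(codes: np.ndarray) -> np.ndarray:
    """Treatment-coded main-effect dummies, reference = most frequent allele."""
    alleles, counts = np.unique(codes, return_counts=True)
    ref = alleles[np.argmax(counts)]
    return np.column_stack([(codes == a).astype(float) for a in alleles if a != ref])


def _rss(X: np.ndarray, y: np.ndarray) -> tuple:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ beta) ** 2)), rank


def _interaction_test(code_cols, y, cell_floor: int, order: int):
    """F-test of the highest-order interaction beyond all lower-order terms.

    Returns (partial_r2, p, n) or None when the design is unusable.
    """
    n = len(y)
    X_parts = [np.ones((n, 1))]
    for c in code_cols:
        X_parts.append(_main_dummies(c))
    if order == 3:
        for c1, c2 in combinations(code_cols, 2):
            X_parts.append(_pair_dummies(c1, c2, cell_floor))
    X_reduced = np.column_stack(X_parts)
    top = (
        _pair_dummies(code_cols[0], code_cols[1], cell_floor)
        if order == 2
        else _triple_dummies(code_cols, cell_floor)
    )
    if top.shape[1] == 0:
        return None
    X_full = np.column_stack([X_reduced, top])
    rss0, rank0 = _rss(X_reduced, y)
    rss1, rank1 = _rss(X_full, y)
    df_num = rank1 - rank0
    df_den = n - rank1
    if df_num < 1 or df_den < 1:
        return None
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= 0 or rss1 < 0:
        return None
    partial_r2 = max(rss0 - rss1, 0.0) / tss
    f = ((rss0 - rss1) / df_num) / max(rss1 / df_den, 1e-300)
    p = float(stats.f.sf(max(f, 0.0), df_num, df_den))
    return partial_r2, p, n


def _pair_dummies(c1: np.ndarray, c2: np.ndarray, cell_floor: int) -> np.ndarray:
    """Interaction dummies for non-reference allele combinations with at
    least ``cell_floor`` lines; rarer cells are pooled with the reference."""
    d1, d2 = _main_dummies(c1), _main_dummies(c2)
    cols = []
    for i in range(d1.shape[1]):
        for j in range(d2.shape[1]):
            col = d1[:, i] * d2[:, j]
            if col.sum() >= cell_floor:
                cols.append(col)
    return np.column_stack(cols) if cols else np.empty((len(c1), 0))


def _triple_dummies(code_cols, cell_floor: int) -> np.ndarray:
    ds = [_main_dummies(c) for c in code_cols]
    cols = []
    for i, j, k in product(*(range(d.shape[1]) for d in ds)):
        col = ds[0][:, i] * ds[1][:, j] * ds[2][:, k]
        if col.sum() >= cell_floor:
            cols.append(col)
    return np.column_stack(cols) if cols else np.empty((len(code_cols[0]), 0))


def _usable(codes_list, y, min_class: int):
    """Complete-case mask + per-block class floor; None when untestable."""
    mask = np.ones(len(y), dtype=bool)
    pruned = []
    for c in codes_list:
        c = prepare_block_column(np.asarray(c), min_class=min_class)
        pruned.append(c)
        mask &= c != MISSING
    if mask.sum() < 3 * min_class:
        return None
    out = []
    for c in pruned:
        cc = c[mask]
        if len(np.unique(cc)) < 2:
            return None
        out.append(cc)
    return out, np.asarray(y, dtype=np.float64)[mask]


def pairwise_scan(
    haps,
    y: np.ndarray,
    pairs="all",
    alpha: float = 1e-4,
    trial_id: str = "",
    environment: str = "",
    min_class: int = 10,
    cell_floor: int = 5,
) -> list:
    """Scan block pairs for two-locus interactions.

    Parameters
    ----------
    haps : HaplotypeGenotypes
    y : adjusted phenotype aligned to ``haps.line_ids``.
    pairs : "all" or an iterable of (block_id, block_id) tuples.
    alpha : report only interactions with p < alpha; ``None`` reports all.

    Returns a list of :class:`EpistasisResult` sorted by p-value.
    """
    ids = haps.block_ids
    if pairs == "all":
        pairs = list(combinations(ids, 2))
    results = []
    for b1, b2 in pairs:
        cols = _usable([haps.column(b1), haps.column(b2)], y, min_class)
        if cols is None:
            continue
        codes, ysub = cols
        fit = _interaction_test(codes, ysub, cell_floor, order=2)
        if fit is None:
            continue
        r2, p, n = fit
        if alpha is None or p < alpha:
            results.append(EpistasisResult((b1, b2), trial_id, environment, r2, p, n))
    results.sort(key=lambda r: r.p_value)
    return results


def threeway_scan(
    haps,
    y: np.ndarray,
    triples,
    alpha: float = 1e-4,
    trial_id: str = "",
    environment: str = "",
    min_class: int = 10,
    cell_floor: int = 5,
) -> list:
    """Scan candidate block triples for three-locus interactions.

    The reported p and partial R2 are for the three-way dummies beyond all
    main effects and two-way interactions.  ``triples`` must be an explicit
    candidate set (an exhaustive genome-wide triple scan is out of scope);
    :func:`candidate_triples` builds one from marginal and pairwise hits.
    """
    results = []
    for trip in triples:
        cols = _usable([haps.column(b) for b in trip], y, min_class)
        if cols is None:
            continue
        codes, ysub = cols
        fit = _interaction_test(codes, ysub, cell_floor, order=3)
        if fit is None:
            continue
        r2, p, n = fit
        if alpha is None or p < alpha:
            results.append(EpistasisResult(tuple(trip), trial_id, environment, r2, p, n))
    results.sort(key=lambda r: r.p_value)
    return results


def candidate_triples(haps, assoc_results=None, pair_results=None, marginal_p: float = 0.01, cap: int = 100_000):
    """Triples among blocks that are marginally associated (p < marginal_p)
    or belong to a significant pair; capped for cost control."""
    cand = set()
    if assoc_results:
        cand |= {r.block_id for r in assoc_results if r.p_value < marginal_p}
    if pair_results:
        for r in pair_results:
            cand |= set(r.loci)
    cand = sorted(cand & set(haps.block_ids))
    triples = list(combinations(cand, 3))
    return triples[:cap]
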