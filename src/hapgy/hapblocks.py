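"""Confidence-interval (Gabriel-style) haplotype block construction.

A contiguous marker interval [a, b] forms a block when (i) the outermost
pair is in strong LD and (ii) at least 95% of the informative pairwise
comparisons inside the interval (strong-LD or strong-recombination pairs;
inconclusive pairs are excluded from the denominator) are in strong LD.
Candidates are accepted greedily — most SNPs first, then widest span, then
leftmost — and overlapping candidates are discarded.  Accepted blocks are
recoded as multiallelic markers: each distinct homozygous allele
combination across the member SNPs is one haplotype allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from hapgy import ld as _ld
from hapgy.io_genotypes import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class BlockParams:
    """Tunable thresholds for block construction."""

    ci_low_bound: float = _ld.CI_LOW_BOUND
    ci_high_bound: float = _ld.CI_HIGH_BOUND
    recomb_high_bound: float = _ld.RECOMB_HIGH_BOUND
    strong_fraction: float = 0.95
    max_span_bp: int = 10_000_000
    grid_step: float = 0.001
    informative_only: bool = True  # denominator excludes inconclusive pairs


@dataclass
class HaplotypeBlock:
    block_id: str
    chrom: str
    marker_indices: list  # contiguous, sorted positions in the genotype matrix
    marker_ids: list
    start_bp: int
    end_bp: int
    alleles: list = field(default_factory=list)  # haplotype strings, frequency-ordered
    allele_freqs: list = field(default_factory=list)

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp

    @property
    def n_snps(self) -> int:
        return len(self.marker_indices)


@dataclass
class HaplotypeGenotypes:
    """Lines x blocks matrix of haplotype-allele indices (-1 = missing)."""

    line_ids: list
    blocks: list  # HaplotypeBlock, aligned with columns
    calls: np.ndarray  # int16, -1 missing

    @property
    def block_ids(self) -> list:
        return [b.block_id for b in self.blocks]

    def column(self, block_id: str) -> np.ndarray:
        return self.calls[:, self.block_ids.index(block_id)]


def _pair_class(g: GenotypeMatrix, i: int, j: int, params: BlockParams) -> str:
    """Classification for one marker pair; undefined pairs count as inconclusive."""
    counts = _ld._two_locus_hap_counts(g.calls[:, i], g.calls[:, j])
    total = counts.sum()
    if total < 4:
        return _ld.INCONCLUSIVE
    p_A = (counts[0] + counts[1]) / total
    p_B = (counts[0] + counts[2]) / total
    if p_A in (0.0, 1.0) or p_B in (0.0, 1.0):
        return _ld.INCONCLUSIVE
    lo, hi = _ld.dprime_ci(counts, grid_step=params.grid_step)
    return _ld.classify_pair(lo, hi, params.ci_low_bound, params.ci_high_bound, params.recomb_high_bound)


def _candidate_intervals(g, idx, pos, params):
    """All [a, b] index intervals passing rules (i) + (ii) on one chromosome."""
    m = len(idx)
    cache = {}

    def klass(a, b):
        if (a, b) not in cache:
            cache[(a, b)] = _pair_class(g, idx[a], idx[b], params)
        return cache[(a, b)]

    out = []
    for a in range(m - 1):
        for b in range(a + 1, m):
            if pos[b] - pos[a] > params.max_span_bp:
                break
            if klass(a, b) != _ld.STRONG_LD:
                continue
            n_strong = n_info = n_all = 0
            for i in range(a, b + 1):
                for j in range(i + 1, b + 1):
                    c = klass(i, j)
                    n_all += 1
                    if c == _ld.STRONG_LD:
                        n_strong += 1
                        n_info += 1
                    elif c == _ld.STRONG_RECOMB:
                        n_info += 1
            denom = n_info if params.informative_only else n_all
            if denom >= 1 and n_strong / denom >= params.strong_fraction:
                out.append((a, b))
    return out


def find_blocks(g: GenotypeMatrix, params: BlockParams = None) -> list:
    """Find haplotype blocks on every chromosome of ``g``.

    Returns blocks named ``HB<chrom>.<ordinal>`` with ordinals assigned by
    start position within each chromosome.  Deterministic for fixed input
    and parameters.
    """
    params = params or BlockParams()
    blocks = []
    for chrom in g.chromosomes():
        idx = np.flatnonzero(g.chrom == chrom)
        if len(idx) < 2:
            continue
        pos = g.pos_bp[idx]
        cands = _candidate_intervals(g, idx, pos, params)
        # greedy: most SNPs, widest span, leftmost start
        cands.sort(key=lambda ab: (-(ab[1] - ab[0] + 1), -(pos[ab[1]] - pos[ab[0]]), ab[0]))
        taken = np.zeros(len(idx), dtype=bool)
        accepted = []
        for a, b in cands:
            if taken[a : b + 1].any():
                continue
            taken[a : b + 1] = True
            accepted.append((a, b))
        accepted.sort()
        for ordinal, (a, b) in enumerate(accepted, start=1):
            members = [int(i) for i in idx[a : b + 1]]
            blocks.append(
                HaplotypeBlock(
                    block_id=f"HB{chrom}.{ordinal}",
                    chrom=str(chrom),
                    marker_indices=members,
                    marker_ids=[g.marker_ids[i] for i in members],
                    start_bp=int(pos[a]),
                    end_bp=int(pos[b]),
                )
            )
    return blocks


def call_haplotype_alleles(
    g: GenotypeMatrix, block: HaplotypeBlock, min_allele_freq: float = 0.05
) -> tuple:
    """Per-line haplotype-allele calls for one block.

    A line's haplotype is the concatenation of its homozygous nucleotide
    calls across the member SNPs; any missing or heterozygous member call
    makes the line missing for the block.  Alleles below ``min_allele_freq``
    (among called lines) are recoded missing and dropped from the catalogue.

    Returns
    -------
    (codes, block) : (ndarray of int16, HaplotypeBlock)
        Allele indices per line (-1 = missing) ordered by descending allele
        frequency, and the block with its allele catalogue filled in.
    """
    sub = g.calls[:, block.marker_indices]
    hom = (sub == 0) | (sub == 2)
    called = hom.all(axis=1)
    if not called.any():
        logger.warning("block %s: no line has a complete homozygous haplotype", block.block_id)
        block.alleles, block.allele_freqs = [], []
        return np.full(g.n_lines, MISSING, dtype=np.int16), block
    nucs = np.array(
        [[maj, mnr] for (maj, mnr) in (g.alleles[i] for i in block.marker_indices)], dtype=object
    )
    pat = sub[called] // 2  # 0 major / 1 minor
    strings = np.array(["".join(nucs[k][p] for k, p in enumerate(row)) for row in pat], dtype=object)
    uniq, counts = np.unique(strings, return_counts=True)
    freqs = counts / called.sum()
    keep = freqs >= min_allele_freq
    order = np.lexsort((uniq[keep], -freqs[keep]))
    catalogue = list(uniq[keep][order])
    block.alleles = catalogue
    block.allele_freqs = [float(f) for f in freqs[keep][order]]
    code_of = {s: k for k, s in enumerate(catalogue)}
    codes = np.full(g.n_lines, MISSING, dtype=np.int16)
    codes[np.flatnonzero(called)] = [code_of.get(s, MISSING) for s in strings]
    return codes, block


def build_haplotype_genotypes(
    g: GenotypeMatrix, blocks: list, min_allele_freq: float = 0.05
) -> HaplotypeGenotypes:
    """Call alleles for every block and assemble the lines x blocks matrix."""
    cols = []
    for b in blocks:
        codes, _ = call_haplotype_alleles(g, b, min_allele_freq)
        cols.append(codes)
    calls = np.stack(cols, axis=1) if cols else np.empty((g.n_lines, 0), dtype=np.int16)
    return HaplotypeGenotypes(line_ids=list(g.line_ids), blocks=list(blocks), calls=calls)


def genome_coverage(g: GenotypeMatrix) -> dict:
    """Per-chromosome, per-subgenome, and total genome span in Mb.

    Span per chromosome is last-SNP minus first-SNP physical position.
    Subgenomes are read from the trailing letter of wheat-style chromosome
    labels (1A..7D); other labels are pooled under ``"other"``.
    """
    per_chrom = {}
    for chrom in g.chromosomes():
        pos = g.pos_bp[g.chrom == chrom]
        if len(pos) < 2:
            continue
        per_chrom[str(chrom)] = (int(pos.max()) - int(pos.min())) / 1e6
    per_subgenome = {}
    for chrom, mb in per_chrom.items():
        sub = chrom[-1] if chrom and chrom[-1] in "ABD" else "other"
        per_subgenome[sub] = per_subgenome.get(sub, 0.0) + mb
    return {
        "per_chromosome_mb": per_chrom,
        "per_subgenome_mb": per_subgenome,
        "total_mb": sum(per_chrom.values()),
    }
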