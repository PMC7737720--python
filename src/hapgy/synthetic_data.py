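"""Forward-in-time simulation of inbred-line genotypes and multi-environment
yield-trial phenotypes.

The generator emulates the statistical structure of an elite-yield-trial
panel: a few dozen founders, several generations of random crossing with
Poisson crossovers (producing block-structured LD that decays over ~Mb
scales), selfing to near-homozygosity, GBS-style missingness, and grain
yield built from additive QTL at SNPs or haplotype blocks, planted
epistatic terms, a polygenic term with VanRaden-kinship covariance,
genotype-by-environment effect scaling, and alpha-lattice trial noise
(replicate, incomplete-block, and plot residual effects) calibrated so the
entry-mean broad-sense heritability hits a per-environment target.

One global seed expands into per-stage child streams, so adding a stage
never perturbs earlier draws, and every output is deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from hapgy.io_genotypes import MISSING, GenotypeMatrix

_NUCS = ("A", "C", "G", "T")


@dataclass
class ChromosomeSpec:
    length_bp: int = 100_000_000
    n_markers: int = 667


@dataclass
class QTLEffect:
    """Additive QTL: per-environment effect (kg/ha) of one minor-allele copy
    relative to the major homozygote is ``env_effects[env] / 2``; the
    minor homozygote carries the full effect."""

    marker: int
    env_effects: dict  # environment -> kg/ha for the minor homozygote


@dataclass
class EpistaticTerm:
    """Interaction effect added for lines carrying the minor homozygote at
    every listed marker (2 or 3 loci)."""

    markers: tuple
    effect: float  # kg/ha
    environments: Optional[tuple] = None  # None = all


@dataclass
class SimulationSpec:
    """Study-condition defaults for the generator.

    Defaults mirror an elite-yield-trial cohort at desk scale: 1,000 inbred
    lines over three 100-Mb chromosomes with 2,000 markers, founder MAF in
    [0.2, 0.5], 8 generations of random crossing at ~1.5 crossovers per
    chromosome per meiosis, 6 selfing generations, 10% missing calls, four
    testing environments with entry-mean heritability targets inside the
    0.31-0.63 range observed in such trials, and an alpha-lattice layout of
    3 replicates with incomplete blocks of 6 plots.
    """

    n_lines: int = 1000
    n_founders: int = 40
    chromosomes: list = field(default_factory=lambda: [ChromosomeSpec() for _ in range(3)])
    founder_maf_range: tuple = (0.2, 0.5)
    founder_ld_scale_bp: float = 2_000_000.0  # ancestral LD correlation length
    recombination_rate: float = 1.5  # crossovers / chromosome / meiosis
    generations: int = 8
    selfing_generations: int = 6
    missing_rate: float = 0.10
    het_residual_rate: float = 0.0  # extra hets injected on top of residual selfing hets
    qtl: list = field(default_factory=list)  # QTLEffect
    epistasis: list = field(default_factory=list)  # EpistaticTerm
    environments: tuple = ("I", "MD", "SD", "HS")
    env_means: dict = field(
        default_factory=lambda: {"I": 6000.0, "MD": 4500.0, "SD": 2500.0, "HS": 3500.0}
    )
    gxe_scale: dict = field(default_factory=lambda: {"I": 1.0, "MD": 0.9, "SD": 0.7, "HS": 0.8})
    target_h2: dict = field(default_factory=lambda: {"I": 0.6, "MD": 0.5, "SD": 0.4, "HS": 0.35})
    polygenic_sd: float = 300.0  # kg/ha
    n_cohorts: int = 7
    replicates: int = 3
    block_size: int = 6
    block_effect_sd: float = 150.0  # kg/ha
    replicate_effect_sd: float = 100.0  # kg/ha
    dh_gy_corr: dict = field(default_factory=lambda: {"I": 0.3, "MD": -0.25, "SD": -0.3, "HS": -0.3})
    seed: int = 0

    def __post_init__(self):
        for r in (self.missing_rate, self.het_residual_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if sum(c.n_markers for c in self.chromosomes) == 0:
            raise ValueError("spec places no markers")


def _stage_rngs(seed: int, names):
    """Named independent child streams from one global seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _meiosis(h0, h1, pos, length_bp, rate, rng):
    """One gamete from a diploid (two marker-indexed haplotypes)."""
    n_x = rng.poisson(rate)
    cur = rng.integers(2)
    if n_x == 0:
        return (h0 if cur == 0 else h1).copy()
    breaks = np.sort(rng.integers(1, length_bp, size=n_x))
    seg = np.searchsorted(breaks, pos, side="right")  # segment index per marker
    pick = (seg + cur) % 2
    return np.where(pick == 0, h0, h1)


def simulate_genotypes(spec: SimulationSpec):
    """Simulate the inbred-line genotype matrix.

    Returns
    -------
    (g, ancestry) : (GenotypeMatrix, ndarray)
        ``ancestry`` holds the founder index of origin for each line's two
        haplotypes at every marker (n_lines x 2 x n_markers, int16).
    """
    rngs = _stage_rngs(spec.seed, ["founders", "positions", "mating", "selfing", "missing", "hets"])
    # marker map
    chroms, poss = [], []
    for c_idx, c in enumerate(spec.chromosomes):
        p = np.sort(rngs["positions"].choice(np.arange(1, c.length_bp), size=c.n_markers, replace=False))
        poss.append(p)
        chroms.extend([f"chr{c_idx + 1}"] * c.n_markers)
    n_markers = sum(len(p) for p in poss)
    bounds = np.cumsum([0] + [len(p) for p in poss])

    freqs = rngs["founders"].uniform(*spec.founder_maf_range, size=n_markers)
    # Founder haplotypes: marginal allele frequency `freqs`, with ancestral
    # LD built in through a Gaussian-copula AR(1) along each chromosome
    # (correlation exp(-d / founder_ld_scale_bp) between adjacent markers).
    # Descendants carry founder-haplotype ids (ancestry); alleles are looked
    # up at the end -- every haplotype is a mosaic of founder haplotypes.
    from scipy.stats import norm as _norm

    n_hap = 2 * spec.n_founders
    z = np.empty((n_hap, n_markers))
    rng_f = rngs["founders"]
    for c_idx in range(len(spec.chromosomes)):
        s, t = bounds[c_idx], bounds[c_idx + 1]
        eps = rng_f.standard_normal((n_hap, t - s))
        z[:, s] = eps[:, 0]
        if spec.founder_ld_scale_bp > 0:
            a = np.exp(-np.diff(poss[c_idx]) / spec.founder_ld_scale_bp)
        else:
            a = np.zeros(t - s - 1)
        for m in range(1, t - s):
            z[:, s + m] = a[m - 1] * z[:, s + m - 1] + np.sqrt(1 - a[m - 1] ** 2) * eps[:, m]
    fh = (z < _norm.ppf(freqs)).astype(np.int8)
    f_anc = np.arange(2 * spec.n_founders, dtype=np.int16).reshape(spec.n_founders, 2)
    f_anc = np.broadcast_to(f_anc[:, :, None], (spec.n_founders, 2, n_markers)).copy()

    def recombine(anc_pair, rng):
        """Gamete ancestry from one diploid's two ancestry tracks."""
        out = np.empty(n_markers, dtype=np.int16)
        for c_idx in range(len(spec.chromosomes)):
            s, t = bounds[c_idx], bounds[c_idx + 1]
            out[s:t] = _meiosis(
                anc_pair[0, s:t], anc_pair[1, s:t], poss[c_idx],
                spec.chromosomes[c_idx].length_bp, spec.recombination_rate, rng,
            )
        return out

    anc = f_anc
    rng_mate = rngs["mating"]
    for gen in range(spec.generations):
        n_parents = anc.shape[0]
        n_children = (
            spec.n_lines
            if gen == spec.generations - 1 or n_parents >= spec.n_lines
            else min(spec.n_lines, n_parents * 4)
        )
        child = np.empty((n_children, 2, n_markers), dtype=np.int16)
        for k in range(n_children):
            pa, pb = rng_mate.choice(n_parents, size=2, replace=False)
            child[k, 0] = recombine(anc[pa], rng_mate)
            child[k, 1] = recombine(anc[pb], rng_mate)
        anc = child

    rng_self = rngs["selfing"]
    for _ in range(spec.selfing_generations):
        new_a = np.empty_like(anc)
        for k in range(anc.shape[0]):
            new_a[k, 0] = recombine(anc[k], rng_self)
            new_a[k, 1] = recombine(anc[k], rng_self)
        anc = new_a

    # alleles from founder ancestry
    col = np.arange(n_markers)
    hap = fh[anc, col]  # (n_lines, 2, n_markers)
    dose = hap.sum(axis=1)  # copies of allele 1
    # orient so code 2 = minor homozygote
    p1 = dose.mean(axis=0) / 2.0
    flip = p1 > 0.5
    dose[:, flip] = 2 - dose[:, flip]
    calls = dose.astype(np.int8)
    if spec.het_residual_rate > 0:
        inject = rngs["hets"].random(calls.shape) < spec.het_residual_rate
        calls = np.where(inject, 1, calls)
    if spec.missing_rate > 0:
        miss = rngs["missing"].random(calls.shape) < spec.missing_rate
        calls = np.where(miss, MISSING, calls)
    nuc_pairs = [tuple(rngs["founders"].choice(_NUCS, size=2, replace=False)) for _ in range(n_markers)]
    g = GenotypeMatrix(
        line_ids=[f"L{k:05d}" for k in range(calls.shape[0])],
        marker_ids=[f"S{c}_{p}" for c, p in zip(chroms, np.concatenate(poss))],
        chrom=np.asarray(chroms, dtype=object),
        pos_bp=np.concatenate(poss),
        calls=calls,
        alleles=np.array(nuc_pairs, dtype=object),
    )
    return g, anc


# ---------------------------------------------------------------------------
# phenotypes


def _true_dose(g: GenotypeMatrix, rng) -> np.ndarray:
    """Minor-allele dose with missing calls filled from column frequency
    (phenotype generation must not depend on missingness)."""
    dose = g.calls.astype(np.float64)
    obs = g.calls != MISSING
    col_mean = np.where(obs, dose, 0.0).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
    return np.where(obs, dose, col_mean)


def genetic_values(g: GenotypeMatrix, spec: SimulationSpec, rng) -> dict:
    """Per-environment total genetic value (kg/ha) for every line."""
    dose = _true_dose(g, rng)
    n = g.n_lines
    u = np.zeros(n)
    if spec.polygenic_sd > 0:
        from hapgy.assoc import vanraden_kinship

        K = vanraden_kinship(g).values
        w, V = np.linalg.eigh(K)
        w = np.maximum(w, 0.0)
        u = V @ (np.sqrt(w) * rng.standard_normal(n)) * spec.polygenic_sd
    values = {}
    for env in spec.environments:
        gv = u.copy()
        for q in spec.qtl:
            eff = q.env_effects.get(env, 0.0)
            gv += eff * dose[:, q.marker] / 2.0
        for t in spec.epistasis:
            if t.environments is not None and env not in t.environments:
                continue
            ind = np.ones(n)
            for m in t.markers:
                ind *= dose[:, m] >= 1.5  # minor homozygote (allowing imputed)
            gv += t.effect * ind
        values[env] = spec.gxe_scale.get(env, 1.0) * gv
    return values


def simulate_phenotypes(g: GenotypeMatrix, spec: SimulationSpec, genetic: Optional[dict] = None) -> pd.DataFrame:
    """Alpha-lattice plot-level phenotype table for every environment.

    Lines are split into ``n_cohorts`` trials; within a trial x environment
    the entries are laid out in experiments of 28 entries plus 2 shared
    check lines, 3 replicates each, with incomplete blocks of
    ``block_size`` plots.  The plot residual standard deviation is set per
    environment so that the realized entry-mean broad-sense heritability

        H2 = Var_g / (Var_g + sigma2_plot / r)

    matches ``target_h2``.  Raises when the target is positive but the
    genetic variance is zero.
    """
    rngs = _stage_rngs(spec.seed + 1_000_003, ["genetic", "layout", "noise", "traits"])
    if genetic is None:
        genetic = genetic_values(g, spec, rngs["genetic"])
    n = g.n_lines
    cohort_of = np.array_split(np.arange(n), spec.n_cohorts)
    check_ids = ["CHECK1", "CHECK2"]
    rows = {k: [] for k in (
        "trial_id", "environment", "experiment_id", "replicate", "incomplete_block",
        "entry_id", "is_check", "GY", "DH", "PH",
    )}
    rng_noise = rngs["noise"]
    rng_traits = rngs["traits"]
    for env in spec.environments:
        gv = genetic[env]
        var_g = float(np.var(gv))
        h2 = spec.target_h2.get(env, 0.5)
        if h2 > 0 and var_g <= 0:
            raise ValueError(f"target H2 {h2} unattainable: zero genetic variance in {env}")
        sigma_plot = np.sqrt(spec.replicates * var_g * (1 - h2) / h2) if h2 > 0 else spec.polygenic_sd + 500.0
        z = (gv - gv.mean()) / (np.sqrt(var_g) if var_g > 0 else 1.0)
        rho = spec.dh_gy_corr.get(env, 0.0)
        dh_line = 70.0 + 5.0 * (rho * z + np.sqrt(max(1 - rho ** 2, 0.0)) * rng_traits.standard_normal(n))
        ph_line = 100.0 + 8.0 * (0.3 * z + np.sqrt(1 - 0.09) * rng_traits.standard_normal(n))
        check_gv = float(gv.mean())
        for c_idx, members in enumerate(cohort_of):
            trial = f"EYT{c_idx + 1}"
            n_exp = int(np.ceil(len(members) / 28))
            for e_idx in range(n_exp):
                entry_lines = members[e_idx * 28 : (e_idx + 1) * 28]
                entry_ids = [g.line_ids[i] for i in entry_lines] + check_ids
                entry_gv = np.concatenate([gv[entry_lines], [check_gv, check_gv]])
                entry_dh = np.concatenate([dh_line[entry_lines], [70.0, 70.0]])
                entry_ph = np.concatenate([ph_line[entry_lines], [100.0, 100.0]])
                n_entries = len(entry_ids)
                for rep in range(1, spec.replicates + 1):
                    rep_eff = rng_noise.normal(0.0, spec.replicate_effect_sd)
                    order = rng_noise.permutation(n_entries)
                    n_blocks = int(np.ceil(n_entries / spec.block_size))
                    blk_eff = rng_noise.normal(0.0, spec.block_effect_sd, size=n_blocks)
                    for slot, k in enumerate(order):
                        blk = slot // spec.block_size
                        gy = (
                            spec.env_means.get(env, 5000.0)
                            + entry_gv[k]
                            + rep_eff
                            + blk_eff[blk]
                            + rng_noise.normal(0.0, sigma_plot)
                        )
                        rows["trial_id"].append(trial)
                        rows["environment"].append(env)
                        rows["experiment_id"].append(f"{trial}-{env}-E{e_idx + 1}")
                        rows["replicate"].append(rep)
                        rows["incomplete_block"].append(blk + 1)
                        rows["entry_id"].append(entry_ids[k])
                        rows["is_check"].append(entry_ids[k] in check_ids)
                        rows["GY"].append(gy)
                        rows["DH"].append(entry_dh[k] + rng_noise.normal(0.0, 1.5))
                        rows["PH"].append(entry_ph[k] + rng_noise.normal(0.0, 3.0))
    return pd.DataFrame(rows)


def cohort_labels(g: GenotypeMatrix, spec: SimulationSpec) -> np.ndarray:
    """Trial (cohort) label per line, matching simulate_phenotypes."""
    labels = np.empty(g.n_lines, dtype=object)
    for c_idx, members in enumerate(np.array_split(np.arange(g.n_lines), spec.n_cohorts)):
        labels[members] = f"EYT{c_idx + 1}"
    return labels


# ---------------------------------------------------------------------------
# structured-null cohort (population stratification without genetic signal)


def simulate_structured_genotypes(
    n_lines: int, n_markers: int, seed: int, fst: float = 0.1, n_chrom: int = 3
):
    """Two-subpopulation genotype panel (Balding-Nichols allele
    frequencies) for null-calibration studies.  Returns the matrix and the
    subpopulation label per line."""
    rng = np.random.default_rng(seed)
    anc = rng.uniform(0.1, 0.9, size=n_markers)
    a = anc * (1 - fst) / fst
    b = (1 - anc) * (1 - fst) / fst
    p_sub = rng.beta(a, b, size=(2, n_markers))
    half = n_lines // 2
    labels = np.array([0] * half + [1] * (n_lines - half))
    # inbred lines: a single allele draw per line determines the homozygote
    u = rng.random((n_lines, n_markers))
    dose = (u < p_sub[labels]).astype(np.int8) * 2
    p_hat = dose.mean(axis=0) / 2.0
    flip = p_hat > 0.5
    dose[:, flip] = 2 - dose[:, flip]
    per = n_markers // n_chrom
    chroms = np.concatenate(
        [[f"chr{c + 1}"] * (per if c < n_chrom - 1 else n_markers - per * (n_chrom - 1)) for c in range(n_chrom)]
    )
    pos = np.concatenate(
        [np.sort(rng.choice(np.arange(1, 100_000_000), size=(chroms == f"chr{c + 1}").sum(), replace=False))
         for c in range(n_chrom)]
    )
    g = GenotypeMatrix(
        line_ids=[f"L{k:05d}" for k in range(n_lines)],
        marker_ids=[f"S{c}_{p}" for c, p in zip(chroms, pos)],
        chrom=chroms.astype(object),
        pos_bp=pos,
        calls=dose,
    )
    return g, labels


# ---------------------------------------------------------------------------
# fixture suite


def fixture_suite(seed: int = 0) -> dict:
    """Small named fixtures with embedded expected-output manifests.

    Every expected value in the manifest is computed at generation time by
    a brute-force oracle (direct counting or enumeration), independent of
    the analysis modules the fixtures exercise.
    """
    rng = np.random.default_rng(seed)
    bundle = {}

    # perfect-LD pair: identical columns
    calls = np.repeat(rng.choice([0, 2], size=(500, 1), p=[0.6, 0.4]), 2, axis=1).astype(np.int8)
    g_perfect = GenotypeMatrix(
        line_ids=[f"P{i}" for i in range(500)],
        marker_ids=["M1", "M2"],
        chrom=["chr1", "chr1"],
        pos_bp=[1000, 2000],
        calls=calls,
    )
    bundle["perfect_ld_pair"] = {
        "genotypes": g_perfect,
        "expected": {"Dprime": 1.0, "r2": 1.0, "classification": "strong_LD"},
    }

    # independence pair: all four gamete classes equally frequent
    quarters = np.array([[0, 0], [0, 2], [2, 0], [2, 2]], dtype=np.int8)
    calls = np.repeat(quarters, 125, axis=0)
    g_indep = GenotypeMatrix(
        line_ids=[f"I{i}" for i in range(500)],
        marker_ids=["M1", "M2"],
        chrom=["chr1", "chr1"],
        pos_bp=[1000, 2000],
        calls=calls,
    )
    bundle["independence_pair"] = {
        "genotypes": g_indep,
        "expected": {"D": 0.0, "r2": 0.0, "classification": "strong_recombination"},
    }

    # 6-SNP chromosome with two planted 3-SNP blocks separated by free recombination
    n = 400
    left = rng.choice([0, 2], size=n, p=[0.5, 0.5])
    right = rng.choice([0, 2], size=n, p=[0.5, 0.5])
    calls = np.column_stack([left, left, left, right, right, right]).astype(np.int8)
    g_blocks = GenotypeMatrix(
        line_ids=[f"B{i}" for i in range(n)],
        marker_ids=[f"M{i}" for i in range(6)],
        chrom=["chr1"] * 6,
        pos_bp=[1_000, 2_000, 3_000, 5_000_000, 5_001_000, 5_002_000],
        calls=calls,
    )
    bundle["block_oracle_6snp"] = {
        "genotypes": g_blocks,
        "expected": {"block_member_ids": [["M0", "M1", "M2"], ["M3", "M4", "M5"]]},
    }

    # 3-block, 4-line stacking fixture with hand-enumerable indicator matrix
    hap_calls = np.array(
        [[0, 0, 0],
         [1, 0, MISSING],
         [0, 1, 1],
         [1, 1, 0]],
        dtype=np.int16,
    )
    favorable = {"HBchr1.1": [0], "HBchr1.2": [1], "HBchr1.3": [0, 1]}
    expected_indicator = np.empty((4, 3), dtype=int)
    for j, bid in enumerate(["HBchr1.1", "HBchr1.2", "HBchr1.3"]):
        fav = favorable[bid]
        for i in range(4):
            c = hap_calls[i, j]
            if c == MISSING:
                expected_indicator[i, j] = MISSING
            elif fav and c == fav[0]:
                expected_indicator[i, j] = 1
            elif c in fav[1:]:
                expected_indicator[i, j] = 2
            else:
                expected_indicator[i, j] = 0
    bundle["stacking_3block"] = {
        "hap_calls": hap_calls,
        "favorable": favorable,
        "expected": {
            "indicator": expected_indicator,
            "counts": ((expected_indicator == 1) | (expected_indicator == 2)).sum(axis=1),
        },
    }

    return bundle
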