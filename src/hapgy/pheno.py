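"""Trial-design-aware phenotype adjustment, ANOVA, and heritability.

Trials follow an alpha-lattice layout: each trial x environment experiment
has entries in 3 replicates, each replicate divided into incomplete blocks.
Grain yield is adjusted for incomplete-block effects within replicate
(blocks treated as random, shrunk toward zero); days-to-heading and plant
height are adjusted against the trial's check lines with

    Y_adj = (Y_ij - Y_i) + Y_all,

where Y_i is the check mean of the trial and Y_all the check mean across
all trials — a location shift that preserves within-trial entry ranking.

Phenotype tables are plain DataFrames with the columns in
:data:`PHENO_COLUMNS` (traits may be missing per plot).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

PHENO_COLUMNS = [
    "trial_id",       # EYT-year cohort label
    "environment",    # I / MD / SD / HS
    "experiment_id",
    "replicate",
    "incomplete_block",
    "entry_id",
    "is_check",
    "GY",             # kg/ha
    "DH",             # days
    "PH",             # cm
]

ENVIRONMENTS = ("I", "MD", "SD", "HS")


@dataclass
class TrialSummary:
    """Variance components and broad-sense heritability for one trial."""

    sigma2_g: float
    sigma2_gxe: float
    sigma2_error: float
    p_genotype: float
    p_environment: float
    p_gxe: float
    heritability: float
    n_entries: int
    n_environments: int
    n_replicates: float
    trait_min: float
    trait_max: float

    def __post_init__(self):
        if not (0.0 <= self.heritability <= 1.0):
            raise ValueError("H2 must lie in [0, 1]")


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# incomplete-block adjustment


def _adjust_one_experiment(sub: pd.DataFrame, trait: str) -> pd.Series:
    """Entry means of block-corrected plot values for one experiment.

    Block effects (within replicate) are estimated from residuals after
    removing replicate and entry effects, then shrunk by the BLUP factor
    sigma2_b / (sigma2_b + sigma2_e / n_b) with moment-based variance
    estimates.  A replicate with a single block gets a zero block effect
    automatically (its residual block mean is zero by construction).
    """
    sub = sub.dropna(subset=[trait])
    y = sub[trait].to_numpy(dtype=np.float64)
    if len(sub) == 0:
        return pd.Series(dtype=np.float64)
    grand = y.mean()
    rep_eff = sub.groupby("replicate")[trait].transform("mean").to_numpy() - grand
    entry_eff = sub.groupby("entry_id")[trait].transform("mean").to_numpy() - grand
    resid = y - grand - rep_eff - entry_eff
    blk = sub["replicate"].astype(str) + "/" + sub["incomplete_block"].astype(str)
    resid_s = pd.Series(resid, index=sub.index)
    blk_mean = resid_s.groupby(blk).transform("mean")
    blk_n = resid_s.groupby(blk).transform("size")
    within = resid_s - blk_mean
    n_blocks = blk.nunique()
    if n_blocks <= sub["replicate"].nunique():
        block_eff = np.zeros(len(sub))
    else:
        dof = max(len(sub) - n_blocks, 1)
        sigma2_e = float((within ** 2).sum()) / dof
        raw_means = resid_s.groupby(blk).mean()
        sizes = resid_s.groupby(blk).size()
        sigma2_b = max(float(raw_means.var(ddof=1)) - sigma2_e / float(sizes.mean()), 0.0)
        if sigma2_b <= 0:
            block_eff = np.zeros(len(sub))
        else:
            shrink = sigma2_b / (sigma2_b + sigma2_e / blk_n)
            block_eff = (shrink * blk_mean).to_numpy()
    corrected = pd.Series(y - block_eff, index=sub.index)
    return corrected.groupby(sub["entry_id"]).mean()


def adjust_gy_block_effects(df: pd.DataFrame, trait: str = "GY") -> pd.DataFrame:
    """Block-effect-adjusted entry means per trial x environment.

    Returns a tidy DataFrame (entry_id, trial_id, environment, value) with
    one adjusted mean per entry x trial x environment.
    """
    validate_phenotypes(df)
    out = []
    for (trial, env, _exp), sub in df.groupby(["trial_id", "environment", "experiment_id"], sort=True):
        if sub["incomplete_block"].isna().all():
            raise ValueError(f"trial {trial}/{env}: incomplete-block labels absent")
        means = _adjust_one_experiment(sub, trait)
        out.append(
            pd.DataFrame(
                {"entry_id": means.index, "trial_id": trial, "environment": env, "value": means.to_numpy()}
            )
        )
    res = pd.concat(out, ignore_index=True)
    # an entry belongs to exactly one experiment; average defensively if not
    return res.groupby(["entry_id", "trial_id", "environment"], as_index=False)["value"].mean()


# ---------------------------------------------------------------------------
# check-based adjustment


def check_adjusted_means(y_ij: float, y_i: float, y_all: float) -> float:
    """(Y_ij - Y_i) + Y_all: shift an entry value by its trial's check mean
    toward the grand check mean."""
    if not (np.isfinite(y_i) and np.isfinite(y_all)):
        raise ValueError("check means must be finite")
    return (y_ij - y_i) + y_all


def check_adjust_table(df: pd.DataFrame, trait: str) -> pd.DataFrame:
    """Vectorized check adjustment of ``trait`` over a phenotype table.

    Check means are computed per trial from plots flagged ``is_check``;
    the grand check mean pools checks over all trials.  Returns a tidy
    (entry_id, trial_id, environment, value) frame of adjusted entry means.
    """
    validate_phenotypes(df)
    work = df.dropna(subset=[trait]).copy()
    checks = work[work["is_check"].astype(bool)]
    if checks.empty:
        raise ValueError("no check plots in the table")
    y_all = checks[trait].mean()
    trial_means = checks.groupby(["trial_id", "environment"])[trait].mean()
    rows = []
    for (trial, env), sub in work.groupby(["trial_id", "environment"]):
        if (trial, env) not in trial_means.index:
            raise ValueError(f"trial {trial}/{env}: no checks, cannot adjust")
        y_i = trial_means.loc[(trial, env)]
        entries = sub[~sub["is_check"].astype(bool)]
        means = entries.groupby("entry_id")[trait].mean()
        rows.append(
            pd.DataFrame(
                {
                    "entry_id": means.index,
                    "trial_id": trial,
                    "environment": env,
                    "value": (means.to_numpy() - y_i) + y_all,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# ANOVA and heritability


def anova_gxe(df: pd.DataFrame, value_col: str = "value") -> TrialSummary:
    """Two-way genotype x environment ANOVA with variance components.

    Input is replicate-level data for one trial: columns ``entry_id``,
    ``environment``, ``replicate``, and ``value_col``.  Expected mean
    squares give the components (replicate count r taken as the harmonic
    mean over cells when unbalanced):

        sigma2_err = MS_err
        sigma2_gxe = (MS_GxE - MS_err) / r
        sigma2_g   = (MS_G - MS_GxE) / (e * r)

    and the entry-mean broad-sense heritability

        H2 = sigma2_g / (sigma2_g + sigma2_gxe / e + sigma2_err / (e r)).

    With a single environment the G x E stratum vanishes and genotype is
    tested against error.  Components are clamped at zero.
    """
    d = df.dropna(subset=[value_col])
    y = d[value_col].to_numpy(dtype=np.float64)
    envs = d["environment"].unique()
    e = len(envs)
    entries = d["entry_id"].unique()
    g = len(entries)
    if g < 2:
        raise ValueError("need >= 2 entries")
    n = len(d)
    cell_sizes = d.groupby(["entry_id", "environment"])[value_col].size()
    r = float(len(cell_sizes) / np.sum(1.0 / cell_sizes))  # harmonic mean reps/cell
    grand = y.mean()
    gm = d.groupby("entry_id")[value_col].agg(["mean", "size"])
    ss_g = float((gm["size"] * (gm["mean"] - grand) ** 2).sum())
    df_g = g - 1
    cell = d.groupby(["entry_id", "environment"])[value_col].agg(["mean", "size"])
    ss_err = float(((y - d.groupby(["entry_id", "environment"])[value_col].transform("mean")) ** 2).sum())
    if e >= 2:
        em = d.groupby("environment")[value_col].agg(["mean", "size"])
        ss_e = float((em["size"] * (em["mean"] - grand) ** 2).sum())
        df_e = e - 1
        ss_cells = float((cell["size"] * (cell["mean"] - grand) ** 2).sum())
        ss_gxe = max(ss_cells - ss_g - ss_e, 0.0)
        df_gxe = (g - 1) * (e - 1)
        df_err = n - len(cell)
        ms_g, ms_e = ss_g / df_g, ss_e / df_e
        ms_gxe = ss_gxe / df_gxe if df_gxe > 0 else np.nan
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        # mixed-model convention: genotype and environment tested against GxE
        p_g = float(stats.f.sf(ms_g / ms_gxe, df_g, df_gxe)) if np.isfinite(ms_gxe) and ms_gxe > 0 else np.nan
        p_e = float(stats.f.sf(ms_e / ms_gxe, df_e, df_gxe)) if np.isfinite(ms_gxe) and ms_gxe > 0 else np.nan
        p_gxe = float(stats.f.sf(ms_gxe / ms_err, df_gxe, df_err)) if df_err > 0 and ms_err > 0 else np.nan
        sigma2_err = ms_err if np.isfinite(ms_err) else 0.0
        sigma2_gxe = max((ms_gxe - sigma2_err) / r, 0.0) if np.isfinite(ms_gxe) else 0.0
        sigma2_g = max((ms_g - (ms_gxe if np.isfinite(ms_gxe) else sigma2_err)) / (e * r), 0.0)
    else:
        df_err = n - g
        ms_g = ss_g / df_g
        ms_err = ss_err / df_err if df_err > 0 else np.nan
        p_g = float(stats.f.sf(ms_g / ms_err, df_g, df_err)) if df_err > 0 and ms_err > 0 else np.nan
        p_e, p_gxe = np.nan, np.nan
        sigma2_err = ms_err if np.isfinite(ms_err) else 0.0
        sigma2_gxe = 0.0
        sigma2_g = max((ms_g - sigma2_err) / r, 0.0)
    denom = sigma2_g + sigma2_gxe / e + sigma2_err / (e * r)
    h2 = sigma2_g / denom if denom > 0 else 0.0
    return TrialSummary(
        sigma2_g=sigma2_g,
        sigma2_gxe=sigma2_gxe,
        sigma2_error=sigma2_err,
        p_genotype=p_g,
        p_environment=p_e,
        p_gxe=p_gxe,
        heritability=min(max(h2, 0.0), 1.0),
        n_entries=g,
        n_environments=e,
        n_replicates=r,
        trait_min=float(y.min()),
        trait_max=float(y.max()),
    )


def trait_correlations(means: pd.DataFrame, traits=("GY", "DH", "PH")) -> pd.DataFrame:
    """Pairwise Pearson correlations among traits per trial x environment.

    ``means`` is a wide frame with one row per entry x trial x environment
    and one column per trait.  Complete cases only; pairs with < 3 complete
    observations or a constant trait are reported with NaN r.
    """
    rows = []
    for (trial, env), sub in means.groupby(["trial_id", "environment"]):
        for t1, t2 in combinations(traits, 2):
            pair = sub[[t1, t2]].dropna()
            if len(pair) < 3 or pair[t1].nunique() < 2 or pair[t2].nunique() < 2:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(pair[t1], pair[t2])
            rows.append(
                {
                    "trial_id": trial,
                    "environment": env,
                    "trait_1": t1,
                    "trait_2": t2,
                    "r": r,
                    "p_value": p,
                    "n": len(pair),
                }
            )
    return pd.DataFrame(rows)
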