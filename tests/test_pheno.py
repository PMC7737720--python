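import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hapgy import pheno


def lattice_table(gv, rng, n_reps=3, block_size=6, block_effects=None, noise_sd=60.0,
                  trial="T1", env="I"):
    """One alpha-lattice experiment with known genotypic values."""
    n = len(gv)
    rows = []
    for rep in range(1, n_reps + 1):
        order = rng.permutation(n)
        n_blocks = int(np.ceil(n / block_size))
        if block_effects is None:
            be = np.zeros(n_blocks)
        elif callable(block_effects):
            be = block_effects(n_blocks)
        else:
            be = block_effects
        for slot, k in enumerate(order):
            b = slot // block_size
            rows.append(
                {
                    "trial_id": trial, "environment": env, "experiment_id": "E1",
                    "replicate": rep, "incomplete_block": b + 1, "entry_id": f"G{k:03d}",
                    "is_check": False, "GY": 5000 + gv[k] + be[b] + rng.normal(0, noise_sd),
                    "DH": np.nan, "PH": np.nan,
                }
            )
    return pd.DataFrame(rows)


class TestBlockAdjustment:
    def test_zero_block_effects_equals_raw_means(self):
        rng = np.random.default_rng(0)
        gv = rng.normal(0, 100, 24)
        df = lattice_table(gv, rng, block_effects=None, noise_sd=0.0)
        adj = pheno.adjust_gy_block_effects(df).set_index("entry_id")["value"]
        raw = df.groupby("entry_id")["GY"].mean()
        assert np.allclose(adj.sort_index(), raw.sort_index(), atol=1e-6)

    def test_planted_block_effects_improve_recovery(self):
        rng = np.random.default_rng(1)
        wins = 0
        for _ in range(10):
            gv = rng.normal(0, 100, 30)
            df = lattice_table(
                gv, rng, block_effects=lambda nb: np.where(rng.random(nb) < 0.5, 200.0, 0.0),
                noise_sd=60.0,
            )
            adj = pheno.adjust_gy_block_effects(df).set_index("entry_id")["value"]
            raw = df.groupby("entry_id")["GY"].mean()
            truth = pd.Series(gv, index=[f"G{k:03d}" for k in range(30)])
            wins += stats.pearsonr(truth[adj.index], adj).statistic > stats.pearsonr(
                truth[raw.index], raw
            ).statistic
        assert wins >= 8

    def test_single_entry_returns_its_mean(self):
        df = pd.DataFrame(
            {
                "trial_id": "T1", "environment": "I", "experiment_id": "E1",
                "replicate": [1, 2, 3], "incomplete_block": 1, "entry_id": "G0",
                "is_check": False, "GY": [100.0, 110.0, 120.0], "DH": np.nan, "PH": np.nan,
            }
        )
        adj = pheno.adjust_gy_block_effects(df)
        assert adj["value"].iloc[0] == pytest.approx(110.0)

    def test_single_block_replicate_gets_zero_effect(self):
        rng = np.random.default_rng(2)
        gv = rng.normal(0, 50, 6)
        df = lattice_table(gv, rng, block_size=6, noise_sd=0.0)  # one block per rep
        adj = pheno.adjust_gy_block_effects(df).set_index("entry_id")["value"]
        raw = df.groupby("entry_id")["GY"].mean()
        assert np.allclose(adj.sort_index(), raw.sort_index(), atol=1e-9)


class TestCheckAdjustment:
    @pytest.mark.parametrize(
        "y_ij,y_i,y_all,expected", [(100, 90, 90, 100), (100, 95, 90, 95), (50, 40, 60, 70)]
    )
    def test_formula(self, y_ij, y_i, y_all, expected):
        assert pheno.check_adjusted_means(y_ij, y_i, y_all) == pytest.approx(expected)

    def test_nonfinite_check_mean_rejected(self):
        with pytest.raises(ValueError):
            pheno.check_adjusted_means(100, np.nan, 90)

    def test_three_trial_hand_calculation(self):
        rows = []
        # checks: trial T1 mean 60, T2 mean 65, T3 mean 70 -> grand 65
        check_vals = {"T1": [58, 62], "T2": [64, 66], "T3": [69, 71]}
        entry_vals = {"T1": 61.0, "T2": 67.0, "T3": 72.0}
        for trial in ("T1", "T2", "T3"):
            for k, v in enumerate(check_vals[trial]):
                rows.append(
                    {"trial_id": trial, "environment": "I", "experiment_id": "E1",
                     "replicate": 1, "incomplete_block": 1, "entry_id": f"CHK{k}",
                     "is_check": True, "GY": np.nan, "DH": v, "PH": np.nan}
                )
            rows.append(
                {"trial_id": trial, "environment": "I", "experiment_id": "E1",
                 "replicate": 1, "incomplete_block": 1, "entry_id": "G0",
                 "is_check": False, "GY": np.nan, "DH": entry_vals[trial], "PH": np.nan}
            )
        adj = pheno.check_adjust_table(pd.DataFrame(rows), "DH").set_index("trial_id")["value"]
        assert adj["T1"] == pytest.approx((61 - 60) + 65)
        assert adj["T2"] == pytest.approx((67 - 65) + 65)
        assert adj["T3"] == pytest.approx((72 - 70) + 65)

    def test_no_checks_raises(self):
        df = pd.DataFrame(
            {"trial_id": "T1", "environment": "I", "experiment_id": "E1", "replicate": [1],
             "incomplete_block": 1, "entry_id": "G0", "is_check": False, "GY": np.nan,
             "DH": [70.0], "PH": np.nan}
        )
        with pytest.raises(ValueError):
            pheno.check_adjust_table(df, "DH")

    def test_rank_preserved_within_trial(self):
        rng = np.random.default_rng(3)
        rows = []
        for k in range(10):
            rows.append(
                {"trial_id": "T1", "environment": "I", "experiment_id": "E1", "replicate": 1,
                 "incomplete_block": 1, "entry_id": f"G{k}", "is_check": False,
                 "GY": np.nan, "DH": float(rng.normal(70, 5)), "PH": np.nan}
            )
        rows.append(
            {"trial_id": "T1", "environment": "I", "experiment_id": "E1", "replicate": 1,
             "incomplete_block": 1, "entry_id": "CHK", "is_check": True, "GY": np.nan,
             "DH": 68.0, "PH": np.nan}
        )
        df = pd.DataFrame(rows)
        adj = pheno.check_adjust_table(df, "DH").set_index("entry_id")["value"]
        raw = df[~df.is_check].set_index("entry_id")["DH"]
        assert (adj.sort_index().rank() == raw.sort_index().rank()).all()


def gxe_table(gv, rng, envs=("I", "MD"), n_reps=3, sigma_gxe=0.0, sigma_err=1.0):
    rows = []
    for env in envs:
        gxe = rng.normal(0, sigma_gxe, len(gv)) if sigma_gxe > 0 else np.zeros(len(gv))
        for k, v in enumerate(gv):
            for rep in range(1, n_reps + 1):
                rows.append(
                    {"entry_id": f"G{k}", "environment": env, "replicate": rep,
                     "value": v + gxe[k] + rng.normal(0, sigma_err)}
                )
    return pd.DataFrame(rows)


class TestAnovaGxE:
    def test_h2_closed_form_single_env(self):
        # sigma2_G = 1, sigma2_err = 1, e = 1, r = 3 -> H2 = 1/(1 + 1/3) = 0.75
        rng = np.random.default_rng(4)
        h2 = [
            pheno.anova_gxe(gxe_table(rng.standard_normal(400), rng, envs=("I",))).heritability
            for _ in range(10)
        ]
        assert np.mean(h2) == pytest.approx(0.75, abs=0.1)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        ps = [
            pheno.anova_gxe(gxe_table(np.zeros(30), rng)).p_genotype for _ in range(200)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_environment_only_clamps_genotype_component(self):
        rng = np.random.default_rng(6)
        df = gxe_table(np.zeros(50), rng, envs=("I", "MD", "SD"), sigma_err=0.1)
        df.loc[df.environment == "MD", "value"] += 100.0
        s = pheno.anova_gxe(df)
        assert s.sigma2_g == pytest.approx(0.0, abs=0.05)
        assert s.p_environment < 1e-6

    def test_h2_recovery_grid(self):
        # entry-mean H2 = sG2 / (sG2 + sE2/(e*r)) recovered within +-0.05
        rng = np.random.default_rng(7)
        for s_g, s_e in [(1.0, 1.0), (2.0, 1.0), (1.0, 3.0)]:
            h2s = []
            for _ in range(5):
                df = gxe_table(rng.normal(0, s_g, 500), rng, envs=("I", "MD"), sigma_err=s_e)
                h2s.append(pheno.anova_gxe(df).heritability)
            expected = s_g**2 / (s_g**2 + s_e**2 / 6)
            assert np.mean(h2s) == pytest.approx(expected, abs=0.05)

    def test_detects_planted_gxe(self):
        rng = np.random.default_rng(8)
        df = gxe_table(rng.standard_normal(100), rng, sigma_gxe=1.0)
        assert pheno.anova_gxe(df).p_gxe < 1e-4


class TestTraitCorrelations:
    def test_perfect_correlation(self):
        df = pd.DataFrame(
            {"trial_id": "T1", "environment": "I", "entry_id": range(10),
             "GY": np.arange(10.0), "DH": np.arange(10.0), "PH": np.nan}
        )
        out = pheno.trait_correlations(df)
        row = out[(out.trait_1 == "GY") & (out.trait_2 == "DH")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.p_value < 1e-10

    def test_independent_traits_near_zero(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(40):
            df = pd.DataFrame(
                {"trial_id": "T1", "environment": "I", "entry_id": range(500),
                 "GY": rng.standard_normal(500), "DH": rng.standard_normal(500), "PH": np.nan}
            )
            out = pheno.trait_correlations(df, traits=("GY", "DH"))
            hits += abs(out.iloc[0].r) < 0.12
        assert hits >= 36  # ~99% expected under the null at n=500

    def test_constant_trait_reported_missing(self):
        df = pd.DataFrame(
            {"trial_id": "T1", "environment": "I", "entry_id": range(5),
             "GY": np.arange(5.0), "DH": 70.0, "PH": np.nan}
        )
        out = pheno.trait_correlations(df, traits=("GY", "DH"))
        assert np.isnan(out.iloc[0].r)
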