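import numpy as np
import pytest
from scipy import stats

from hapgy import assoc
from hapgy.io_genotypes import MISSING


class TestVanRadenKinship:
    def test_hand_computed_toy(self, toy):
        g = toy([[0, 2, 0, 2], [0, 2, 0, 0], [2, 0, 2, 2]])
        K = assoc.vanraden_kinship(g).values
        dose = g.calls.astype(float)
        p = dose.mean(axis=0) / 2
        Z = dose - 2 * p
        expected = Z @ Z.T / (2 * np.sum(p * (1 - p)))
        np.testing.assert_allclose(K, expected, atol=1e-12)

    def test_identical_lines_share_diagonal(self, toy):
        g = toy([[0, 2, 2, 0], [0, 2, 2, 0], [2, 0, 0, 2]])
        K = assoc.vanraden_kinship(g).values
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert K[0, 1] == pytest.approx(K[1, 1])

    def test_fully_inbred_mean_diagonal_near_two(self, toy):
        # homozygous lines have inbreeding F = 1, so E[diag] = 1 + F = 2
        rng = np.random.default_rng(0)
        p = rng.uniform(0.2, 0.5, size=1000)
        calls = (rng.random((200, 1000)) < p).astype(np.int8) * 2
        g = toy(calls, pos=np.arange(1000) + 1)
        K = assoc.vanraden_kinship(g).values
        assert np.mean(np.diag(K)) == pytest.approx(2.0, abs=0.15)
        assert np.mean(np.diag(K)) > K[~np.eye(200, dtype=bool)].mean()

    def test_marker_order_invariance(self, toy):
        rng = np.random.default_rng(1)
        calls = rng.choice([0, 2, MISSING], size=(30, 50), p=[0.5, 0.4, 0.1])
        g = toy(calls, pos=np.arange(50) + 1)
        perm = rng.permutation(50)
        g2 = g.take_markers(perm)
        np.testing.assert_allclose(
            assoc.vanraden_kinship(g).values, assoc.vanraden_kinship(g2).values, atol=1e-10
        )

    def test_monomorphic_input_rejected(self, toy):
        g = toy(np.zeros((5, 4), dtype=np.int8))
        with pytest.raises(ValueError):
            assoc.vanraden_kinship(g)


class TestSelectPcsBic:
    def test_null_prefers_zero_pcs(self):
        rng = np.random.default_rng(2)
        zero = 0
        for _ in range(100):
            pcs = rng.standard_normal((200, 10))
            y = rng.standard_normal(200)
            zero += assoc.select_pcs_bic(pcs, y) == 0
        assert zero >= 80

    def test_structure_effect_detected(self):
        rng = np.random.default_rng(3)
        pcs = rng.standard_normal((300, 10))
        y = pcs[:, 0] + rng.standard_normal(300) * 0.3
        assert assoc.select_pcs_bic(pcs, y) >= 1

    def test_pcs_nonincreasing_in_noise(self):
        rng = np.random.default_rng(4)
        mean_npcs = []
        for noise in (0.2, 1.0, 5.0):
            picks = []
            for rep in range(20):
                sub = np.random.default_rng(100 + rep)
                pcs = sub.standard_normal((200, 10))
                y = pcs[:, 0] + sub.standard_normal(200) * noise
                picks.append(assoc.select_pcs_bic(pcs, y))
            mean_npcs.append(np.mean(picks))
        assert mean_npcs[0] >= mean_npcs[1] >= mean_npcs[2]


class TestMlmAssoc:
    def _simple_setup(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        K = np.eye(n)
        X = np.ones((n, 1))
        codes = rng.integers(0, 3, size=n).astype(np.int16)
        return rng, K, X, codes

    def test_constant_phenotype_p_one(self):
        _, K, X, codes = self._simple_setup()
        y = np.full(200, 5.0)
        null = assoc.fit_null_mlm(y, X, K, delta=np.inf)
        r = assoc.mlm_assoc(codes, y, null, "b")
        assert r.p_value == pytest.approx(1.0)

    def test_sigma_g_zero_matches_ols(self):
        rng, _, X, codes = self._simple_setup(seed=5)
        n = 200
        K = rng.standard_normal((n, n))
        K = K @ K.T / n  # arbitrary PSD kinship
        y = rng.standard_normal(n)
        null = assoc.fit_null_mlm(y, X, K, delta=np.inf)
        r = assoc.mlm_assoc(codes, y, null, "b")
        # reference OLS F-test with the same treatment coding
        alleles, counts = np.unique(codes, return_counts=True)
        ref = alleles[np.argmax(counts)]
        D = np.column_stack([(codes == a).astype(float) for a in alleles if a != ref])
        X1 = np.column_stack([X, D])
        b0, *_ = np.linalg.lstsq(X, y, rcond=None)
        b1, *_ = np.linalg.lstsq(X1, y, rcond=None)
        rss0, rss1 = np.sum((y - X @ b0) ** 2), np.sum((y - X1 @ b1) ** 2)
        f = ((rss0 - rss1) / 2) / (rss1 / (n - 3))
        p = stats.f.sf(f, 2, n - 3)
        assert abs(r.p_value - p) < 1e-10

    def test_relabeling_and_shift_invariance(self):
        rng, K, X, codes = self._simple_setup(seed=6)
        y = rng.standard_normal(200) + 0.5 * (codes == 2)
        null = assoc.fit_null_mlm(y, X, K)
        p1 = assoc.mlm_assoc(codes, y, null, "b").p_value
        relabel = np.array([2, 0, 1], dtype=np.int16)[codes]
        p2 = assoc.mlm_assoc(relabel, y, null, "b").p_value
        null3 = assoc.fit_null_mlm(y + 1000.0, X, K)
        p3 = assoc.mlm_assoc(codes, y + 1000.0, null3, "b").p_value
        assert p1 == pytest.approx(p2, rel=1e-9)
        assert p1 == pytest.approx(p3, rel=1e-6)

    def test_small_classes_merged(self):
        rng, K, X, _ = self._simple_setup(seed=7)
        codes = np.zeros(200, dtype=np.int16)
        codes[:90] = 1
        codes[:5] = 2  # 5-line class, below the 10-line floor
        y = rng.standard_normal(200)
        null = assoc.fit_null_mlm(y, X, K, delta=np.inf)
        r = assoc.mlm_assoc(codes, y, null, "b")
        assert r.df == 1  # only two testable alleles remain
        assert r.n_lines == 195

    def test_single_allele_rejected(self):
        _, K, X, _ = self._simple_setup()
        codes = np.zeros(200, dtype=np.int16)
        y = np.random.default_rng(0).standard_normal(200)
        null = assoc.fit_null_mlm(y, X, K, delta=np.inf)
        with pytest.raises(ValueError):
            assoc.mlm_assoc(codes, y, null, "b")

    def test_polygenic_confounding_controlled(self):
        # a marker correlated with kinship structure should not inflate the
        # MLM test the way it inflates plain OLS
        rng = np.random.default_rng(8)
        n = 300
        labels = np.repeat([0, 1], n // 2)
        base = rng.choice([0, 2], size=(n, 400), p=[0.5, 0.5]).astype(np.int8)
        shift = (rng.random(400) < 0.4)
        base[labels == 1] = np.where(
            (rng.random((n // 2, 400)) < 0.6) & shift, 2, base[labels == 1]
        )
        from hapgy.io_genotypes import GenotypeMatrix

        g = GenotypeMatrix(
            [f"L{i}" for i in range(n)], [f"M{j}" for j in range(400)],
            ["chr1"] * 400, np.arange(400) + 1, base,
        )
        K = assoc.vanraden_kinship(g).values
        y = 0.8 * labels + rng.standard_normal(n)
        X = np.ones((n, 1))
        null = assoc.fit_null_mlm(y, X, K)
        ps_mlm, ps_ols = [], []
        null_ols = assoc.fit_null_mlm(y, X, K, delta=np.inf)
        for j in range(0, 400, 2):
            codes = (base[:, j] // 2).astype(np.int16)
            if len(np.unique(codes)) < 2 or min((codes == 0).sum(), (codes == 1).sum()) < 10:
                continue
            ps_mlm.append(assoc.mlm_assoc(codes, y, null, "b").p_value)
            ps_ols.append(assoc.mlm_assoc(codes, y, null_ols, "b").p_value)
        lam_mlm = assoc.genomic_lambda(ps_mlm)
        lam_ols = assoc.genomic_lambda(ps_ols)
        assert lam_mlm < lam_ols
        assert 0.8 < lam_mlm < 1.3


class TestAllelicEffect:
    def test_equal_means_zero_effect(self):
        codes = np.array([0, 0, 1, 1], dtype=np.int16)
        y = np.array([5.0, 7.0, 5.0, 7.0])
        _, fav, eff = assoc.allelic_effect(codes, y)
        assert eff == pytest.approx(0.0)

    def test_toy_effect_200(self):
        codes = np.array([0] * 10 + [1] * 10 + [2] * 10, dtype=np.int16)
        y = np.array([5200.0] * 10 + [5000.0] * 10 + [5000.0] * 10)
        means, fav, eff = assoc.allelic_effect(codes, y)
        assert fav == [0]
        assert eff == pytest.approx(200.0)

    def test_two_favorable_alleles(self):
        rng = np.random.default_rng(9)
        codes = np.repeat([0, 1, 2], 100).astype(np.int16)
        y = np.concatenate(
            [rng.normal(5300, 30, 100), rng.normal(5280, 30, 100), rng.normal(5000, 30, 100)]
        )
        _, fav, _ = assoc.allelic_effect(codes, y)
        assert set(fav) == {0, 1}

    def test_planted_effect_recovery(self):
        rng = np.random.default_rng(10)
        n, q = 1000, 0.3
        carrier = rng.random(n) < q
        codes = carrier.astype(np.int16)
        var_b = 300**2 * q * (1 - q)
        sd_e = np.sqrt(var_b * (1 - 0.05) / 0.05)  # block h2 = 0.05
        effs = [
            assoc.allelic_effect(codes, 300.0 * carrier + rng.normal(0, sd_e, n))[2]
            for _ in range(100)
        ]
        assert np.mean(effs) == pytest.approx(300.0, rel=0.15)
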