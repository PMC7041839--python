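import itertools

import numpy as np
import pandas as pd
import pytest

from oasisnet import relatedness as rl
from oasisnet import synthdata as sd


def _gt(rows, n_loci=1):
    """Genotype frame from {id: [(a,b), ...]} records."""
    cols = {}
    for li in range(n_loci):
        cols[f"L{li + 1}_a"] = [rows[i][li][0] for i in rows]
        cols[f"L{li + 1}_b"] = [rows[i][li][1] for i in rows]
    return pd.DataFrame(cols, index=pd.Index(list(rows), name="individual"), dtype=float)


class TestAlleleFreqs:
    def test_counting(self):
        gt = _gt({"i1": [(0, 0)], "i2": [(0, 1)]})
        freqs = rl.estimate_allele_freqs(gt)
        assert freqs["L1"] == {0: 0.75, 1: 0.25}

    def test_fixed_locus(self):
        gt = _gt({"i1": [(0, 0)], "i2": [(0, 0)]})
        assert rl.estimate_allele_freqs(gt)["L1"] == {0: 1.0}

    def test_all_missing_locus_errors(self):
        gt = _gt({"i1": [(np.nan, np.nan)], "i2": [(np.nan, np.nan)]})
        with pytest.raises(ValueError, match="typed"):
            rl.estimate_allele_freqs(gt)

    def test_recovers_known_frequencies(self):
        """500 founders at known frequencies: estimates within 0.03 per allele."""
        p = np.array([0.5, 0.3, 0.2])
        ped = sd.Pedigree(tuple(sd.Individual(f"I{i}", "F") for i in range(500)))
        gt = sd.simulate_genotypes(ped, 1, [p], np.random.default_rng(5))
        freqs = rl.estimate_allele_freqs(gt)["L1"]
        for a, want in enumerate(p):
            assert freqs.get(a, 0.0) == pytest.approx(want, abs=0.03)


class TestPairLoglik:
    FREQ = {0: 0.5, 1: 0.3, 2: 0.2}

    def test_ibd_incompatible_pair(self):
        """(AA, BB) can share no allele IBD: P1 = P2 = 0, P0 is the HWE product."""
        p0, p1, p2 = rl.ibd_pair_probs((0, 0), (1, 1), self.FREQ)
        assert (p1, p2) == (0.0, 0.0)
        assert p0 == pytest.approx(0.5**2 * 0.3**2)

    def test_unrelated_limit_is_hwe(self):
        gt_a = np.array([[0, 1], [1, 2]])
        gt_b = np.array([[0, 0], [2, 2]])
        freqs = {"L1": self.FREQ, "L2": self.FREQ}
        ll = rl.pair_loglik(gt_a, gt_b, freqs, (1, 0, 0))
        hwe = np.log(2 * 0.5 * 0.3) + np.log(0.3 * 0.2 * 2) + np.log(0.5**2) + np.log(0.2**2)
        assert ll == pytest.approx(hwe)

    def test_het_pair_at_k1_hand_value(self):
        """(AB, AB) at p = (0.5, 0.5), two loci, k = (0,1,0): each locus term
        is p_A p_B (p_A + p_B) = 0.25."""
        freqs = {"L1": {0: 0.5, 1: 0.5}, "L2": {0: 0.5, 1: 0.5}}
        g = np.array([[0, 1], [0, 1]])
        ll = rl.pair_loglik(g, g, freqs, (0, 1, 0))
        assert ll == pytest.approx(2 * np.log(0.25))

    def test_k_off_simplex_errors(self):
        with pytest.raises(ValueError, match="simplex"):
            rl.pair_loglik(np.array([[0, 1]]), np.array([[0, 1]]), {"L1": self.FREQ}, (0.5, 0.6, 0.2))

    def test_unknown_allele_errors(self):
        with pytest.raises(ValueError, match="absent"):
            rl.ibd_pair_probs((0, 7), (0, 0), self.FREQ)

    @pytest.mark.parametrize("n_alleles", [2, 3, 4])
    def test_conditional_probs_normalize(self, n_alleles):
        """Over all ordered genotype pairs, P0, P1 and P2 each sum to 1."""
        rng = np.random.default_rng(n_alleles)
        p = rng.dirichlet(np.full(n_alleles, 2.0))
        freq = {a: float(p[a]) for a in range(n_alleles)}
        genos = [(i, j) for i in range(n_alleles) for j in range(i, n_alleles)]
        tot = np.zeros(3)
        for ga, gb in itertools.product(genos, genos):
            tot += rl.ibd_pair_probs(ga, gb, freq)
        np.testing.assert_allclose(tot, 1.0, atol=1e-12)

    def test_missing_loci_skipped(self):
        freqs = {"L1": self.FREQ, "L2": self.FREQ}
        ga = np.array([[0, 1], [-1, -1]])
        gb = np.array([[0, 1], [0, 0]])
        full = rl.pair_loglik(ga[:1], gb[:1], {"L1": self.FREQ}, (1, 0, 0))
        assert rl.pair_loglik(ga, gb, freqs, (1, 0, 0)) == pytest.approx(full)


class TestMLRelatedness:
    def test_identical_twins(self):
        """Same informative multilocus genotype: likelihood pushes k2 -> 1."""
        rows = {"t1": [(0, 1), (1, 2), (0, 2), (0, 1)], "t2": [(0, 1), (1, 2), (0, 2), (0, 1)],
                "u1": [(0, 0), (2, 2), (1, 1), (2, 2)]}
        gt = _gt(rows, n_loci=4)
        freqs = {f"L{i}": {0: 0.4, 1: 0.35, 2: 0.25} for i in range(1, 5)}
        res = rl.ml_relatedness(gt, freqs)
        pair = res.pairs.set_index(["id_a", "id_b"]).loc[("t1", "t2")]
        assert pair["k2"] > 0.9 and pair["r"] > 0.9

    def test_grid_oracle(self):
        """Optimized r within 0.02 of the best point on a fine (0.01) grid."""
        rng = np.random.default_rng(9)
        freqs_list = sd.random_allele_frequencies(13, rng)
        ped = sd.simulate_pedigree(10, 1, 2.0, rng)
        gt = sd.simulate_genotypes(ped, 13, freqs_list, rng)
        ids, loci, arr = rl.genotypes_from_frame(gt)
        freqs = rl.estimate_allele_freqs(gt)
        fine = rl._simplex_grid(0.01)
        pairs = list(itertools.combinations(range(len(ids)), 2))[:20]
        for i, j in pairs:
            probs = rl._pair_prob_matrix(arr[i], arr[j], loci, freqs)
            *_, r_hat = rl.ml_pair(probs)
            vals = probs @ fine.T
            with np.errstate(divide="ignore"):
                ll = np.where(vals > 0, np.log(np.maximum(vals, 1e-300)), -np.inf).sum(axis=0)
            k_best = fine[np.argmax(ll)]
            r_grid = k_best[1] / 2 + k_best[2]
            assert abs(r_hat - r_grid) <= 0.02

    def test_zero_shared_loci_missing(self):
        rows = {"a": [(0, 1), (np.nan, np.nan)], "b": [(np.nan, np.nan), (0, 1)],
                "c": [(0, 1), (0, 1)]}
        gt = _gt(rows, n_loci=2)
        freqs = {"L1": {0: 0.5, 1: 0.5}, "L2": {0: 0.5, 1: 0.5}}
        res = rl.ml_relatedness(gt, freqs)
        pair = res.pairs.set_index(["id_a", "id_b"]).loc[("a", "b")]
        assert np.isnan(pair["r"])

    def test_single_individual_errors(self):
        with pytest.raises(ValueError, match="2 individuals"):
            rl.ml_relatedness(_gt({"a": [(0, 1)]}))

    def test_matrix_symmetric_and_aligned(self):
        rng = np.random.default_rng(10)
        ped = sd.simulate_pedigree(6, 1, 2.0, rng)
        gt = sd.simulate_genotypes(ped, 5, sd.random_allele_frequencies(5, rng), rng)
        res = rl.ml_relatedness(gt)
        m = res.matrix.to_numpy()
        np.testing.assert_allclose(m, m.T, equal_nan=True)
        assert list(res.matrix.index) == res.individuals
        off = m[~np.eye(len(m), dtype=bool)]
        assert np.nanmin(off) >= 0.0 and np.nanmax(off) <= 1.0
        k = res.pairs[["k0", "k1", "k2"]].to_numpy()
        np.testing.assert_allclose(k.sum(axis=1), 1.0, atol=1e-6)


class TestCompareDistributions:
    @staticmethod
    def _matrix(values_by_pair, ids):
        m = pd.DataFrame(np.nan, index=ids, columns=ids)
        for (a, b), v in values_by_pair.items():
            m.loc[a, b] = m.loc[b, a] = v
        return m

    def test_identical_distributions_d_zero(self):
        ids = ["a1", "a2", "a3", "b1", "b2", "b3"]
        vals = {}
        for grp in (["a1", "a2", "a3"], ["b1", "b2", "b3"]):
            for x, y in itertools.combinations(grp, 2):
                vals[(x, y)] = 0.25
        m = self._matrix(vals, ids)
        labels = pd.Series({"a1": "w", "a2": "w", "a3": "w", "b1": "s", "b2": "s", "b3": "s"})
        res = rl.compare_r_distributions(m, labels, n_perm=99, rng=np.random.default_rng(0))
        assert res["statistic"] == 0.0

    def test_disjoint_distributions_d_one(self):
        ids = ["a1", "a2", "a3", "b1", "b2", "b3"]
        vals = {}
        for grp, v in ((["a1", "a2", "a3"], 0.0), (["b1", "b2", "b3"], 1.0)):
            for x, y in itertools.combinations(grp, 2):
                vals[(x, y)] = v
        m = self._matrix(vals, ids)
        labels = pd.Series({i: ("w" if i.startswith("a") else "s") for i in ids})
        res = rl.compare_r_distributions(m, labels, n_perm=99, rng=np.random.default_rng(0))
        assert res["statistic"] == 1.0

    def test_single_group_errors(self):
        ids = ["a1", "a2", "a3"]
        m = self._matrix({(a, b): 0.1 for a, b in itertools.combinations(ids, 2)}, ids)
        labels = pd.Series({i: "w" for i in ids})
        with pytest.raises(ValueError, match="2 season groups"):
            rl.compare_r_distributions(m, labels, n_perm=99)

    def test_fast_d_matches_scipy(self):
        from scipy import stats

        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.normal(size=13), rng.normal(0.3, 1, size=17)
            assert rl.ks_statistic(a, b) == pytest.approx(
                stats.ks_2samp(a, b).statistic, abs=1e-12
            )

    def test_type_one_error_calibrated(self):
        """Random season labels at study scale (31 vs 32 individuals):
        rejection rate at alpha=0.05 stays near nominal.  Scaled down to
        200 reps x 299 permutations to keep the suite fast, with the band
        widened accordingly for Monte-Carlo error.  Small groups make the
        discrete D statistic conservative; study-sized groups do not."""
        rng = np.random.default_rng(17)
        n = 63
        base = rng.beta(0.5, 4, size=(n, n))
        m_arr = (base + base.T) / 2
        np.fill_diagonal(m_arr, np.nan)
        ids = [f"i{k}" for k in range(n)]
        m = pd.DataFrame(m_arr, index=ids, columns=ids)
        reps, reject = 200, 0
        for _ in range(reps):
            lab = np.array(["w"] * 31 + ["s"] * 32)
            rng.shuffle(lab)
            labels = pd.Series(lab, index=ids)
            res = rl.compare_r_distributions(m, labels, n_perm=299, rng=rng)
            reject += res["p"] <= 0.05
        assert 0.02 <= reject / reps <= 0.09
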