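import numpy as np
import pytest

from admixkit import (AlleleFrequencyTable, block_jackknife, f4,
                      f4_ratio_ancestry, four_population_test, fst_pairwise,
                      simulate_admixture_graph, allele_frequencies)
from admixkit.fstats import jackknife_from_deletes, map_blocks

from conftest import make_genotypes


def freq_table(freqs_by_pop, gpos=None, chrom=None, counts=None):
    pops = list(freqs_by_pop)
    F = np.column_stack([freqs_by_pop[p] for p in pops])
    m = F.shape[0]
    C = np.full_like(F, 100, dtype=np.int64) if counts is None else counts
    gpos = np.linspace(0, 1.0, m, endpoint=False) if gpos is None else gpos
    chrom = np.full(m, "1", dtype=object) if chrom is None else chrom
    return AlleleFrequencyTable(pops, F, C, [f"snp{i}" for i in range(m)],
                                chrom, gpos)


class TestBlockJackknife:
    def test_identical_block_means_zero_se(self):
        vals = np.tile([1.0, 2.0, 3.0], 10)
        gpos = np.repeat(np.arange(10) * 0.05, 3) + np.tile([0.01, 0.02, 0.03], 10)
        est = block_jackknife(vals, np.full(30, "1", dtype=object), gpos,
                              block_m=0.05)
        assert est.std_err == pytest.approx(0.0, abs=1e-12)
        assert est.estimate == pytest.approx(2.0)

    def test_two_equal_blocks_closed_form(self):
        # blocks of k values v1 and v2: delete-one estimates are v2 and v1;
        # equal weights give SE = |v1 - v2| / 2
        v1, v2, k = 0.3, 0.9, 8
        vals = np.r_[np.full(k, v1), np.full(k, v2)]
        gpos = np.r_[np.linspace(0, 0.04, k), np.linspace(0.05, 0.09, k)]
        est = block_jackknife(vals, np.full(2 * k, "1", dtype=object), gpos,
                              block_m=0.05)
        assert est.n_blocks == 2
        assert est.std_err == pytest.approx(abs(v1 - v2) / 2)

    def test_linear_statistic_unbiased(self, rng):
        vals = rng.normal(size=200)
        est = block_jackknife(vals, np.full(200, "1", dtype=object),
                              np.linspace(0, 1, 200), block_m=0.05)
        assert est.estimate == pytest.approx(vals.mean())

    def test_se_shrinks_with_n(self, rng):
        ses = []
        for m in (200, 3200):
            vals = rng.normal(size=m)
            est = block_jackknife(vals, np.full(m, "1", dtype=object),
                                  np.linspace(0, 1, m), block_m=0.05)
            ses.append(est.std_err)
        assert ses[1] < ses[0] / 2  # ~1/4 expected for 16x the data

    def test_single_block_rejected(self):
        with pytest.raises(ValueError):
            block_jackknife(np.ones(5), np.full(5, "1", dtype=object),
                            np.linspace(0, 0.01, 5), block_m=0.05)

    def test_chromosome_blocks(self):
        chrom = np.array(["1"] * 5 + ["2"] * 5, dtype=object)
        blocks = map_blocks(chrom, np.r_[np.linspace(0, 1, 5)] .repeat(1)
                            if False else np.tile(np.linspace(0, 1, 5), 2),
                            "chromosome")
        assert len(np.unique(blocks)) == 2


class TestF4:
    def test_hand_mean_of_products(self):
        t = freq_table({"A": [1, 0.5], "B": [0, 0.5], "C": [1, 0.2], "D": [0, 0.9]})
        est = f4(t, "A", "B", "C", "D", block_m=0.25)
        # products: (1-0)(1-0)=1 and (0)(...)=0 -> mean 0.5
        assert est.estimate == pytest.approx(0.5)

    def test_identical_cd_gives_zero(self, rng):
        p = rng.uniform(0.1, 0.9, 40)
        t = freq_table({"A": rng.uniform(0.1, 0.9, 40),
                        "B": rng.uniform(0.1, 0.9, 40), "C": p, "D": p})
        assert f4(t, "A", "B", "C", "D").estimate == 0.0

    def test_antisymmetry_and_pair_swap(self, rng):
        t = freq_table({k: rng.uniform(0.05, 0.95, 60) for k in "ABCD"})
        a = f4(t, "A", "B", "C", "D").estimate
        assert f4(t, "B", "A", "C", "D").estimate == pytest.approx(-a, abs=1e-15)
        assert f4(t, "C", "D", "A", "B").estimate == pytest.approx(a, abs=1e-15)

    def test_linearity_in_frequency_vectors(self, rng):
        base = {k: rng.uniform(0.05, 0.95, 60) for k in "ABCD"}
        mix = dict(base)
        lam = 0.3
        other = rng.uniform(0.05, 0.95, 60)
        mix["A"] = lam * base["A"] + (1 - lam) * other
        fa = f4(freq_table(base), "A", "B", "C", "D").estimate
        fo = f4(freq_table({**base, "A": other}), "A", "B", "C", "D").estimate
        fm = f4(freq_table(mix), "A", "B", "C", "D").estimate
        assert fm == pytest.approx(lam * fa + (1 - lam) * fo)


class TestFourPopulationTest:
    def _tree_table(self, rng, admix=0.0, m=4000):
        """((A,B),(C,D)) tree at frequency level; D optionally admixed from B."""
        from admixkit.simulate import balding_nichols
        p = rng.uniform(0.1, 0.9, m)
        pab = balding_nichols(p, 0.05, rng)
        pcd = balding_nichols(p, 0.05, rng)
        A = balding_nichols(pab, 0.05, rng)
        B = balding_nichols(pab, 0.05, rng)
        C = balding_nichols(pcd, 0.05, rng)
        D = balding_nichols(pcd, 0.05, rng)
        if admix:
            D = admix * B + (1 - admix) * D
        return freq_table({"A": A, "B": B, "C": C, "D": D})

    def test_null_tree_accepted_in_most_replicates(self):
        hits = 0
        for s in range(20):
            t = self._tree_table(np.random.default_rng(100 + s))
            res = four_population_test(t, "A", "B", "C", "D")
            hits += not res.tree_rejected
        assert hits >= 18

    def test_admixture_rejected(self):
        t = self._tree_table(np.random.default_rng(7), admix=0.2)
        res = four_population_test(t, "A", "B", "C", "D")
        assert res.tree_rejected and abs(res.z) > 3

    def test_constant_difference_rejected(self):
        p = np.full(50, 0.5)
        t = freq_table({"A": p, "B": p, "C": p + 0.1, "D": p - 0.1})
        with pytest.raises(ValueError, match="constant"):
            four_population_test(t, "A", "B", "C", "D")


class TestF4Ratio:
    def test_pure_clade_w_gives_one(self, rng):
        t = {k: rng.uniform(0.05, 0.95, 300) for k in ("OUT", "REF", "W", "S")}
        t["REF"] = 0.6 * t["W"] + 0.4 * rng.uniform(0.05, 0.95, 300)
        t["X"] = t["W"]
        est = f4_ratio_ancestry(freq_table(t), "X", "OUT", "REF", "W", "S")
        assert est.estimate == pytest.approx(1.0)

    def test_pure_clade_s_gives_zero(self, rng):
        t = {k: rng.uniform(0.05, 0.95, 300) for k in ("OUT", "REF", "W", "S")}
        t["REF"] = 0.6 * t["W"] + 0.4 * rng.uniform(0.05, 0.95, 300)
        t["X"] = t["S"]
        est = f4_ratio_ancestry(freq_table(t), "X", "OUT", "REF", "W", "S")
        assert est.estimate == pytest.approx(0.0, abs=1e-12)

    def test_simulated_80_20_recovery(self):
        g = simulate_admixture_graph(n_snps=20_000, alpha=0.8, t_admix=30,
                                     n_per_pop=20, n_admixed=20, seed=21)
        freqs = allele_frequencies(g)
        est = f4_ratio_ancestry(freqs, "X", "OUT", "REF", "W", "S")
        assert abs(est.estimate - 0.8) < 3 * est.std_err
        assert est.std_err < 0.05

    def test_insignificant_denominator_refused(self, rng):
        t = {k: rng.uniform(0.05, 0.95, 100) for k in ("OUT", "REF", "W", "S", "X")}
        with pytest.raises(ValueError, match="denominator"):
            f4_ratio_ancestry(freq_table(t), "X", "OUT", "REF", "W", "S")


class TestFst:
    def test_same_population_near_zero(self, rng):
        # two independent draws from one population: expectation 0
        p = rng.uniform(0.2, 0.8, 2000)
        dos = rng.binomial(2, p[:, None], (2000, 20)).astype(np.int8)
        data = make_genotypes(dos, pops=["P"] * 10 + ["Q"] * 10)
        freqs = allele_frequencies(data, ["P", "Q"])
        est = fst_pairwise(freqs, "P", "Q")
        assert abs(est.estimate) < max(3 * est.std_err, 0.01)

    def test_fixed_difference_gives_one(self):
        dos = np.zeros((50, 8), dtype=np.int8)
        dos[:, 4:] = 2
        data = make_genotypes(dos, pops=["P"] * 4 + ["Q"] * 4)
        freqs = allele_frequencies(data, ["P", "Q"])
        assert fst_pairwise(freqs, "P", "Q").estimate == pytest.approx(1.0)

    def test_balding_nichols_parameter_recovery(self, rng):
        from admixkit.simulate import balding_nichols
        m, n = 20_000, 25
        p0 = rng.uniform(0.1, 0.9, m)
        pa = balding_nichols(p0, 0.1, rng)
        pb = balding_nichols(p0, 0.1, rng)
        dos = np.concatenate([
            rng.binomial(2, pa[:, None], (m, n)),
            rng.binomial(2, pb[:, None], (m, n))], axis=1).astype(np.int8)
        data = make_genotypes(dos, pops=["P"] * n + ["Q"] * n)
        freqs = allele_frequencies(data, ["P", "Q"])
        est = fst_pairwise(freqs, "P", "Q")
        assert abs(est.estimate - 0.1) < max(3 * est.std_err, 0.01)

    def test_monomorphic_everywhere_rejected(self):
        dos = np.zeros((20, 6), dtype=np.int8)
        data = make_genotypes(dos, pops=["P"] * 3 + ["Q"] * 3)
        freqs = allele_frequencies(data, ["P", "Q"])
        with pytest.raises(ValueError):
            fst_pairwise(freqs, "P", "Q")


class TestWeightedJackknifeCore:
    def test_reduces_to_unweighted_for_equal_blocks(self, rng):
        vals = rng.normal(size=12)
        theta = vals.mean()
        dels = np.array([np.delete(vals, [3 * i, 3 * i + 1, 3 * i + 2]).mean()
                         for i in range(4)])
        est = jackknife_from_deletes(theta, dels, np.full(4, 3.0))
        g = 4
        ps = g * theta - (g - 1) * dels
        expect = np.sqrt(ps.var(ddof=0) / (g - 1))
        assert est.std_err == pytest.approx(expect)
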