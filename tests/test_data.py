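import numpy as np
import pytest

from admixkit import (MISSING, DataFormatError, allele_frequencies,
                      filter_missingness, ld_thin, read_eigenstrat,
                      read_plink_text, write_eigenstrat)
from admixkit.data import (read_haplotype_eigenstrat,
                           write_haplotype_eigenstrat)

from conftest import make_genotypes, make_haplotypes


class TestEigenstratIO:
    def test_round_trip_identity(self, tmp_path):
        data = make_genotypes([[0, 1], [2, MISSING], [1, 1]],
                              pops=["P1", "P2"])
        write_eigenstrat(data, tmp_path / "x")
        back = read_eigenstrat(tmp_path / "x")
        assert back == data

    def test_missing_written_as_9(self, tmp_path):
        data = make_genotypes([[0, MISSING]])
        write_eigenstrat(data, tmp_path / "x")
        assert (tmp_path / "x.geno").read_text().strip() == "09"
        assert read_eigenstrat(tmp_path / "x").dosages[0, 1] == MISSING

    def test_empty_dataset_round_trips(self, tmp_path):
        data = make_genotypes(np.empty((0, 2), dtype=np.int8))
        write_eigenstrat(data, tmp_path / "x")
        back = read_eigenstrat(tmp_path / "x")
        assert back.n_snps == 0 and back.n_samples == 2

    def test_row_count_mismatch_rejected(self, tmp_path):
        data = make_genotypes([[0, 1], [2, 0]])
        write_eigenstrat(data, tmp_path / "x")
        with open(tmp_path / "x.geno", "a") as fh:
            fh.write("00\n")
        with pytest.raises(DataFormatError, match="rows"):
            read_eigenstrat(tmp_path / "x")

    def test_non_monotone_map_rejected(self, tmp_path):
        data = make_genotypes([[0, 1], [2, 0]])
        write_eigenstrat(data, tmp_path / "x")
        lines = (tmp_path / "x.snp").read_text().splitlines()
        lines.reverse()
        (tmp_path / "x.snp").write_text("\n".join(lines) + "\n")
        with pytest.raises(DataFormatError, match="monotone"):
            read_eigenstrat(tmp_path / "x")

    def test_centimorgan_units_converted(self, tmp_path):
        data = make_genotypes([[0, 1], [2, 0]], gpos=[0.0, 0.5])
        write_eigenstrat(data, tmp_path / "x")
        back = read_eigenstrat(tmp_path / "x", genetic_units="cM")
        assert np.allclose(back.genetic_pos, [0.0, 0.005])

    def test_haplotype_round_trip(self, tmp_path):
        haps = make_haplotypes([[0, 1, 1, 0], [1, 1, 0, 0]], pops=["A", "B"])
        write_haplotype_eigenstrat(haps, tmp_path / "h")
        back = read_haplotype_eigenstrat(tmp_path / "h")
        assert np.array_equal(back.haplotypes, haps.haplotypes)
        assert list(back.sample_ids) == list(haps.sample_ids)


class TestPlinkReader:
    def test_ped_map_matches_eigenstrat_content(self, tmp_path):
        (tmp_path / "p.map").write_text(
            "1 snp0 0.0 100\n1 snp1 5.0 200\n")
        (tmp_path / "p.ped").write_text(
            "POP1 s0 0 0 0 -9 A A A C\n"
            "POP2 s1 0 0 0 -9 A C C C\n"
            "POP2 s2 0 0 0 -9 A A 0 0\n")
        data = read_plink_text(tmp_path / "p")
        assert data.n_snps == 2 and data.n_samples == 3
        # ref = first observed allele (A); dosage counts the alternate (C)
        assert list(data.dosages[0]) == [0, 1, 0]
        assert list(data.dosages[1]) == [1, 2, MISSING]
        assert np.allclose(data.genetic_pos, [0.0, 0.05])
        assert list(data.pop_labels) == ["POP1", "POP2", "POP2"]


class TestAlleleFrequencies:
    def test_simple_dosages_give_half(self):
        data = make_genotypes([[0], [1], [2]]).take_snps([0])
        data = make_genotypes([[0, 1, 2]])
        freqs = allele_frequencies(data, ["pop0"])
        assert freqs.freq("pop0")[0] == pytest.approx(0.5)

    def test_all_missing_snp_flagged(self):
        data = make_genotypes([[MISSING, MISSING], [0, 1]])
        freqs = allele_frequencies(data, ["pop0"])
        assert np.isnan(freqs.freq("pop0")[0])
        assert freqs.count("pop0")[0] == 0

    def test_two_population_hand_tally(self):
        # pop A: dosages (0,1,1) -> 2/6; pop B: (2,2,MISSING) -> 4/4
        data = make_genotypes([[0, 1, 1, 2, 2, MISSING]],
                              pops=["A", "A", "A", "B", "B", "B"])
        freqs = allele_frequencies(data, ["A", "B"])
        assert freqs.freq("A")[0] == pytest.approx(2 / 6)
        assert freqs.freq("B")[0] == pytest.approx(1.0)
        assert freqs.count("B")[0] == 4

    def test_merged_population_is_count_weighted_mean(self, rng):
        dos = rng.integers(0, 3, (30, 12)).astype(np.int8)
        dos[rng.random(dos.shape) < 0.2] = MISSING
        pops = ["A"] * 5 + ["B"] * 7
        data = make_genotypes(dos, pops=pops)
        merged = make_genotypes(dos, pops=["AB"] * 12)
        fa = allele_frequencies(data, ["A", "B"])
        fm = allele_frequencies(merged, ["AB"])
        w = fa.counts.astype(float)
        expect = np.nansum(fa.freqs * w, axis=1) / w.sum(axis=1)
        ok = fm.count("AB") > 0
        assert np.allclose(fm.freq("AB")[ok], expect[ok])

    def test_unknown_population_rejected(self):
        data = make_genotypes([[0, 1]])
        with pytest.raises(KeyError):
            allele_frequencies(data, ["nope"])


class TestMissingnessFilter:
    def test_bad_sample_dropped(self):
        dos = np.zeros((10, 3), dtype=np.int8)
        dos[0, 1] = MISSING  # sample s1: 10% missing
        data = make_genotypes(dos)
        out = filter_missingness(data, 0.05)
        assert list(out.sample_ids) == ["s0", "s2"]
        assert out.n_snps == 10

    def test_complete_data_unchanged(self):
        data = make_genotypes(np.ones((5, 4), dtype=np.int8))
        out = filter_missingness(data)
        assert out == data

    def test_hand_counted_fixture_samples_then_snps(self):
        # 20 SNPs x 4 samples; sample s3 has 2 missing (10% > 5%) -> dropped;
        # after that, SNP 0 is missing in 1/3 of the remaining samples -> dropped
        dos = np.ones((20, 4), dtype=np.int8)
        dos[5, 3] = MISSING
        dos[6, 3] = MISSING
        dos[0, 0] = MISSING
        data = make_genotypes(dos)
        out = filter_missingness(data, 0.05)
        assert list(out.sample_ids) == ["s0", "s1", "s2"]
        assert out.n_snps == 19 and "snp0" not in out.snp_ids

    def test_idempotent(self, rng):
        dos = rng.integers(0, 3, (40, 10)).astype(np.int8)
        dos[rng.random(dos.shape) < 0.08] = MISSING
        once = filter_missingness(make_genotypes(dos), 0.05)
        twice = filter_missingness(once, 0.05)
        assert twice == once


def _brute_force_thin(data, r2_max=0.1, window=50, step=5):
    """Reference greedy pass repeated to a fixed point."""
    from admixkit.data import _pairwise_r2
    alive = np.ones(data.n_snps, dtype=bool)
    changed = True
    while changed:
        changed = False
        for c in data.chromosomes:
            idx = np.flatnonzero((data.chrom == c) & alive)
            for w0 in range(0, max(1, len(idx) - 1), step):
                widx = idx[w0:w0 + window]
                widx = widx[alive[widx]]
                r2 = _pairwise_r2(data.dosages[widx])
                for a in range(len(widx)):
                    for b in range(a + 1, len(widx)):
                        if alive[widx[a]] and alive[widx[b]] and r2[a, b] > r2_max:
                            alive[widx[b]] = False
                            changed = True
    return np.flatnonzero(alive)


class TestLdThin:
    def test_duplicate_snp_removed_lower_index_kept(self, rng):
        base = rng.integers(0, 3, (1, 20)).astype(np.int8)
        dos = np.vstack([base, base, rng.integers(0, 3, (1, 20), dtype=np.int8)])
        out = ld_thin(make_genotypes(dos))
        assert "snp0" in out.snp_ids and "snp1" not in out.snp_ids

    def test_independent_snps_untouched(self, rng):
        # orthogonal-by-construction columns: identity-like patterns
        dos = rng.integers(0, 3, (10, 400)).astype(np.int8)
        data = make_genotypes(dos)
        out = ld_thin(data)
        assert out.n_snps == 10

    def test_matches_brute_force_on_planted_block(self, rng):
        n = 30
        dos = rng.integers(0, 3, (60, n)).astype(np.int8)
        # plant a correlated block: SNPs 10-14 copy SNP 10 with small noise
        for k in range(11, 15):
            dos[k] = dos[10]
            flip = rng.random(n) < 0.05
            dos[k, flip] = rng.integers(0, 3, flip.sum())
        data = make_genotypes(dos)
        out = ld_thin(data)
        expect = _brute_force_thin(data)
        assert list(out.snp_ids) == [f"snp{i}" for i in expect]

    def test_idempotent(self, rng):
        dos = rng.integers(0, 3, (80, 25)).astype(np.int8)
        for k in range(20, 40, 3):
            dos[k] = dos[k - 1]
        once = ld_thin(make_genotypes(dos))
        assert ld_thin(once) == once
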