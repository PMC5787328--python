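import numpy as np
import pytest

from dirdom.genotypes import (
    MISSING,
    GenotypeMatrix,
    GenotypeParseError,
    encode_design,
    encode_dominance_deviation,
    homozygosity_covariate,
    qc_filter,
    read_genotypes,
    write_genotypes,
)
from dirdom.synthetic_data import SimScenario, simulate


def _write(tmp_path, text, name="g.tsv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadGenotypes:
    def test_tsv_frequency_from_counts(self, tmp_path):
        path = _write(tmp_path, "id\tsnp1\na\t0\nb\t1\nc\t2\n")
        G = read_genotypes(path)
        assert G.ind_ids == ["a", "b", "c"]
        assert G.freqs[0] == pytest.approx(0.5)  # (0+1+2)/6

    def test_missing_excluded_from_frequency(self, tmp_path):
        path = _write(tmp_path, "id\tsnp1\na\t0\nb\t1\nc\t2\nd\tNA\n")
        G = read_genotypes(path)
        assert G.freqs[0] == pytest.approx(0.5)  # over 3 observed calls
        assert G.missing_mask[3, 0]

    def test_plink_raw_dialect(self, tmp_path):
        text = (
            "FID IID PAT MAT SEX PHENOTYPE snp1_A snp2_B\n"
            "0 pig1 0 0 2 -9 2 NA\n"
            "0 pig2 0 0 2 -9 1 0\n"
        )
        G = read_genotypes(_write(tmp_path, text, "g.raw"), dialect="plink_raw")
        assert G.ind_ids == ["pig1", "pig2"]
        assert G.counts[0, 1] == MISSING
        assert G.freqs[1] == pytest.approx(0.0)

    def test_malformed_row_names_line(self, tmp_path):
        path = _write(tmp_path, "id\tsnp1\tsnp2\na\t0\n")
        with pytest.raises(GenotypeParseError, match="line 2"):
            read_genotypes(path)

    def test_count_out_of_range_rejected(self, tmp_path):
        path = _write(tmp_path, "id\tsnp1\na\t3\n")
        with pytest.raises(GenotypeParseError, match="outside"):
            read_genotypes(path)

    @pytest.mark.parametrize("dialect", ["tsv", "plink_raw"])
    def test_round_trip_preserves_counts(self, tmp_path, dialect):
        sim = simulate(SimScenario(n_sows=50, n_snp=100, n_groups=10, seed=42))
        path = tmp_path / "rt.txt"
        write_genotypes(sim.genotypes, path, dialect=dialect)
        back = read_genotypes(path, dialect=dialect)
        np.testing.assert_array_equal(back.counts, sim.genotypes.counts)
        assert back.ind_ids == sim.genotypes.ind_ids


class TestQCFilter:
    def test_low_maf_snp_removed(self):
        counts = np.array([[0, 1], [0, 1], [0, 2], [0, 0], [0, 1], [1, 2],
                           [0, 1], [0, 0], [0, 1], [0, 2]])
        G = GenotypeMatrix(counts, [f"i{k}" for k in range(10)], ["rare", "ok"])
        # p(rare) = 1/20 = 0.05 boundary is kept; make it 0.03 via 16 individuals
        counts2 = np.vstack([counts, np.tile([0, 1], (6, 1))])
        counts2[0, 0] = 1
        counts2[5, 0] = 0
        G2 = GenotypeMatrix(counts2, [f"i{k}" for k in range(16)], ["rare", "ok"])
        assert G2.freqs[0] == pytest.approx(1 / 32)
        filtered, report = qc_filter(G2)
        assert report.removed_snp_ids == ["rare"]
        assert filtered.snp_ids == ["ok"]

    def test_planted_violations_removed_exactly(self, tiny_sim):
        G, report = qc_filter(tiny_sim.genotypes)
        assert report.n_snp_in == 50 and report.n_snp_out == 45
        assert report.removed_snp_ids == [f"snp{j:05d}" for j in range(46, 51)]
        assert report.removed_ind_ids == ["sow00001", "sow00002"]

    def test_idempotent(self, tiny_sim):
        G1, _ = qc_filter(tiny_sim.genotypes)
        G2, report2 = qc_filter(G1)
        np.testing.assert_array_equal(G1.counts, G2.counts)
        assert report2.removed_snp_ids == [] and report2.removed_ind_ids == []

    def test_all_removed_raises(self):
        counts = np.zeros((4, 2), dtype=np.int8)  # monomorphic: MAF 0
        G = GenotypeMatrix(counts, list("abcd"), ["s1", "s2"])
        with pytest.raises(ValueError, match="every SNP"):
            qc_filter(G)

    def test_freqs_recomputed_on_retained_set(self, tiny_sim):
        G, _ = qc_filter(tiny_sim.genotypes)
        expected = GenotypeMatrix(G.counts, G.ind_ids, G.snp_ids).freqs
        np.testing.assert_allclose(G.freqs, expected)


class TestHomozygosity:
    def test_counted_fraction(self):
        G = GenotypeMatrix(np.array([[0, 1, 2, 2, 1]]), ["a"], list("vwxyz"))
        assert homozygosity_covariate(G)[0] == pytest.approx(3 / 5)

    def test_all_heterozygote_is_zero(self):
        G = GenotypeMatrix(np.ones((1, 4), dtype=int), ["a"], list("wxyz"))
        assert homozygosity_covariate(G)[0] == 0.0

    def test_ignores_missing_calls(self):
        counts = np.array([[0, 1, MISSING, 2], [1, 1, 1, 1]])
        G = GenotypeMatrix(counts, ["a", "b"], list("wxyz"))
        # 2 homozygous of 3 observed, not of 4
        assert homozygosity_covariate(G)[0] == pytest.approx(2 / 3)

    def test_hwe_mean_matches_expectation(self, rng):
        # at p = 0.5 expected homozygosity 1 - 2pq = 0.5
        counts = rng.binomial(2, 0.5, size=(2000, 200)).astype(np.int8)
        G = GenotypeMatrix(counts, [str(i) for i in range(2000)],
                           [f"s{j}" for j in range(200)])
        assert homozygosity_covariate(G).mean() == pytest.approx(0.5, abs=0.01)


class TestEncodeDesign:
    def test_heterozygote_codes_at_half(self):
        G = GenotypeMatrix(np.array([[1], [0], [2], [1]]), list("abcd"), ["s"])
        Zc, Kc = encode_design(G, centering="freq")
        assert G.freqs[0] == 0.5
        assert Zc[0, 0] == pytest.approx(0.0)
        assert Kc[0, 0] == pytest.approx(0.5)
        assert Zc[2, 0] == pytest.approx(1.0)
        assert Kc[2, 0] == pytest.approx(-0.5)

    def test_centering_none_returns_raw(self):
        G = GenotypeMatrix(np.array([[1], [0], [2], [1]]), list("abcd"), ["s"])
        Z, K = encode_design(G, centering="none")
        np.testing.assert_array_equal(Z[:, 0], [1, 0, 2, 1])
        np.testing.assert_array_equal(K[:, 0], [1, 0, 0, 1])

    def test_monomorphic_rejected(self):
        G = GenotypeMatrix(np.zeros((3, 1), dtype=int), list("abc"), ["s"])
        with pytest.raises(ValueError, match="monomorphic"):
            encode_design(G)

    def test_hwe_column_means_near_zero(self, rng):
        p = rng.uniform(0.1, 0.9, 50)
        counts = rng.binomial(2, p, size=(5000, 50)).astype(np.int8)
        G = GenotypeMatrix(counts, [str(i) for i in range(5000)],
                           [f"s{j}" for j in range(50)])
        Zc, Kc = encode_design(G)
        assert np.abs(Zc.mean(axis=0)).max() < 1e-12  # centered at realized p
        assert np.abs(Kc.mean(axis=0)).max() < 0.02

    def test_missing_mean_imputed_to_zero_code(self):
        counts = np.array([[1], [0], [2], [1], [MISSING]])
        G = GenotypeMatrix(counts, list("abcde"), ["s"])
        Zc, Kc = encode_design(G)
        assert Zc[4, 0] == pytest.approx(0.0)  # 2p - 2p
        assert Kc[4, 0] == pytest.approx(0.0)  # 2pq - 2pq

    def test_dominance_deviation_codes(self):
        G = GenotypeMatrix(np.array([[2], [1], [0], [1]]), list("abcd"), ["s"])
        Kdev = encode_dominance_deviation(G)
        p = G.freqs[0]
        q = 1 - p
        assert Kdev[0, 0] == pytest.approx(-2 * q**2)
        assert Kdev[1, 0] == pytest.approx(2 * p * q)
        assert Kdev[2, 0] == pytest.approx(-2 * p**2)
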