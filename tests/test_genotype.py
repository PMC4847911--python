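import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinpatch.genotype import (
    MISSING,
    GenotypeTable,
    GenotypeTableError,
    allele_frequencies,
    locus_summary,
    read_genotype_table,
    write_genotype_table,
)


class TestReaders:
    def test_csv_round_trip(self, tiny_table, tmp_path):
        path = tmp_path / "t.csv"
        write_genotype_table(tiny_table, path, dialect="csv")
        back = read_genotype_table(path, dialect="csv")
        assert back.ids == tiny_table.ids
        assert back.loci == tiny_table.loci
        assert np.array_equal(back.alleles, tiny_table.alleles)
        assert list(back.sites) == list(tiny_table.sites)

    def test_genepop_round_trip(self, tiny_table, tmp_path):
        path = tmp_path / "t.gen"
        write_genotype_table(tiny_table, path, dialect="genepop")
        back = read_genotype_table(path, dialect="genepop")
        assert back.loci == tiny_table.loci
        assert np.array_equal(back.alleles, tiny_table.alleles)
        # genepop names populations positionally
        assert len(set(back.sites)) == 2

    def test_empty_file_is_structured_error(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(GenotypeTableError):
            read_genotype_table(path)

    def test_missing_codes(self, tmp_path):
        path = tmp_path / "m.csv"
        path.write_text("id,site,L1_1,L1_2,L2_1,L2_2\nx,A,0,0,5,5\ny,A,-9,-9,5,7\n")
        t = read_genotype_table(path, missing_codes=(0, -9))
        assert t.missing_mask()[:, 0].all()
        assert not t.missing_mask()[:, 1].any()

    def test_unparseable_rows_reported_with_numbers(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,site,L1_1,L1_2\nx,A,5,5\ny,A,oops,5\n")
        with pytest.raises(GenotypeTableError, match="3"):
            read_genotype_table(path)

    def test_odd_allele_columns(self, tmp_path):
        path = tmp_path / "odd.csv"
        path.write_text("id,site,L1_1\nx,A,5\n")
        with pytest.raises(GenotypeTableError, match="odd allele column"):
            read_genotype_table(path)

    def test_low_coverage_individuals_rejected_with_report(self, tmp_path):
        path = tmp_path / "cov.csv"
        path.write_text(
            "id,site,L1_1,L1_2,L2_1,L2_2\nx,A,5,5,7,7\ny,A,5,5,0,0\n")
        with pytest.warns(UserWarning, match="y"):
            t = read_genotype_table(path, min_loci=2)
        assert t.ids == ["x"]


class TestTableInvariants:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(GenotypeTableError, match="duplicate"):
            GenotypeTable(["a", "a"], np.asarray(["s", "s"], object), ["L"],
                          np.full((2, 1, 2), 5))

    def test_half_missing_demoted_with_warning(self):
        alleles = np.array([[[5, 0], [3, 3]], [[5, 7], [3, 4]]])
        with pytest.warns(UserWarning, match="half-missing"):
            t = GenotypeTable(["a", "b"], np.asarray(["s", "s"], object),
                              ["L", "L2"], alleles)
        assert t.missing_mask()[0, 0]

    @given(a=st.integers(1, 300), b=st.integers(1, 300))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_canonical_pair_order(self, a, b):
        """Genotype equality must not depend on input allele order."""
        t1 = GenotypeTable(["x"], np.asarray(["s"], object), ["L"],
                           np.array([[[a, b]]]))
        t2 = GenotypeTable(["x"], np.asarray(["s"], object), ["L"],
                           np.array([[[b, a]]]))
        assert np.array_equal(t1.alleles, t2.alleles)


class TestFrequencies:
    def test_all_heterozygous(self):
        alleles = np.tile([[1, 2]], (4, 1)).reshape(4, 1, 2)
        t = GenotypeTable([f"i{k}" for k in range(4)],
                          np.asarray(["s"] * 4, object), ["L"], alleles)
        f = allele_frequencies(t)
        assert f.group_freqs("__all__", "L") == {1: 0.5, 2: 0.5}

    def test_missing_excluded(self):
        alleles = np.array([[[7, 7], [3, 3]], [[0, 0], [3, 4]]])
        t = GenotypeTable(["a", "b"], np.asarray(["s", "s"], object),
                          ["L", "L2"], alleles)
        f = allele_frequencies(t)
        assert f.group_freqs("__all__", "L") == {7: 1.0}
        assert f.n[("__all__", "L")] == 1

    def test_matches_gene_copy_counting(self, kin_study):
        """Frequencies equal direct gene-copy counts / 2n on simulated data."""
        table, _ = kin_study
        f = allele_frequencies(table, "site")
        rng = np.random.default_rng(0)
        for _ in range(10):
            site = rng.choice(table.site_labels)
            locus = table.loci[rng.integers(len(table.loci))]
            sub = table.site_table(site)
            j = sub.locus_index(locus)
            ok = ~sub.missing_mask()[:, j]
            copies = sub.alleles[ok, j, :].ravel().tolist()
            for a, freq in f.group_freqs(site, locus).items():
                assert freq == pytest.approx(copies.count(a) / len(copies))

    def test_zero_coverage_cell_flagged(self):
        alleles = np.array([[[5, 5], [0, 0]], [[5, 7], [0, 0]]])
        t = GenotypeTable(["a", "b"], np.asarray(["s", "s"], object),
                          ["L1", "L2"], alleles)
        f = allele_frequencies(t)
        assert ("__all__", "L2") in f.empty
        assert ("__all__", "L2") not in f.freqs


class TestLocusSummary:
    def test_all_heterozygous_pair(self):
        alleles = np.tile([[1, 2]], (6, 1)).reshape(6, 1, 2)
        t = GenotypeTable([f"i{k}" for k in range(6)],
                          np.asarray(["s"] * 6, object), ["L"], alleles)
        s = locus_summary(t, "L")
        assert (s.richness, s.ho, s.he) == (2, 1.0, 0.5)

    def test_monomorphic(self):
        alleles = np.full((5, 1, 2), 9)
        t = GenotypeTable([f"i{k}" for k in range(5)],
                          np.asarray(["s"] * 5, object), ["L"], alleles)
        s = locus_summary(t, "L")
        assert (s.richness, s.ho, s.he) == (1, 0.0, 0.0)

    def test_unknown_locus(self, tiny_table):
        with pytest.raises(GenotypeTableError):
            locus_summary(tiny_table, "nope")

    def test_he_matches_recount(self, kin_study):
        table, _ = kin_study
        for locus in table.loci[:3]:
            s = locus_summary(table, locus)
            j = table.locus_index(locus)
            ok = ~table.missing_mask()[:, j]
            copies = table.alleles[ok, j, :].ravel()
            _, counts = np.unique(copies, return_counts=True)
            p = counts / counts.sum()
            assert s.he == pytest.approx(1 - (p ** 2).sum())
            assert 0 <= s.ho <= 1 and 0 <= s.he <= 1
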