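import numpy as np
import pytest

from kinpatch.genotype import GenotypeTable, GenotypeTableError, allele_frequencies
from kinpatch.relatedness import (
    IBDModel,
    TRIO_STATES,
    dyad_mode_likelihoods,
    mean_group_relatedness,
    pairwise_relatedness,
    relatedness_permutation_test,
)
from kinpatch.simulate import SimulationConfig, simulate_dyads, simulate_study


class TestIBDModel:
    def test_pedigree_anchors(self):
        assert IBDModel(0.25, 0.5, 0.25).r == pytest.approx(0.5)
        assert IBDModel(0.5, 0.5, 0.0).r == pytest.approx(0.25)
        assert IBDModel(1.0, 0.0, 0.0).r == pytest.approx(0.0)


class TestEmissionModel:
    def test_error_free_matches_textbook_pair_probabilities(self):
        """Per-mode genotype-pair probabilities at e=0 for AB vs AB."""
        alleles = np.array([[[1, 2]], [[1, 2]], [[1, 1]], [[2, 2]]])
        t = GenotypeTable([f"i{k}" for k in range(4)],
                          np.asarray(["s"] * 4, object), ["L"], alleles)
        f = allele_frequencies(t)
        pa = f.pooled("L")[1]
        pb = f.pooled("L")[2]
        p, valid = dyad_mode_likelihoods(t, f, 0.0,
                                         pairs=(np.array([0]), np.array([1])))
        assert p[0, 0, 0] == pytest.approx(4 * pa ** 2 * pb ** 2)
        assert p[0, 0, 1] == pytest.approx(pa * pb * (pa + pb))
        assert p[0, 0, 2] == pytest.approx(2 * pa * pb)

    def test_mode_probabilities_sum_over_genotype_pairs(self):
        """Each IBD mode's emissions sum to 1 over all ordered pairs."""
        freqs = {1: 0.5, 2: 0.3, 3: 0.2}
        genos = [(a, b) for a in freqs for b in freqs if a <= b]
        for e in (0.0, 0.05):
            totals = np.zeros(3)
            for g1 in genos:
                for g2 in genos:
                    alleles = np.array([[list(g1)], [list(g2)], [[1, 1]]])
                    t = GenotypeTable(["a", "b", "c"],
                                      np.asarray(["s"] * 3, object), ["L"], alleles)
                    f = allele_frequencies(t)
                    f.freqs[("__all__", "L")] = freqs
                    p, _ = dyad_mode_likelihoods(
                        t, f, e, pairs=(np.array([0]), np.array([1])))
                    totals += p[0, 0]
            assert np.allclose(totals, 1.0, atol=1e-9)


class TestRecovery:
    @pytest.mark.parametrize("rel,target,tol", [
        ("FS", 0.5, 0.05), ("HS", 0.25, 0.05), ("U", 0.0, 0.05)])
    def test_dyad_means(self, rel, target, tol):
        cfg = SimulationConfig(seed=77, missingness_range=(0.0, 0.0))
        table, _ = simulate_dyads(rel, 80, cfg)
        m = pairwise_relatedness(table, error_rate=0.01, seed=5)
        vals = np.asarray([m.values[2 * i, 2 * i + 1] for i in range(80)])
        assert abs(np.nanmean(vals) - target) < tol

    def test_identical_genotypes_near_one(self):
        cfg = SimulationConfig(seed=31, n_loci=20,
                               allele_counts=tuple([10] * 20),
                               missingness_range=(0.0, 0.0), error_rate=0.0)
        table, _ = simulate_dyads("U", 20, cfg)
        # clone individual 0's genotypes into individual 1
        table.alleles[1] = table.alleles[0]
        m = pairwise_relatedness(table, error_rate=0.0, seed=1)
        assert m.values[0, 1] >= 0.9

    def test_rmse_decreases_with_locus_count(self):
        rmses = []
        for n_loci in (10, 20, 40):
            cfg = SimulationConfig(seed=88, n_loci=n_loci,
                                   allele_counts=tuple([12] * n_loci),
                                   missingness_range=(0.0, 0.0))
            table, _ = simulate_dyads("FS", 60, cfg)
            m = pairwise_relatedness(table, error_rate=0.01, seed=3)
            vals = np.asarray([m.values[2 * i, 2 * i + 1] for i in range(60)])
            rmses.append(float(np.sqrt(np.nanmean((vals - 0.5) ** 2))))
        assert rmses[0] > rmses[1] > rmses[2]

    def test_invariance_to_relabeling_and_locus_order(self):
        cfg = SimulationConfig(seed=13, missingness_range=(0.0, 0.0))
        table, _ = simulate_dyads("HS", 10, cfg)
        base = pairwise_relatedness(table, error_rate=0.01, seed=2)
        relab = GenotypeTable(
            ids=list(table.ids), sites=table.sites.copy(), loci=list(table.loci),
            alleles=np.where(table.alleles > 0, table.alleles * 3 + 7, 0))
        m2 = pairwise_relatedness(relab, error_rate=0.01, seed=2)
        assert np.allclose(base.values, m2.values, equal_nan=True, atol=1e-6)
        order = np.array([3, 1, 4, 0, 2, 5, 9, 8, 7, 6])
        reordered = GenotypeTable(
            ids=list(table.ids), sites=table.sites.copy(),
            loci=[table.loci[j] for j in order],
            alleles=table.alleles[:, order, :])
        m3 = pairwise_relatedness(reordered, error_rate=0.01, seed=2)
        assert np.allclose(base.values, m3.values, equal_nan=True, atol=1e-6)

    def test_trio_state_space(self):
        """16 states; marginal modes span 0/1/2; unrelated state first."""
        assert len(TRIO_STATES) == 16
        modes = {m for _, m in TRIO_STATES}
        assert modes == {0, 1, 2}
        assert TRIO_STATES[0][0] == ((0,), (1,), (2,), (3,), (4,), (5,))


class TestGroupMeans:
    def _matrix(self, values):
        n = values.shape[0]
        from kinpatch.relatedness import RelatednessMatrix
        return RelatednessMatrix([f"i{k}" for k in range(n)], values,
                                 "ml-triad", 0.01, 1, 0)

    def test_pair_group(self):
        v = np.full((2, 2), np.nan)
        v[0, 1] = v[1, 0] = 0.37
        out = mean_group_relatedness(self._matrix(v), ["g", "g"])
        assert out.loc["g", "r_mean"] == pytest.approx(0.37)
        assert out.loc["g", "se"] == 0.0

    def test_hand_mean_of_three(self):
        v = np.full((3, 3), np.nan)
        v[0, 1] = v[1, 0] = 0.1
        v[0, 2] = v[2, 0] = 0.2
        v[1, 2] = v[2, 1] = 0.3
        out = mean_group_relatedness(self._matrix(v), ["g"] * 3)
        assert out.loc["g", "r_mean"] == pytest.approx(0.2)

    def test_singleton_group_nan(self):
        v = np.full((3, 3), 0.1)
        out = mean_group_relatedness(self._matrix(v), ["a", "a", "b"])
        assert np.isnan(out.loc["b", "r_mean"])


class TestPermutationTest:
    def test_clonemate_group_minimal_p(self):
        cfg = SimulationConfig(seed=19, n_loci=15,
                               allele_counts=tuple([12] * 15),
                               missingness_range=(0.0, 0.0), error_rate=0.0)
        table, _ = simulate_dyads("U", 15, cfg)
        for i in range(1, 5):
            table.alleles[i] = table.alleles[0]  # 5 clonemates
        m = pairwise_relatedness(table, error_rate=0.0, seed=4)
        groups = ["clones" if i < 5 else "rest" for i in range(30)]
        out = relatedness_permutation_test(m, groups, n_perm=200, seed=6)
        assert out.loc["clones", "p_value"] == pytest.approx(1 / 201)

    def test_null_rejection_rate_near_alpha(self):
        hits = total = 0
        for rep in range(60):
            cfg = SimulationConfig(seed=7000 + rep, n_sites=2,
                                   site_size_range=(20, 20), panmictic=True,
                                   missingness_range=(0.0, 0.0))
            table, _ = simulate_study(cfg)
            m = pairwise_relatedness(table, error_rate=0.01, seed=rep)
            out = relatedness_permutation_test(
                m, list(table.sites), n_perm=199, seed=rep)
            hits += int((out["p_value"] < 0.05).sum())
            total += len(out)
        assert 0.01 <= hits / total <= 0.09

    def test_envelope_brackets_null(self, kin_study):
        table, truth = kin_study
        m = pairwise_relatedness(table, error_rate=0.01, seed=1)
        out = relatedness_permutation_test(m, list(table.sites), n_perm=100, seed=2)
        assert (out["null_lo"] <= out["null_hi"]).all()

    def test_needs_two_groups(self, tiny_table):
        m = pairwise_relatedness(tiny_table, error_rate=0.0, seed=0)
        with pytest.raises(GenotypeTableError):
            relatedness_permutation_test(m, ["g"] * 6, n_perm=10, seed=0)
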