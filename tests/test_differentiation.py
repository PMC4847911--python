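import numpy as np
import pandas as pd
import pytest

from kinpatch.differentiation import (
    differentiation_significance,
    great_circle_distances,
    mantel_test,
    pairwise_fst,
    pairwise_pd,
)
from kinpatch.genotype import GenotypeTable, GenotypeTableError
from kinpatch.simulate import SimulationConfig, simulate_study


def _two_pop_table(genos_a, genos_b, loci=1):
    """Build a 2-site table from per-site genotype pair lists."""
    rows = genos_a + genos_b
    alleles = np.asarray(rows).reshape(len(rows), loci, 2)
    sites = ["A"] * len(genos_a) + ["B"] * len(genos_b)
    return GenotypeTable([f"i{k}" for k in range(len(rows))],
                         np.asarray(sites, object),
                         [f"L{j}" for j in range(loci)], alleles)


class TestPD:
    def test_identical_frequencies_zero(self):
        g = [[1, 2]] * 5 + [[1, 1]] * 5
        t = _two_pop_table(g, list(g))
        assert pairwise_pd(t).loc["A", "B"] == pytest.approx(0.0)

    def test_disjoint_allele_sets_one(self):
        t = _two_pop_table([[1, 2]] * 6, [[3, 4]] * 6)
        assert pairwise_pd(t).loc["A", "B"] == pytest.approx(1.0)

    def test_hand_computed_overlap(self):
        # A: all 1/1 (p1=1); B: half 1/1, half 2/2 (p1=p2=0.5)
        t = _two_pop_table([[1, 1]] * 4, [[1, 1]] * 2 + [[2, 2]] * 2)
        # shared proportion = min(1, .5) + min(0, .5) = 0.5
        assert pairwise_pd(t).loc["A", "B"] == pytest.approx(0.5)

    def test_symmetric_zero_diagonal(self, kin_study):
        table, _ = kin_study
        m = pairwise_pd(table)
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 0)
        assert ((m.values >= 0) & (m.values <= 1)).all()


class TestFST:
    def test_fixed_differences_nei_is_one(self):
        t = _two_pop_table([[1, 1]] * 8, [[2, 2]] * 8)
        assert pairwise_fst(t, "nei").loc["A", "B"] == pytest.approx(1.0)

    def test_fixed_differences_wc_near_one(self):
        t = _two_pop_table([[1, 1]] * 8, [[2, 2]] * 8)
        assert pairwise_fst(t, "weir_cockerham").loc["A", "B"] == pytest.approx(1.0, abs=0.01)

    def test_panmictic_mean_near_zero(self):
        """WC theta is unbiased around 0 for samples from one pool."""
        vals = []
        for rep in range(60):
            cfg = SimulationConfig(seed=3000 + rep, n_sites=2,
                                   site_size_range=(50, 50), panmictic=True,
                                   missingness_range=(0.0, 0.0), error_rate=0.0,
                                   clusters_per_site=(2, 5))
            table, _ = simulate_study(cfg)
            vals.append(pairwise_fst(table).iloc[0, 1])
        assert abs(np.mean(vals)) < 0.01

    def test_allele_relabeling_and_order_invariance(self, kin_study):
        table, _ = kin_study
        base = pairwise_fst(table)
        perm = np.random.default_rng(5).permutation(table.n_individuals)
        shuffled = table.subset(perm)
        m2 = pairwise_fst(shuffled)
        assert np.allclose(base.loc[m2.index, m2.columns].values, m2.values)
        relab = GenotypeTable(
            ids=list(table.ids), sites=table.sites.copy(), loci=list(table.loci),
            alleles=np.where(table.alleles > 0, table.alleles + 1000, 0))
        assert np.allclose(pairwise_fst(relab).values, base.values)


class TestSignificance:
    def test_fully_differentiated_minimum_p(self):
        t = _two_pop_table([[1, 1]] * 8, [[2, 2]] * 8)
        out = differentiation_significance(t, "fst", n_perm=200, seed=1,
                                           correction="none")
        assert out["p_raw"].loc["A", "B"] == pytest.approx(1 / 201)

    def test_null_rejection_rate_near_alpha(self):
        hits = 0
        n_rep = 120
        for rep in range(n_rep):
            cfg = SimulationConfig(seed=5000 + rep, n_sites=2,
                                   site_size_range=(40, 40), panmictic=True,
                                   missingness_range=(0.0, 0.0), error_rate=0.0)
            table, _ = simulate_study(cfg)
            out = differentiation_significance(table, "fst", n_perm=199, seed=rep,
                                               correction="none")
            if out["p_raw"].loc["S1", "S2"] < 0.05:
                hits += 1
        assert 0.01 <= hits / n_rep <= 0.09

    def test_holm_never_below_raw_and_monotone(self, kin_study):
        table, _ = kin_study
        out = differentiation_significance(table, "pd", n_perm=150, seed=2)
        sites = list(out["p_raw"].index)
        raw, adj = [], []
        for i, a in enumerate(sites):
            for b in sites[i + 1:]:
                raw.append(out["p_raw"].loc[a, b])
                adj.append(out["p_adjusted"].loc[a, b])
        raw, adj = np.asarray(raw), np.asarray(adj)
        assert (adj >= raw - 1e-12).all()
        order = np.argsort(raw)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestGeography:
    def test_haversine_reference_value(self):
        d = great_circle_distances({"a": (0.0, 0.0), "b": (0.0, 1.0)})
        assert d.loc["a", "b"] == pytest.approx(111.195, abs=0.001)

    def test_identical_points_zero_and_symmetry(self):
        d = great_circle_distances({"a": (10.0, 20.0), "b": (10.0, 20.0),
                                    "c": (-5.0, 30.0)})
        assert d.loc["a", "b"] == 0.0
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)

    def test_out_of_range_coordinates(self):
        with pytest.raises(GenotypeTableError, match="bad"):
            great_circle_distances({"bad": (95.0, 0.0)})


class TestMantel:
    def test_perfect_correlation(self):
        d = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        res = mantel_test(d, d * 2.0, n_perm=200, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_independent_matrices_mean_r_zero(self):
        rng = np.random.default_rng(8)
        rs = []
        for _ in range(300):
            def sym():
                m = rng.random((9, 9))
                m = (m + m.T) / 2
                np.fill_diagonal(m, 0)
                return m
            rs.append(mantel_test(sym(), sym(), n_perm=10, seed=1).statistic)
        assert abs(np.mean(rs)) < 0.02

    def test_constant_matrix_error(self):
        d = np.zeros((4, 4))
        with pytest.raises(GenotypeTableError):
            mantel_test(d, d, n_perm=100, seed=0)

    def test_agrees_with_skbio(self):
        """Cross-check r and permutation p against the scikit-bio oracle."""
        from skbio.stats.distance import DistanceMatrix, mantel
        rng = np.random.default_rng(3)
        a = rng.random((7, 7))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0)
        b = a + rng.normal(0, 0.3, (7, 7))
        b = np.abs(b + b.T) / 2
        np.fill_diagonal(b, 0)
        ours = mantel_test(a, b, n_perm=5000, seed=4)
        r_ref, p_ref, _ = mantel(DistanceMatrix(a), DistanceMatrix(b),
                                 permutations=5000, alternative="greater", seed=9)
        assert ours.statistic == pytest.approx(r_ref, abs=1e-9)
        assert ours.p_value == pytest.approx(p_ref, abs=0.02)
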