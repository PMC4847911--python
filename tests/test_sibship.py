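import numpy as np
import pytest

from kinpatch.genotype import FrequencyTable, GenotypeTable, GenotypeTableError, allele_frequencies
from kinpatch.sibship import (
    classify_dyads,
    exclusion_probability,
    sib_count_permutation,
)
from kinpatch.simulate import SimulationConfig, simulate_dyads

from _oracles import exclusion_probability_enum


def _freq_table(per_locus: dict[str, dict[int, float]]) -> FrequencyTable:
    return FrequencyTable(
        grouping="global", groups=["__all__"], loci=list(per_locus),
        freqs={("__all__", l): f for l, f in per_locus.items()},
        n={("__all__", l): 1000 for l in per_locus})


class TestClassifyDyads:
    def test_posteriors_sum_to_one(self):
        table, _ = simulate_dyads("FS", 30, SimulationConfig(seed=5))
        out = classify_dyads(table).table
        sums = out[["pFS", "pHS", "pU"]].sum(axis=1)
        finite = sums[np.isfinite(sums)]
        assert np.allclose(finite, 1.0, atol=1e-9)

    def test_no_shared_alleles_labels_unrelated(self):
        # 6 informative loci, dyad shares zero alleles anywhere
        n_loci = 6
        a = np.stack([np.stack([[1, 2]] * n_loci), np.stack([[3, 4]] * n_loci)])
        filler = np.stack([np.stack([[i, i + 1]] * n_loci) for i in (1, 2, 3)])
        alleles = np.concatenate([a, filler])
        t = GenotypeTable([f"i{k}" for k in range(5)],
                          np.asarray(["s"] * 5, object),
                          [f"L{j}" for j in range(n_loci)], alleles)
        out = classify_dyads(t, error_rate=0.01)
        row = out.table[(out.table.id1 == "i0") & (out.table.id2 == "i1")].iloc[0]
        assert row["label"] == "U"

    def test_low_overlap_unassigned(self):
        alleles = np.zeros((4, 4, 2), dtype=int)
        alleles[:, :, :] = [[1, 2]]
        alleles[0, 2:] = 0
        alleles[1, :2] = 0  # dyad (i0, i1) overlaps at 0 loci
        t = GenotypeTable([f"i{k}" for k in range(4)],
                          np.asarray(["s"] * 4, object),
                          [f"L{j}" for j in range(4)], alleles)
        out = classify_dyads(t, min_loci=3)
        row = out.table[(out.table.id1 == "i0") & (out.table.id2 == "i1")].iloc[0]
        assert row["label"] == "UNASSIGNED" and np.isnan(row["pFS"])

    def test_fs_vs_u_discrimination(self):
        """Among confident calls, unrelated dyads are almost never called sib."""
        cfg = SimulationConfig(seed=303, missingness_range=(0.0, 0.0))
        fs_table, _ = simulate_dyads("FS", 100, cfg)
        u_table, _ = simulate_dyads("U", 100, SimulationConfig(
            seed=304, missingness_range=(0.0, 0.0)))
        freqs = allele_frequencies(u_table)
        fp = recall = 0
        out_u = classify_dyads(u_table, error_rate=0.01).table
        for i in range(100):
            row = out_u[(out_u.id1 == f"D{i+1}a") & (out_u.id2 == f"D{i+1}b")].iloc[0]
            if row["label"] in ("FS", "HS"):
                fp += 1
        out_fs = classify_dyads(fs_table, error_rate=0.01).table
        for i in range(100):
            row = out_fs[(out_fs.id1 == f"D{i+1}a") & (out_fs.id2 == f"D{i+1}b")].iloc[0]
            if row["label"] == "FS":
                recall += 1
        assert fp / 100 < 0.05
        assert recall > 0  # recall reported, power depends on panel

    def test_posterior_concentration_grows_with_loci(self):
        means = []
        for n_loci in (5, 10, 20):
            cfg = SimulationConfig(seed=42, n_loci=n_loci,
                                   allele_counts=tuple([10] * n_loci),
                                   missingness_range=(0.0, 0.0))
            table, _ = simulate_dyads("FS", 60, cfg)
            out = classify_dyads(table, error_rate=0.01).table
            keep = out[np.isfinite(out["pFS"])]
            means.append(float(keep[["pFS", "pHS", "pU"]].max(axis=1).mean()))
        assert means[0] < means[1] < means[2]

    def test_locus_order_invariance(self):
        cfg = SimulationConfig(seed=21, missingness_range=(0.0, 0.0))
        table, _ = simulate_dyads("HS", 15, cfg)
        base = classify_dyads(table).table
        order = np.array([9, 0, 4, 2, 7, 1, 8, 3, 6, 5])
        shuffled = GenotypeTable(
            ids=list(table.ids), sites=table.sites.copy(),
            loci=[table.loci[j] for j in order],
            alleles=table.alleles[:, order, :])
        out = classify_dyads(shuffled).table
        assert np.allclose(base[["pFS", "pHS", "pU"]].to_numpy(),
                           out[["pFS", "pHS", "pU"]].to_numpy(),
                           equal_nan=True, atol=1e-9)


class TestSibCountPermutation:
    def test_all_sibs_in_one_cluster_min_two_tailed_p(self):
        cfg = dict(n_loci=20, allele_counts=tuple([15] * 20),
                   missingness_range=(0.0, 0.0))
        fs, _ = simulate_dyads("FS", 8, SimulationConfig(seed=9, **cfg))
        un, _ = simulate_dyads("U", 8, SimulationConfig(seed=8, **cfg))
        table = GenotypeTable(
            ids=list(fs.ids) + [f"u_{i}" for i in un.ids],
            sites=np.asarray(["s"] * 32, object), loci=list(fs.loci),
            alleles=np.concatenate([fs.alleles, un.alleles]))
        dyads = classify_dyads(table, error_rate=0.01)
        clusters = {i: ("A" if not i.startswith("u_") else "B")
                    for i in table.ids}
        out = sib_count_permutation(dyads, clusters, n_perm=500, seed=2)
        assert out.loc["A", "sib_dyads"] >= 6  # informative panel calls the sibs
        # every sib dyad sits inside cluster A: the doubled upper tail is minimal
        assert out.loc["A", "p_value"] == pytest.approx(2 / 501)

    def test_total_count_conserved(self):
        table, _ = simulate_dyads("HS", 10, SimulationConfig(seed=10))
        dyads = classify_dyads(table)
        rng = np.random.default_rng(0)
        labels = rng.permutation(["X"] * 10 + ["Y"] * 10)
        clusters = dict(zip(table.ids, labels))
        sib_pairs = dyads.sib_pairs()
        ids = list(table.ids)
        idx = {i: k for k, i in enumerate(ids)}
        total = len(sib_pairs)
        for _ in range(20):
            perm = rng.permutation(list(clusters.values()))
            inside = sum(perm[idx[a]] == perm[idx[b]] for a, b in sib_pairs)
            assert inside <= total  # permutation can't create dyads

    def test_needs_two_clusters(self):
        table, _ = simulate_dyads("U", 5, SimulationConfig(seed=3))
        dyads = classify_dyads(table)
        with pytest.raises(GenotypeTableError):
            sib_count_permutation(dyads, {i: "only" for i in table.ids},
                                  n_perm=10, seed=0)


class TestExclusionProbability:
    def test_monomorphic_locus_zero(self):
        res = exclusion_probability(_freq_table({"L": {5: 1.0}}),
                                    n_mc=1000, seed=0)
        assert res.probability == 0.0

    @pytest.mark.parametrize("freqs", [
        {1: 0.5, 2: 0.5},
        {1: 0.6, 2: 0.3, 3: 0.1},
        {1: 1 / 3, 2: 1 / 3, 3: 1 / 3},
    ])
    def test_matches_enumeration(self, freqs):
        mc = exclusion_probability(_freq_table({"L": freqs}),
                                   n_mc=100_000, seed=4)
        assert mc.probability == pytest.approx(
            exclusion_probability_enum(freqs), abs=0.005)

    def test_monotone_in_locus_subsets(self):
        per_locus = {f"L{j}": {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
                     for j in range(5)}
        ft = _freq_table(per_locus)
        loci = list(per_locus)
        probs = [exclusion_probability(ft, loci_subset=loci[:k], n_mc=20_000,
                                       seed=1).probability
                 for k in range(1, 6)]
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))

    def test_subset_ci(self):
        per_locus = {f"L{j}": {1: 0.4, 2: 0.3, 3: 0.2, 4: 0.1}
                     for j in range(6)}
        res = exclusion_probability(_freq_table(per_locus), n_mc=5000, seed=2,
                                    n_subsets=200, subset_size=3)
        lo, hi = res.ci
        assert lo <= res.probability <= hi

    def test_empty_subset_errors(self):
        with pytest.raises(GenotypeTableError):
            exclusion_probability(_freq_table({"L": {1: 1.0}}), loci_subset=[],
                                  n_mc=100, seed=0)
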