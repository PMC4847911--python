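"""Pedigree-structured genotype simulator with known truth.

Emulates a multi-site microsatellite survey of a reef fish whose sites are
pools of kin-structured shoals: each site is composed of a few clusters,
each cluster of full-sib families optionally chained by a shared father
into half-sib groups.  Offspring genotypes follow Mendelian segregation
from parents drawn at Hardy-Weinberg proportions out of one shared
baseline allele-frequency distribution, so any between-site
differentiation in the output arises from family sampling alone (the
chaotic-genetic-patchiness mechanism under study), not from baseline
divergence; set ``site_divergence`` > 0 to add real frequency divergence.

Observation noise is applied in three layers: genotyping error (each gene
copy replaced, with probability e, by a random draw from the locus
frequencies), per-locus missingness, and optional null alleles (a null
copy amplifies nothing: null/null presents as missing, null/visible as an
apparent homozygote).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype import MISSING, GenotypeTable, GenotypeTableError

__all__ = ["SimulationConfig", "Truth", "simulate_study", "inject_null_alleles",
           "DEFAULT_ALLELE_COUNTS"]

# per-locus allelic richness matching a 10-locus microsatellite panel
# spanning 7-50 alleles
DEFAULT_ALLELE_COUNTS = (13, 9, 14, 24, 10, 7, 33, 19, 50, 24)


@dataclass
class SimulationConfig:
    """Study-design parameters for :func:`simulate_study`.

    Defaults mirror the surveyed design: 9 sites of 34-85 individuals,
    each split into 2-5 clusters of 8-36, 10 loci with 7-50 alleles,
    per-locus missingness drawn from 0.06-0.26, and a 1% genotyping error
    rate.  ``seed`` is mandatory.
    """

    seed: int
    n_sites: int = 9
    site_size_range: tuple[int, int] = (34, 85)
    clusters_per_site: tuple[int, int] = (2, 5)
    cluster_size_range: tuple[int, int] = (8, 36)
    family_size_range: tuple[int, int] = (2, 6)
    half_sib_prob: float = 0.5
    n_loci: int = 10
    allele_counts: tuple[int, ...] = DEFAULT_ALLELE_COUNTS
    freq_model: str = "dirichlet"  # "dirichlet" | "uniform"
    dirichlet_concentration: float = 1.0
    error_rate: float = 0.01
    missingness_range: tuple[float, float] = (0.06, 0.26)
    null_allele_freq: float | dict[str, float] = 0.0
    panmictic: bool = False
    site_divergence: float = 0.0
    # breeding adults per cluster are themselves bred from this many
    # founder genotypes, so parents within a cluster are related and their
    # offspring inbred -- the mechanism behind the within-site homozygote
    # excess that accompanies persistent kin aggregations.  None = parents
    # drawn independently from the baseline (no inbreeding).
    founder_pool_size: int | None = 4

    def __post_init__(self) -> None:
        for lo, hi in (self.site_size_range, self.clusters_per_site,
                       self.cluster_size_range, self.family_size_range):
            if lo > hi or lo < 1:
                raise GenotypeTableError("invalid range in simulation config")
        if len(self.allele_counts) != self.n_loci:
            raise GenotypeTableError("allele_counts length must equal n_loci")
        if not (0 <= self.half_sib_prob <= 1 and 0 <= self.error_rate < 1):
            raise GenotypeTableError("probabilities must lie in [0, 1]")
        lo, hi = self.missingness_range
        if not (0 <= lo <= hi <= 1):
            raise GenotypeTableError("invalid missingness range")
        if self.cluster_size_range[0] > self.site_size_range[1]:
            raise GenotypeTableError("cluster sizes exceed site sizes")


@dataclass
class Truth:
    """Ground truth: pedigree, memberships and noise bookkeeping."""

    parents: dict[str, tuple[str, str] | None]
    site_of: dict[str, str]
    cluster_of: dict[str, str]
    locus_missing_rates: dict[str, float] = field(default_factory=dict)
    null_carriers: list[tuple[str, str]] = field(default_factory=list)

    def dyad_label(self, id1: str, id2: str) -> str:
        p1, p2 = self.parents.get(id1), self.parents.get(id2)
        if p1 is None or p2 is None:
            return "U"
        shared = len(set(p1) & set(p2))
        return {2: "FS", 1: "HS", 0: "U"}[shared]

    def pedigree_r(self, id1: str, id2: str) -> float:
        return {"FS": 0.5, "HS": 0.25, "U": 0.0}[self.dyad_label(id1, id2)]


def _cluster_sizes(n: int, cfg: SimulationConfig, rng: np.random.Generator) -> list[int]:
    k_lo, k_hi = cfg.clusters_per_site
    s_lo, s_hi = cfg.cluster_size_range
    feasible = [k for k in range(k_lo, k_hi + 1) if k * s_lo <= n <= k * s_hi]
    if not feasible:
        raise GenotypeTableError(
            f"no cluster count in {cfg.clusters_per_site} can partition a site of {n} "
            f"into clusters of {cfg.cluster_size_range}"
        )
    k = int(rng.choice(feasible))
    sizes = np.full(k, s_lo)
    spare = n - k * s_lo
    while spare > 0:
        room = np.flatnonzero(sizes < s_hi)
        sizes[rng.choice(room)] += 1
        spare -= 1
    return sizes.tolist()


def _baseline_frequencies(cfg: SimulationConfig, rng: np.random.Generator):
    """Per-locus allele size vectors and global baseline frequencies."""
    sizes, freqs = [], []
    for l, k in enumerate(cfg.allele_counts):
        start = 100 + 20 * l
        sizes.append(np.arange(start, start + 2 * k, 2))
        if cfg.freq_model == "uniform":
            freqs.append(np.full(k, 1.0 / k))
        else:
            freqs.append(rng.dirichlet(np.full(k, cfg.dirichlet_concentration)))
    return sizes, freqs


def _site_coordinates(n_sites: int, rng: np.random.Generator) -> dict[str, tuple[float, float]]:
    """Sites along a reef-like arc with ~5-200 km pairwise separations."""
    lat0, lon0 = 16.2, -87.9
    coords = {}
    lat = lat0
    for s in range(n_sites):
        lat += float(rng.uniform(0.05, 0.25))  # ~5-28 km steps
        lon = lon0 + float(rng.uniform(-0.1, 0.1))
        coords[f"S{s + 1}"] = (lat, lon)
    return coords


def _draw_genotype(freq: np.ndarray, sizes: np.ndarray, rng) -> np.ndarray:
    return rng.choice(sizes, size=2, p=freq)


def simulate_study(config: SimulationConfig) -> tuple[GenotypeTable, Truth]:
    """Simulate the full study design; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    sizes, base_freqs = _baseline_frequencies(config, rng)
    coords = _site_coordinates(config.n_sites, rng)
    ids: list[str] = []
    site_labels: list[str] = []
    genotypes: list[np.ndarray] = []
    parents: dict[str, tuple[str, str] | None] = {}
    site_of: dict[str, str] = {}
    cluster_of: dict[str, str] = {}
    for s in range(config.n_sites):
        site = f"S{s + 1}"
        if config.site_divergence > 0:
            site_freqs = [
                rng.dirichlet(np.maximum(f, 1e-6) / config.site_divergence)
                for f in base_freqs
            ]
        else:
            site_freqs = base_freqs
        n_site = int(rng.integers(config.site_size_range[0], config.site_size_range[1] + 1))
        counter = 0
        for c, c_size in enumerate(_cluster_sizes(n_site, config, rng)):
            cluster = f"G{c + 1}"
            made = 0
            fam = 0
            prev_father: list[np.ndarray] | None = None
            prev_father_id: str | None = None
            founders: list[list[np.ndarray]] | None = None
            if config.founder_pool_size and not config.panmictic:
                founders = [[_draw_genotype(f, sz, rng)
                             for f, sz in zip(site_freqs, sizes)]
                            for _ in range(config.founder_pool_size)]

            def draw_parent():
                if founders is None:
                    return [_draw_genotype(f, sz, rng)
                            for f, sz in zip(site_freqs, sizes)]
                i, j = rng.choice(len(founders), size=2, replace=False)
                return [np.array([ga[rng.integers(2)], gb[rng.integers(2)]])
                        for ga, gb in zip(founders[i], founders[j])]

            while made < c_size:
                fam += 1
                fam_size = int(rng.integers(config.family_size_range[0],
                                            config.family_size_range[1] + 1))
                fam_size = min(fam_size, c_size - made)
                mother = draw_parent()
                mother_id = f"{site}{cluster}M{fam}"
                if (prev_father is not None and fam > 1
                        and rng.random() < config.half_sib_prob):
                    father, father_id = prev_father, prev_father_id
                else:
                    father = draw_parent()
                    father_id = f"{site}{cluster}F{fam}"
                prev_father, prev_father_id = father, father_id
                for _ in range(fam_size):
                    counter += 1
                    ind = f"{site}_{counter:03d}"
                    if config.panmictic:
                        g = np.vstack([
                            _draw_genotype(f, sz, rng)
                            for f, sz in zip(site_freqs, sizes)
                        ])
                        parents[ind] = None
                    else:
                        g = np.vstack([
                            [m[rng.integers(2)], f[rng.integers(2)]]
                            for m, f in zip(mother, father)
                        ])
                        parents[ind] = (mother_id, father_id)
                    ids.append(ind)
                    site_labels.append(site)
                    site_of[ind] = site
                    cluster_of[ind] = f"{site}-{cluster}"
                    genotypes.append(g)
                    made += 1
    alleles = np.stack(genotypes)  # (n, L, 2)
    n, n_loci, _ = alleles.shape
    # genotyping error: frequency-weighted allele substitution per gene copy
    if config.error_rate > 0:
        for l in range(n_loci):
            err = rng.random((n, 2)) < config.error_rate
            k = err.sum()
            if k:
                alleles[:, l, :][err] = rng.choice(sizes[l], size=k, p=base_freqs[l])
    # per-locus missingness
    miss_rates: dict[str, float] = {}
    loci = [f"L{l + 1:02d}" for l in range(n_loci)]
    lo, hi = config.missingness_range
    pre_mask = alleles.copy()
    for l, locus in enumerate(loci):
        rate = float(rng.uniform(lo, hi))
        miss_rates[locus] = rate
        mask = rng.random(n) < rate
        alleles[mask, l, :] = MISSING
    # never leave an individual with zero scored loci: unmask one at random
    all_missing = (alleles == MISSING).all(axis=2).all(axis=1)
    for i in np.flatnonzero(all_missing):
        l = int(rng.integers(n_loci))
        alleles[i, l, :] = pre_mask[i, l, :]
    table = GenotypeTable(
        ids=ids,
        sites=np.asarray(site_labels, object),
        loci=loci,
        alleles=np.sort(alleles, axis=2),
        coords={s: coords[s] for s in dict.fromkeys(site_labels)},
    )
    truth = Truth(parents=parents, site_of=site_of, cluster_of=cluster_of,
                  locus_missing_rates=miss_rates)
    null = config.null_allele_freq
    if isinstance(null, dict):
        for locus, f_null in null.items():
            if f_null > 0:
                table, carriers = _apply_nulls(table, locus, f_null, rng)
                truth.null_carriers.extend(carriers)
    elif null > 0:
        for locus in loci:
            table, carriers = _apply_nulls(table, locus, float(null), rng)
            truth.null_carriers.extend(carriers)
    return table, truth


def simulate_dyads(
    relationship: str,
    n_dyads: int,
    config: SimulationConfig,
) -> tuple[GenotypeTable, Truth]:
    """Independent dyads of a known pedigree class for recovery checks.

    ``relationship`` is "FS", "HS" or "U".  Parents are drawn unrelated
    from the baseline, so the pedigree r is exactly 0.5 / 0.25 / 0.
    Error and missingness follow the config; founder pooling and site
    structure do not apply.
    """
    if relationship not in ("FS", "HS", "U"):
        raise GenotypeTableError("relationship must be FS, HS or U")
    rng = np.random.default_rng(config.seed)
    sizes, freqs = _baseline_frequencies(config, rng)
    n_loci = len(sizes)
    ids, genotypes = [], []
    parents: dict[str, tuple[str, str] | None] = {}
    for d in range(n_dyads):
        mother = [_draw_genotype(f, sz, rng) for f, sz in zip(freqs, sizes)]
        father = [_draw_genotype(f, sz, rng) for f, sz in zip(freqs, sizes)]
        if relationship == "U":
            others = [None, None]
        elif relationship == "FS":
            others = [(mother, father), (mother, father)]
        else:  # HS: shared mother, different fathers
            father2 = [_draw_genotype(f, sz, rng) for f, sz in zip(freqs, sizes)]
            others = [(mother, father), (mother, father2)]
        for member, par in zip("ab", others):
            ind = f"D{d + 1}{member}"
            if par is None:
                g = np.vstack([_draw_genotype(f, sz, rng)
                               for f, sz in zip(freqs, sizes)])
                parents[ind] = None
            else:
                mo, fa = par
                g = np.vstack([[m[rng.integers(2)], f[rng.integers(2)]]
                               for m, f in zip(mo, fa)])
                parents[ind] = (f"M{d + 1}", f"F{d + 1}{member if relationship == 'HS' else ''}")
            ids.append(ind)
            genotypes.append(g)
    alleles = np.stack(genotypes)
    n = len(ids)
    if config.error_rate > 0:
        for l in range(n_loci):
            err = rng.random((n, 2)) < config.error_rate
            k = err.sum()
            if k:
                alleles[:, l, :][err] = rng.choice(sizes[l], size=k, p=freqs[l])
    lo, hi = config.missingness_range
    loci = [f"L{l + 1:02d}" for l in range(n_loci)]
    pre_mask = alleles.copy()
    for l in range(n_loci):
        rate = float(rng.uniform(lo, hi))
        mask = rng.random(n) < rate
        alleles[mask, l, :] = MISSING
    all_missing = (alleles == MISSING).all(axis=2).all(axis=1)
    for i in np.flatnonzero(all_missing):
        l = int(rng.integers(n_loci))
        alleles[i, l, :] = pre_mask[i, l, :]
    table = GenotypeTable(ids=ids, sites=np.asarray(["DY"] * n, object),
                          loci=loci, alleles=np.sort(alleles, axis=2))
    truth = Truth(parents=parents, site_of={i: "DY" for i in ids},
                  cluster_of={i: "DY" for i in ids})
    return table, truth


def _apply_nulls(table: GenotypeTable, locus: str, f_null: float, rng):
    j = table.locus_index(locus)
    alleles = table.alleles.copy()
    carriers = []
    for i in range(table.n_individuals):
        a, b = alleles[i, j]
        if a == MISSING:
            continue
        null_a = rng.random() < f_null
        null_b = rng.random() < f_null
        if null_a and null_b:
            alleles[i, j] = MISSING
        elif null_a:
            alleles[i, j] = (b, b)
        elif null_b:
            alleles[i, j] = (a, a)
        if null_a or null_b:
            carriers.append((table.ids[i], locus))
    out = GenotypeTable(ids=list(table.ids), sites=table.sites.copy(),
                        loci=list(table.loci), alleles=alleles, coords=table.coords)
    return out, carriers


def inject_null_alleles(
    table: GenotypeTable,
    locus: str,
    null_frequency: float,
    seed: int | None = None,
) -> GenotypeTable:
    """Convert gene copies to nulls at one locus.

    Each copy independently becomes null with probability
    ``null_frequency``: null/null presents as missing, null/visible as an
    apparent homozygote for the visible allele.
    """
    if not 0.0 <= null_frequency <= 1.0:
        raise GenotypeTableError("null_frequency must lie in [0, 1]")
    if null_frequency == 0.0:
        return table
    rng = np.random.default_rng(seed)
    out, _ = _apply_nulls(table, locus, null_frequency, rng)
    return out
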