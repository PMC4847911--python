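"""Pairwise between-site differentiation and isolation-by-distance.

Two multilocus distances are computed between every pair of sites:

* ``P_D`` — the proportion of different alleles, defined at the
  population-frequency level as ``1 - (1/L) * sum_l sum_a min(p_a^A, p_a^B)``
  over loci scored in both sites (the shared-allele proportion is the
  Manhattan overlap of the two frequency vectors);
* ``F_ST`` — Weir-Cockerham theta by default (ratio-of-sums of the a, b, c
  variance components across loci and alleles), with a Nei G_ST-style
  option.  Negative estimates are reported as computed.

Significance is a conditional permutation test: for each pair, individuals
are permuted between the two sites only (preserving sample sizes), with the
add-one rule and Holm (sequential Bonferroni) correction across pairs.
Isolation-by-distance is a Mantel test of the genetic matrix against
great-circle distances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genotype import GenotypeTable, GenotypeTableError
from .results import TestResult

__all__ = [
    "DistanceMatrices",
    "pairwise_pd",
    "pairwise_fst",
    "differentiation_significance",
    "great_circle_distances",
    "mantel_test",
]

EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrices:
    """Bundle of pairwise site matrices (genetic, geographic, significance)."""

    sites: list[str]
    pd_matrix: pd.DataFrame
    fst_matrix: pd.DataFrame
    geographic: pd.DataFrame | None
    p_values: dict[str, pd.DataFrame]
    correction: str


# -- per-pair statistic engine --------------------------------------------

def _locus_arrays(pair_table: GenotypeTable):
    """Per-locus dosage/heterozygote/scored arrays for the stat engine."""
    out = []
    miss = pair_table.missing_mask()
    for j in range(len(pair_table.loci)):
        ok = ~miss[:, j]
        pairs = pair_table.alleles[:, j, :]
        uniq = np.unique(pairs[ok])
        if uniq.size == 0:
            out.append(None)
            continue
        lookup = {int(a): i for i, a in enumerate(uniq)}
        k = uniq.size
        dos = np.zeros((pair_table.n_individuals, k))
        het_a = np.zeros((pair_table.n_individuals, k))
        for i in np.flatnonzero(ok):
            a, b = int(pairs[i, 0]), int(pairs[i, 1])
            dos[i, lookup[a]] += 1
            dos[i, lookup[b]] += 1
            if a != b:
                het_a[i, lookup[a]] = 1
                het_a[i, lookup[b]] = 1
        out.append((dos, het_a, ok.astype(float)))
    return out


def _pair_stats(arrays, member: np.ndarray, statistic: str, estimator: str) -> np.ndarray:
    """Statistic per membership row.

    ``member`` is (R, n) with 1 where the individual is assigned to the
    first site of the pair.  Row 0 is conventionally the observed split.
    """
    r_rows = member.shape[0]
    if statistic == "fst" and estimator == "weir_cockerham":
        num = np.zeros(r_rows)
        den = np.zeros(r_rows)
    elif statistic == "fst":
        num = np.zeros(r_rows)
        den = np.zeros(r_rows)
    else:
        shared = np.zeros(r_rows)
        n_loci = np.zeros(r_rows)
    for entry in arrays:
        if entry is None:
            continue
        dos, het_a, ok = entry
        tot_dos = dos.sum(axis=0)
        tot_het = het_a.sum(axis=0)
        tot_n = ok.sum()
        n1 = member @ ok
        n2 = tot_n - n1
        valid = (n1 >= 1) & (n2 >= 1)
        n1s = np.where(valid, n1, 1.0)
        n2s = np.where(valid, n2, 1.0)
        c1 = member @ dos
        c2 = tot_dos[None, :] - c1
        p1 = c1 / (2.0 * n1s[:, None])
        p2 = c2 / (2.0 * n2s[:, None])
        if statistic == "pd":
            shared += np.where(valid, np.minimum(p1, p2).sum(axis=1), 0.0)
            n_loci += valid
            continue
        if estimator == "nei":
            hs = 1.0 - 0.5 * ((p1 ** 2).sum(axis=1) + (p2 ** 2).sum(axis=1))
            pbar = 0.5 * (p1 + p2)
            ht = 1.0 - (pbar ** 2).sum(axis=1)
            num += np.where(valid, ht - hs, 0.0)
            den += np.where(valid, ht, 0.0)
            continue
        # Weir-Cockerham components, r = 2 populations
        nbar = 0.5 * (n1 + n2)
        nbar_s = np.where(nbar > 1, nbar, 2.0)
        nc = 2.0 * nbar - (n1 ** 2 + n2 ** 2) / (2.0 * nbar_s)
        nc = np.where(nc > 0, nc, 1.0)
        pbar_a = (c1 + c2) / (2.0 * (n1s + n2s))[:, None]
        s2 = (n1s[:, None] * (p1 - pbar_a) ** 2 + n2s[:, None] * (p2 - pbar_a) ** 2) / nbar_s[:, None]
        # heterozygote-for-allele totals are conserved by permutation
        hbar = (tot_het[None, :]) / (n1s + n2s)[:, None]
        inner = pbar_a * (1 - pbar_a) - 0.5 * s2
        a_c = (nbar_s / nc)[:, None] * (s2 - (inner - 0.25 * hbar) / (nbar_s - 1.0)[:, None])
        b_c = (nbar_s / (nbar_s - 1.0))[:, None] * (inner - ((2 * nbar_s - 1) / (4 * nbar_s))[:, None] * hbar)
        c_c = 0.5 * hbar
        ok_rows = valid & (nbar > 1)
        num += np.where(ok_rows, a_c.sum(axis=1), 0.0)
        den += np.where(ok_rows, (a_c + b_c + c_c).sum(axis=1), 0.0)
    if statistic == "pd":
        with np.errstate(invalid="ignore"):
            return np.where(n_loci > 0, 1.0 - shared / np.maximum(n_loci, 1), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den != 0, num / den, np.nan)


def _pair_engine(table: GenotypeTable, site_a: str, site_b: str,
                 statistic: str, estimator: str,
                 n_perm: int = 0, rng: np.random.Generator | None = None):
    sel = (table.sites == site_a) | (table.sites == site_b)
    pair = table.subset(sel)
    arrays = _locus_arrays(pair)
    in_a = (pair.sites == site_a).astype(float)
    n_a = int(in_a.sum())
    rows = [in_a]
    if n_perm:
        assert rng is not None
        base = np.zeros(pair.n_individuals)
        for _ in range(n_perm):
            perm = base.copy()
            perm[rng.choice(pair.n_individuals, n_a, replace=False)] = 1.0
            rows.append(perm)
    member = np.vstack(rows)
    return _pair_stats(arrays, member, statistic, estimator)


# -- public matrices -------------------------------------------------------

def _site_pairs(table: GenotypeTable) -> list[tuple[str, str]]:
    sites = table.site_labels
    if len(sites) < 2:
        raise GenotypeTableError("need >= 2 sites for differentiation")
    return list(itertools.combinations(sites, 2))


def _empty_matrix(sites: list[str]) -> pd.DataFrame:
    m = pd.DataFrame(np.zeros((len(sites), len(sites))), index=sites, columns=sites)
    return m


def pairwise_pd(table: GenotypeTable) -> pd.DataFrame:
    """Pairwise proportion-of-different-alleles matrix (symmetric, 0 diagonal)."""
    sites = table.site_labels
    m = _empty_matrix(sites)
    for a, b in _site_pairs(table):
        v = float(_pair_engine(table, a, b, "pd", "")[0])
        m.loc[a, b] = m.loc[b, a] = v
    return m


def pairwise_fst(table: GenotypeTable, estimator: str = "weir_cockerham") -> pd.DataFrame:
    """Pairwise multilocus F_ST matrix (ratio-of-sums across loci)."""
    if estimator not in ("weir_cockerham", "nei"):
        raise ValueError("estimator must be 'weir_cockerham' or 'nei'")
    sites = table.site_labels
    m = _empty_matrix(sites)
    for a, b in _site_pairs(table):
        v = float(_pair_engine(table, a, b, "fst", estimator)[0])
        m.loc[a, b] = m.loc[b, a] = v
    return m


def differentiation_significance(
    table: GenotypeTable,
    statistic: str = "fst",
    estimator: str = "weir_cockerham",
    n_perm: int = 10_000,
    seed: int | None = None,
    correction: str = "sequential_bonferroni",
) -> dict[str, pd.DataFrame]:
    """Per-pair permutation p-values with Holm step-down correction.

    For each site pair the two samples' individuals are pooled and
    re-split at the observed sample sizes; p = add-one upper-tail
    probability of a permuted statistic >= observed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if statistic not in ("fst", "pd"):
        raise ValueError("statistic must be 'fst' or 'pd'")
    sites = table.site_labels
    pairs = _site_pairs(table)
    rng = np.random.default_rng(seed)
    observed = _empty_matrix(sites)
    raw = _empty_matrix(sites)
    raw[:] = np.nan
    np.fill_diagonal(raw.values, np.nan)
    raw_flat = []
    for a, b in pairs:
        stats = _pair_engine(table, a, b, statistic, estimator, n_perm=n_perm, rng=rng)
        obs, null = stats[0], stats[1:]
        null = null[np.isfinite(null)]
        p = (int((null >= obs - 1e-12).sum()) + 1) / (len(null) + 1)
        observed.loc[a, b] = observed.loc[b, a] = obs
        raw.loc[a, b] = raw.loc[b, a] = p
        raw_flat.append(p)
    adj = _empty_matrix(sites)
    adj[:] = np.nan
    if correction == "sequential_bonferroni":
        adj_flat = multipletests(raw_flat, method="holm")[1]
    elif correction == "none":
        adj_flat = np.asarray(raw_flat)
    else:
        raise ValueError(f"unknown correction {correction!r}")
    for (a, b), p in zip(pairs, adj_flat):
        adj.loc[a, b] = adj.loc[b, a] = p
    return {"statistic": observed, "p_raw": raw, "p_adjusted": adj}


def great_circle_distances(coords: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Haversine distance matrix in km (Earth radius 6371.0088 km)."""
    sites = list(coords)
    for s, (lat, lon) in coords.items():
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise GenotypeTableError(f"coordinates out of range for site {s!r}")
    lat = np.radians([coords[s][0] for s in sites])
    lon = np.radians([coords[s][1] for s in sites])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=sites, columns=sites)


def mantel_test(
    d_genetic: pd.DataFrame | np.ndarray,
    d_geographic: pd.DataFrame | np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Mantel correlation with simultaneous row/column permutation.

    r is the Pearson correlation of the lower-triangle entries; p is the
    add-one upper-tail probability of a permuted r >= observed (the
    isolation-by-distance alternative is positive correlation).
    """
    x = np.asarray(d_genetic, float)
    y = np.asarray(d_geographic, float)
    if x.shape != y.shape or x.shape[0] != x.shape[1]:
        raise GenotypeTableError("distance matrices must be square and conformable")
    if not (np.allclose(x, x.T, equal_nan=True) and np.allclose(y, y.T, equal_nan=True)):
        raise GenotypeTableError("distance matrices must be symmetric")
    n = x.shape[0]
    tri = np.tril_indices(n, k=-1)
    xv = x[tri]
    if np.std(xv) == 0 or np.std(y[tri]) == 0:
        raise GenotypeTableError("constant distance matrix: Mantel r undefined")
    rng = np.random.default_rng(seed)

    def corr(mat: np.ndarray) -> float:
        return float(np.corrcoef(xv, mat[tri])[0, 1])

    r_obs = corr(y)
    hits = 0
    for _ in range(n_perm):
        order = rng.permutation(n)
        if corr(y[np.ix_(order, order)]) >= r_obs - 1e-12:
            hits += 1
    return TestResult(r_obs, (hits + 1) / (n_perm + 1), n_perm, "upper", seed)
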